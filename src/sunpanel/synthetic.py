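"""Synthetic inbred-line SNP panel generator.

Panels are built from a small set of founder haplotypes per linkage group:
each accession is a mosaic of founder segments (recombination breakpoints
drawn from a Poisson process along the cM map), made near-fully homozygous
— the structure expected for a pedigree-derived inbred collection whose
signal is shared haplotype blocks.  Two divergent breeding pools are
created by applying pool-specific allele-frequency offsets on the logit
scale, and a localized selective sweep can be planted by near-fixing one
designated founder haplotype across a configured cM interval in one pool.
Residual heterozygosity and missing calls are injected at configured rates.

Default dimensions emulate a diverse cultivated sunflower association
panel: 271 accessions (100 maintainer HA, 125 restorer RHA, 46 other) by
17 linkage groups x 340 markers (= 5,780 SNPs), observed heterozygosity
around 0.03, genome-wide between-pool F_ST near 0.05, and a ~25 cM sweep
on linkage group 10 carried at high frequency by the restorer pool.

Phenotypes are simulated at plant level with a major-locus + polygenic
architecture, location main effects, genotype-by-environment noise, and
rep/block design effects, and emitted in long format
(accession, location, rep, block, plant, trait, value).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    PanelMetadata,
)

#: Sentinel marker name: resolve to the marker nearest the sweep midpoint.
SWEEP_LOCUS = "@sweep"


class ConfigError(ValueError):
    pass


@dataclass
class SweepConfig:
    """A localized selective sweep: one founder haplotype near-fixed in one
    pool across a cM interval."""

    linkage_group: int = 10
    start_cM: float = 10.0
    end_cM: float = 35.0
    swept_pool: str = "RHA"
    sweep_frequency: float = 0.95


@dataclass
class TraitConfig:
    """Architecture of one simulated trait.

    ``polygenic_h2`` is the broad-sense heritability of the polygenic
    component at the entry-by-location mean level (excluding the major
    locus); ``gxe_sd`` is the SD of the accession-by-location interaction;
    plant-level noise has unit variance.
    """

    name: str = "trait"
    major_locus: str | None = None  # marker id or SWEEP_LOCUS or None
    major_effect: float = 0.0
    polygenic_h2: float = 0.4
    gxe_sd: float = 0.3
    n_locations: int = 3
    n_reps: int = 2
    n_plants: int = 4
    intercept: float = 10.0
    plant_noise_sd: float = 1.0
    design_sd: float = 0.3      # SD of rep and block-within-rep effects


def _default_pools() -> dict[str, int]:
    return {"HA": 100, "RHA": 125, "other": 46}


def _default_traits() -> list[TraitConfig]:
    return [
        TraitConfig(name="branching", major_locus=SWEEP_LOCUS,
                    major_effect=1.0, polygenic_h2=0.4, gxe_sd=0.3),
        TraitConfig(name="dtf", major_locus=None, major_effect=0.0,
                    polygenic_h2=0.12, gxe_sd=0.8, intercept=60.0),
    ]


@dataclass
class SimulationConfig:
    """Full description of a synthetic panel; the seed determines all output."""

    seed: int = 0
    n_per_pool: dict[str, int] = field(default_factory=_default_pools)
    n_linkage_groups: int = 17
    markers_per_group: int = 340
    map_length_cM: float = 100.0
    pool_divergence: float = 0.5
    residual_het_rate: float = 0.03
    missing_rate: float = 0.01
    sweep: SweepConfig | None = field(default_factory=SweepConfig)
    n_founder_haplotypes: int = 12
    crossovers_per_morgan: float = 3.0
    trait_configs: list[TraitConfig] = field(default_factory=_default_traits)

    def validate(self) -> None:
        for r, name in ((self.residual_het_rate, "residual_het_rate"),
                        (self.missing_rate, "missing_rate")):
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{name}={r} outside [0,1]")
        if self.pool_divergence < 0:
            raise ConfigError("pool_divergence must be >= 0")
        if self.n_founder_haplotypes < 2:
            raise ConfigError("need at least 2 founder haplotypes")
        if min(self.n_per_pool.values()) < 1:
            raise ConfigError("each pool needs at least one accession")
        unknown = set(self.n_per_pool) - {"HA", "RHA", "other"}
        if unknown:
            raise ConfigError(f"unknown pools {sorted(unknown)}")
        if self.sweep is not None:
            s = self.sweep
            if not (0.0 <= s.sweep_frequency <= 1.0):
                raise ConfigError("sweep_frequency outside [0,1]")
            if not (0 <= s.start_cM < s.end_cM <= self.map_length_cM):
                raise ConfigError("sweep interval outside the map")
            if s.linkage_group not in range(1, self.n_linkage_groups + 1):
                raise ConfigError("sweep linkage group outside the map")
            if s.swept_pool not in self.n_per_pool:
                raise ConfigError(f"swept pool {s.swept_pool!r} not simulated")
        for t in self.trait_configs:
            if not 0.0 <= t.polygenic_h2 < 1.0:
                raise ConfigError(
                    f"trait {t.name}: polygenic_h2 outside [0,1)"
                )
            if t.gxe_sd < 0:
                raise ConfigError(f"trait {t.name}: gxe_sd < 0")


@dataclass
class PanelTruth:
    """Generative ground truth, for tests and calibration studies."""

    base_freqs: np.ndarray            # per-marker founder-draw frequency
    pool_freqs: dict[str, np.ndarray]  # realized per-pool allele frequency
                                       # (founder-usage weighted)
    founder_of: np.ndarray            # accessions x markers founder index
    sweep_markers: np.ndarray         # boolean mask over markers
    sweep_carriers: np.ndarray        # boolean mask over accessions
    major_loci: dict[str, str | None] = field(default_factory=dict)
    target_pool_freqs: dict[str, np.ndarray] | None = None  # logit targets


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_panel(
    cfg: SimulationConfig, return_truth: bool = False
) -> tuple[GenotypeMatrix, GeneticMap, PanelMetadata] | tuple[
        GenotypeMatrix, GeneticMap, PanelMetadata, PanelTruth]:
    """Simulate a genotype panel, its genetic map and its metadata.

    Identical configs (including seed) give byte-identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))

    n_lg = cfg.n_linkage_groups
    m_per = cfg.markers_per_group
    n_markers = n_lg * m_per

    # --- map: sorted uniform positions per linkage group
    lgs = np.repeat(np.arange(1, n_lg + 1), m_per)
    positions = np.concatenate(
        [np.sort(rng.uniform(0.0, cfg.map_length_cM, size=m_per))
         for _ in range(n_lg)]
    )
    marker_ids = [f"LG{g:02d}_M{i:04d}"
                  for g in range(1, n_lg + 1) for i in range(m_per)]
    gmap = GeneticMap(pd.DataFrame(
        {"linkage_group": lgs, "position_cM": positions},
        index=pd.Index(marker_ids, name="marker_id"),
    ))

    # --- accessions
    pools: list[str] = []
    acc_ids: list[str] = []
    for pool in ("HA", "RHA", "other"):
        k = cfg.n_per_pool.get(pool, 0)
        for i in range(k):
            acc_ids.append(f"{pool}_{i + 1:03d}")
            pools.append(pool)
    pools_arr = np.array(pools)
    n_acc = len(acc_ids)

    # --- founder haplotypes; array-ascertained SNPs skew toward common
    # variants, so founder-draw frequencies avoid the rare tail
    base_p = rng.uniform(0.1, 0.9, size=n_markers)
    founders = (rng.random((cfg.n_founder_haplotypes, n_markers))
                < base_p).astype(np.int8)
    # skewed founder usage: elite panels trace to a few key ancestors
    founder_w = 1.0 / np.arange(1, cfg.n_founder_haplotypes + 1)
    founder_w /= founder_w.sum()

    # --- mosaic assignment of founder segments along each linkage group
    founder_of = np.empty((n_acc, n_markers), dtype=np.int16)
    lg_slices = [slice(g * m_per, (g + 1) * m_per) for g in range(n_lg)]
    xo_rate = cfg.map_length_cM / 100.0 * cfg.crossovers_per_morgan
    for a in range(n_acc):
        for sl in lg_slices:
            pos = positions[sl]
            n_break = rng.poisson(xo_rate)
            breaks = np.sort(rng.uniform(0.0, cfg.map_length_cM, size=n_break))
            seg_of_marker = np.searchsorted(breaks, pos)
            seg_founders = rng.choice(cfg.n_founder_haplotypes,
                                      size=n_break + 1, p=founder_w)
            founder_of[a, sl] = seg_founders[seg_of_marker]

    # --- pool-specific allele-frequency offsets on the logit scale,
    # applied at the founder-by-pool level: each pool carries its own
    # variant of every founder haplotype, flipped toward the pool's target
    # frequency.  This differentiates the pools while preserving the
    # shared-haplotype block structure within each pool.
    delta = (rng.normal(0.0, np.sqrt(cfg.pool_divergence), size=n_markers)
             if cfg.pool_divergence > 0 else np.zeros(n_markers))
    pool_freqs = {
        "HA": _expit(_logit(base_p) + delta / 2.0),
        "RHA": _expit(_logit(base_p) - delta / 2.0),
        "other": base_p.copy(),
    }
    pool_founders = {}
    for pool in ("HA", "RHA", "other"):
        pt = pool_freqs[pool]
        up = np.clip((pt - base_p) / np.maximum(1.0 - base_p, 1e-12), 0, 1)
        down = np.clip((base_p - pt) / np.maximum(base_p, 1e-12), 0, 1)
        f = founders.copy()
        u = rng.random(f.shape)
        flip_up = (f == 0) & (u < up[None, :])
        flip_down = (f == 1) & (u < down[None, :])
        pool_founders[pool] = np.where(
            flip_up, 1, np.where(flip_down, 0, f)).astype(np.int8)

    allele = np.empty((n_acc, n_markers), dtype=np.int8)
    marker_idx = np.arange(n_markers)
    for pool in ("HA", "RHA", "other"):
        rows = np.flatnonzero(pools_arr == pool)
        if rows.size:
            allele[rows] = pool_founders[pool][
                founder_of[rows], marker_idx[None, :]]

    # --- sweep: near-fixation of one founder haplotype in one pool
    sweep_markers = np.zeros(n_markers, dtype=bool)
    sweep_carriers = np.zeros(n_acc, dtype=bool)
    if cfg.sweep is not None:
        s = cfg.sweep
        sweep_markers = (
            (lgs == s.linkage_group)
            & (positions >= s.start_cM) & (positions < s.end_cM)
        )
        rows = np.flatnonzero(pools_arr == s.swept_pool)
        carriers = rows[rng.random(rows.size) < s.sweep_frequency]
        sweep_carriers[carriers] = True
        allele[np.ix_(carriers, np.flatnonzero(sweep_markers))] = \
            pool_founders[s.swept_pool][0, sweep_markers]

    dosage = (2 * allele).astype(np.int8)

    # --- residual heterozygosity, concentrated in the non-elite pool
    # (open-pollinated / introgressed material is far less inbred than
    # elite maintainer and restorer lines); the panel-wide mean rate
    # equals residual_het_rate
    if cfg.residual_het_rate > 0:
        other_mult = 8.0
        n_other = int((pools_arr == "other").sum())
        n_elite = n_acc - n_other
        base_rate = cfg.residual_het_rate * n_acc / (
            n_elite + other_mult * n_other)
        acc_rate = np.where(pools_arr == "other",
                            min(other_mult * base_rate, 1.0), base_rate)
        het = rng.random(dosage.shape) < acc_rate[:, None]
        dosage[het] = 1
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = MISSING

    class_of = {"HA": "HA-Oil", "RHA": "RHA-Oil", "other": "Other"}
    meta = PanelMetadata(pd.DataFrame(
        {"class_label": [class_of[p] for p in pools], "pool": pools},
        index=pd.Index(acc_ids, name="accession_id"),
    ))

    g = GenotypeMatrix(acc_ids, marker_ids, dosage, gmap)
    if not return_truth:
        return g, gmap, meta
    realized_freqs = {pool: founder_w @ pool_founders[pool]
                      for pool in pool_founders}
    truth = PanelTruth(
        base_freqs=base_p, pool_freqs=realized_freqs,
        target_pool_freqs=pool_freqs, founder_of=founder_of,
        sweep_markers=sweep_markers, sweep_carriers=sweep_carriers,
        major_loci={t.name: resolve_major_locus(t, gmap, cfg, g)
                    for t in cfg.trait_configs},
    )
    return g, gmap, meta, truth


def resolve_major_locus(
    trait: TraitConfig, gmap: GeneticMap, cfg: SimulationConfig,
    g: GenotypeMatrix | None = None,
) -> str | None:
    """Resolve a trait's major-locus marker id.

    :data:`SWEEP_LOCUS` picks the mapped marker closest to the
    sweep-interval midpoint; when a genotype matrix is supplied, markers
    with panel MAF < 0.10 are skipped so the planted causal variant is a
    common polymorphism (as a major-gene locus segregating between
    breeding pools would be) rather than a near-fixed one.
    """
    if trait.major_locus is None:
        return None
    if trait.major_locus != SWEEP_LOCUS:
        return trait.major_locus
    if cfg.sweep is None:
        return None
    s = cfg.sweep
    tab = gmap.table
    on_lg = tab[(tab["linkage_group"] == s.linkage_group)
                & (tab["position_cM"] >= s.start_cM)
                & (tab["position_cM"] < s.end_cM)]
    if on_lg.empty:
        on_lg = tab[tab["linkage_group"] == s.linkage_group]
    mid = 0.5 * (s.start_cM + s.end_cM)
    ranked = (on_lg["position_cM"] - mid).abs().sort_values().index
    if g is not None:
        from .panel_io import compute_allele_frequencies

        maf = compute_allele_frequencies(g)["maf"]
        for marker in ranked:
            if maf.get(marker, 0.0) >= 0.10:
                return marker
    return ranked[0]


def simulate_phenotypes(
    g: GenotypeMatrix, cfg: SimulationConfig
) -> pd.DataFrame:
    """Simulate long-format plant-level phenotypes for the configured traits.

    Plant value = intercept + major effect x dosage + polygenic value +
    location effect + GxE deviation + rep effect + block effect + unit
    plant noise.  The polygenic value is a dosage-weighted sum of random
    marker effects rescaled so that, with unit plant noise and the
    configured design, its share of entry-by-location mean variance equals
    ``polygenic_h2``.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    if g.gmap is None:
        raise ConfigError("genotype matrix needs an attached map")

    n = g.n_accessions
    x = g.dosage_float()
    col_mean = np.nanmean(x, axis=0)
    filled = np.where(np.isnan(x), col_mean[None, :], x)

    rows = []
    n_blocks = max(2, n // 30)
    for trait in cfg.trait_configs:
        locus = resolve_major_locus(trait, g.gmap, cfg, g)
        if locus is not None and locus not in g.marker_ids:
            raise ConfigError(f"major locus {locus!r} not in the panel")
        major = (filled[:, g.marker_indexer([locus])[0]]
                 if locus is not None else np.zeros(n))

        # polygenic entry values, rescaled to the target entry-mean h2
        h2 = trait.polygenic_h2
        if h2 > 0:
            b = rng.normal(0.0, 1.0, size=g.n_markers)
            u = (filled - col_mean[None, :]) @ b
            sd = u.std()
            resid_var = (
                trait.gxe_sd ** 2
                + trait.plant_noise_sd ** 2 / (trait.n_reps * trait.n_plants)
                + trait.design_sd ** 2 / trait.n_reps
            )
            target_var = (h2 / (1.0 - h2) * resid_var) if resid_var > 0 \
                else h2 / (1.0 - h2)
            u = u / (sd if sd > 0 else 1.0) * np.sqrt(target_var)
        else:
            u = np.zeros(n)
        entry_value = trait.intercept + trait.major_effect * major + u

        loc_effects = rng.normal(0.0, 1.0, size=trait.n_locations)
        gxe = (rng.normal(0.0, trait.gxe_sd,
                          size=(n, trait.n_locations))
               if trait.gxe_sd > 0 else np.zeros((n, trait.n_locations)))

        for li in range(trait.n_locations):
            loc = f"L{li + 1}"
            for rep in range(1, trait.n_reps + 1):
                rep_eff = rng.normal(0.0, trait.design_sd) \
                    if trait.design_sd > 0 else 0.0
                block_of = rng.integers(1, n_blocks + 1, size=n)
                block_eff = (rng.normal(0.0, trait.design_sd, size=n_blocks)
                             if trait.design_sd > 0 else np.zeros(n_blocks))
                noise = rng.normal(0.0, trait.plant_noise_sd,
                                   size=(n, trait.n_plants))
                base = (entry_value + loc_effects[li] + gxe[:, li]
                        + rep_eff + block_eff[block_of - 1])
                for pi in range(trait.n_plants):
                    vals = base + noise[:, pi]
                    rows.append(pd.DataFrame({
                        "accession_id": g.accession_ids,
                        "location": loc,
                        "rep": rep,
                        "block": block_of,
                        "plant": pi + 1,
                        "trait": trait.name,
                        "value": vals,
                    }))
    return pd.concat(rows, ignore_index=True)
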