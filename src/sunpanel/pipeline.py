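"""End-to-end orchestration of the panel analysis.

One config and one seed drive the full study analogue: simulate (or load)
a panel, then run diversity, LD, differentiation, structure/kinship,
phenotype summaries, per-location association scans and graphical
genotypes, writing every output as TSV plus a JSON manifest of artifact
hashes, parameters and the per-stage child seeds.  The global seed fans
out to fixed per-stage child seeds through ``numpy.random.SeedSequence``
spawn keys, so disabling one stage never shifts another stage's
randomness and a rerun with the same config reproduces every output
hash-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, differentiation, diversity, ld, painting, phenotypes
from . import structure as structure_mod
from .panel_io import (
    GeneticMap, GenotypeMatrix, PanelMetadata, filter_by_maf,
)
from .synthetic import (
    SimulationConfig, SweepConfig, TraitConfig,
    simulate_panel, simulate_phenotypes,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "diversity", "ld", "fst", "structure",
              "pheno", "assoc", "paint")

# fixed spawn keys: one per stage, independent of which stages run
_STAGE_KEYS = {name: (i + 10,) for i, name in enumerate(ALL_STAGES)}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "sunpanel_out"
    simulation: SimulationConfig | None = None
    genotype_path: str | None = None
    map_path: str | None = None
    metadata_path: str | None = None
    phenotype_path: str | None = None
    maf_threshold: float = 0.10
    window_width_cM: float = 5.0
    window_step_cM: float = 1.0
    ld_bandwidth_cM: float = 2.0
    ld_r2_threshold: float = 0.1
    ld_n_pairs: int = 10000
    ld_max_distance_cM: float = 50.0
    pools: tuple[str, str] = ("RHA", "HA")
    n_permutations: int = 1000
    outlier_q: float = 0.05
    kinship_estimator: str = "loiselle"
    models: tuple[str, ...] = ("naive", "k", "pk")
    n_pcs: int = 2
    q_matrix_path: str | None = None
    alpha: float = 0.05
    meff_c: float = 0.995
    lsmean_traits: tuple[str, ...] = ("dtf",)  # others use raw means
    paint_min_block: int = 25
    paint_cycles: int = 25
    stages: tuple[str, ...] = ALL_STAGES

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(self.seed, spawn_key=_STAGE_KEYS[stage])
        return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, stage: str,
           index: bool = False, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format="%.6g")
    manifest["artifacts"].append(
        {"stage": stage, "path": path.name, "sha256": _sha256(path)}
    )


def load_pipeline_config(path) -> PipelineConfig:
    """Read a flat YAML key-value config into a PipelineConfig."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_raw = raw.pop("simulation", None)
    cfg = PipelineConfig(**{k: v for k, v in raw.items()
                            if k in {f.name for f in
                                     dataclasses.fields(PipelineConfig)}})
    if sim_raw is not None:
        sweep = sim_raw.pop("sweep", "default")
        traits = sim_raw.pop("trait_configs", None)
        sim = SimulationConfig(**sim_raw)
        if sweep != "default":
            sim.sweep = SweepConfig(**sweep) if sweep else None
        if traits is not None:
            sim.trait_configs = [TraitConfig(**t) for t in traits]
        sim.seed = cfg.seed
        cfg.simulation = sim
    return cfg


def run_full_analysis(cfg: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; returns the manifest."""
    data_mode = "simulate" not in set(cfg.stages) and cfg.simulation is None
    if data_mode and (cfg.genotype_path is None or cfg.map_path is None):
        raise ValueError("data mode needs genotype_path and map_path")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "stage_seeds": {s: cfg.stage_seed(s) for s in cfg.stages},
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items()
            if k not in {"simulation"}
        },
        "artifacts": [],
    }
    stages = set(cfg.stages)

    # ---- inputs -----------------------------------------------------------
    if "simulate" in stages or cfg.simulation is not None:
        sim = cfg.simulation or SimulationConfig(seed=cfg.seed)
        sim.seed = cfg.seed
        g, gmap, meta = simulate_panel(sim)
        pheno = simulate_phenotypes(g, sim)
        manifest["parameters"]["simulation"] = dataclasses.asdict(sim)
        g.to_dosage_tsv(out / "genotypes.tsv")
        gmap.to_tsv(out / "map.tsv")
        meta.to_tsv(out / "metadata.tsv")
        pheno.to_csv(out / "phenotypes.csv", index=False)
        for name in ("genotypes.tsv", "map.tsv", "metadata.tsv",
                     "phenotypes.csv"):
            manifest["artifacts"].append(
                {"stage": "simulate", "path": name,
                 "sha256": _sha256(out / name)}
            )
    else:
        if cfg.genotype_path is None or cfg.map_path is None:
            raise ValueError("data mode needs genotype_path and map_path")
        gmap = GeneticMap.from_tsv(cfg.map_path)
        g = GenotypeMatrix.from_dosage_tsv(cfg.genotype_path, gmap=gmap)
        meta = (PanelMetadata.from_tsv(cfg.metadata_path)
                if cfg.metadata_path else None)
        pheno = (pd.read_csv(cfg.phenotype_path)
                 if cfg.phenotype_path else None)

    g = g.ordered_by_map(gmap)
    g_maf = filter_by_maf(g, cfg.maf_threshold)
    gmap_maf = g_maf.gmap
    manifest["n_markers_total"] = g.n_markers
    manifest["n_markers_maf"] = g_maf.n_markers
    manifest["n_accessions"] = g.n_accessions

    def _stage(name: str) -> bool:
        return name in stages

    try:
        if _stage("diversity"):
            ho, ho_mean, ho_se = diversity.observed_heterozygosity(g)
            uhe, uhe_mean, uhe_se = diversity.unbiased_gene_diversity(g)
            per_marker = pd.DataFrame({"Ho": ho, "UHe": uhe})
            _write(per_marker, out / "diversity_markers.tsv", manifest,
                   "diversity", index=True, index_label="marker_id")
            track = diversity.sliding_window_diversity(
                g, gmap, cfg.window_width_cM, cfg.window_step_cM)
            _write(track, out / "diversity_windows.tsv", manifest, "diversity")
            manifest["diversity"] = {
                "mean_Ho": ho_mean, "se_Ho": ho_se,
                "mean_UHe": uhe_mean, "se_UHe": uhe_se,
            }

        if _stage("ld"):
            rng_seed = cfg.stage_seed("ld")
            pairs = ld.sample_random_pairs(
                gmap_maf, cfg.ld_n_pairs, cfg.ld_max_distance_cM, rng_seed)
            pair_tab = ld.pairwise_r2(g_maf, pairs, gmap_maf)
            _write(pair_tab, out / "ld_pairs.tsv", manifest, "ld")
            decay = ld.ld_decay_curve(
                pair_tab, cfg.ld_bandwidth_cM, cfg.ld_r2_threshold)
            _write(decay.curves, out / "ld_decay_curves.tsv", manifest, "ld")
            _write(decay.summary, out / "ld_decay_summary.tsv", manifest, "ld")
            track = ld.sliding_window_r2(
                g_maf, gmap_maf, cfg.window_width_cM, cfg.window_step_cM)
            _write(track, out / "ld_windows.tsv", manifest, "ld")

        if _stage("fst") and meta is not None:
            scan = differentiation.fst_outlier_scan(
                g_maf, meta, cfg.pools[0], cfg.pools[1],
                n_permutations=cfg.n_permutations,
                q_threshold=cfg.outlier_q,
                seed=cfg.stage_seed("fst"),
            )
            scan = scan.join(gmap_maf.table)
            _write(scan.reset_index(), out / "fst_scan.tsv", manifest, "fst")
            manifest["fst"] = {
                "multilocus_fst": differentiation.multilocus_fst(
                    g_maf, meta, cfg.pools[0], cfg.pools[1]),
                "n_outliers": int(scan["outlier"].sum()),
            }

        kin = None
        covars = None
        if _stage("structure") or _stage("assoc"):
            kin = structure_mod.kinship_matrix(
                g_maf, estimator=cfg.kinship_estimator)
            covars, var_exp = structure_mod.genotype_pca(g_maf, cfg.n_pcs)
        if _stage("structure"):
            kin.to_tsv(out / "kinship.tsv")
            manifest["artifacts"].append(
                {"stage": "structure", "path": "kinship.tsv",
                 "sha256": _sha256(out / "kinship.tsv")})
            dist = structure_mod.nei_standard_distance(g_maf)
            _write(dist, out / "nei_distance.tsv", manifest, "structure",
                   index=True, index_label="accession_id")
            coords, evals = structure_mod.pcoa(dist)
            _write(coords, out / "pcoa.tsv", manifest, "structure",
                   index=True, index_label="accession_id")
            _write(covars, out / "pca_covariates.tsv", manifest, "structure",
                   index=True, index_label="accession_id")
            manifest["structure"] = {
                "pca_var_explained": [float(v) for v in var_exp],
                "kinship_negatives_truncated": kin.n_truncated,
            }

        trait_means: dict[tuple[str, str], pd.Series] = {}
        if (_stage("pheno") or _stage("assoc")) and pheno is not None:
            traits = sorted(pheno["trait"].unique())
            locations = sorted(pheno["location"].unique())
            summaries = []
            for trait in traits:
                for loc in locations:
                    em = phenotypes.entry_means_and_lsmeans(pheno, trait, loc)
                    use_ls = trait in cfg.lsmean_traits
                    trait_means[(trait, loc)] = em[
                        "ls_mean" if use_ls else "raw_mean"]
                    em2 = em.reset_index()
                    em2.insert(0, "trait", trait)
                    em2.insert(1, "location", loc)
                    summaries.append(em2)
            if _stage("pheno"):
                _write(pd.concat(summaries, ignore_index=True),
                       out / "entry_means.tsv", manifest, "pheno")
                h2_rows = []
                for trait in traits:
                    h2, comps = phenotypes.broad_sense_heritability(
                        pheno, trait)
                    h2_rows.append({"trait": trait, "H2": h2, **comps})
                _write(pd.DataFrame(h2_rows), out / "heritability.tsv",
                       manifest, "pheno")
                corr = phenotypes.trait_correlations_holm(pheno)
                _write(corr, out / "trait_correlations.tsv", manifest, "pheno")

        if _stage("assoc") and pheno is not None:
            thr = association.simpleM_threshold(
                g_maf, gmap_maf, cfg.alpha, cfg.meff_c)
            thr_tab = pd.DataFrame(
                [{"linkage_group": k, "meff": v}
                 for k, v in thr.meff_per_group.items()]
            )
            thr_tab.loc[len(thr_tab)] = {"linkage_group": "total",
                                         "meff": thr.meff_total}
            _write(thr_tab, out / "meff.tsv", manifest, "assoc")
            manifest["assoc"] = {
                "meff_total": thr.meff_total, "p_star": thr.p_star,
                "lambda": {},
            }
            q_cov = (structure_mod.read_q_matrix(cfg.q_matrix_path)
                     if cfg.q_matrix_path else None)
            results = []
            for (trait, loc), yv in trait_means.items():
                for model in cfg.models:
                    if model == "naive":
                        fit = association.fit_null_mlm(
                            yv, None, model="naive")
                    elif model == "k":
                        fit = association.fit_null_mlm(yv, kin, model="k")
                    elif model == "pk":
                        fit = association.fit_null_mlm(
                            yv, kin, covars, model="pk")
                    elif model == "qk":
                        if q_cov is None:
                            logger.warning("qk requested but no Q matrix")
                            continue
                        fit = association.fit_null_mlm(
                            yv, kin, q_cov, model="qk")
                    else:
                        raise ValueError(f"unknown model {model!r}")
                    tab, lam = association.scan_association(
                        g_maf, fit, model, gmap_maf)
                    tab.insert(0, "trait", trait)
                    tab.insert(1, "location", loc)
                    tab.insert(2, "model", model)
                    tab["significant"] = tab["p"] <= thr.p_star
                    results.append(tab)
                    manifest["assoc"]["lambda"][
                        f"{trait}:{loc}:{model}"] = lam
            assoc_tab = pd.concat(results, ignore_index=True)
            _write(assoc_tab, out / "associations.tsv", manifest, "assoc")

        if _stage("paint"):
            paint = painting.greedy_template_cycles(
                g, gmap, cfg.paint_cycles, cfg.paint_min_block)
            frac, avg, cum = painting.genome_share_fractions(paint)
            _write(frac, out / "paint_fractions.tsv", manifest, "paint",
                   index=True, index_label="accession_id")
            _write(paint.label_frame(), out / "paint_labels.tsv", manifest,
                   "paint", index=True, index_label="accession_id")
            manifest["paint"] = {
                "templates": paint.templates,
                "g1_average_share": float(avg.get("G1", 0.0)),
                "top_cumulative_share": (
                    float(cum.iloc[-1]) if len(cum) else 0.0),
            }
    except Exception as exc:
        manifest["failed_stage"] = repr(exc)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str))
        raise

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
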