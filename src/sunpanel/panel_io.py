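"""Panel data model and I/O.

The central container is :class:`GenotypeMatrix`, an accessions x markers
matrix of alternate-allele dosages (0/1/2, with a dedicated missing
sentinel).  Array genotypes for an inbred-line panel are unphased, so every
downstream statistic in this package is dosage/frequency based.  A
:class:`GeneticMap` (marker -> linkage group, position in cM) supplies
ordering, window definitions and pairwise distances; :class:`PanelMetadata`
carries the accession class labels and the breeding-pool assignment
(HA = maintainer, RHA = restorer, other) used for differentiation scans.

Interchange formats are deliberately plain text: a dosage TSV (header row of
marker ids, first column the accession id, missing encoded as "NA"), a map
TSV (marker_id, linkage_group, position_cM) and a metadata TSV
(accession_id, class_label, pool).  VCF input is supported for diploid
biallelic SNP records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call (distinct from any dosage).
MISSING: int = -1


class PanelFormatError(ValueError):
    """Raised when an input file cannot be parsed into panel objects."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Marker positions on a genetic (cM) map.

    Parameters
    ----------
    table
        DataFrame indexed by marker_id with integer ``linkage_group`` and
        float ``position_cM`` columns.  Positions need not be unique
        (co-segregating markers are allowed); ties in position are broken
        by marker id so that the map order is deterministic.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"linkage_group", "position_cM"}
        if not required.issubset(self.table.columns):
            raise PanelFormatError(
                f"genetic map needs columns {sorted(required)}"
            )
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise PanelFormatError(f"duplicate markers in map: {dups[:5]}")
        if (self.table["position_cM"] < 0).any():
            raise PanelFormatError("map positions must be non-negative")
        tab = self.table.copy()
        tab["linkage_group"] = tab["linkage_group"].astype(int)
        tab["position_cM"] = tab["position_cM"].astype(float)
        self.table = tab

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def linkage_groups(self) -> list[int]:
        return sorted(self.table["linkage_group"].unique().tolist())

    def ordered_markers(self) -> list[str]:
        """Marker ids sorted by (linkage group, position, marker id)."""
        tab = self.table.reset_index(names="marker_id")
        tab = tab.sort_values(
            ["linkage_group", "position_cM", "marker_id"], kind="mergesort"
        )
        return tab["marker_id"].tolist()

    def positions(self, markers: Sequence[str]) -> np.ndarray:
        return self.table.loc[list(markers), "position_cM"].to_numpy()

    def groups(self, markers: Sequence[str]) -> np.ndarray:
        return self.table.loc[list(markers), "linkage_group"].to_numpy()

    def subset(self, markers: Sequence[str]) -> "GeneticMap":
        return GeneticMap(self.table.loc[list(markers)].copy())

    def to_tsv(self, path) -> None:
        out = self.table.reset_index(names="marker_id")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        tab = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
        if "marker_id" not in tab.columns:
            raise PanelFormatError(f"{path}: map TSV lacks marker_id column")
        return cls(tab.set_index("marker_id"))


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Accessions x markers alternate-allele dosage matrix.

    ``dosage`` holds values in {0, 1, 2} or :data:`MISSING`; rows follow
    ``accession_ids`` and columns follow ``marker_ids``.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    gmap: GeneticMap | None = None

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.accession_ids) or m != len(self.marker_ids):
            raise PanelFormatError(
                f"dosage shape {self.dosage.shape} does not match id lists "
                f"({len(self.accession_ids)} accessions, "
                f"{len(self.marker_ids)} markers)"
            )
        if len(set(self.accession_ids)) != n:
            raise PanelFormatError("duplicate accession ids")
        if len(set(self.marker_ids)) != m:
            raise PanelFormatError("duplicate marker ids")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise PanelFormatError(
                f"{bad.sum()} dosage values outside {{0,1,2,missing}}"
            )

    # -- basic views --------------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def called_mask(self) -> np.ndarray:
        """Boolean mask of non-missing cells."""
        return self.dosage != MISSING

    def dosage_float(self) -> np.ndarray:
        """Dosage as float with missing cells as NaN."""
        x = self.dosage.astype(float)
        x[self.dosage == MISSING] = np.nan
        return x

    def accession_indexer(self, accessions: Sequence[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in accessions if a not in lookup]
        if missing:
            raise KeyError(f"unknown accessions: {missing[:5]}")
        return np.array([lookup[a] for a in accessions], dtype=int)

    def marker_indexer(self, markers: Sequence[str]) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        missing = [m for m in markers if m not in lookup]
        if missing:
            raise KeyError(f"unknown markers: {missing[:5]}")
        return np.array([lookup[m] for m in markers], dtype=int)

    # -- subsetting ---------------------------------------------------------

    def take_accessions(self, accessions: Sequence[str]) -> "GenotypeMatrix":
        idx = self.accession_indexer(accessions)
        return GenotypeMatrix(
            [self.accession_ids[i] for i in idx],
            list(self.marker_ids),
            self.dosage[idx, :],
            self.gmap,
        )

    def take_markers(self, markers: Sequence[str]) -> "GenotypeMatrix":
        idx = self.marker_indexer(markers)
        sub_map = self.gmap.subset(markers) if self.gmap is not None else None
        return GenotypeMatrix(
            list(self.accession_ids),
            [self.marker_ids[i] for i in idx],
            self.dosage[:, idx],
            sub_map,
        )

    def ordered_by_map(self, gmap: GeneticMap | None = None) -> "GenotypeMatrix":
        """Reorder markers into map order; unmapped markers are dropped."""
        gmap = gmap if gmap is not None else self.gmap
        if gmap is None:
            raise ValueError("no genetic map attached or supplied")
        present = set(self.marker_ids)
        unknown = [m for m in gmap.marker_ids if m not in present]
        if unknown:
            raise PanelFormatError(
                f"map references markers absent from the matrix: {unknown[:5]}"
            )
        ordered = [m for m in gmap.ordered_markers() if m in present]
        out = self.take_markers(ordered)
        out.gmap = gmap.subset(ordered)
        return out

    # -- text I/O -----------------------------------------------------------

    def to_dosage_tsv(self, path) -> None:
        frame = pd.DataFrame(
            self.dosage.astype(object), index=self.accession_ids,
            columns=self.marker_ids,
        )
        frame = frame.mask(self.dosage == MISSING, "NA")
        frame.to_csv(path, sep="\t", index_label="accession_id")

    @classmethod
    def from_dosage_tsv(cls, path, gmap: GeneticMap | None = None) -> "GenotypeMatrix":
        frame = pd.read_csv(
            path, sep="\t", index_col="accession_id", na_values=["NA"],
            keep_default_na=False, dtype=str,
        )
        raw = frame.to_numpy()
        dosage = np.full(raw.shape, MISSING, dtype=np.int8)
        filled = ~pd.isna(raw)
        try:
            dosage[filled] = np.asarray(raw[filled], dtype=float).astype(np.int8)
        except ValueError as exc:
            raise PanelFormatError(f"{path}: non-numeric dosage value ({exc})")
        g = cls([str(a) for a in frame.index], [str(c) for c in frame.columns],
                dosage, gmap)
        if gmap is not None:
            g = g.ordered_by_map(gmap)
        return g


# ---------------------------------------------------------------------------
# Panel metadata
# ---------------------------------------------------------------------------

#: Default mapping from class-label prefixes to breeding pools.
_POOL_PREFIXES = (("RHA", "RHA"), ("INRA-RHA", "RHA"), ("HA", "HA"),
                  ("INRA-HA", "HA"))


def pool_from_class_label(label: str) -> str:
    """Derive the breeding pool (HA / RHA / other) from a class label.

    Labels beginning with ``RHA`` or ``INRA-RHA`` map to the restorer pool,
    labels beginning with ``HA`` or ``INRA-HA`` to the maintainer pool, and
    everything else (OPVs, landraces, introgressed, unassigned) to
    ``other``.
    """
    u = label.upper()
    if u.startswith("RHA") or u.startswith("INRA-RHA"):
        return "RHA"
    if u.startswith("HA") or u.startswith("INRA-HA"):
        return "HA"
    return "other"


@dataclass
class PanelMetadata:
    """Accession class labels and pool assignment."""

    table: pd.DataFrame  # index accession_id; columns class_label, pool

    def __post_init__(self) -> None:
        if "class_label" not in self.table.columns:
            raise PanelFormatError("metadata needs a class_label column")
        if "pool" not in self.table.columns:
            tab = self.table.copy()
            tab["pool"] = [pool_from_class_label(c) for c in tab["class_label"]]
            self.table = tab
        bad = set(self.table["pool"]) - {"HA", "RHA", "other"}
        if bad:
            raise PanelFormatError(f"unknown pools: {sorted(bad)}")

    def pool_accessions(self, pool: str) -> list[str]:
        if pool not in {"HA", "RHA", "other"}:
            raise ValueError(f"unknown pool {pool!r}")
        return list(self.table.index[self.table["pool"] == pool])

    def validate_against(self, g: GenotypeMatrix) -> None:
        missing = [a for a in g.accession_ids if a not in self.table.index]
        if missing:
            raise PanelFormatError(
                f"accessions without metadata: {missing[:5]}"
            )

    def to_tsv(self, path) -> None:
        self.table.reset_index(names="accession_id").to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "PanelMetadata":
        tab = pd.read_csv(path, sep="\t", dtype=str)
        if "accession_id" not in tab.columns:
            raise PanelFormatError(f"{path}: metadata lacks accession_id")
        return cls(tab.set_index("accession_id"))


# ---------------------------------------------------------------------------
# Allele frequencies and MAF filtering
# ---------------------------------------------------------------------------

def compute_allele_frequencies(
    g: GenotypeMatrix, subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-marker alternate-allele frequency table.

    Missing cells are excluded from both the numerator and the denominator:
    ``p_alt = sum(dosage) / (2 * n_called)``.  Markers with no called
    genotypes get ``n_called = 0`` and NaN frequencies, and carry an
    ``undefined`` flag so downstream filters can drop them.

    Returns a DataFrame indexed by marker_id with columns
    ``p_alt, n_called, maf, undefined``.
    """
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("empty accession subset")
        g = g.take_accessions(subset)
    called = g.called_mask()
    n_called = called.sum(axis=0)
    total = np.where(called, g.dosage, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(n_called > 0, total / (2.0 * n_called), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    return pd.DataFrame(
        {
            "p_alt": p_alt,
            "n_called": n_called.astype(int),
            "maf": maf,
            "undefined": n_called == 0,
        },
        index=pd.Index(g.marker_ids, name="marker_id"),
    )


def filter_by_maf(
    g: GenotypeMatrix, threshold: float,
    subset: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Keep exactly the markers with MAF >= ``threshold`` (boundary inclusive).

    Markers whose frequency is undefined (all calls missing) are removed.
    Marker order is preserved; the number removed is logged.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold {threshold} outside [0, 0.5]")
    freqs = compute_allele_frequencies(g, subset=subset)
    keep = (freqs["maf"] >= threshold) & ~freqs["undefined"]
    kept = [m for m, k in zip(g.marker_ids, keep.to_numpy()) if k]
    n_removed = g.n_markers - len(kept)
    logger.info("MAF filter at %.3f removed %d of %d markers",
                threshold, n_removed, g.n_markers)
    return g.take_markers(kept)


# ---------------------------------------------------------------------------
# VCF / table reading
# ---------------------------------------------------------------------------

def read_genotype_table(
    path, format: str = "vcf", map_path=None
) -> tuple[GenotypeMatrix, GeneticMap | None, dict]:
    """Read a genotype matrix from a VCF or dosage TSV.

    Biallelic SNP records are converted to alternate-allele dosage;
    multi-allelic and non-SNP records are dropped with a logged reason.
    When a map is supplied the markers are reordered into map order,
    otherwise file order is kept.

    Returns ``(matrix, map_or_None, report)`` where the report records the
    number of markers kept and dropped with reasons.
    """
    gmap = GeneticMap.from_tsv(map_path) if map_path is not None else None
    report: dict = {"n_kept": 0, "dropped": {}}
    if format == "dosage_tsv":
        g = GenotypeMatrix.from_dosage_tsv(path, gmap=gmap)
        report["n_kept"] = g.n_markers
        return g, gmap, report
    if format != "vcf":
        raise ValueError(f"unknown format {format!r}")

    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise PanelFormatError(f"{path}: cannot open as VCF ({exc})")
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    dropped: dict[str, int] = {}
    for rec in vcf:
        name = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            dropped["multiallelic"] = dropped.get("multiallelic", 0) + 1
            logger.info("dropped %s: multiallelic", name)
            continue
        if not rec.is_snp:
            dropped["non_snp"] = dropped.get("non_snp", 0) + 1
            logger.info("dropped %s: not a SNP", name)
            continue
        # gts012: 0/1/2 dosage, 3 = unknown
        gt = rec.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        marker_ids.append(name)
        columns.append(gt)
    if not marker_ids:
        raise PanelFormatError(f"{path}: no usable biallelic SNP records")
    dosage = np.stack(columns, axis=1)
    g = GenotypeMatrix(samples, marker_ids, dosage, gmap)
    if gmap is not None:
        g = g.ordered_by_map(gmap)
    report["n_kept"] = g.n_markers
    report["dropped"] = dropped
    return g, gmap, report
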