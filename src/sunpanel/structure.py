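"""Genetic distances, ordination and marker-based kinship.

Nei's standard genetic distance is applied between individual accessions
by treating each accession as a population with genotype-implied allele
frequencies (0, 0.5, 1 per locus) — the standard individual-level
reduction of the population formula.  Classical metric scaling (PCoA) of
the resulting distance matrix visualizes panel structure; a genotype PCA
provides structure covariates (the P matrix) for mixed-model association;
and the Loiselle multilocus kinship estimator (Ritland variant behind a
flag) provides the K matrix, with negative pairwise estimates set to 0 so
that "less related than random" pairs carry no weight in the model.
Admixture-style membership fractions (Q matrices) are read from file,
never computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import GenotypeMatrix

logger = logging.getLogger(__name__)

#: Cap applied to Nei distances when the shared identity J_xy is zero.
NEI_DISTANCE_CAP = 10.0


def nei_standard_distance(g: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise Nei standard distance between accessions.

    D = -ln( Jxy / sqrt(Jx * Jy) ) with the J identities averaged over the
    loci called in both accessions.  Pairs with Jxy = 0 are capped at
    :data:`NEI_DISTANCE_CAP` (logged); pairs with no shared called locus
    are NaN.
    """
    p = g.dosage_float() / 2.0               # individual allele frequency
    called = ~np.isnan(p)
    m = called.astype(float)
    pf = np.nan_to_num(p)

    n_sh = m @ m.T                            # shared called loci
    sum_pxpy = pf @ pf.T
    sum_p_sh = pf @ m.T                       # sum of p_x over shared loci
    # sum over shared loci of (1-px)(1-py) = Nsh - Spx - Spy + Spxpy
    sum_qxqy = n_sh - sum_p_sh - sum_p_sh.T + sum_pxpy
    jxy = sum_pxpy + sum_qxqy

    hom = np.where(called, pf ** 2 + (1.0 - pf) ** 2, 0.0)
    jx = hom @ m.T                            # sum over shared of px^2+qx^2
    jy = jx.T

    # the 1/Nsh factor in each J term cancels inside the ratio
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n_sh > 0, -np.log(
            np.where(jxy > 0, jxy, np.nan) / np.sqrt(jx * jy)), np.nan)
    capped = (n_sh > 0) & ~(jxy > 0)
    if capped.any():
        logger.info("capped %d Nei distances with Jxy = 0",
                    int(capped.sum() // 2))
    d = np.where(capped, NEI_DISTANCE_CAP, d)
    np.fill_diagonal(d, 0.0)
    d = np.minimum(d, NEI_DISTANCE_CAP)
    d = np.where(np.isnan(d), np.nan, np.maximum(d, 0.0))
    ids = pd.Index(g.accession_ids, name="accession_id")
    return pd.DataFrame(d, index=ids, columns=ids)


def pcoa(
    d: pd.DataFrame | np.ndarray, n_axes: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, truncates negative eigenvalues
    to 0 (count reported via the returned eigenvalue vector) and returns
    coordinates on the leading ``n_axes`` axes ordered by eigenvalue.
    """
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
        ids = [f"s{i}" for i in range(dm.shape[0])]
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, equal_nan=True):
        raise ValueError("distance matrix must be square and symmetric")
    if np.isnan(dm).any():
        raise ValueError("distance matrix contains NaN")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals_trunc = np.maximum(evals, 0.0)
    k = min(n_axes, n)
    coords = evecs[:, :k] * np.sqrt(evals_trunc[:k])[None, :]
    # deterministic sign: largest-magnitude loading positive per axis
    for a in range(k):
        i = np.argmax(np.abs(coords[:, a]))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    frame = pd.DataFrame(
        coords, index=pd.Index(ids, name="accession_id"),
        columns=[f"PCo{i + 1}" for i in range(k)],
    )
    return frame, evals_trunc


def genotype_pca(
    g: GenotypeMatrix, n_components: int = 2, standardize: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the centered dosage matrix (per-marker mean imputation).

    Constant markers are removed before the decomposition.  Returns the
    accession scores (the P matrix of structure covariates) and the
    variance explained per component.
    """
    x = g.dosage_float()
    mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mean[None, :], x)
    x = x - mean[None, :]
    sd = x.std(axis=0)
    keep = sd > 0
    x = x[:, keep]
    if standardize:
        x = x / x.std(axis=0)[None, :]
    rank = min(x.shape)
    if n_components > rank:
        logger.warning("n_components %d > rank %d; reduced", n_components, rank)
        n_components = rank
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components][None, :]
    for a in range(n_components):
        i = np.argmax(np.abs(scores[:, a]))
        if scores[i, a] < 0:
            scores[:, a] = -scores[:, a]
    var_explained = (s ** 2) / (s ** 2).sum()
    frame = pd.DataFrame(
        scores, index=pd.Index(g.accession_ids, name="accession_id"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, var_explained[:n_components]


@dataclass
class KinshipMatrix:
    """Relative kinship with negatives truncated to 0.

    The diagonal holds the estimator's self-kinship; ``n_truncated``
    counts the negative off-diagonal estimates that were set to 0.
    """

    values: pd.DataFrame
    estimator: str
    n_truncated: int

    def aligned(self, accessions) -> np.ndarray:
        return self.values.loc[list(accessions), list(accessions)].to_numpy()

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="accession_id")

    @classmethod
    def from_tsv(cls, path, estimator: str = "file") -> "KinshipMatrix":
        vals = pd.read_csv(path, sep="\t", index_col="accession_id")
        vals.columns = [str(c) for c in vals.columns]
        return cls(vals, estimator, 0)


def kinship_matrix(
    g: GenotypeMatrix, estimator: str = "loiselle"
) -> KinshipMatrix:
    """Multilocus marker-based relative kinship.

    Loiselle form (default): ratio of sums over loci of
    ``sum_alleles (p_i,a - pbar_a)(p_j,a - pbar_a)`` plus the small-sample
    correction ``sum_alleles pbar_a (1 - pbar_a) / (n_l - 1)``, normalized
    by ``sum_alleles pbar_a (1 - pbar_a)``.  The Ritland variant divides
    each locus term by its heterozygosity before averaging.  Negative
    pairwise values are then set to 0.
    """
    if estimator not in {"loiselle", "ritland"}:
        raise ValueError(f"unknown estimator {estimator!r}")
    p = g.dosage_float() / 2.0
    called = ~np.isnan(p)
    if (~called.any(axis=1)).any():
        bad = [a for a, row in zip(g.accession_ids, called)
               if not row.any()]
        raise ValueError(f"accessions with no called markers: {bad[:5]}")
    n_l = called.sum(axis=0).astype(float)
    pbar = np.nanmean(p, axis=0)
    het = 2.0 * pbar * (1.0 - pbar)          # sum over the 2 alleles of p(1-p)
    poly = (het > 0) & (n_l >= 2)

    c = np.where(called & poly[None, :], p - pbar[None, :], 0.0)
    m = (called & poly[None, :]).astype(float)
    if estimator == "loiselle":
        num_cross = 2.0 * (c @ c.T)           # sum_l 2 (pi-pb)(pj-pb)
        w_corr = np.where(poly, het / (n_l - 1.0), 0.0)
        num_corr = m @ (w_corr[:, None] * m.T)
        denom = m @ (het[:, None] * m.T)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_het = np.where(poly, 1.0 / het, 0.0)
        cs = c * np.sqrt(inv_het)[None, :]
        num_cross = 2.0 * (cs @ cs.T)
        num_corr = m @ (np.where(poly, 1.0 / (n_l - 1.0), 0.0)[:, None] * m.T)
        denom = 2.0 * (m @ m.T) / 2.0         # number of shared polymorphic loci
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(denom > 0, (num_cross + num_corr) / denom, np.nan)
    off = ~np.eye(k.shape[0], dtype=bool)
    n_trunc = int(np.nansum((k < 0) & off))
    k = np.where((k < 0) & off, 0.0, k)
    k = 0.5 * (k + k.T)
    ids = pd.Index(g.accession_ids, name="accession_id")
    if n_trunc:
        logger.info("set %d negative kinship estimates to 0", n_trunc)
    return KinshipMatrix(pd.DataFrame(k, index=ids, columns=ids),
                         estimator, n_trunc)


def read_q_matrix(path) -> pd.DataFrame:
    """Read admixture membership fractions (accession_id, Q1..Qc) from TSV
    and drop the last column for identifiability."""
    q = pd.read_csv(path, sep="\t", index_col="accession_id")
    if ((q < -1e-9) | (q > 1 + 1e-9)).any().any():
        raise ValueError("Q entries must lie in [0, 1]")
    if q.shape[1] > 1:
        q = q.iloc[:, :-1]
    return q
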