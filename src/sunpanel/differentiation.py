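"""Between-pool differentiation: per-SNP F_ST and a permutation outlier scan.

F_ST uses the Nei/Chesser heterozygosity decomposition:
``Hs`` is the mean of the two pools' unbiased expected heterozygosities,
``Ht`` the unbiased expected heterozygosity computed from the pooled-mean
(unweighted) allele frequency, and ``F_ST = (Ht - Hs) / Ht``.  Small
negative estimates are truncated to 0 (count logged); markers with Ht = 0
or fewer than two called accessions in either pool are NaN.  A
Weir-Cockerham theta estimator is available behind a flag for sensitivity
analysis.

The outlier scan is a permutation surrogate for Bayesian F_ST outlier
methods: pool labels are permuted across accessions and each marker's
p-value is ``(1 + #{permuted F_ST >= observed}) / (1 + n_permutations)``.
By default the permuted reference value for a marker is the most extreme
permuted F_ST within its expected-heterozygosity stratum (a
Westfall-Young-style family correction conditioned on allele frequency),
so the scan asks whether a locus is an outlier relative to loci of
similar diversity — the question a genome-scan selection test answers —
rather than whether it shows any differentiation at all, which with
hundreds of lines and a genuinely divergent pair of breeding pools would
flag much of the genome.  ``null_reference="marker"`` switches to each
marker's own permutation distribution.  Benjamini-Hochberg FDR control is
applied across markers.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .panel_io import GenotypeMatrix, PanelMetadata

logger = logging.getLogger(__name__)


def _pool_freq_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker (allele frequency, called count) for a dosage block."""
    called = ~np.isnan(x)
    n = called.sum(axis=0).astype(float)
    s = np.nansum(x, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, s / (2.0 * n), np.nan)
    return p, n


def _unbiased_he(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        he = 1.0 - p ** 2 - (1.0 - p) ** 2
        return np.where(n >= 2, 2.0 * n / (2.0 * n - 1.0) * he, np.nan)


def _fst_from_counts(
    pa: np.ndarray, na: np.ndarray, pb: np.ndarray, nb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nei/Chesser-style F_ST from per-pool frequencies and called counts.

    Returns (fst, ht, hs); fst is NaN where undefined, negatives truncated
    to 0 by the caller so the raw estimate stays inspectable here.
    """
    hs = 0.5 * (_unbiased_he(pa, na) + _unbiased_he(pb, nb))
    pbar = 0.5 * (pa + pb)
    nt = na + nb
    ht = _unbiased_he(pbar, nt)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / ht, np.nan)
    fst = np.where((na >= 2) & (nb >= 2), fst, np.nan)
    return fst, ht, hs


def _wc_theta(
    pa: np.ndarray, na: np.ndarray, pb: np.ndarray, nb: np.ndarray
) -> np.ndarray:
    """Weir-Cockerham theta for two populations from allele frequencies
    (heterozygosity term omitted: inbred panels are ~fully homozygous)."""
    r = 2.0
    nbar = (na + nb) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (na + nb - (na ** 2 + nb ** 2) / (na + nb)) / (r - 1.0)
        pbar = (na * pa + nb * pb) / (na + nb)
        s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1.0) * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2)
        theta = np.where(a + b > 0, a / (a + b), np.nan)
    return np.where((na >= 2) & (nb >= 2), theta, np.nan)


def per_snp_fst(
    g: GenotypeMatrix,
    metadata: PanelMetadata,
    pool_a: str = "RHA",
    pool_b: str = "HA",
    estimator: str = "nei",
) -> pd.DataFrame:
    """Per-marker F_ST between two breeding pools.

    Returns a DataFrame indexed by marker_id with columns fst (truncated
    at 0), fst_raw, ht, hs, n_a, n_b.
    """
    if estimator not in {"nei", "wc"}:
        raise ValueError(f"unknown estimator {estimator!r}")
    acc_a = [a for a in metadata.pool_accessions(pool_a)
             if a in g.accession_ids]
    acc_b = [a for a in metadata.pool_accessions(pool_b)
             if a in g.accession_ids]
    if len(acc_a) < 2 or len(acc_b) < 2:
        raise ValueError("each pool needs at least 2 genotyped accessions")
    x = g.dosage_float()
    xa = x[g.accession_indexer(acc_a)]
    xb = x[g.accession_indexer(acc_b)]
    pa, na = _pool_freq_stats(xa)
    pb, nb = _pool_freq_stats(xb)
    if estimator == "wc":
        raw = _wc_theta(pa, na, pb, nb)
        ht = hs = np.full_like(raw, np.nan)
    else:
        raw, ht, hs = _fst_from_counts(pa, na, pb, nb)
    n_neg = int(np.nansum(raw < 0))
    if n_neg:
        logger.info("truncated %d negative F_ST estimates to 0", n_neg)
    fst = np.where(raw < 0, 0.0, raw)
    return pd.DataFrame(
        {"fst": fst, "fst_raw": raw, "ht": ht, "hs": hs,
         "n_a": na.astype(int), "n_b": nb.astype(int)},
        index=pd.Index(g.marker_ids, name="marker_id"),
    )


def multilocus_fst(
    g: GenotypeMatrix, metadata: PanelMetadata,
    pool_a: str = "RHA", pool_b: str = "HA",
) -> float:
    """Genome-wide multi-locus F_ST as a ratio of sums over markers:
    ``(sum Ht - sum Hs) / sum Ht``."""
    track = per_snp_fst(g, metadata, pool_a, pool_b)
    ok = track.dropna(subset=["ht", "hs"])
    sht, shs = ok["ht"].sum(), ok["hs"].sum()
    if sht <= 0:
        return np.nan
    return float((sht - shs) / sht)


def fst_outlier_scan(
    g: GenotypeMatrix,
    metadata: PanelMetadata,
    pool_a: str = "RHA",
    pool_b: str = "HA",
    n_permutations: int = 1000,
    q_threshold: float = 0.05,
    n_het_strata: int = 10,
    seed: int | np.random.Generator = 0,
    null_reference: str = "stratum_max",
    chunk: int = 200,
) -> pd.DataFrame:
    """Permutation F_ST outlier scan between two pools.

    Pool labels are permuted across the union of the two pools' accessions
    ``n_permutations`` times.  With ``null_reference="stratum_max"``
    (default) the permuted reference for each marker is the maximum
    permuted F_ST in its expected-heterozygosity stratum; with
    ``"marker"`` it is the marker's own permuted value.  Either way the
    p-value is ``(1 + #{reference >= observed})/(1 + n_permutations)`` and
    is floored at ``1/(1 + n_permutations)``.  BH-adjusted q-values and
    outlier flags (q <= q_threshold) are added.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if null_reference not in {"stratum_max", "marker"}:
        raise ValueError(f"unknown null_reference {null_reference!r}")
    if n_permutations < 100:
        logger.warning("only %d permutations: p-value floor %.3f",
                       n_permutations, 1 / (1 + n_permutations))
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    track = per_snp_fst(g, metadata, pool_a, pool_b)

    acc_a = [a for a in metadata.pool_accessions(pool_a)
             if a in g.accession_ids]
    acc_b = [a for a in metadata.pool_accessions(pool_b)
             if a in g.accession_ids]
    both = acc_a + acc_b
    n_a = len(acc_a)
    x = g.dosage_float()[g.accession_indexer(both)]
    called = (~np.isnan(x)).astype(float)
    xf = np.nan_to_num(x)
    n_pool = len(both)
    tot_s = xf.sum(axis=0)
    tot_n = called.sum(axis=0)

    # compare raw (untruncated) estimates: truncation at 0 would create a
    # mass of ties that distorts the null p-value distribution
    observed = track["fst_raw"].to_numpy()

    # heterozygosity strata condition the null on allele frequency
    ht = track["ht"].to_numpy()
    strata = np.full(g.n_markers, -1)
    ok_ht = ~np.isnan(ht)
    if ok_ht.sum() and n_het_strata > 1:
        qs = np.quantile(ht[ok_ht], np.linspace(0, 1, n_het_strata + 1)[1:-1])
        strata[ok_ht] = np.searchsorted(qs, ht[ok_ht])
    elif ok_ht.sum():
        strata[ok_ht] = 0

    exceed = np.zeros(g.n_markers)
    done = 0
    while done < n_permutations:
        k = min(chunk, n_permutations - done)
        ind = np.zeros((n_pool, k))
        for j in range(k):
            ind[rng.permutation(n_pool)[:n_a], j] = 1.0
        sa = xf.T @ ind          # markers x k
        na = called.T @ ind
        sb = tot_s[:, None] - sa
        nb = tot_n[:, None] - na
        with np.errstate(invalid="ignore", divide="ignore"):
            pa = sa / (2.0 * na)
            pb = sb / (2.0 * nb)
        perm, _, _ = _fst_from_counts(pa, na, pb, nb)
        if null_reference == "stratum_max":
            ref = np.full_like(perm, -np.inf)
            for s in np.unique(strata[strata >= 0]):
                rows = strata == s
                smax = np.nanmax(
                    np.where(np.isnan(perm[rows]), -np.inf, perm[rows]),
                    axis=0,
                )
                ref[rows] = smax[None, :]
        else:
            ref = perm
        exceed += np.nansum(ref >= observed[:, None], axis=1)
        done += k

    with np.errstate(invalid="ignore"):
        p = (1.0 + exceed) / (1.0 + n_permutations)
    p = np.where(np.isnan(observed), np.nan, p)

    q = np.full(g.n_markers, np.nan)
    finite = ~np.isnan(p)
    if finite.sum():
        _, q_adj, _, _ = multipletests(p[finite], method="fdr_bh")
        q[finite] = q_adj
    out = track.copy()
    out["het_stratum"] = strata
    out["perm_p"] = p
    out["q_value"] = q
    out["outlier"] = (q <= q_threshold) & finite
    return out
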