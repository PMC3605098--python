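"""Heterozygosity statistics and their sliding-window genome tracks.

Observed heterozygosity Ho is the fraction of called genotypes that are
heterozygous; unbiased gene diversity UHe is Nei's expected heterozygosity
with the small-sample correction, ``UHe = 2N/(2N-1) * (1 - sum p_i^2)``
with N the number of called diploids.  Sliding windows are half-open
``[start, start + width)`` intervals anchored at 0 cM within each linkage
group, advancing by a configurable step; the window value is the unweighted
mean over member markers and empty windows are reported as NaN.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .panel_io import GeneticMap, GenotypeMatrix, compute_allele_frequencies


def observed_heterozygosity(
    g: GenotypeMatrix, subset: Sequence[str] | None = None
) -> tuple[pd.Series, float, float]:
    """Per-marker Ho plus the across-marker mean and standard error."""
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("empty accession subset")
        g = g.take_accessions(subset)
    called = g.called_mask()
    n_called = called.sum(axis=0)
    n_het = (g.dosage == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        ho = np.where(n_called > 0, n_het / n_called, np.nan)
    per_marker = pd.Series(ho, index=pd.Index(g.marker_ids, name="marker_id"),
                           name="Ho")
    vals = per_marker.dropna()
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
    return per_marker, mean, se


def unbiased_gene_diversity(
    g: GenotypeMatrix, subset: Sequence[str] | None = None
) -> tuple[pd.Series, float, float]:
    """Per-marker UHe plus the across-marker mean and standard error.

    Markers with fewer than two called genotypes are flagged undefined
    (NaN) and excluded from the mean.
    """
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("empty accession subset")
        g = g.take_accessions(subset)
    freqs = compute_allele_frequencies(g)
    n = freqs["n_called"].to_numpy().astype(float)
    p = freqs["p_alt"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        he = 1.0 - p ** 2 - (1.0 - p) ** 2
        uhe = np.where(n >= 2, (2.0 * n) / (2.0 * n - 1.0) * he, np.nan)
    per_marker = pd.Series(uhe, index=freqs.index, name="UHe")
    vals = per_marker.dropna()
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
    return per_marker, mean, se


def iter_windows(
    gmap: GeneticMap, width_cM: float = 5.0, step_cM: float = 1.0
):
    """Yield (linkage_group, start, end, marker_ids) for half-open windows
    anchored at 0 cM within each linkage group."""
    if width_cM <= 0:
        raise ValueError("window width must be > 0")
    if step_cM <= 0:
        raise ValueError("window step must be > 0")
    tab = gmap.table
    for lg in gmap.linkage_groups:
        sub = tab[tab["linkage_group"] == lg]
        pos = sub["position_cM"].to_numpy()
        ids = np.asarray(sub.index)
        order = np.argsort(pos, kind="mergesort")
        pos, ids = pos[order], ids[order]
        max_pos = pos.max() if pos.size else 0.0
        start = 0.0
        while start <= max_pos:
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, start + width_cM, side="left")
            yield lg, start, start + width_cM, list(ids[lo:hi])
            start += step_cM


def sliding_window_track(
    values: pd.Series, gmap: GeneticMap,
    width_cM: float = 5.0, step_cM: float = 1.0,
) -> pd.DataFrame:
    """Mean of a per-marker statistic in sliding windows.

    ``values`` is indexed by marker_id (NaN entries are skipped); windows
    with no contributing marker get NaN.  Returns a DataFrame with columns
    linkage_group, window_start_cM, window_end_cM, n_markers, value.
    """
    rows = []
    for lg, start, end, ids in iter_windows(gmap, width_cM, step_cM):
        v = values.reindex(ids).dropna()
        rows.append((lg, start, end, len(v),
                     float(v.mean()) if len(v) else np.nan))
    return pd.DataFrame(
        rows, columns=["linkage_group", "window_start_cM", "window_end_cM",
                       "n_markers", "value"],
    )


def sliding_window_diversity(
    g: GenotypeMatrix, gmap: GeneticMap | None = None,
    width_cM: float = 5.0, step_cM: float = 1.0,
    subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sliding-window track of mean UHe across each linkage group."""
    gmap = gmap if gmap is not None else g.gmap
    if gmap is None:
        raise ValueError("a genetic map is required")
    uhe, _, _ = unbiased_gene_diversity(g, subset=subset)
    return sliding_window_track(uhe, gmap, width_cM, step_cM)
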