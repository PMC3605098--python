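"""Pairwise linkage disequilibrium (r^2), decay curves and window tracks.

r^2 here is the composite measure: the squared Pearson correlation of the
two markers' dosage vectors over the accessions called at both markers.
For fully homozygous inbred lines this coincides with the haplotype
frequency correlation; with a few percent residual heterozygosity the two
differ negligibly and the composite form needs no phasing.

Decay summaries follow a per-focal-marker construction: each marker's own
(distance, r^2) pairs are smoothed with a Nadaraya-Watson box kernel, and
the crossing distance is the smallest grid distance at which that smoothed
profile falls below the threshold (censored at the marker's maximum
observed pair distance when it never does).  Per linkage group the mean
and median of these per-marker crossings are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import GeneticMap, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Minimum number of accessions called at both markers for a defined r^2.
MIN_SHARED_CALLS = 4


def r2_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Full marker x marker r^2 matrix with pairwise-complete observations.

    Entries with fewer than :data:`MIN_SHARED_CALLS` shared calls or a
    constant dosage vector in the shared subset are NaN.  The diagonal is
    1 for polymorphic markers.
    """
    x = g.dosage_float()
    m = (~np.isnan(x)).astype(float)
    xf = np.nan_to_num(x)
    xf2 = xf * xf
    n = m.T @ m                 # shared call counts
    sx = xf.T @ m               # sum of x over shared calls (rows: marker a)
    sxx = xf2.T @ m
    sxy = xf.T @ xf
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx * sx
        var = varx * varx.T     # var_a(shared) * var_b(shared), both sided
        r2 = np.where(var > 0, (cov * cov) / var, np.nan)
    r2[n < MIN_SHARED_CALLS] = np.nan
    return r2


def _r2_single_pair(xa: np.ndarray, xb: np.ndarray) -> float:
    ok = ~(np.isnan(xa) | np.isnan(xb))
    if ok.sum() < MIN_SHARED_CALLS:
        return np.nan
    a, b = xa[ok], xb[ok]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pair_frame(
    g: GenotypeMatrix, gmap: GeneticMap | None,
    idx_a: np.ndarray, idx_b: np.ndarray, r2: np.ndarray,
) -> pd.DataFrame:
    ma = [g.marker_ids[i] for i in idx_a]
    mb = [g.marker_ids[i] for i in idx_b]
    out = pd.DataFrame({"marker_a": ma, "marker_b": mb, "r2": r2})
    if gmap is not None:
        lg_a = gmap.groups(ma).astype(float)
        lg_b = gmap.groups(mb).astype(float)
        dist = np.abs(gmap.positions(ma) - gmap.positions(mb))
        dist = np.where(lg_a == lg_b, dist, np.nan)
        out.insert(2, "lg_a", lg_a.astype(int))
        out.insert(3, "lg_b", lg_b.astype(int))
        out.insert(4, "distance_cM", dist)
    return out


def pairwise_r2(
    g: GenotypeMatrix,
    pairs: list[tuple[str, str]] | str = "within_group",
    gmap: GeneticMap | None = None,
) -> pd.DataFrame:
    """r^2 for explicit marker pairs, all within-group pairs, or all pairs.

    ``pairs`` is either a list of (marker_a, marker_b) tuples, the string
    ``"within_group"`` (all unordered pairs within each linkage group;
    requires a map) or ``"all"``.  Returns a DataFrame with columns
    marker_a, marker_b[, lg_a, lg_b, distance_cM], r2; cross-group pairs
    carry NaN distance.
    """
    gmap = gmap if gmap is not None else g.gmap
    if isinstance(pairs, str):
        if pairs == "within_group":
            if gmap is None:
                raise ValueError("within_group pairs require a genetic map")
            lg = gmap.groups(g.marker_ids)
            mat = r2_matrix(g)
            ia, ib = np.triu_indices(g.n_markers, k=1)
            same = lg[ia] == lg[ib]
            ia, ib = ia[same], ib[same]
            return _pair_frame(g, gmap, ia, ib, mat[ia, ib])
        if pairs == "all":
            mat = r2_matrix(g)
            ia, ib = np.triu_indices(g.n_markers, k=1)
            return _pair_frame(g, gmap, ia, ib, mat[ia, ib])
        raise ValueError(f"unknown pair selector {pairs!r}")
    x = g.dosage_float()
    idx_a = g.marker_indexer([a for a, _ in pairs])
    idx_b = g.marker_indexer([b for _, b in pairs])
    vals = np.array([_r2_single_pair(x[:, i], x[:, j])
                     for i, j in zip(idx_a, idx_b)])
    return _pair_frame(g, gmap, idx_a, idx_b, vals)


def sample_random_pairs(
    gmap: GeneticMap,
    n_pairs: int = 10000,
    max_distance_cM: float = 50.0,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, str]]:
    """Uniform sample (without replacement) of within-group marker pairs
    separated by at most ``max_distance_cM``.

    If fewer eligible pairs exist than requested, all are returned and the
    shortfall is logged.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cand_a: list[np.ndarray] = []
    cand_b: list[np.ndarray] = []
    tab = gmap.table
    for lg in gmap.linkage_groups:
        sub = tab[tab["linkage_group"] == lg]
        ids = np.asarray(sub.index)
        pos = sub["position_cM"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        ids, pos = ids[order], pos[order]
        for i in range(len(pos)):
            hi = np.searchsorted(pos, pos[i] + max_distance_cM, side="right")
            js = np.arange(i + 1, hi)
            if js.size:
                cand_a.append(np.repeat(ids[i], js.size))
                cand_b.append(ids[js])
    if not cand_a:
        logger.warning("no eligible pairs within %.1f cM", max_distance_cM)
        return []
    all_a = np.concatenate(cand_a)
    all_b = np.concatenate(cand_b)
    total = all_a.size
    if total <= n_pairs:
        if total < n_pairs:
            logger.warning("only %d eligible pairs (requested %d)",
                           total, n_pairs)
        chosen = np.arange(total)
    else:
        chosen = rng.choice(total, size=n_pairs, replace=False)
        chosen.sort()
    return [(str(a), str(b)) for a, b in zip(all_a[chosen], all_b[chosen])]


def _box_smooth(
    dist: np.ndarray, r2: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Nadaraya-Watson estimate with a box kernel of half-width
    ``bandwidth``; grid points with no pair in the window are NaN."""
    inside = np.abs(dist[None, :] - grid[:, None]) <= bandwidth
    counts = inside.sum(axis=1)
    sums = inside @ r2
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


@dataclass
class LDDecay:
    """Smoothed decay curves and per-marker threshold crossings."""

    curves: pd.DataFrame      # linkage_group, distance_cM, r2_smooth, n_pairs
    crossings: pd.DataFrame   # marker_id, linkage_group, crossing_cM, censored
    summary: pd.DataFrame     # linkage_group, mean/median crossing, counts


def ld_decay_curve(
    pairs: pd.DataFrame,
    bandwidth_cM: float = 2.0,
    threshold: float = 0.1,
    grid_step_cM: float = 0.25,
) -> LDDecay:
    """Kernel-smoothed r^2 decay and per-marker crossing summaries.

    ``pairs`` must contain marker_a, marker_b, lg_a, distance_cM, r2 (as
    produced by :func:`pairwise_r2`); cross-group and NaN entries are
    dropped.  Crossings that never occur are censored at the marker's
    maximum observed pair distance and flagged.
    """
    if bandwidth_cM <= 0:
        raise ValueError("bandwidth must be > 0")
    ok = pairs.dropna(subset=["distance_cM", "r2"])
    if len(ok) < 2:
        raise ValueError("need at least 2 pairs with finite distance")

    curve_rows = []
    cross_rows = []
    for lg, sub in ok.groupby("lg_a"):
        dist = sub["distance_cM"].to_numpy()
        r2 = sub["r2"].to_numpy()
        grid = np.arange(0.0, dist.max() + grid_step_cM, grid_step_cM)
        sm = _box_smooth(dist, r2, grid, bandwidth_cM)
        inside = np.abs(dist[None, :] - grid[:, None]) <= bandwidth_cM
        for gpt, val, cnt in zip(grid, sm, inside.sum(axis=1)):
            curve_rows.append((int(lg), gpt, val, int(cnt)))

        # per focal marker profile
        markers = pd.unique(np.concatenate(
            [sub["marker_a"].to_numpy(), sub["marker_b"].to_numpy()]
        ))
        by_marker: dict[str, list[int]] = {m: [] for m in markers}
        for row_i, (a, b) in enumerate(zip(sub["marker_a"], sub["marker_b"])):
            by_marker[a].append(row_i)
            by_marker[b].append(row_i)
        for m in markers:
            rows_i = np.asarray(by_marker[m])
            d_m, r_m = dist[rows_i], r2[rows_i]
            gmax = d_m.max()
            g_m = grid[grid <= gmax + grid_step_cM]
            prof = _box_smooth(d_m, r_m, g_m, bandwidth_cM)
            below = np.flatnonzero(prof < threshold)
            if below.size:
                cross_rows.append((m, int(lg), float(g_m[below[0]]), False))
            else:
                cross_rows.append((m, int(lg), float(gmax), True))

    curves = pd.DataFrame(
        curve_rows,
        columns=["linkage_group", "distance_cM", "r2_smooth", "n_pairs"],
    )
    crossings = pd.DataFrame(
        cross_rows,
        columns=["marker_id", "linkage_group", "crossing_cM", "censored"],
    )
    summary = (
        crossings.groupby("linkage_group")
        .agg(mean_crossing_cM=("crossing_cM", "mean"),
             median_crossing_cM=("crossing_cM", "median"),
             n_markers=("marker_id", "size"),
             n_censored=("censored", "sum"))
        .reset_index()
    )
    return LDDecay(curves=curves, crossings=crossings, summary=summary)


def sliding_window_r2(
    g: GenotypeMatrix, gmap: GeneticMap | None = None,
    width_cM: float = 5.0, step_cM: float = 1.0,
) -> pd.DataFrame:
    """Sliding-window track of mean pairwise r^2.

    The window value is the mean r^2 over all unordered pairs of markers
    with both members inside the window; windows with fewer than two
    markers are NaN.
    """
    from .diversity import iter_windows

    gmap = gmap if gmap is not None else g.gmap
    if gmap is None:
        raise ValueError("a genetic map is required")
    mat = r2_matrix(g)
    pos_of = {m: i for i, m in enumerate(g.marker_ids)}
    rows = []
    for lg, start, end, ids in iter_windows(gmap, width_cM, step_cM):
        idx = np.array([pos_of[m] for m in ids if m in pos_of], dtype=int)
        if idx.size < 2:
            rows.append((lg, start, end, idx.size, np.nan))
            continue
        block = mat[np.ix_(idx, idx)]
        vals = block[np.triu_indices(idx.size, k=1)]
        vals = vals[~np.isnan(vals)]
        rows.append((lg, start, end, idx.size,
                     float(vals.mean()) if vals.size else np.nan))
    return pd.DataFrame(
        rows, columns=["linkage_group", "window_start_cM", "window_end_cM",
                       "n_markers", "value"],
    )
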