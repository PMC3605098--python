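"""Greedy graphical genotypes: shared haplotype blocks and template cycles.

A shared block is a maximal run of >= ``min_block`` consecutive
map-ordered markers (never spanning a linkage-group boundary) at which two
accessions are both homozygous, non-missing, unmasked and carry the same
dosage.  Heterozygous and missing calls terminate runs and are never
painted, so stretches with fewer than ``min_block`` consecutive
homozygous SNPs remain unassigned ("white").

The painting proceeds greedily.  Each cycle: (1) shared blocks are found
on the currently unmasked cells; (2) every accession i is scored as the
mean, over all other accessions j, of the fraction of j's genome lying in
blocks shared with i; (3) the best-scoring accession becomes the cycle's
template (ties broken by input order); (4) the template's unmasked
homozygous cells, plus every cell of other accessions inside blocks
shared with the template, receive the cycle's label; (5) labeled cells
are masked.  The default 25 cycles produce labels G1..G25; the loop stops
early once no block remains.  Genome-share fractions per accession and
label, and the cumulative coverage of the most common labels, summarize
the painting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import MISSING, GeneticMap, GenotypeMatrix

logger = logging.getLogger(__name__)

UNASSIGNED = 0


@dataclass
class Block:
    """A shared homozygous run between two accessions (indices refer to
    map-ordered marker positions, end inclusive)."""

    accession_i: str
    accession_j: str
    linkage_group: int
    start_index: int
    end_index: int

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1


def _ordered(g: GenotypeMatrix, gmap: GeneticMap | None) -> GenotypeMatrix:
    gmap = gmap if gmap is not None else g.gmap
    if gmap is None:
        raise ValueError("a genetic map is required")
    return g.ordered_by_map(gmap)


def _lg_bounds(gmap: GeneticMap, marker_ids: list[str]) -> list[tuple[int, int, int]]:
    """(linkage_group, start, stop) contiguous spans in map order."""
    lg = gmap.groups(marker_ids)
    bounds = []
    start = 0
    for i in range(1, len(lg) + 1):
        if i == len(lg) or lg[i] != lg[start]:
            bounds.append((int(lg[start]), start, i))
            start = i
    return bounds


def _runs(ok: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open index pairs."""
    if not ok.any():
        return []
    padded = np.concatenate([[False], ok, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def shared_block_mask(
    g: GenotypeMatrix,
    gmap: GeneticMap | None = None,
    min_block: int = 25,
    mask: np.ndarray | None = None,
) -> list[Block]:
    """All shared blocks of length >= ``min_block`` between accession pairs.

    ``mask`` marks cells already painted (True = masked/unavailable).
    Intended for modest panels and for auditing the greedy cycles; the
    cycle driver itself uses a streaming equivalent.
    """
    if min_block < 2:
        raise ValueError("min_block must be >= 2")
    g = _ordered(g, gmap)
    d = g.dosage
    hom = (d == 0) | (d == 2)
    avail = hom if mask is None else (hom & ~mask)
    bounds = _lg_bounds(g.gmap, g.marker_ids)
    lg_of = g.gmap.groups(g.marker_ids)
    ext_index, shift = _break_layout(bounds, g.n_markers)
    ext_buf = np.zeros(len(shift) - 1, dtype=bool)
    blocks: list[Block] = []
    n = g.n_accessions
    for i in range(n):
        for j in range(i + 1, n):
            for s, e in _pair_shared_runs(d, avail, i, j, ext_index,
                                          ext_buf, shift, min_block):
                blocks.append(Block(
                    g.accession_ids[i], g.accession_ids[j],
                    int(lg_of[s]), s, e - 1,
                ))
    return blocks


@dataclass
class GenotypePainting:
    """Result of the greedy template cycles.

    ``labels`` is an accession x marker integer matrix in map order;
    0 = unassigned, c = painted in cycle c (label "Gc").
    """

    accession_ids: list[str]
    marker_ids: list[str]
    labels: np.ndarray
    templates: list[str]
    min_block: int
    n_cycles_run: int

    def label_frame(self) -> pd.DataFrame:
        txt = np.where(self.labels > 0,
                       np.char.add("G", self.labels.astype(str)), "")
        return pd.DataFrame(txt, index=self.accession_ids,
                            columns=self.marker_ids)


def _break_layout(
    bounds: list[tuple[int, int, int]], m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index layout that inserts a permanently-False slot between linkage
    groups so a single run scan never crosses a boundary.

    Returns (ext_index such that ext[ext_index] = values, shift such that
    original_start = ext_start - shift[ext_start]).
    """
    lg_ordinal = np.zeros(m, dtype=int)
    for k, (_, lo, hi) in enumerate(bounds):
        lg_ordinal[lo:hi] = k
    ext_index = np.arange(m) + lg_ordinal
    # run starts/stops always sit on real-marker slots (break slots are
    # False), so a per-slot shift indexed there is sufficient; stops may
    # land one past a run on a break slot, which carries the same shift.
    shift = np.zeros(m + len(bounds) + 1, dtype=int)
    shift[ext_index] = lg_ordinal
    shift[ext_index + 1] = np.maximum(shift[ext_index + 1], lg_ordinal)
    return ext_index, shift


def _pair_shared_runs(
    d: np.ndarray, avail: np.ndarray, i: int, j: int,
    ext_index: np.ndarray, ext_buf: np.ndarray, shift: np.ndarray,
    min_block: int,
) -> list[tuple[int, int]]:
    """Shared runs (start, stop half-open, original indices) for one pair."""
    pair_ok = avail[i] & avail[j] & (d[i] == d[j])
    ext_buf[ext_index] = pair_ok
    out = []
    for s, e in _runs(ext_buf):
        if e - s >= min_block:
            out.append((s - shift[s], e - shift[s]))
    return out


def greedy_template_cycles(
    g: GenotypeMatrix,
    gmap: GeneticMap | None = None,
    n_cycles: int = 25,
    min_block: int = 25,
    score: str = "mean_share",
    template_cells: str = "full",
) -> GenotypePainting:
    """Run the greedy template-painting algorithm.

    ``score="mean_share"`` (default) scores a candidate template by the
    mean over other accessions of their genome fraction shared with it;
    ``"union_coverage"`` scores by the fraction of the candidate's own
    genome covered by blocks shared with anyone.  ``template_cells="full"``
    labels the template's entire unmasked homozygous genome (its solid
    track); ``"blocks"`` labels only its block-participating cells.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if min_block < 2:
        raise ValueError("min_block must be >= 2")
    if score not in {"mean_share", "union_coverage"}:
        raise ValueError(f"unknown score {score!r}")
    if template_cells not in {"full", "blocks"}:
        raise ValueError(f"unknown template_cells {template_cells!r}")

    g = _ordered(g, gmap)
    d = g.dosage
    n, m = d.shape
    hom = (d == 0) | (d == 2)
    bounds = _lg_bounds(g.gmap, g.marker_ids)
    ext_index, shift = _break_layout(bounds, m)
    ext_buf = np.zeros(len(shift) - 1, dtype=bool)
    labels = np.zeros((n, m), dtype=np.int16)
    templates: list[str] = []
    cycles_run = 0

    for cycle in range(1, n_cycles + 1):
        avail = hom & (labels == UNASSIGNED)
        shared = np.zeros((n, n))
        runs_cache: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for i in range(n):
            for j in range(i + 1, n):
                runs = _pair_shared_runs(d, avail, i, j, ext_index,
                                         ext_buf, shift, min_block)
                if runs:
                    runs_cache[(i, j)] = runs
                    total = sum(e - s for s, e in runs)
                    shared[i, j] = shared[j, i] = total
        if not runs_cache:
            break
        if score == "mean_share":
            scores = shared.sum(axis=1) / (m * (n - 1))
        else:
            # union coverage: cells of i covered by a block with any j
            union = np.zeros((n, m), dtype=bool)
            for (i, j), runs in runs_cache.items():
                for s, e in runs:
                    union[i, s:e] = True
                    union[j, s:e] = True
            scores = union.sum(axis=1) / m
        t = int(np.argmax(scores))  # argmax keeps first index on ties

        cells = np.zeros((n, m), dtype=bool)
        if template_cells == "full":
            cells[t] = avail[t]
        for (i, j), runs in runs_cache.items():
            if i == t or j == t:
                for s, e in runs:
                    cells[i, s:e] = True
                    cells[j, s:e] = True
        labels[cells] = cycle
        templates.append(g.accession_ids[t])
        cycles_run = cycle

    return GenotypePainting(
        list(g.accession_ids), list(g.marker_ids), labels, templates,
        min_block, cycles_run,
    )


def genome_share_fractions(
    painting: GenotypePainting,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Per-accession and panel-average genome-share fractions per label.

    Returns (per-accession fractions with an "unassigned" column, average
    fraction per label, cumulative average coverage of the top-k most
    common labels).
    """
    n, m = painting.labels.shape
    n_labels = painting.n_cycles_run
    cols = {}
    for c in range(1, n_labels + 1):
        cols[f"G{c}"] = (painting.labels == c).sum(axis=1) / m
    frame = pd.DataFrame(
        cols, index=pd.Index(painting.accession_ids, name="accession_id")
    )
    frame["unassigned"] = (painting.labels == UNASSIGNED).sum(axis=1) / m
    avg = frame.drop(columns="unassigned").mean(axis=0)
    ranked = avg.sort_values(ascending=False)
    cumulative = ranked.cumsum()
    return frame, avg, cumulative
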