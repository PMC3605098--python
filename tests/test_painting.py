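import numpy as np
import pandas as pd
import pytest

from sunpanel.panel_io import MISSING, GeneticMap, GenotypeMatrix
from sunpanel.painting import (
    genome_share_fractions,
    greedy_template_cycles,
    shared_block_mask,
)

from conftest import make_matrix


def hap_matrix(haps, positions=None, lgs=None):
    """Accessions as full haplotype copies (dosage rows)."""
    return make_matrix(np.array(haps, dtype=np.int8), positions=positions
                       if positions is not None
                       else list(np.arange(len(haps[0]), dtype=float)),
                       lgs=lgs)


class TestSharedBlocks:
    def test_thirty_marker_identical_run_found(self):
        rng = np.random.default_rng(0)
        h = (2 * rng.integers(0, 2, 30)).astype(np.int8)
        g = hap_matrix([h, h])
        blocks = shared_block_mask(g, min_block=25)
        assert len(blocks) == 1
        assert blocks[0].length == 30

    def test_twenty_four_marker_run_rejected(self):
        rng = np.random.default_rng(1)
        h = (2 * rng.integers(0, 2, 24)).astype(np.int8)
        g = hap_matrix([h, h])
        assert shared_block_mask(g, min_block=25) == []

    def test_het_call_splits_fifty_marker_run(self):
        rng = np.random.default_rng(2)
        h = (2 * rng.integers(0, 2, 50)).astype(np.int8)
        other = h.copy()
        other[25] = 1            # heterozygous at ordinal 26
        g = hap_matrix([h, other])
        blocks = shared_block_mask(g, min_block=25)
        assert len(blocks) == 1
        assert (blocks[0].start_index, blocks[0].end_index) == (0, 24)

    def test_runs_do_not_span_linkage_groups(self):
        rng = np.random.default_rng(3)
        h = (2 * rng.integers(0, 2, 40)).astype(np.int8)
        g = hap_matrix([h, h], lgs=[1] * 20 + [2] * 20,
                       positions=list(np.arange(20.0)) * 2)
        assert shared_block_mask(g, min_block=25) == []
        blocks = shared_block_mask(g, min_block=20)
        assert {(b.linkage_group, b.length) for b in blocks} == \
            {(1, 20), (2, 20)}

    def test_missing_cells_terminate_runs(self):
        rng = np.random.default_rng(4)
        h = (2 * rng.integers(0, 2, 30)).astype(np.int8)
        other = h.copy()
        other[10] = MISSING
        g = hap_matrix([h, other])
        assert shared_block_mask(g, min_block=25) == []

    def test_min_block_validation(self):
        g = hap_matrix([[0, 2], [0, 2]])
        with pytest.raises(ValueError):
            shared_block_mask(g, min_block=1)


class TestGreedyCycles:
    def toy_panel(self):
        rng = np.random.default_rng(5)
        hap_a = (2 * rng.integers(0, 2, 60)).astype(np.int8)
        hap_b = (2 - hap_a).astype(np.int8)
        return hap_matrix([hap_a, hap_a, hap_a, hap_b, hap_b])

    def test_hand_traced_greedy_order(self):
        g = self.toy_panel()
        paint = greedy_template_cycles(g, n_cycles=25, min_block=25)
        # cycle 1: a1-a3 tie at score 0.5, lowest index wins; covers 1-3
        # cycle 2: haplotype B pair; nothing left afterwards
        assert paint.templates == ["a1", "a4"]
        assert paint.n_cycles_run == 2
        frac, avg, cum = genome_share_fractions(paint)
        np.testing.assert_allclose(frac["G1"], [1, 1, 1, 0, 0])
        assert avg["G1"] == pytest.approx(0.6)
        assert cum.iloc[-1] == pytest.approx(1.0)
        assert (frac["unassigned"] == 0).all()

    def test_all_distinct_panel_entirely_unassigned(self):
        rng = np.random.default_rng(6)
        dosage = (2 * rng.integers(0, 2, size=(4, 40))).astype(np.int8)
        dosage[1] = 2 - dosage[0]
        dosage[3] = 2 - dosage[2]
        # ensure pairwise mismatch within any 25-marker stretch
        dosage[2, ::2] = 2 - dosage[0, ::2]
        g = make_matrix(dosage, positions=list(np.arange(40.0)))
        paint = greedy_template_cycles(g, n_cycles=25, min_block=25)
        assert paint.n_cycles_run == 0
        frac, avg, _ = genome_share_fractions(paint)
        assert (frac["unassigned"] == 1.0).all()

    def test_masking_monotone_and_labels_final(self):
        rng = np.random.default_rng(7)
        founders = (2 * rng.integers(0, 2, size=(3, 120))).astype(np.int8)
        copies = founders[[0, 0, 0, 1, 1, 2, 0, 1, 2, 2]]
        g = make_matrix(copies, positions=list(np.arange(120.0)))
        prev_labeled = 0
        prev = None
        for c in range(1, 6):
            paint = greedy_template_cycles(g, n_cycles=c, min_block=25)
            labeled = (paint.labels > 0).sum()
            assert labeled >= prev_labeled
            if prev is not None:
                mask = prev.labels > 0
                np.testing.assert_array_equal(paint.labels[mask],
                                              prev.labels[mask])
            prev, prev_labeled = paint, labeled
        assert prev_labeled <= g.dosage.size

    def test_founder_recovery_with_exact_fractions(self):
        rng = np.random.default_rng(8)
        founders = (2 * rng.integers(0, 2, size=(3, 200))).astype(np.int8)
        counts = [5, 3, 2]
        rows = [founders[f] for f, c in enumerate(counts) for _ in range(c)]
        g = make_matrix(np.array(rows), positions=list(np.arange(200.0)))
        paint = greedy_template_cycles(g, n_cycles=25, min_block=25)
        frac, avg, cum = genome_share_fractions(paint)
        # templates recover the three founders in copy-count order
        assert paint.n_cycles_run == 3
        founder_of_acc = [f for f, c in enumerate(counts) for _ in range(c)]
        for cycle, tmpl in enumerate(paint.templates):
            idx = g.accession_ids.index(tmpl)
            assert founder_of_acc[idx] == cycle
        np.testing.assert_allclose(
            [avg[f"G{c}"] for c in (1, 2, 3)], [0.5, 0.3, 0.2])
        assert cum.iloc[-1] == pytest.approx(1.0)

    def test_every_labeled_nontemplate_cell_in_audited_block(self):
        rng = np.random.default_rng(9)
        founders = (2 * rng.integers(0, 2, size=(2, 80))).astype(np.int8)
        g = make_matrix(founders[[0, 0, 1, 1, 0]],
                        positions=list(np.arange(80.0)))
        paint = greedy_template_cycles(g, n_cycles=1, min_block=25)
        blocks = shared_block_mask(g, min_block=25)
        t = paint.templates[0]
        covered = np.zeros_like(paint.labels, dtype=bool)
        for b in blocks:
            if t in (b.accession_i, b.accession_j):
                for acc in (b.accession_i, b.accession_j):
                    ai = g.accession_ids.index(acc)
                    covered[ai, b.start_index:b.end_index + 1] = True
        for ai, acc in enumerate(g.accession_ids):
            if acc == t:
                continue
            assert (covered[ai] | (paint.labels[ai] == 0)).all()

    def test_sweep_pool_shares_one_label_across_interval(self, sweep_panel):
        cfg, g, gmap, meta, truth = sweep_panel
        paint = greedy_template_cycles(g, gmap, n_cycles=10, min_block=15)
        order = [m for m in paint.marker_ids]
        sweep_cols = np.array([
            truth.sweep_markers[g.marker_ids.index(m)] for m in order])
        carriers = [i for i, a in enumerate(paint.accession_ids)
                    if truth.sweep_carriers[g.accession_ids.index(a)]]
        sub = paint.labels[np.ix_(carriers, np.flatnonzero(sweep_cols))]
        assigned = sub[sub > 0]
        # one label dominates the swept pool across the interval
        top_share = np.bincount(assigned).max() / assigned.size
        assert top_share > 0.6
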