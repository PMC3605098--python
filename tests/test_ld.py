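import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sunpanel.panel_io import MISSING, GeneticMap
from sunpanel.ld import (
    ld_decay_curve,
    pairwise_r2,
    r2_matrix,
    sample_random_pairs,
    sliding_window_r2,
)

from conftest import make_matrix


def brute_force_r2(xa, xb):
    ok = ~(np.isnan(xa) | np.isnan(xb))
    if ok.sum() < 4:
        return np.nan
    a, b = xa[ok], xb[ok]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return np.corrcoef(a, b)[0, 1] ** 2


class TestPairwiseR2:
    def test_duplicated_marker_gives_one(self):
        g = make_matrix([[0, 0], [0, 0], [2, 2], [2, 2], [1, 1]])
        tab = pairwise_r2(g, [("m001", "m002")])
        assert tab["r2"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_markers_give_zero(self):
        g = make_matrix([[0, 0], [0, 2], [2, 0], [2, 2]])
        tab = pairwise_r2(g, [("m001", "m002")])
        assert tab["r2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_half_correlation_hand_example(self):
        x = [0, 0, 0, 2, 2, 2]
        y = [0, 0, 2, 2, 2, 2]
        g = make_matrix(np.array([x, y]).T)
        tab = pairwise_r2(g, [("m001", "m002")])
        assert tab["r2"].iloc[0] == pytest.approx(0.5, rel=1e-12)

    def test_too_few_shared_calls_is_nan(self):
        x = [0, 2, MISSING, MISSING, MISSING]
        y = [0, 2, 0, 2, 1]
        g = make_matrix(np.array([x, y]).T)
        tab = pairwise_r2(g, [("m001", "m002")])
        assert np.isnan(tab["r2"].iloc[0])

    def test_constant_in_shared_subset_is_nan(self):
        x = [0, 0, 0, 0, 2]
        y = [0, 2, 0, 2, MISSING]
        g = make_matrix(np.array([x, y]).T)
        tab = pairwise_r2(g, [("m001", "m002")])
        assert np.isnan(tab["r2"].iloc[0])

    def test_matrix_matches_brute_force_with_missing(self):
        rng = np.random.default_rng(7)
        dosage = rng.choice([0, 1, 2, MISSING], p=[.4, .1, .4, .1],
                            size=(30, 12)).astype(np.int8)
        g = make_matrix(dosage)
        mat = r2_matrix(g)
        x = g.dosage_float()
        for i in range(12):
            for j in range(i + 1, 12):
                expect = brute_force_r2(x[:, i], x[:, j])
                if np.isnan(expect):
                    assert np.isnan(mat[i, j])
                else:
                    assert mat[i, j] == pytest.approx(expect, rel=1e-10)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_allele_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        dosage = rng.choice([0, 1, 2], size=(12, 2)).astype(np.int8)
        g = make_matrix(dosage)
        flipped = dosage.copy()
        flipped[:, 0] = 2 - flipped[:, 0]
        gf = make_matrix(flipped)
        a = pairwise_r2(g, [("m001", "m002")])["r2"].iloc[0]
        b = pairwise_r2(gf, [("m001", "m002")])["r2"].iloc[0]
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, abs=1e-12)


class TestRandomPairs:
    def make_map(self, positions, lgs=None):
        markers = [f"m{i + 1:03d}" for i in range(len(positions))]
        return GeneticMap(pd.DataFrame(
            {"linkage_group": lgs or [1] * len(positions),
             "position_cM": positions},
            index=pd.Index(markers, name="marker_id")))

    def test_shortfall_returns_all_pairs(self):
        gmap = self.make_map([0.0, 10.0, 20.0])
        pairs = sample_random_pairs(gmap, n_pairs=10, max_distance_cM=50)
        assert len(pairs) == 3

    def test_reproducible_under_seed(self):
        gmap = self.make_map(list(np.linspace(0, 80, 40)))
        a = sample_random_pairs(gmap, 100, seed=9)
        b = sample_random_pairs(gmap, 100, seed=9)
        assert a == b

    def test_all_pairs_too_distant_gives_empty(self):
        gmap = self.make_map([0.0, 90.0])
        assert sample_random_pairs(gmap, 10, max_distance_cM=50) == []

    def test_distance_bound_respected(self):
        gmap = self.make_map(list(np.linspace(0, 200, 60)))
        pairs = sample_random_pairs(gmap, 200, max_distance_cM=30, seed=1)
        pos = gmap.table["position_cM"]
        for a, b in pairs:
            assert abs(pos[a] - pos[b]) <= 30


class TestDecayCurve:
    def test_all_pairs_at_one_never_cross(self):
        pairs = pd.DataFrame({
            "marker_a": ["a"] * 5, "marker_b": list("bcdef"),
            "lg_a": 1, "lg_b": 1,
            "distance_cM": [1.0, 2, 3, 4, 5], "r2": 1.0,
        })
        decay = ld_decay_curve(pairs, bandwidth_cM=2, threshold=0.1)
        assert (decay.curves["r2_smooth"].dropna() == 1.0).all()
        assert decay.crossings["censored"].all()

    def test_exponential_decay_crossing_near_ln10(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 10, 4000)
        r2 = np.clip(np.exp(-d) + rng.normal(0, 0.01, d.size), 0, 1)
        markers_a = [f"x{i}" for i in range(len(d))]
        pairs = pd.DataFrame({
            "marker_a": "focal", "marker_b": markers_a,
            "lg_a": 1, "lg_b": 1, "distance_cM": d, "r2": r2,
        })
        decay = ld_decay_curve(pairs, bandwidth_cM=0.5, threshold=0.1,
                               grid_step_cM=0.05)
        focal = decay.crossings.set_index("marker_id").loc["focal"]
        # smoothed exp(-d) falls below 0.1 near ln(10) ~ 2.30
        assert abs(focal["crossing_cM"] - np.log(10)) < 0.5

    def test_crossings_match_grid_scan_oracle(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 8, 500)
        r2 = np.clip(1.2 * np.exp(-d / 2) + rng.normal(0, 0.02, d.size), 0, 1)
        pairs = pd.DataFrame({
            "marker_a": "focal", "marker_b": [f"y{i}" for i in range(len(d))],
            "lg_a": 1, "lg_b": 1, "distance_cM": d, "r2": r2,
        })
        bw, thr, step = 1.0, 0.1, 0.25
        decay = ld_decay_curve(pairs, bw, thr, step)
        # oracle: explicit scan of the box-kernel smoother on the grid
        grid = np.arange(0.0, d.max() + step, step)
        cross = None
        for gpt in grid:
            inside = np.abs(d - gpt) <= bw
            if inside.any() and r2[inside].mean() < thr:
                cross = gpt
                break
        focal = decay.crossings.set_index("marker_id").loc["focal"]
        assert focal["crossing_cM"] == pytest.approx(cross)

    def test_needs_two_pairs(self):
        pairs = pd.DataFrame({
            "marker_a": ["a"], "marker_b": ["b"], "lg_a": [1], "lg_b": [1],
            "distance_cM": [1.0], "r2": [0.5]})
        with pytest.raises(ValueError):
            ld_decay_curve(pairs)


class TestWindowR2:
    def test_duplicated_pair_window_is_one(self):
        g = make_matrix([[0, 0], [2, 2], [0, 0], [2, 2]],
                        positions=[1.0, 2.0])
        track = sliding_window_r2(g, width_cM=5, step_cM=5)
        assert track["value"].iloc[0] == pytest.approx(1.0)

    def test_window_mean_of_three_pairs(self, sweep_panel):
        # brute-force oracle on a toy map
        rng = np.random.default_rng(11)
        dosage = rng.choice([0, 2], size=(40, 8)).astype(np.int8)
        positions = np.sort(rng.uniform(0, 12, 8))
        g = make_matrix(dosage, positions=list(positions))
        track = sliding_window_r2(g, width_cM=5, step_cM=1)
        mat = r2_matrix(g)
        for _, row in track.iterrows():
            idx = [i for i, p in enumerate(positions)
                   if row["window_start_cM"] <= p < row["window_end_cM"]]
            if len(idx) < 2:
                assert np.isnan(row["value"])
                continue
            vals = [mat[i, j] for i in idx for j in idx if i < j]
            vals = [v for v in vals if not np.isnan(v)]
            if vals:
                assert row["value"] == pytest.approx(np.mean(vals), rel=1e-10)

    def test_sweep_windows_exceed_genome_median(self, sweep_panel):
        cfg, g, gmap, _, _ = sweep_panel
        track = sliding_window_r2(g, gmap)
        s = cfg.sweep
        inside = track[(track["linkage_group"] == s.linkage_group)
                       & (track["window_start_cM"] >= s.start_cM)
                       & (track["window_end_cM"] <= s.end_cM)]
        assert np.nanmean(inside["value"]) > np.nanmedian(track["value"])

    def test_fraction_below_cutoff_monotone(self, sweep_panel):
        _, g, gmap, _, _ = sweep_panel
        track = sliding_window_r2(g, gmap)["value"].dropna()
        fracs = [(track < c).mean() for c in (0.05, 0.1, 0.2, 0.4)]
        assert fracs == sorted(fracs)
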