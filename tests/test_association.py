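import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from sunpanel.association import (
    fit_null_mlm,
    genomic_lambda,
    qq_data,
    scan_association,
    simpleM_threshold,
)
from sunpanel.structure import KinshipMatrix, kinship_matrix

from conftest import make_matrix


def identity_kinship(accessions):
    ids = pd.Index(accessions, name="accession_id")
    # relative-kinship scale: 2K = I  =>  K = I/2
    return KinshipMatrix(pd.DataFrame(np.eye(len(ids)) / 2.0,
                                      index=ids, columns=ids), "identity", 0)


class TestNullFit:
    def test_zero_kinship_collapses_to_ols(self):
        rng = np.random.default_rng(0)
        acc = [f"a{i}" for i in range(40)]
        ids = pd.Index(acc, name="accession_id")
        kin = KinshipMatrix(pd.DataFrame(np.zeros((40, 40)),
                                         index=ids, columns=ids), "zero", 0)
        y = pd.Series(rng.normal(size=40), index=acc)
        fit = fit_null_mlm(y, kin)
        assert fit.sigma2_g == pytest.approx(0.0, abs=1e-6)
        assert fit.sigma2_e == pytest.approx(y.var(ddof=1), rel=0.1)

    def test_constant_phenotype_rejected(self):
        acc = [f"a{i}" for i in range(10)]
        y = pd.Series(1.0, index=acc)
        with pytest.raises(ValueError):
            fit_null_mlm(y, identity_kinship(acc))

    def test_variance_ratio_recovery(self, sweep_panel):
        # sigma2_g = sigma2_e = 1 under the panel kinship: the mean
        # estimated ratio over replicates stays within a factor of 2
        _, g, _, _, _ = sweep_panel
        kin = kinship_matrix(g)
        a = 2.0 * kin.values.to_numpy()
        a = 0.5 * (a + a.T)
        evals, evecs = np.linalg.eigh(a)
        evals = np.maximum(evals, 0)
        rng = np.random.default_rng(42)
        ratios = []
        for _ in range(10):
            u = evecs @ (np.sqrt(evals) * rng.normal(size=len(a)))
            y = pd.Series(u + rng.normal(size=len(a)),
                          index=kin.values.index)
            fit = fit_null_mlm(y, kin)
            ratios.append(fit.sigma2_g / max(fit.sigma2_e, 1e-12))
        mean_ratio = np.mean(ratios)
        assert 0.5 < mean_ratio < 2.0


class TestScan:
    def test_identity_kinship_matches_ols_pvalues(self):
        rng = np.random.default_rng(1)
        dosage = rng.choice([0, 1, 2], size=(50, 20)).astype(np.int8)
        g = make_matrix(dosage)
        y = pd.Series(rng.normal(size=50), index=g.accession_ids)
        fit = fit_null_mlm(y, identity_kinship(g.accession_ids))
        tab, _ = scan_association(g, fit, "k")
        x = dosage.astype(float)
        for i in range(20):
            if np.isnan(tab["p"].iloc[i]):
                continue
            ols = sm.OLS(y.values, sm.add_constant(x[:, i])).fit()
            assert tab["p"].iloc[i] == pytest.approx(ols.pvalues[1], rel=1e-6)
            assert tab["effect"].iloc[i] == pytest.approx(ols.params[1],
                                                          rel=1e-6)

    def test_effect_sign_flips_with_allele_labels_p_unchanged(self):
        rng = np.random.default_rng(2)
        dosage = rng.choice([0, 2], size=(60, 5)).astype(np.int8)
        g = make_matrix(dosage)
        y = pd.Series(dosage[:, 0] + rng.normal(size=60),
                      index=g.accession_ids)
        fit = fit_null_mlm(y, None, model="naive")
        tab, _ = scan_association(g, fit, "naive")
        flipped = make_matrix((2 - dosage).astype(np.int8))
        tabf, _ = scan_association(flipped, fit, "naive")
        np.testing.assert_allclose(tab["effect"], -tabf["effect"], rtol=1e-8)
        np.testing.assert_allclose(tab["p"], tabf["p"], rtol=1e-8)

    def test_marker_collinear_with_covariates_flagged(self):
        rng = np.random.default_rng(3)
        dosage = rng.choice([0, 2], size=(30, 3)).astype(np.int8)
        g = make_matrix(dosage)
        y = pd.Series(rng.normal(size=30), index=g.accession_ids)
        covar = pd.DataFrame({"c1": dosage[:, 0].astype(float)},
                             index=pd.Index(g.accession_ids,
                                            name="accession_id"))
        fit = fit_null_mlm(y, identity_kinship(g.accession_ids), covar)
        tab, _ = scan_association(g, fit, "pk")
        assert tab["note"].iloc[0] == "collinear"
        assert np.isnan(tab["p"].iloc[0])


class TestSimpleM:
    def test_independent_markers_meff_near_count(self):
        rng = np.random.default_rng(4)
        dosage = (2 * (rng.random((400, 100)) < 0.5)).astype(np.int8)
        g = make_matrix(dosage, positions=list(np.linspace(0, 99, 100)))
        thr = simpleM_threshold(g, alpha=0.05)
        assert 90 <= thr.meff_total <= 100
        # oracle: direct eigen-sum scan
        corr = np.corrcoef(dosage.astype(float), rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        frac = np.cumsum(evals) / evals.sum()
        expect = int(np.searchsorted(frac, 0.995) + 1)
        assert thr.meff_total == expect

    def test_duplicated_markers_do_not_inflate_meff(self):
        rng = np.random.default_rng(5)
        base = (2 * (rng.random((400, 100)) < 0.5)).astype(np.int8)
        tripled = np.repeat(base, 3, axis=1)
        g = make_matrix(tripled, positions=list(np.linspace(0, 99, 300)))
        thr = simpleM_threshold(g)
        assert 90 <= thr.meff_total <= 105

    def test_threshold_scales_as_alpha_over_meff(self, sweep_panel):
        _, g, gmap, _, _ = sweep_panel
        t1 = simpleM_threshold(g, gmap, alpha=0.05)
        t2 = simpleM_threshold(g, gmap, alpha=0.01)
        assert t1.meff_total == t2.meff_total
        assert t1.p_star == pytest.approx(0.05 / t1.meff_total)
        assert t2.p_star == pytest.approx(t1.p_star / 5.0)

    def test_single_marker_group_contributes_one(self):
        g = make_matrix([[0, 0], [2, 2], [0, 2], [2, 0]],
                        positions=[0.0, 0.0], lgs=[1, 2])
        thr = simpleM_threshold(g)
        assert thr.meff_per_group == {1: 1, 2: 1}


class TestQQ:
    def test_uniform_pvalues_lambda_near_one(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=20000)
        _, lam = qq_data(p)
        assert lam == pytest.approx(1.0, abs=0.05)

    def test_doubled_chisq_lambda_near_two(self):
        from scipy import stats
        rng = np.random.default_rng(7)
        chi = stats.chi2.rvs(1, size=20000, random_state=rng)
        p = stats.chi2.sf(2.0 * chi, 1)
        _, lam = qq_data(p)
        # oracle: direct median ratio
        expect = np.median(2.0 * chi) / stats.chi2.ppf(0.5, 1)
        assert lam == pytest.approx(expect, rel=1e-10)
        assert lam == pytest.approx(2.0, abs=0.1)

    def test_all_pvalues_one_gives_zero_observed(self):
        frame, _ = qq_data(np.ones(10))
        assert (frame["observed_neglog10"] == 0).all()

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            qq_data(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            qq_data(np.array([1.5]))
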