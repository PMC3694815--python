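import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from conftest import random_dosages
from pmrgwas.glm import (conditional_scan, fit_glm, genomic_inflation,
                         prescreen, single_marker_scan)
from pmrgwas.io import CovariateMatrix, GenotypeDataset, PhenotypeVector


def _dataset(dosages, bp_step=1000, chrom="1"):
    n, p = dosages.shape
    markers = pd.DataFrame({"chrom": chrom, "id": [f"m{j}" for j in range(p)],
                            "cm": np.arange(p) * 1e-3,
                            "bp": (np.arange(p) + 1) * bp_step})
    samples = pd.DataFrame({"fid": [f"s{i}" for i in range(n)],
                            "iid": "1", "sex": 0})
    return GenotypeDataset(dosages, markers, samples,
                           np.zeros((n, p), dtype=bool))


def test_intercept_only_logistic_closed_form():
    y = PhenotypeVector(np.r_[np.ones(30), np.zeros(70)], "logistic")
    fit = fit_glm(y, None, CovariateMatrix.intercept_only(100))
    assert fit.params[0] == pytest.approx(np.log(30 / 70), abs=1e-6)


def test_noiseless_linear_slope_exact(rng):
    x = rng.normal(0, 1, 50)
    y = PhenotypeVector(2.0 * x, "linear")
    C = CovariateMatrix(np.column_stack([np.ones(50), x]), ["intercept", "x"])
    fit = fit_glm(y, None, C)
    assert fit.params[1] == pytest.approx(2.0, abs=1e-10)


def test_logistic_fit_matches_generic_optimizer(rng):
    n = 500
    x = rng.normal(0, 1, n)
    eta = -0.4 + 0.8 * x
    y = PhenotypeVector((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float),
                        "logistic")
    C = CovariateMatrix(np.column_stack([np.ones(n), x]), ["intercept", "x"])
    fit = fit_glm(y, None, C)

    def negll(b):
        e = C.values @ b
        return -np.sum(y.values * e - np.logaddexp(0, e))

    res = optimize.minimize(negll, np.zeros(2), method="BFGS", tol=1e-12)
    np.testing.assert_allclose(fit.params, res.x, atol=1e-6)
    assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)


def test_logistic_fit_matches_statsmodels(rng):
    import statsmodels.api as sm
    n = 300
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    y = (rng.random(n) < 0.4).astype(float)
    ours = fit_glm(PhenotypeVector(y, "logistic"), None,
                   CovariateMatrix(X, ["intercept", "a", "b"]))
    ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(ours.params, ref.params, atol=1e-6)


def test_rank_deficiency_names_columns(rng):
    n = 50
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x, 2 * x])
    with pytest.raises(np.linalg.LinAlgError, match="collinear"):
        fit_glm(PhenotypeVector(rng.normal(size=n), "linear"), None, X)


def test_perfect_separation_flagged(rng):
    n = 60
    x = np.r_[np.zeros(30), np.ones(30)]
    y = PhenotypeVector(x.copy(), "logistic")
    C = CovariateMatrix(np.column_stack([np.ones(n), x]), ["intercept", "x"])
    fit = fit_glm(y, None, C)
    assert not fit.converged
    assert np.max(np.abs(fit.params)) <= 30.0 + 1e-9


class TestSingleMarkerScan:
    def test_marker_equal_to_covariate_gives_p_one(self, rng):
        n = 80
        x = rng.binomial(2, 0.3, n).astype(float)
        g = _dataset(x[:, None])
        y = PhenotypeVector(rng.normal(size=n) + x, "linear")
        C = CovariateMatrix(np.column_stack([np.ones(n), x]), ["intercept", "x"])
        res = single_marker_scan(g, y, C)
        assert res.p_values[0] > 0.99

    def test_perfect_predictor_is_top_hit(self, rng):
        dos = random_dosages(rng, 100, 20)
        y = (dos[:, 7] > 0).astype(float)
        res = single_marker_scan(_dataset(dos), PhenotypeVector(y, "logistic"))
        assert res.p_values.argmin() == 7

    def test_monomorphic_marker_reported_null(self, rng):
        dos = random_dosages(rng, 60, 3)
        dos[:, 1] = 2.0
        with pytest.warns(UserWarning, match="monomorphic"):
            res = single_marker_scan(_dataset(dos),
                                     PhenotypeVector(rng.normal(size=60), "linear"))
        assert res.p_values[1] == 1.0
        assert res.table["effect"].iloc[1] == 0.0

    def test_null_pvalues_uniform(self, rng):
        """Exact F-test p-values are U(0,1) under the global null."""
        pvals = []
        for _ in range(10):
            dos = random_dosages(rng, 120, 400)
            y = PhenotypeVector(rng.normal(size=120), "linear")
            pvals.append(single_marker_scan(_dataset(dos), y).p_values)
        stat = stats.kstest(np.concatenate(pvals), "uniform")
        assert stat.pvalue > 0.01

    def test_scan_invariant_to_marker_order(self, rng):
        dos = random_dosages(rng, 90, 30)
        y = PhenotypeVector((rng.random(90) < 0.5).astype(float), "logistic")
        perm = rng.permutation(30)
        a = single_marker_scan(_dataset(dos), y).p_values[perm]
        b = single_marker_scan(_dataset(dos[:, perm]), y).p_values
        np.testing.assert_allclose(a, b, rtol=1e-9)


class TestPrescreen:
    def _scan(self, p):
        tab = pd.DataFrame({"chrom": "1", "id": [f"m{i}" for i in range(len(p))],
                            "bp": np.arange(len(p)) + 1, "effect": 0.0,
                            "stat": 0.0, "p": p})
        from pmrgwas.glm import ScanResult
        return ScanResult(tab, "F-test")

    def test_vacuous_and_exact_threshold(self):
        assert list(prescreen(self._scan(np.array([0.5, 0.005, 0.02])), 1.0)) \
            == [0, 1, 2]
        assert list(prescreen(self._scan(np.array([0.5, 0.005, 0.02])), 0.01)) \
            == [1]

    def test_empty_survivors_raise(self):
        with pytest.raises(ValueError, match="relax"):
            prescreen(self._scan(np.array([0.5, 0.9])), 1e-4)

    def test_null_retention_matches_binomial(self, rng):
        p = rng.random(10_000)
        kept = prescreen(self._scan(p), 0.01)
        se = np.sqrt(0.01 * 0.99 / 10_000)
        assert abs(kept.size / 10_000 - 0.01) < 3 * se


class TestConditionalScan:
    def test_no_hits_returns_marginal_scan(self, rng):
        dos = random_dosages(rng, 80, 50)
        y = PhenotypeVector(rng.normal(size=80), "linear")
        g = _dataset(dos)
        cond = conditional_scan(g, y, stage1_cutoff=1e-12)
        marg = single_marker_scan(g, y)
        np.testing.assert_array_equal(cond.p_values, marg.p_values)

    def test_matches_manual_two_stage_fit(self, small_study):
        g, y, truth, cfg = small_study
        cond = conditional_scan(g, y, stage1_cutoff=1e-5)
        marg = single_marker_scan(g, y)
        hits = np.flatnonzero(marg.p_values <= 1e-5)
        assert hits.size > 0
        from pmrgwas.glm import _prune_hits_by_window
        lead = _prune_hits_by_window(marg.table, hits, 100_000)
        C2 = CovariateMatrix(
            np.column_stack([np.ones(g.n), g.dosages[:, lead]]),
            ["intercept"] + [f"l{j}" for j in lead])
        stage2 = single_marker_scan(g, y, C2)
        expect = np.minimum(marg.p_values, stage2.p_values)
        expect[lead] = marg.p_values[lead]
        np.testing.assert_allclose(cond.p_values, expect, rtol=1e-9)

    def test_high_ld_proxy_of_covariate_loses_stage2_signal(self, small_study):
        """Conditioning on a lead marker strips the signal from its proxies."""
        g, y, truth, cfg = small_study
        marg = single_marker_scan(g, y)
        hits = np.flatnonzero(marg.p_values <= 1e-5)
        from pmrgwas.glm import _prune_hits_by_window
        lead = _prune_hits_by_window(marg.table, hits, 100_000)
        C2 = CovariateMatrix(
            np.column_stack([np.ones(g.n), g.dosages[:, lead]]),
            ["intercept"] + [f"l{j}" for j in lead])
        stage2 = single_marker_scan(g, y, C2)
        X = g.dosages - g.dosages.mean(0)
        norms = np.sqrt(np.einsum("ij,ij->j", X, X))
        found = 0
        for j in lead:
            r2 = ((X.T @ X[:, j]) / (norms * norms[j])) ** 2
            for q in np.flatnonzero((r2 > 0.9) & (np.arange(g.p) != j)):
                if q not in lead and marg.p_values[q] < 1e-4:
                    found += 1
                    assert stage2.p_values[q] > 1e-2
        assert found > 0


class TestGenomicInflation:
    def test_null_calibration(self, rng):
        lam = genomic_inflation(rng.random(10_000))
        assert lam == pytest.approx(1.0, abs=0.05)

    def test_median_identity(self):
        assert genomic_inflation(np.full(200, 0.5)) == pytest.approx(1.0)

    def test_scale_equivariance(self, rng):
        s = stats.chi2.rvs(1, size=5000, random_state=123)
        lam1 = genomic_inflation(stats.chi2.sf(s, 1))
        lam2 = genomic_inflation(stats.chi2.sf(2 * s, 1))
        assert lam2 == pytest.approx(2 * lam1, rel=1e-9)
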