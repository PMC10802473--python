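"""Regulon dynamics: logistic fits, derived kinetics, PCA, tradeoff."""

import numpy as np
import pytest
from scipy.optimize import brentq

from hsrkit.dynamics import (
    GeneTimeCourse,
    RegulonMatrix,
    fit_logistic,
    fit_logistic_arrays,
    fold_change_normalize,
    logistic,
    max_induction_rate,
    run_pca,
    time_to_half_max,
    tradeoff_fit,
)

TIMES = np.array([0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0, 150.0, 180.0, 240.0])


class TestLogisticFit:
    @pytest.mark.parametrize(
        "B,M,k,t50",
        [(100.0, 800.0, 0.05, 60.0), (1.0, 9.0, 0.12, 30.0), (50.0, 60.0, 0.02, 150.0)],
    )
    def test_exact_samples_recover_parameters(self, B, M, k, t50):
        tc = GeneTimeCourse("g", TIMES, logistic(TIMES, B, M, k, t50))
        fit = fit_logistic(tc)
        assert not fit.degenerate
        assert fit.B == pytest.approx(B, rel=1e-6)
        assert fit.M == pytest.approx(M, rel=1e-6)
        assert fit.k == pytest.approx(k, rel=1e-6)
        assert fit.t50 == pytest.approx(t50, rel=1e-6)

    def test_constant_series_flagged_degenerate(self):
        fit = fit_logistic(GeneTimeCourse("g", TIMES, np.full_like(TIMES, 5.0)))
        assert fit.degenerate
        assert fit.fold_change == 1.0
        assert np.isnan(fit.t50)
        assert np.isnan(time_to_half_max(fit))
        assert np.isnan(max_induction_rate(fit))

    def test_decreasing_series_flagged_degenerate(self):
        values = 100.0 * np.exp(-TIMES / 80.0) + 10.0
        fit = fit_logistic(GeneTimeCourse("g", TIMES, values))
        assert fit.degenerate

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_arrays(TIMES[:5], np.arange(5) + 1.0)


class TestDerivedKinetics:
    def test_half_max_time_is_inflection(self):
        fit = fit_logistic_arrays(TIMES, logistic(TIMES, 0.0, 1.0, 0.1, 75.0))
        assert time_to_half_max(fit) == pytest.approx(75.0, rel=1e-9)
        # symmetric: the curve crosses the mid-level exactly at t50
        mid = fit.predict(fit.t50) - fit.B
        assert mid == pytest.approx((fit.M - fit.B) / 2.0, abs=1e-12)

    def test_half_max_matches_bisection_oracle(self):
        fit = fit_logistic_arrays(TIMES, logistic(TIMES, 20.0, 120.0, 0.07, 95.0))
        target = fit.B + (fit.M - fit.B) / 2.0
        t_half = brentq(lambda t: fit.predict(t) - target, 0.0, 240.0, xtol=1e-9)
        assert t_half == pytest.approx(time_to_half_max(fit), abs=1e-6)

    def test_max_rate_formula_and_oracle(self):
        from hsrkit.dynamics import LogisticFit

        # k (M - B) / 4 on a unit-rate curve
        fit = LogisticFit(B=0.0, M=4.0, k=1.0, t50=60.0, rss=0.0)
        assert max_induction_rate(fit) == pytest.approx(1.0, rel=1e-12)
        # and against a finite-difference oracle on a fitted curve
        fit = fit_logistic_arrays(TIMES, logistic(TIMES, 0.0, 4.0, 0.08, 60.0))
        grid = np.linspace(0.0, 240.0, 200_001)
        deriv = np.gradient(fit.predict(grid), grid)
        assert max_induction_rate(fit) == pytest.approx(deriv.max(), rel=1e-4)

    def test_max_rate_depends_only_on_amplitude(self):
        f1 = fit_logistic_arrays(TIMES, logistic(TIMES, 10.0, 50.0, 0.08, 70.0))
        f2 = fit_logistic_arrays(TIMES, logistic(TIMES, 110.0, 150.0, 0.08, 70.0))
        assert max_induction_rate(f1) == pytest.approx(
            max_induction_rate(f2), rel=1e-6
        )


class TestRegulonMatrix:
    def test_fold_change_normalization(self):
        m = RegulonMatrix(
            genes=("a", "b", "c"),
            times=np.array([0.0, 60.0, 240.0]),
            values=np.array([[10.0, 20.0, 80.0], [5.0, 5.0, 5.0], [2.0, 3.0, 4.0]]),
        )
        fc = fold_change_normalize(m)
        assert fc.kind == "fold_change"
        assert np.array_equal(fc.values[0], [1.0, 2.0, 8.0])
        assert np.array_equal(fc.values[1], [1.0, 1.0, 1.0])
        assert np.all(fc.values[:, 0] == 1.0)
        with pytest.raises(ValueError, match="raw"):
            fold_change_normalize(fc)

    def test_zero_basal_rejected(self):
        with pytest.raises(ValueError):
            RegulonMatrix(
                genes=("a", "b", "c"),
                times=np.array([0.0, 60.0, 240.0]),
                values=np.array([[0.0, 1.0, 2.0], [1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]),
            )


class TestPca:
    def test_rank_one_matrix_puts_all_variance_on_pc1(self):
        t = np.array([0.0, 30.0, 60.0, 120.0])
        profile = np.array([1.0, 2.0, 4.0, 8.0])
        weights = np.array([1.0, 3.0, 5.0, 7.0, 11.0])
        m = RegulonMatrix(
            genes=tuple("abcde"), times=t, values=np.outer(weights, profile)
        )
        pca = run_pca(m)
        assert pca.variance_ratio[0] == pytest.approx(1.0, abs=1e-12)
        assert pca.variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_covariance_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.lognormal(2.0, 1.0, size=(10, 5))
        m = RegulonMatrix(
            genes=tuple(f"g{i}" for i in range(10)),
            times=np.arange(5, dtype=float),
            values=X,
        )
        pca = run_pca(m)

        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(5):
            v = evecs[:, j]
            if v[np.argmax(np.abs(v))] < 0:  # same sign convention
                v = -v
            assert np.allclose(pca.loadings[j], v, rtol=1e-8, atol=1e-10)
            assert np.allclose(pca.scores[:, j], Xc @ v, rtol=1e-8, atol=1e-8)
        assert np.allclose(
            pca.variance_ratio, evals / evals.sum(), rtol=1e-10, atol=1e-12
        )

    def test_small_or_degenerate_matrices_rejected(self):
        with pytest.raises(ValueError):
            run_pca(
                RegulonMatrix(
                    genes=("a", "b"),
                    times=np.arange(3, dtype=float),
                    values=np.ones((2, 3)) + np.arange(3),
                )
            )
        with pytest.raises(ValueError, match="rank 0"):
            run_pca(
                RegulonMatrix(
                    genes=("a", "b", "c"),
                    times=np.arange(3, dtype=float),
                    values=np.ones((3, 3)),
                )
            )

    def test_fold_change_pca_invariant_to_gene_rescaling(self):
        rng = np.random.default_rng(9)
        X = rng.lognormal(1.0, 0.5, size=(6, 4)).cumsum(axis=1)
        times = np.arange(4, dtype=float)
        genes = tuple(f"g{i}" for i in range(6))
        m1 = RegulonMatrix(genes=genes, times=times, values=X)
        X2 = X.copy()
        X2[2] *= 37.5  # rescale one gene's raw row
        m2 = RegulonMatrix(genes=genes, times=times, values=X2)
        p1 = run_pca(fold_change_normalize(m1))
        p2 = run_pca(fold_change_normalize(m2))
        assert np.allclose(p1.scores, p2.scores, rtol=1e-10, atol=1e-12)
        assert np.allclose(p1.variance_ratio, p2.variance_ratio, rtol=1e-10)


class TestTradeoff:
    def test_exact_power_law(self):
        t_half = np.array([10.0, 20.0, 40.0, 80.0, 160.0, 320.0])
        rate = 100.0 / t_half
        fit = tradeoff_fit(t_half, rate, n_boot=200, seed=0)
        assert fit.slope == pytest.approx(-1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(2.0, abs=1e-9)
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]
        assert fit.intercept_ci[0] <= fit.intercept <= fit.intercept_ci[1]

    def test_needs_five_informative_genes(self):
        with pytest.raises(ValueError):
            tradeoff_fit(
                np.array([10.0, 20.0, np.nan, 40.0, np.nan, 80.0]),
                np.array([1.0, 0.5, 1.0, 0.25, np.nan, 0.125]),
            )
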