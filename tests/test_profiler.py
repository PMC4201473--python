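"""Patient-specific orchestration: screening, local fits, prediction,
biomarker frequencies."""

import numpy as np
import pytest

from robustprofiler.enet import FitResult, PenaltySpec, fit_adaptive_enet
from robustprofiler.kernels import KernelSpec
from robustprofiler.outliers import OutlierWeights, compute_sample_weights
from robustprofiler.profiler import (
    TargetFit,
    biomarker_frequency,
    fit_all_targets,
    fit_target,
    predict,
    prescreen_by_variance,
)


class TestPrescreen:
    def test_keeps_requested_count(self, rng):
        X = rng.standard_normal((30, 1000))
        Xr, kept = prescreen_by_variance(X, 200)
        assert Xr.shape == (30, 200) and kept.shape == (200,)
        assert np.array_equal(Xr, X[:, kept])

    def test_constant_column_never_beats_varying_one(self, rng):
        X = rng.standard_normal((20, 5))
        X[:, 2] = 7.0
        _, kept = prescreen_by_variance(X, 4)
        assert 2 not in kept

    def test_ranking_by_known_variances(self, rng):
        n, p = 200, 10
        # well-separated column variances 4^j so sampling noise cannot swap
        X = rng.standard_normal((n, p)) * 2.0 ** np.arange(p)
        _, kept = prescreen_by_variance(X, 3)
        assert np.array_equal(kept, [7, 8, 9])

    def test_invalid_count(self, rng):
        X = rng.standard_normal((10, 5))
        with pytest.raises(ValueError, match="invalid count"):
            prescreen_by_variance(X, 0)
        with pytest.raises(ValueError, match="invalid count"):
            prescreen_by_variance(X, 6)


def _toy(rng, n=40, p=6, noise=0.2):
    X = rng.standard_normal((n, p))
    m = rng.uniform(0, 1, n)
    y = (1 + m) * X[:, 0] - 1.5 * X[:, 1] + noise * rng.standard_normal(n)
    return X, y, m


class TestFitTarget:
    def test_unit_outlier_weights_reproduce_nonrobust_fit(self, rng):
        X, y, m = _toy(rng)
        ones = OutlierWeights(
            distances_sq=np.zeros(40), weights=np.ones(40), cutoff=1.0, df=1
        )
        kern, pen = KernelSpec(0.3), PenaltySpec(lam=1.0, delta=1.0)
        a = fit_target(X, y, m, 5, kern, pen, outlier=ones)
        b = fit_target(X, y, m, 5, kern, pen, outlier=None)
        assert np.array_equal(a.fit.coefficients, b.fit.coefficients)
        assert a.fit.intercept == b.fit.intercept

    def test_identical_modulators_give_identical_fits(self, rng):
        X, y, m = _toy(rng)
        m[3] = m[17]
        kern, pen = KernelSpec(0.2), PenaltySpec(lam=2.0, delta=1.0)
        fits = fit_all_targets(X, y, m, kern, pen, outlier=None)
        assert np.array_equal(fits[3].fit.coefficients, fits[17].fit.coefficients)

    def test_outlier_far_from_target_in_modulator_space_is_moot(self):
        # the kernel already suppresses a gross outlier whose modulator is
        # far from the target, so robust and non-robust fits coincide
        r = np.random.default_rng(11)
        X = r.standard_normal((40, 5))
        m = np.sort(r.uniform(0, 0.4, 40))
        m[-1] = 0.99
        y = 2 * X[:, 0] + 0.1 * r.standard_normal(40)
        y[-1] = 40.0
        X[-1, 2:] = 8.0
        ow = OutlierWeights(
            distances_sq=np.zeros(40), weights=np.ones(40), cutoff=1.0, df=1
        )
        ow.weights[-1] = 0.05  # robust chain would cap the outlier hard
        kern = KernelSpec(0.05, normalize=False)
        pen = PenaltySpec(lam=0.5, delta=1.0)
        rob = fit_target(X, y, m, 3, kern, pen, outlier=ow)
        non = fit_target(X, y, m, 3, kern, pen, outlier=None)
        assert np.allclose(rob.fit.coefficients, non.fit.coefficients, atol=1e-5)

    def test_outlier_at_target_modulator_hurts_nonrobust_more(self):
        r = np.random.default_rng(7)
        n, p = 50, 10
        X = r.standard_normal((n, p))
        m = r.uniform(0, 1, n)
        y = 2 * X[:, 0] - 1.5 * X[:, 1] + 0.3 * r.standard_normal(n)
        bad = [3, 11, 29]
        y[bad] = 20.0
        X[np.ix_(bad, [4, 5, 6])] = 8.0
        ow = compute_sample_weights(X, y, seed=1)
        assert np.all(ow.weights[bad] < 0.5)
        Xt = r.standard_normal((30, p))
        mt = r.uniform(0, 1, 30)
        yt = 2 * Xt[:, 0] - 1.5 * Xt[:, 1]
        kern, pen = KernelSpec(0.5), PenaltySpec(lam=2.0, delta=1.0)
        pe_rob = np.median((yt - predict(X, y, m, Xt, mt, kern, pen, outlier=ow)) ** 2)
        pe_non = np.median((yt - predict(X, y, m, Xt, mt, kern, pen, outlier=None)) ** 2)
        assert pe_rob <= pe_non

    def test_neighborhood_too_small(self, rng):
        X, y, m = _toy(rng)
        kern = KernelSpec(1e-6, normalize=False)
        with pytest.raises(ValueError, match="neighborhood too small"):
            fit_target(X, y, m, 0, kern, PenaltySpec(lam=1.0))


class TestFitAllTargets:
    def test_one_fit_per_sample(self, rng):
        X, y, m = _toy(rng, n=15)
        fits = fit_all_targets(X, y, m, KernelSpec(0.3), PenaltySpec(lam=1.0), outlier=None)
        assert len(fits) == 15
        assert [tf.target_id for tf in fits] == list(range(15))

    def test_permutation_equivariance_with_given_weights(self, rng):
        X, y, m = _toy(rng, n=20)
        w = OutlierWeights(
            distances_sq=rng.uniform(0, 5, 20),
            weights=rng.uniform(0.5, 1.0, 20),
            cutoff=3.8, df=2,
        )
        kern, pen = KernelSpec(0.3), PenaltySpec(lam=1.5, delta=1.0)
        fits = fit_all_targets(X, y, m, kern, pen, outlier=w)
        perm = rng.permutation(20)
        wp = OutlierWeights(
            distances_sq=w.distances_sq[perm], weights=w.weights[perm],
            cutoff=3.8, df=2,
        )
        fits_p = fit_all_targets(X[perm], y[perm], m[perm], kern, pen, outlier=wp)
        for t in range(20):
            # identical up to summation order in the weighted inner products
            assert np.allclose(
                fits_p[t].fit.coefficients, fits[perm[t]].fit.coefficients,
                atol=1e-10,
            )


class TestPredict:
    def test_zero_features_predict_intercept(self, rng):
        X, y, m = _toy(rng)
        kern, pen = KernelSpec(0.4), PenaltySpec(lam=1.0, delta=1.0)
        pred = predict(X, y, m, np.zeros((1, 6)), [0.5], kern, pen, outlier=None)
        tf = fit_target(X, y, m, 0, kern, pen, outlier=None, m_target=0.5)
        assert pred[0] == pytest.approx(tf.fit.intercept)

    def test_training_sample_reproduces_in_sample_fitted_value(self, rng):
        X, y, m = _toy(rng)
        kern, pen = KernelSpec(0.4), PenaltySpec(lam=1.0, delta=1.0)
        fits = fit_all_targets(X, y, m, kern, pen, outlier=None)
        pred = predict(X, y, m, X[7:8], m[7:8], kern, pen, outlier=None)
        assert pred[0] == pytest.approx(fits[7].fit.predict(X[7:8])[0], abs=1e-10)

    def test_flat_kernel_no_outlier_equals_global_model(self, rng):
        X, y, m = _toy(rng)
        kern = KernelSpec(1e6)
        pen = PenaltySpec(lam=1.0, delta=1.0)
        preds = predict(X, y, m, X[:5], m[:5], kern, pen, outlier=None)
        glob = fit_adaptive_enet(X, y, np.ones(40), lam=1.0, delta=1.0)
        assert np.allclose(preds, glob.predict(X[:5]), atol=1e-4)

    def test_feature_mismatch_raises(self, rng):
        X, y, m = _toy(rng)
        with pytest.raises(ValueError, match="schema"):
            predict(X, y, m, np.zeros((1, 4)), [0.5], KernelSpec(0.3), PenaltySpec())


def _fake_fits(pattern):
    """TargetFits whose coefficient vectors follow a boolean pattern."""
    fits = []
    for row in pattern:
        coef = np.asarray(row, dtype=float)
        fits.append(
            TargetFit(
                target_id=0, modulator_value=0.5,
                fit=FitResult(
                    intercept=0.0, coefficients=coef,
                    active_set=np.flatnonzero(coef), n_sweeps=1,
                    objective_trace=np.zeros(1), coefficients_std=coef,
                ),
                combined_weights=np.ones(1),
            )
        )
    return fits


class TestBiomarkerFrequency:
    def test_paper_style_threshold_is_strict(self):
        # 121 of 150 models is > 80% and flagged; 120 of 150 is not
        pattern = [[1.0, 1.0] for _ in range(120)] + [[1.0, 0.0]] + [
            [0.0, 0.0] for _ in range(29)
        ]
        table = biomarker_frequency(_fake_fits(pattern), threshold=0.80)
        assert table.loc[0, "selection_count"] == 121
        assert table.loc[0, "selection_fraction"] == pytest.approx(121 / 150)
        assert bool(table.loc[0, "flagged"])
        assert table.loc[1, "selection_count"] == 120
        assert not bool(table.loc[1, "flagged"])

    def test_extremes(self):
        pattern = [[1.0, 0.0] for _ in range(10)]
        table = biomarker_frequency(_fake_fits(pattern))
        assert table.loc[0, "selection_fraction"] == 1.0 and bool(table.loc[0, "flagged"])
        assert table.loc[1, "selection_fraction"] == 0.0 and not bool(table.loc[1, "flagged"])

    def test_empty_fit_list_rejected(self):
        with pytest.raises(ValueError):
            biomarker_frequency([])
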