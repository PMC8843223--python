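"""Selection stages, PLS1, metrics and cross-validation machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligamentnirs.chemometrics import (
    backward_eliminate,
    bootstrap_ci,
    choose_latent_variables,
    compute_metrics,
    explained_variance,
    fit_pls,
    predict,
    repeated_cv,
    standardize_reference,
    top_influential_wavelengths,
    univariate_select,
    variance_filter,
)


def wl(p):
    return np.linspace(400.0, 2000.0, p)


class TestStandardize:
    def test_two_point_example(self):
        y_std, mean, sd = standardize_reference(np.array([0.0, 10.0]))
        np.testing.assert_allclose(y_std, [-0.7071067811865475, 0.7071067811865475])
        assert mean == 5.0

    def test_idempotent_second_pass(self):
        rng = np.random.default_rng(0)
        y, _, _ = standardize_reference(rng.normal(70, 5, 100))
        y2, m, s = standardize_reference(y)
        np.testing.assert_allclose(y2, y, atol=1e-12)
        assert m == pytest.approx(0.0, abs=1e-12)
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_reference(np.full(5, 3.0))


class TestSelectionStages:
    def test_lowest_variance_feature_rejected(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, np.sqrt(v), 50) for v in range(1, 11)]
        ).T  # variances 1..10
        mask = variance_filter(X, wl(10))
        assert mask.n_kept == 9
        assert not mask.keep[0]

    def test_reject_counts_use_floor(self):
        X = np.random.default_rng(1).normal(size=(5, 232))
        mask = variance_filter(X, wl(232))
        assert mask.n_kept == 232 - 23

    def test_reject_frac_zero_keeps_all(self):
        X = np.random.default_rng(1).normal(size=(5, 10))
        assert variance_filter(X, wl(10), reject_frac=0.0).n_kept == 10

    def test_perfect_feature_ranked_first(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=60)
        X = rng.normal(size=(60, 20))
        X[:, 7] = y
        mask = univariate_select(X, y, wl(20), keep_frac=0.05)  # keep 1
        assert mask.keep[7] and mask.n_kept == 1

    def test_keep_counts_use_ceil(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 209))
        y = rng.normal(size=30)
        mask = univariate_select(X, y, wl(209))
        assert mask.n_kept == int(np.ceil(0.875 * 209))  # 183

    def test_keep_frac_one_is_identity(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 7))
        mask = univariate_select(X, rng.normal(size=10), wl(7), keep_frac=1.0)
        assert mask.keep.all()

    def test_zero_variance_feature_is_error(self):
        X = np.random.default_rng(5).normal(size=(10, 4))
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match="variance"):
            univariate_select(X, np.arange(10.0), wl(4))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(12, 500))
    def test_selection_chain_arithmetic(self, p):
        # floor for rejection, ceil for keep: composed retained count
        rng = np.random.default_rng(p)
        X = rng.normal(size=(12, p))
        y = rng.normal(size=12)
        m1 = variance_filter(X, wl(p))
        m2 = univariate_select(X[:, m1.keep], y, wl(p)[m1.keep])
        expected = int(np.ceil(0.875 * (p - int(np.floor(0.10 * p)))))
        assert m2.n_kept == expected


class TestPLS:
    def test_full_rank_pls_matches_ols(self):
        # at n_lv = p, PLS spans the full predictor space, so its fitted
        # values must agree with the least-squares solution
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(size=(20, 5))
            y = X @ rng.normal(size=5) + rng.normal(size=20) * 0.1
            model = fit_pls(X, y, n_lv=5)
            Xc = np.column_stack([np.ones(20), X])
            beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
            yhat_ols = Xc @ beta
            np.testing.assert_allclose(predict(model, X), yhat_ols, atol=1e-8)

    def test_matches_independent_pls_implementation(self):
        # cross-check the NIPALS implementation against scikit-learn's
        # PLSRegression (unscaled) on random instances at several LV counts
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(31)
        for n_lv in (1, 3, 6):
            X = rng.normal(size=(30, 12))
            y = X @ rng.normal(size=12) + 0.3 * rng.normal(size=30)
            ours = fit_pls(X, y, n_lv)
            ref = PLSRegression(n_components=n_lv, scale=False).fit(X, y)
            np.testing.assert_allclose(
                ours.coefficients, ref.coef_.ravel(), atol=1e-8
            )
            np.testing.assert_allclose(
                predict(ours, X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_zero_response_gives_zero_model(self):
        X = np.random.default_rng(1).normal(size=(15, 6))
        model = fit_pls(X, np.zeros(15), n_lv=3)
        np.testing.assert_array_equal(model.coefficients, 0.0)
        np.testing.assert_array_equal(predict(model, X), 0.0)

    def test_sample_duplication_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 8))
        y = X @ rng.normal(size=8)
        a = fit_pls(X, y, 3)
        b = fit_pls(np.vstack([X, X]), np.concatenate([y, y]), 3)
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-9)

    def test_invalid_n_lv_rejected(self):
        X = np.random.default_rng(3).normal(size=(10, 4))
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="n_lv"):
            fit_pls(X, y, 0)
        with pytest.raises(ValueError, match="n_lv"):
            fit_pls(X, y, 5)  # > min(n-1, p) = 4


class TestChooseLatentVariables:
    def test_rank_one_signal_needs_one_lv(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=(50, 1))
        X = t @ rng.normal(size=(1, 10)) + 1e-9 * rng.normal(size=(50, 10))
        y = t[:, 0]
        assert choose_latent_variables(X, y, max_lv=5, seed=0) == 1

    def test_pure_noise_selects_parsimonious_models(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(50, 30))
            y = rng.normal(size=50)
            if choose_latent_variables(X, y, max_lv=10, seed=seed) <= 3:
                hits += 1
        assert hits >= 8

    def test_max_lv_one_returns_one(self):
        rng = np.random.default_rng(1)
        assert (
            choose_latent_variables(
                rng.normal(size=(20, 5)), rng.normal(size=20), max_lv=1
            )
            == 1
        )


class TestBackwardElimination:
    def test_informative_features_survive(self):
        kept_informative = []
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            n, p_noise = 200, 50
            informative = rng.normal(size=(n, 10))
            beta = rng.uniform(1.0, 2.0, 10)
            y = informative @ beta + 0.05 * rng.normal(size=n)
            X = np.hstack([informative, rng.normal(size=(n, p_noise))])
            mask = backward_eliminate(X, y, wl(60), n_lv=5, seed=seed)
            kept_informative.append(mask.keep[:10].sum())
        assert np.mean([k >= 8 for k in kept_informative]) >= 0.9

    def test_identical_copies_keep_lowest_wavelength(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=30)
        X = np.tile(col[:, None], (1, 6))
        y = 2 * col + 0.01 * rng.normal(size=30)
        mask = backward_eliminate(X, y, wl(6), n_lv=1, seed=0)
        # exchangeable copies: the tie rule leaves the lowest-wavelength one
        assert mask.n_kept == 1
        assert mask.keep[0]

    def test_n_lv_not_below_feature_count(self):
        X = np.random.default_rng(1).normal(size=(20, 3))
        with pytest.raises(ValueError, match="features"):
            backward_eliminate(X, np.arange(20.0), wl(3), n_lv=3)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = compute_metrics(y, y)
        assert m.explained_variance == 1.0
        assert m.r == pytest.approx(1.0)
        assert m.R2 == 1.0
        assert m.RMSE == 0.0

    def test_mean_prediction_gives_zero_ev(self):
        y = np.array([1.0, 2.0, 6.0])
        assert explained_variance(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_offset_invariance_of_ev_but_not_r2(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=40)
        m = compute_metrics(y, y + 7.0)
        assert m.explained_variance == pytest.approx(1.0)
        assert m.r == pytest.approx(1.0)
        assert m.R2 < 1.0

    def test_sign_flip_closed_form(self):
        # for zero-mean y and yhat = -y: residual 2y, so R2 = 1 - 4 = -3
        y = np.array([-3.0, -1.0, 1.0, 3.0])
        m = compute_metrics(y, -y)
        assert m.r == pytest.approx(-1.0)
        assert m.R2 == pytest.approx(-3.0)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_metrics(np.full(4, 2.0), np.arange(4.0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ev_offset_invariant_r2_offset_sensitive(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=20)
        yhat = y + 0.3 * rng.normal(size=20)
        c = 1.0 + rng.uniform(0.5, 2.0)
        assert explained_variance(y, yhat + c) == pytest.approx(
            explained_variance(y, yhat), abs=1e-10
        )
        assert compute_metrics(y, yhat + c).R2 < compute_metrics(y, yhat).R2


class TestBootstrapCI:
    def test_constant_values_give_degenerate_interval(self):
        lo, hi = bootstrap_ci(np.full(10, 3.5), seed=0)
        assert lo == hi == 3.5

    def test_interval_brackets_median(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            vals = rng.normal(size=30)
            lo, hi = bootstrap_ci(vals, seed=seed)
            assert lo <= np.median(vals) <= hi

    def test_uniform_1_to_100(self):
        vals = np.arange(1.0, 101.0)
        lo, hi = bootstrap_ci(vals, seed=7)
        assert lo <= 50.5 <= hi
        assert hi - lo < (vals.max() - vals.min()) / 2


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 8))
    y = X @ rng.normal(size=8)
    return X, y


class TestRepeatedCV:
    def test_fold_record_count(self, linear_data):
        X, y = linear_data
        cv = repeated_cv(X, y, n_lv=4, k=10, reps=10, seed=0, n_boot=200)
        assert len(cv.fold_records) == 100

    def test_noiseless_linear_recovery(self, linear_data):
        X, y = linear_data
        cv = repeated_cv(X, y, n_lv=8, k=10, reps=3, seed=0, n_boot=200)
        assert cv.medians["R2"] >= 0.999

    def test_seed_determinism(self, linear_data):
        X, y = linear_data
        a = repeated_cv(X, y, n_lv=4, k=10, reps=4, seed=5, n_boot=200)
        b = repeated_cv(X, y, n_lv=4, k=10, reps=4, seed=5, n_boot=200)
        assert a.fold_records == b.fold_records
        assert a.medians == b.medians
        assert a.ci == b.ci

    def test_fold_wise_standardization_preserves_scale(self, linear_data):
        # the optional per-fold y standardization maps predictions back to
        # the input scale, so a well-specified model still scores highly
        X, y = linear_data
        cv = repeated_cv(
            X, y, n_lv=8, k=10, reps=3, seed=0, n_boot=200,
            standardize_per_fold=True,
        )
        assert cv.medians["R2"] >= 0.999
        assert cv.medians["RMSE"] < 1e-6  # predictions are on the y scale

    def test_ci_brackets_median_for_every_metric(self, linear_data):
        X, y = linear_data
        rng = np.random.default_rng(1)
        cv = repeated_cv(X, y + rng.normal(size=40), n_lv=3, k=10, reps=5, seed=2, n_boot=200)
        for name, med in cv.medians.items():
            lo, hi = cv.ci[name]
            assert lo <= med <= hi


class TestTopInfluentialWavelengths:
    def _model(self, coefs):
        coefs = np.asarray(coefs, dtype=float)
        from ligamentnirs.chemometrics import PLSModel

        p = coefs.size
        return PLSModel(
            n_lv=1,
            x_mean=np.zeros(p),
            y_mean=0.0,
            weights=np.zeros((p, 1)),
            x_loadings=np.zeros((p, 1)),
            y_loadings=np.zeros(1),
            coefficients=coefs,
        )

    def test_sorted_by_absolute_magnitude(self):
        model = self._model([3.0, -5.0, 1.0])
        out = top_influential_wavelengths(model, np.array([500.0, 600.0, 700.0]), k=2)
        assert out == [(600.0, -5.0), (500.0, 3.0)]

    def test_k_equal_to_feature_count(self):
        model = self._model([1.0, -2.0, 0.5])
        out = top_influential_wavelengths(model, np.array([500.0, 600.0, 700.0]), k=3)
        assert [w for w, _ in out] == [600.0, 500.0, 700.0]

    def test_k_too_large_rejected(self):
        model = self._model([1.0])
        with pytest.raises(ValueError, match="exceeds"):
            top_influential_wavelengths(model, np.array([500.0]), k=2)
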