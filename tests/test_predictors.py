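import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import minimize_scalar

from crossage import predictors as P
from crossage.synthgen import CohortData, SimParams1, gen_example1


def _cohort(age, markers):
    return CohortData(age=np.asarray(age, float), markers=pd.DataFrame(markers))


class TestPreselect:
    def test_bonferroni_threshold_value(self):
        assert P.bonferroni_threshold(0.05, 59) == pytest.approx(8.47e-4, rel=1e-3)

    def test_null_marker_not_selected(self):
        rng = np.random.default_rng(0)
        age = rng.normal(50, 7, 5000)
        data = _cohort(age, {"signal": 0.5 * age + rng.normal(0, 2, 5000),
                             "null": rng.normal(0, 1, 5000)})
        assert P.preselect_markers(data, 0.05) == ["signal"]

    def test_constant_marker_skipped_with_warning(self):
        rng = np.random.default_rng(1)
        age = rng.normal(50, 7, 100)
        data = _cohort(age, {"flat": np.ones(100), "ok": age + rng.normal(0, 1, 100)})
        with pytest.warns(UserWarning, match="constant"):
            selected = P.preselect_markers(data, 0.05)
        assert selected == ["ok"]

    def test_pvalue_matches_permutation_oracle(self):
        # moderate correlation, small n, so the p-value is in a testable range
        rng = np.random.default_rng(42)
        n = 200
        age = rng.normal(50, 7, n)
        x = 0.02 * age + rng.normal(0, 1, n)
        r_obs, p_t = stats.pearsonr(x, age)
        perm_rng = np.random.default_rng(7)
        n_perm = 4000
        exceed = sum(
            abs(np.corrcoef(perm_rng.permutation(x), age)[0, 1]) >= abs(r_obs)
            for _ in range(n_perm)
        )
        p_perm = exceed / n_perm
        se = np.sqrt(p_t * (1 - p_t) / n_perm)
        assert abs(p_t - p_perm) < 4 * se + 1e-3


class TestFitMLR:
    def test_perfect_marker_biomarker_paradox(self):
        age = np.linspace(40, 70, 20)
        data = _cohort(age, {"exact": age})
        model = P.fit_mlr(data)
        assert model.intercept == pytest.approx(0.0, abs=1e-8)
        assert model.weights[0] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(model.predict(data), age, atol=1e-8)

    def test_matches_normal_equations_oracle(self, example1_small):
        model = P.fit_mlr(example1_small, ["X"])
        design = np.column_stack(
            [np.ones(example1_small.n), example1_small.markers["X"]]
        )
        oracle = np.linalg.solve(design.T @ design, design.T @ example1_small.age)
        assert model.intercept == pytest.approx(oracle[0], abs=1e-8)
        assert model.weights[0] == pytest.approx(oracle[1], abs=1e-8)

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(3)
        age = rng.normal(50, 5, 30)
        x = rng.normal(0, 1, 30)
        data = _cohort(age, {"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            P.fit_mlr(data)

    def test_observational_equivalence_of_weights(self):
        # fitting on the true vs the false marker yields the same weight law:
        # the per-replicate differences have a symmetric sign distribution
        diffs = []
        for seed in range(50):
            data = gen_example1(SimParams1(n=1000, seed=seed))
            w_x = P.fit_mlr(data, ["X"]).weights[0]
            w_xp = P.fit_mlr(data, ["X_prime"]).weights[0]
            diffs.append(w_x - w_xp)
        positive = int(np.sum(np.array(diffs) > 0))
        p = stats.binomtest(positive, len(diffs), 0.5).pvalue
        assert p > 0.01


class TestRidgeCV:
    def test_zero_penalty_equals_mlr(self, example1_small):
        ridge = P.fit_ridge_cv(example1_small, lambda_grid=[0.0], seed=0)
        mlr = P.fit_mlr(example1_small)
        np.testing.assert_allclose(ridge.weights, mlr.weights, atol=1e-6)
        assert ridge.intercept == pytest.approx(mlr.intercept, abs=1e-6)

    def test_infinite_shrinkage_limit(self, example1_small):
        ridge = P.fit_ridge_cv(example1_small, lambda_grid=[1e12], seed=0)
        np.testing.assert_allclose(ridge.weights, 0.0, atol=1e-6)
        fitted = ridge.predict(example1_small)
        np.testing.assert_allclose(
            fitted, example1_small.age.mean() * np.ones_like(fitted), atol=1e-4
        )

    def test_empty_grid_rejected(self, example1_small):
        with pytest.raises(ValueError, match="non-empty"):
            P.fit_ridge_cv(example1_small, lambda_grid=[])

    def test_chosen_lambda_matches_bruteforce_oracle(self, tiny_cohort):
        grid = [0.01, 0.1, 1.0, 10.0, 100.0]
        folds, seed = 5, 11
        model = P.fit_ridge_cv(
            tiny_cohort, folds=folds, lambda_grid=grid, seed=seed
        )
        # oracle: exhaustive per-fold refits via the penalized normal equations
        x = tiny_cohort.marker_matrix()
        z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        y = tiny_cohort.age
        fold_idx = P._cv_folds(tiny_cohort.n, folds, seed)
        errors = []
        for lam in grid:
            sse = 0.0
            for test in fold_idx:
                train = np.setdiff1d(np.arange(tiny_cohort.n), test)
                zt, yt = z[train], y[train]
                zc = zt - zt.mean(axis=0)
                yc = yt - yt.mean()
                w = np.linalg.solve(zc.T @ zc + lam * np.eye(z.shape[1]), zc.T @ yc)
                b = yt.mean() - zt.mean(axis=0) @ w
                sse += np.sum((y[test] - (z[test] @ w + b)) ** 2)
            errors.append(sse)
        assert model.ridge_lambda == pytest.approx(grid[int(np.argmin(errors))])


class TestKD:
    def test_deterministic_marker_dropped(self):
        age = np.linspace(40, 70, 20)
        data = _cohort(age, {"det": 2 + 3 * age, "noisy": age + np.sin(age)})
        with pytest.warns(UserWarning, match="zero residual sd"):
            fit = P.fit_kd(data)
        assert fit.markers == ["noisy"]

    def test_all_markers_dropped_raises(self):
        age = np.linspace(40, 70, 20)
        data = _cohort(age, {"det": 2 + 3 * age})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no usable markers"):
                P.fit_kd(data)

    def test_matches_normal_equations_oracle(self, tiny_cohort):
        fit = P.fit_kd(tiny_cohort)
        for j, name in enumerate(fit.markers):
            x = tiny_cohort.markers[name].to_numpy()
            design = np.column_stack([np.ones(tiny_cohort.n), tiny_cohort.age])
            q, k = np.linalg.solve(design.T @ design, design.T @ x)
            assert fit.q[j] == pytest.approx(q, abs=1e-8)
            assert fit.k[j] == pytest.approx(k, abs=1e-8)

    def test_plugin_values_on_example1(self):
        data = gen_example1(SimParams1(n=100_000, seed=55))
        fit = P.fit_kd(data, ["X"])
        # generating model: k -> beta = 1, s^2 -> beta^2 var_delta + var_eps = 5
        assert fit.k[0] == pytest.approx(1.0, abs=0.02)
        assert fit.s[0] ** 2 == pytest.approx(5.0, rel=0.05)

    def test_single_marker_prediction_reduction(self, tiny_cohort):
        fit = P.fit_kd(tiny_cohort, ["m1"])
        ba = P.predict_kd(fit, tiny_cohort)
        expected = (tiny_cohort.markers["m1"].to_numpy() - fit.q[0]) / fit.k[0]
        np.testing.assert_allclose(ba, expected, atol=1e-10)

    def test_equal_slope_equal_noise_average(self):
        rng = np.random.default_rng(6)
        age = rng.normal(50, 5, 200)
        x1 = 1.0 + 2.0 * age + rng.normal(0, 1, 200)
        x2 = -3.0 + 2.0 * age + rng.normal(0, 1, 200)
        data = _cohort(age, {"x1": x1, "x2": x2})
        fit = P.fit_kd(data)
        # force exactly equal k and s to check the algebraic simplification
        k = fit.k.mean()
        s = fit.s.mean()
        forced = P.KDFit(markers=fit.markers, q=fit.q, k=np.full(2, k), s=np.full(2, s))
        ba = P.predict_kd(forced, data)
        expected = ((x1 - fit.q[0]) + (x2 - fit.q[1])) / (2 * k)
        np.testing.assert_allclose(ba, expected, atol=1e-10)

    def test_prediction_minimizes_kd_objective(self, tiny_cohort):
        fit = P.fit_kd(tiny_cohort)
        ba = P.predict_kd(fit, tiny_cohort)
        x = tiny_cohort.marker_matrix(fit.markers)

        for i in [0, 4, 9]:
            def objective(b):
                return float(np.sum(((x[i] - fit.q - fit.k * b) / fit.s) ** 2))

            opt = minimize_scalar(objective, bounds=(-200, 400), method="bounded")
            assert ba[i] == pytest.approx(opt.x, abs=1e-4)


class TestPC1:
    def test_duplicated_marker_direction(self):
        rng = np.random.default_rng(12)
        age = rng.normal(50, 7, 500)
        base = 0.8 * age + rng.normal(0, 2, 500)
        data = _cohort(age, {"a": base, "b": base + rng.normal(0, 0.01, 500)})
        model = P.fit_pc1(data, subset=["a", "b"])
        proxy = model.predict(data)
        assert np.corrcoef(proxy, age)[0, 1] > 0.5
        assert model.weights[0] == pytest.approx(model.weights[1], rel=0.05)

    def test_loadings_match_eigendecomposition_oracle(self, example1_small):
        model = P.fit_pc1(example1_small, subset=["X", "X_prime"])
        x = example1_small.marker_matrix(["X", "X_prime"])
        corr = np.corrcoef(x, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        lead = eigvecs[:, -1]
        w = model.weights / np.linalg.norm(model.weights)
        z_dir = lead / np.linalg.norm(lead)
        # weights are loadings rescaled by per-marker sd; compare directions
        sd = x.std(axis=0, ddof=1)
        w_as_loadings = model.weights * sd
        w_as_loadings /= np.linalg.norm(w_as_loadings)
        assert abs(float(w_as_loadings @ z_dir)) == pytest.approx(1.0, abs=1e-8)

    def test_rescaling_identity(self, example1_small):
        model = P.fit_pc1(example1_small, subset=["X", "X_prime"])
        proxy = model.predict(example1_small)
        assert proxy.mean() == pytest.approx(example1_small.age.mean(), abs=1e-8)
        assert proxy.std(ddof=1) == pytest.approx(
            example1_small.age.std(ddof=1), abs=1e-8
        )
        assert model.pc_rescale[0] == pytest.approx(example1_small.age.mean())

    def test_too_few_markers_raises(self):
        rng = np.random.default_rng(2)
        age = rng.normal(50, 7, 300)
        data = _cohort(age, {"only": 0.9 * age + rng.normal(0, 1, 300)})
        with pytest.raises(ValueError, match="at least 2"):
            P.fit_pc1(data)


class TestEqualWeights:
    def test_stated_rule_arithmetic(self):
        mlr = P.LinearAgeModel(
            method="mlr", markers=["a", "b", "c"], intercept=5.0,
            weights=np.array([2.0, -4.0, 6.0]),
        )
        equal = P.make_equal_weights(mlr)
        np.testing.assert_allclose(equal.weights, [4.0, -4.0, 4.0])
        assert equal.intercept == 0.0

    def test_fixed_point_gives_identical_delta(self, example1_small):
        mlr = P.LinearAgeModel(
            method="mlr", markers=["X", "X_prime"], intercept=3.0,
            weights=np.array([0.7, 0.7]),
        )
        equal = P.make_equal_weights(mlr)
        d1 = P.predict_delta(mlr, example1_small).delta_hat
        d2 = P.predict_delta(equal, example1_small).delta_hat
        np.testing.assert_allclose(d1, d2, atol=1e-8)


class TestRandomWeights:
    def test_deterministic_given_seed(self):
        signs = np.array([1.0, -1.0, 1.0])
        a = P.sample_random_weights(signs, ["a", "b", "c"], n_draws=1, seed=5)
        b = P.sample_random_weights(signs, ["a", "b", "c"], n_draws=1, seed=5)
        np.testing.assert_array_equal(a[0].weights, b[0].weights)
        assert a[0].draw_index == 0

    def test_uniform_moments(self):
        signs = np.array([1.0, -1.0])
        models = P.sample_random_weights(signs, ["a", "b"], n_draws=1000, seed=9)
        weights = np.array([m.weights for m in models])
        sd_u = np.sqrt(1.0 / 12.0)
        tol = 4 * sd_u / np.sqrt(1000)
        assert weights[:, 0].mean() == pytest.approx(0.5, abs=tol)
        assert weights[:, 1].mean() == pytest.approx(-0.5, abs=tol)

    def test_default_draw_count(self):
        models = P.sample_random_weights(np.array([1.0]), ["a"], seed=0)
        assert len(models) == 1000

    def test_empty_signs_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            P.sample_random_weights(np.array([]), [], n_draws=1)


class TestPredictDelta:
    def test_perfect_proxy_gives_zero_delta(self, example1_small):
        pred = P.predict_delta(example1_small.age.copy(), example1_small)
        np.testing.assert_allclose(pred.delta_hat, 0.0, atol=1e-8)

    def test_uncorrelated_proxy_is_centered_proxy(self):
        rng = np.random.default_rng(77)
        age = rng.normal(50, 5, 2000)
        noise = rng.normal(0, 1, 2000)
        noise -= np.polyval(np.polyfit(age, noise, 1), age)  # exactly orthogonal
        data = _cohort(age, {"m": 0.1 * age + rng.normal(0, 1, 2000)})
        pred = P.predict_delta(noise + 3.0, data)
        np.testing.assert_allclose(pred.delta_hat, noise - noise.mean(), atol=1e-8)

    def test_matches_residual_oracle(self, example1_small):
        model = P.fit_mlr(example1_small, ["X"])
        pred = P.predict_delta(model, example1_small)
        proxy = model.predict(example1_small)
        design = np.column_stack([np.ones(example1_small.n), example1_small.age])
        coef = np.linalg.solve(design.T @ design, design.T @ proxy)
        np.testing.assert_allclose(pred.delta_hat, proxy - design @ coef, atol=1e-8)

    def test_constant_proxy_warns_degenerate(self, example1_small):
        with pytest.warns(UserWarning, match="constant"):
            pred = P.predict_delta(np.full(example1_small.n, 7.0), example1_small)
        assert pred.degenerate
        np.testing.assert_array_equal(pred.delta_hat, 0.0)

    @given(seed=st.integers(0, 10_000), method=st.sampled_from(["mlr", "kd", "pc1"]))
    @settings(max_examples=25, deadline=None)
    def test_orthogonality_invariant(self, seed, method):
        data = gen_example1(SimParams1(n=200, seed=seed))
        if method == "mlr":
            pred = P.predict_delta(P.fit_mlr(data), data)
        elif method == "kd":
            pred = P.predict_delta(P.fit_kd(data), data)
        else:
            pred = P.predict_delta(P.fit_pc1(data, subset=data.marker_names), data)
        assert abs(pred.delta_hat.mean()) < 1e-8
        denom = pred.delta_hat.std() * data.age.std()
        assert abs(np.mean(pred.delta_hat * (data.age - data.age.mean()))) / denom < 1e-8


class TestSerialization:
    def test_linear_model_json_round_trip(self):
        model = P.LinearAgeModel(
            method="ridge", markers=["m1", "m2"], intercept=1.5,
            weights=np.array([0.2, -0.3]), ridge_lambda=2.0,
        )
        back = P.LinearAgeModel.from_json(model.to_json())
        assert back.method == "ridge"
        assert back.ridge_lambda == 2.0
        np.testing.assert_allclose(back.weights, model.weights)
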