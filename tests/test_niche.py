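"""Native niche models: envelope, logistic GLM, discriminant, tree."""

import numpy as np
import pandas as pd
import pytest

from nicheresilience import (
    PREDICTORS,
    ClimateGrid,
    GridTransform,
    fit_discriminant,
    fit_envelope,
    fit_logistic,
    fit_tree,
    model_from_json,
    model_to_json,
    project,
    variable_importance,
)
from nicheresilience.niche import FitError, logistic_coefficients_original_scale, tree_features_used


def make_table(X: np.ndarray, y: np.ndarray, ecosystem: str = "forest") -> pd.DataFrame:
    df = pd.DataFrame(X, columns=list(PREDICTORS))
    for s in ("grassland", "savanna", "forest"):
        df[f"present_{s}"] = 0
    df[f"present_{ecosystem}"] = y
    # keep the one-hot invariant: absences get one of the other states
    other = "savanna" if ecosystem != "savanna" else "grassland"
    df.loc[df[f"present_{ecosystem}"] == 0, f"present_{other}"] = 1
    df["lon"] = df["lat"] = 0.0
    df["row"] = df["col"] = 0
    return df


class TestEnvelope:
    def test_point_outside_presence_range_scores_zero(self):
        rng = np.random.default_rng(0)
        X = rng.uniform([800, 10, 10, 2], [3000, 100, 28, 15], size=(200, 4))
        y = np.ones(200, dtype=int)
        y[:50] = 0
        model = fit_envelope(make_table(X, y), "forest", trim_q=0.0)
        point = X[y == 1][0].copy()
        point[0] = 500.0  # ACP below every presence
        assert model.predict(point[None, :])[0] == 0.0

    def test_median_presence_point_scores_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal([1500, 50, 20, 8], [300, 10, 3, 2], size=(300, 4))
        y = (rng.random(300) < 0.6).astype(int)
        model = fit_envelope(make_table(X, y), "forest", trim_q=0.1)
        median = np.median(X[y == 1], axis=0)
        assert model.predict(median[None, :])[0] == 1.0

    def test_bounds_match_sort_and_index_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, size=(100, 4)) * [3000, 100, 30, 18]
        table = make_table(X, np.ones(100, dtype=int))
        model = fit_envelope(table, "forest", trim_q=0.025)
        for j in range(4):
            xs = np.sort(X[:, j])
            # linear-interpolation quantile computed by hand
            for q, key in ((0.025, "lower"), (0.975, "upper")):
                h = q * (len(xs) - 1)
                lo_i = int(np.floor(h))
                expect = xs[lo_i] + (h - lo_i) * (xs[min(lo_i + 1, len(xs) - 1)] - xs[lo_i])
                assert model.parameters[key][j] == pytest.approx(expect, rel=1e-12)

    def test_too_few_presences_rejected(self):
        X = np.ones((12, 4))
        y = np.array([1] * 5 + [0] * 7)
        with pytest.raises(FitError):
            fit_envelope(make_table(X, y), "forest")


class TestLogistic:
    def test_uninformative_predictors_give_prevalence(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4000, 4))
        y = (rng.random(4000) < 0.3).astype(int)  # independent of X
        model = fit_logistic(make_table(X, y), "forest", degree=1)
        preds = model.predict(X)
        assert np.max(np.abs(preds - y.mean())) < 0.05

    def test_recovers_generating_coefficients_within_3se(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5000, 4))
        truth = np.array([-0.5, 1.2, -0.8, 0.4, 0.0])
        eta = truth[0] + X @ truth[1:]
        y = (rng.random(5000) < 1 / (1 + np.exp(-eta))).astype(int)
        model = fit_logistic(make_table(X, y), "forest", degree=1)
        coef, se = logistic_coefficients_original_scale(model)
        assert np.all(np.abs(coef - truth) < 3 * se)

    def test_matches_sklearn_unpenalized_fit(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(5)
        X = rng.normal(size=(2000, 4))
        eta = 0.3 + X @ np.array([1.0, -0.5, 0.2, 0.0])
        y = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(int)
        model = fit_logistic(make_table(X, y), "forest", degree=1)
        coef, _ = logistic_coefficients_original_scale(model)
        sk = sklearn.LogisticRegression(penalty=None, tol=1e-10, max_iter=1000).fit(X, y)
        np.testing.assert_allclose(coef[1:], sk.coef_[0], rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(coef[0], sk.intercept_[0], rtol=1e-4, atol=1e-6)

    def test_predictions_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(500, 4))
        y = (X[:, 0] > 0).astype(int)
        y[:20] = 1 - y[:20]  # avoid separation
        model = fit_logistic(make_table(X, y), "forest", degree=2)
        preds = model.predict(rng.normal(size=(100, 4)) * 10)
        assert np.all((preds >= 0) & (preds <= 1))

    def test_complete_separation_falls_back_to_ridge(self):
        X = np.zeros((200, 4))
        X[:, 0] = np.concatenate([np.linspace(-2, -1, 100), np.linspace(1, 2, 100)])
        y = np.array([0] * 100 + [1] * 100)
        model = fit_logistic(make_table(X, y), "forest", degree=1)
        assert model.training_summary["ridge_fallback"] is True

    def test_single_class_rejected(self):
        X = np.random.default_rng(7).normal(size=(50, 4))
        with pytest.raises(FitError):
            fit_logistic(make_table(X, np.ones(50, dtype=int)), "forest")


class TestDiscriminant:
    def test_posterior_near_one_at_class_means(self):
        rng = np.random.default_rng(8)
        mu0, mu1 = np.zeros(4), np.full(4, 4.0)
        X = np.vstack([rng.normal(mu0, 1, size=(300, 4)), rng.normal(mu1, 1, size=(300, 4))])
        y = np.array([0] * 300 + [1] * 300)
        model = fit_discriminant(make_table(X, y), "forest", reg=0.0)
        assert model.predict(mu1[None, :])[0] > 0.95
        assert model.predict(mu0[None, :])[0] < 0.05

    def test_matches_closed_form_gaussian_posterior(self):
        rng = np.random.default_rng(9)
        mu0, mu1 = np.zeros(4), np.array([2.0, -1.0, 0.5, 1.5])
        X = np.vstack([rng.normal(mu0, 1, size=(500, 4)), rng.normal(mu1, 1, size=(500, 4))])
        y = np.array([0] * 500 + [1] * 500)
        model = fit_discriminant(make_table(X, y), "forest", reg=0.0)
        # oracle: explicit Gaussian class-conditional posterior with the
        # same estimated means, pooled covariance, and priors
        m0, m1 = X[:500].mean(0), X[500:].mean(0)
        S = ((X[:500] - m0).T @ (X[:500] - m0) + (X[500:] - m1).T @ (X[500:] - m1)) / (1000 - 2)
        Sinv = np.linalg.inv(S)
        pts = rng.normal(0.5, 2, size=(50, 4))

        def posterior(z):
            def logd(m):
                d = z - m
                return -0.5 * d @ Sinv @ d

            l0, l1 = logd(m0) + np.log(0.5), logd(m1) + np.log(0.5)
            return 1 / (1 + np.exp(l0 - l1))

        expected = np.array([posterior(z) for z in pts])
        np.testing.assert_allclose(model.predict(pts), expected, atol=1e-10)

    def test_identical_classes_return_prior(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(2000, 4))
        y = np.array([0] * 1200 + [1] * 800)  # labels independent of X
        model = fit_discriminant(make_table(X, y), "forest", reg=0.0)
        preds = model.predict(rng.normal(size=(200, 4)))
        # estimation noise in the class means bounds the deviation from the prior
        assert np.max(np.abs(preds - 0.4)) < 0.15
        assert abs(np.mean(preds) - 0.4) < 0.03

    def test_posteriors_bounded(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(100, 4))
        y = (X[:, 0] > 0).astype(int)
        model = fit_discriminant(make_table(X, y), "forest", reg=0.1)
        preds = model.predict(rng.normal(size=(50, 4)) * 100)
        assert np.all((preds >= 0) & (preds <= 1))


class TestTree:
    def test_single_threshold_rule_recovered(self):
        rng = np.random.default_rng(12)
        X = np.zeros((400, 4))
        X[:, 0] = rng.uniform(500, 3000, size=400)
        y = (X[:, 0] > 1500).astype(int)
        model = fit_tree(make_table(X, y), "forest", max_depth=1, min_leaf=5)
        root = model.parameters["root"]
        assert not root["leaf"]
        assert root["feature"] == 0
        max_absence = X[y == 0, 0].max()
        min_presence = X[y == 1, 0].min()
        assert max_absence <= root["threshold"] <= min_presence
        # oracle: exhaustive scan confirms no candidate beats this gain
        assert root["threshold"] == pytest.approx((max_absence + min_presence) / 2)

    def test_pure_presence_single_leaf(self):
        X = np.random.default_rng(13).normal(size=(50, 4))
        model = fit_tree(make_table(X, np.ones(50, dtype=int)), "forest")
        assert model.parameters["root"]["leaf"] is True
        assert model.predict(X)[0] == 1.0

    def test_predictions_are_leaf_fractions_in_unit_interval(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(600, 4))
        y = (rng.random(600) < 0.5).astype(int)
        model = fit_tree(make_table(X, y), "forest", max_depth=3, min_leaf=20)
        preds = model.predict(X)
        assert np.all((preds >= 0) & (preds <= 1))
        assert len(np.unique(preds)) <= 2**3


class TestVariableImportance:
    def test_unused_predictor_has_zero_importance(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(500, 4))
        y = (X[:, 0] > 0).astype(int)
        table = make_table(X, y)
        model = fit_tree(table, "forest", max_depth=2, min_leaf=10)
        used = tree_features_used(model.parameters["root"])
        imp = variable_importance(model, table, n_shuffles=3, seed=0)
        for j, p in enumerate(PREDICTORS):
            if j not in used:
                assert imp[p] == 0.0

    def test_strong_single_predictor_dominates(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(5000, 4))
        eta = 4.0 * X[:, 0]
        y = (rng.random(5000) < 1 / (1 + np.exp(-eta))).astype(int)
        table = make_table(X, y)
        model = fit_logistic(table, "forest", degree=1)
        imp = variable_importance(model, table, n_shuffles=5, seed=1)
        assert imp["ACP"] > 0.5
        for p in PREDICTORS[1:]:
            assert imp["ACP"] > 10 * max(imp[p], 1e-12)

    def test_importance_matches_manual_correlation(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(800, 4))
        y = (rng.random(800) < 1 / (1 + np.exp(-X[:, 1]))).astype(int)
        table = make_table(X, y)
        model = fit_logistic(table, "forest", degree=1)
        imp = variable_importance(model, table, n_shuffles=2, seed=42)
        # manual recomputation with the same permutation stream
        rng2 = np.random.default_rng(42)
        base = model.predict(X)
        expected = {}
        for j, p in enumerate(PREDICTORS):
            corrs = []
            for _ in range(2):
                Xp = X.copy()
                Xp[:, j] = Xp[rng2.permutation(len(Xp)), j]
                perm = model.predict(Xp)
                corrs.append(1.0 if np.array_equal(perm, base) else np.corrcoef(base, perm)[0, 1])
            expected[p] = float(np.clip(1.0 - np.mean(corrs), 0.0, 1.0))
        assert imp == pytest.approx(expected)

    def test_constant_predictions_flagged_zero(self):
        X = np.random.default_rng(18).normal(size=(100, 4))
        y = np.array([1] * 60 + [0] * 40)
        table = make_table(X, y)
        model = fit_envelope(table, "forest", trim_q=0.0)
        # widen bounds so every point is inside -> constant predictions
        model.parameters["lower"] = [-1e9] * 4
        model.parameters["upper"] = [1e9] * 4
        model2 = model_from_json(model_to_json(model))
        imp = variable_importance(model2, table, n_shuffles=2, seed=0)
        assert all(v == 0.0 for v in imp.values())
        assert model2.training_summary["constant_predictions"] is True


class TestProjection:
    def test_envelope_inside_bounds_projects_ones(self, landscape):
        rng = np.random.default_rng(19)
        X = rng.uniform(0, 1, size=(100, 4))  # tiny envelope, then widen
        table = make_table(X, np.ones(100, dtype=int))
        model = fit_envelope(table, "forest", trim_q=0.0)
        model.parameters["lower"] = [-1e12] * 4
        model.parameters["upper"] = [1e12] * 4
        wide = model_from_json(model_to_json(model))
        proj = project(wide, landscape.climate)
        assert np.all(proj[~landscape.climate.nodata_mask] == 1.0)

    def test_nodata_pixels_stay_nodata(self, landscape):
        import numpy as np

        mask = np.zeros(landscape.climate.shape, dtype=bool)
        mask[:5, :] = True
        climate = ClimateGrid(
            layers=landscape.climate.layers, transform=landscape.climate.transform, nodata_mask=mask
        )
        rng = np.random.default_rng(20)
        X = rng.normal(size=(200, 4))
        y = (X[:, 0] > 0).astype(int)
        model = fit_discriminant(make_table(X, y), "forest", reg=0.1)
        proj = project(model, climate)
        assert np.all(np.isnan(proj[:5, :]))
        assert not np.any(np.isnan(proj[5:, :]))

    def test_projection_equals_pointwise_predict(self, landscape, occurrence_table):
        model = fit_logistic(occurrence_table, "forest", degree=2)
        proj = project(model, landscape.climate)
        rng = np.random.default_rng(21)
        h, w = landscape.climate.shape
        rows = rng.integers(0, h, size=100)
        cols = rng.integers(0, w, size=100)
        X = landscape.climate.predictor_matrix(rows, cols)
        np.testing.assert_allclose(proj[rows, cols], model.predict(X), rtol=0, atol=1e-12)

    def test_missing_layer_named_in_error(self, occurrence_table):
        model = fit_logistic(occurrence_table, "forest")
        climate = ClimateGrid(
            layers={p: np.zeros((4, 4)) for p in PREDICTORS}, transform=GridTransform()
        )
        del climate.layers["ART"]
        with pytest.raises(ValueError, match="ART"):
            project(model, climate)


class TestSerialization:
    @pytest.mark.parametrize("fitter,kwargs", [
        (fit_envelope, {"trim_q": 0.05}),
        (fit_logistic, {"degree": 2}),
        (fit_discriminant, {"reg": 0.1}),
        (fit_tree, {"max_depth": 3, "min_leaf": 10}),
    ])
    def test_json_round_trip_preserves_predictions(self, fitter, kwargs):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(300, 4))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
        y[:15] = 1 - y[:15]
        model = fitter(make_table(X, y), "forest", **kwargs)
        clone = model_from_json(model_to_json(model))
        Z = rng.normal(size=(100, 4))
        np.testing.assert_array_equal(model.predict(Z), clone.predict(Z))
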