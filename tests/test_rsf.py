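"""Weighted logistic RSF: likelihood oracles, AICc, selection machinery,
pseudo-R^2, Type II deviance and predictions."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from bayrsf.rsf import (
    ModelSpec,
    ResourceSelectionModel,
    aicc,
    akaike_weights,
    build_design_matrix,
    predict_effects,
    outermost_interval,
)


def _simple_model(y, x_cols: dict, w=None):
    X = pd.DataFrame({"const": np.ones(len(y)), **x_cols})
    w = np.ones(len(y)) if w is None else np.asarray(w, float)
    return ResourceSelectionModel(np.asarray(y, float), X, w)


class TestFitOracles:
    def test_binary_covariate_equals_2x2_log_odds_ratio(self):
        """With one binary covariate and equal weights the slope is the
        closed-form log odds ratio of the 2x2 table."""
        # cells: x=0: 30 ones / 70 zeros; x=1: 55 ones / 45 zeros
        y = np.r_[np.ones(30), np.zeros(70), np.ones(55), np.zeros(45)]
        x = np.r_[np.zeros(100), np.ones(100)]
        res = _simple_model(y, {"x": x}).fit()
        log_or = np.log((55 / 45) / (30 / 70))
        assert res.params["x"] == pytest.approx(log_or, abs=1e-8)
        assert res.params["const"] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_intercept_only_gives_weighted_mean(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200).astype(float)
        w = rng.uniform(0.2, 3.0, 200)
        res = _simple_model(y, {}, w=w).fit()
        assert expit(res.params["const"]) == pytest.approx(
            np.average(y, weights=w), abs=1e-10
        )

    def test_weight_doubling_keeps_beta_scales_se(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        y = (rng.uniform(size=300) < expit(0.8 * x - 0.2)).astype(float)
        w = rng.uniform(0.5, 2.0, 300)
        r1 = _simple_model(y, {"x": x}, w=w).fit()
        r2 = _simple_model(y, {"x": x}, w=2 * w).fit()
        assert r2.params["x"] == pytest.approx(r1.params["x"], abs=1e-8)
        assert r2.bse["x"] == pytest.approx(r1.bse["x"] / np.sqrt(2), rel=1e-6)

    def test_matches_brute_force_newton_on_two_covariates(self):
        """The fit agrees with a direct numerical maximisation of the same
        weighted log-likelihood to 1e-6 in beta."""
        rng = np.random.default_rng(2)
        n = 400
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = (rng.uniform(size=n) < expit(0.5 * x1 - 0.7 * x2)).astype(float)
        w = rng.uniform(0.3, 2.5, n)
        res = _simple_model(y, {"x1": x1, "x2": x2}, w=w).fit()

        X = np.column_stack([np.ones(n), x1, x2])

        def nll(beta):
            p = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
            return -np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p)))

        brute = minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-12})
        np.testing.assert_allclose(res.params.to_numpy(), brute.x, atol=1e-6)

    def test_singular_design_names_aliased_column(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        with pytest.raises(ValueError, match="aliased"):
            _simple_model(np.ones(50), {"a": x, "b": 2 * x})


class TestAICc:
    def test_arithmetic_example(self):
        assert aicc(-100.0, 3, 100) == pytest.approx(206.25)

    def test_exceeds_aic_for_finite_n(self):
        for n in (10, 50, 1000):
            assert aicc(-10.0, 3, n) > -2 * -10.0 + 2 * 3

    def test_equal_fits_equal_aicc(self):
        assert aicc(-5.0, 2, 40) == aicc(-5.0, 2, 40)

    def test_small_n_sentinel(self):
        assert aicc(-5.0, 5, 6) == np.inf


class TestAkaikeWeights:
    def test_tied_models_split_evenly(self):
        t = akaike_weights(pd.DataFrame({"aicc": [10.0, 10.0]}))
        np.testing.assert_allclose(t["akaike_weight"], 0.5)

    def test_delta_two_ratio(self):
        t = akaike_weights(pd.DataFrame({"aicc": [0.0, 2.0]}))
        np.testing.assert_allclose(
            t["akaike_weight"], [1 / (1 + np.exp(-1)), np.exp(-1) / (1 + np.exp(-1))],
            rtol=1e-12,
        )
        assert t["akaike_weight"].iloc[0] == pytest.approx(0.731, abs=5e-4)

    def test_weights_sum_to_one_and_best_has_zero_delta(self):
        rng = np.random.default_rng(0)
        t = akaike_weights(pd.DataFrame({"aicc": rng.uniform(100, 120, 9)}))
        assert t["akaike_weight"].sum() == pytest.approx(1.0, rel=1e-12)
        assert t.loc[t["aicc"].idxmin(), "delta_aicc"] == 0.0


class TestPseudoR2:
    def test_null_model_is_zero(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100).astype(float)
        res = _simple_model(y, {}).fit()
        assert res.pseudo_r2 == pytest.approx(0.0, abs=1e-10)

    def test_near_separation_approaches_one(self):
        x = np.r_[np.full(50, -3.0), np.full(50, 3.0)]
        y = (x > 0).astype(float)
        res = _simple_model(y, {"x": x}).fit()
        assert res.pseudo_r2 > 0.98

    def test_six_row_brute_force_example(self):
        y = np.array([1, 0, 1, 1, 0, 0], dtype=float)
        x = np.array([2.0, 1.0, 0.5, -0.5, -1.0, -2.0])
        w = np.array([1.0, 2.0, 1.0, 1.0, 2.0, 1.0])
        res = _simple_model(y, {"x": x}, w=w).fit()
        p = expit(res.params["const"] + res.params["x"] * x)
        pbar = np.average(y, weights=w)
        expected = 1 - (
            np.sum(w * (y - p) ** 2 / (p * (1 - p)))
            / np.sum(w * (y - pbar) ** 2 / (pbar * (1 - pbar)))
        )
        assert res.pseudo_r2 == pytest.approx(expected, rel=1e-10)


def _design_df(n=600, seed=0, beta=(0.6, -0.5, 0.3), night_dist=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "dist_eelgrass_m": rng.normal(size=n),
            "depth_m": rng.normal(size=n),
            "temp_delta_c": rng.normal(size=n),
            "diel": rng.choice(["day", "night"], n),
            "scl_cm": rng.normal(80, 15, n),
            "season": "warm",
        }
    )
    night = (df["diel"] == "night").astype(float)
    eta = (
        beta[0] * df["dist_eelgrass_m"]
        + beta[1] * df["depth_m"]
        + beta[2] * df["temp_delta_c"]
        + night_dist * night * df["dist_eelgrass_m"]
    )
    df["response"] = (rng.uniform(size=n) < expit(eta)).astype(float)
    df["weight"] = 1.0
    return df


class TestModelSpec:
    def test_threeway_requires_both_twoways(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec("warm", diel_interactions={"dist"}, threeway={"dist"})

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("warm", diel_interactions={"chlorophyll"})

    def test_quadratic_group_travels_with_interaction(self):
        spec = ModelSpec("warm", quad_depth=True, diel_interactions={"depth"})
        X = build_design_matrix(_design_df(20), spec)
        assert "night:depth" in X and "night:depth^2" in X


class TestTypeII:
    def test_lr_equals_explicit_refits(self):
        df = _design_df(seed=4)
        spec = ModelSpec("warm")
        res = ResourceSelectionModel.from_design(df, spec).fit()
        table = res.type2_anova()
        # oracle: explicit refits for 'depth'
        full = res.model.exog.columns.tolist()
        red = [c for c in full if c != "depth"]
        ll_full = ResourceSelectionModel(
            res.model.endog, res.model.exog[full], res.model.weights
        ).fit().llf
        ll_red = ResourceSelectionModel(
            res.model.endog, res.model.exog[red], res.model.weights
        ).fit().llf
        assert table.loc["depth", "lr_chi2"] == pytest.approx(
            2 * (ll_full - ll_red), abs=1e-6
        )

    def test_main_effect_tested_without_its_interaction(self):
        """Type II: 'dist' is tested in models excluding night:dist."""
        df = _design_df(seed=5, night_dist=0.8)
        spec = ModelSpec("warm", diel_interactions={"dist"})
        res = ResourceSelectionModel.from_design(df, spec).fit()
        table = res.type2_anova()

        cols = res.model.exog.columns.tolist()
        keep = [c for c in cols if c != "night:dist"]
        ll_f = ResourceSelectionModel(res.model.endog, res.model.exog[keep], res.model.weights).fit().llf
        keep_r = [c for c in keep if c != "dist"]
        ll_r = ResourceSelectionModel(res.model.endog, res.model.exog[keep_r], res.model.weights).fit().llf
        assert table.loc["dist", "lr_chi2"] == pytest.approx(2 * (ll_f - ll_r), abs=1e-6)
        # the interaction itself is tested against the full model
        assert table.loc["night:dist", "p_value"] < 0.05


class TestPredictions:
    def test_probability_half_at_zero_linear_predictor(self):
        df = _design_df(seed=6)
        res = ResourceSelectionModel.from_design(df, ModelSpec("warm")).fit()
        scen = df.iloc[:5].copy()
        # choose covariates so that x'beta = 0: all zeros except intercept term
        for c in ("dist_eelgrass_m", "depth_m", "temp_delta_c"):
            scen[c] = 0.0
        expected = expit(res.params["const"])
        np.testing.assert_allclose(res.predict(scen), expected, rtol=1e-12)

    def test_intervals_bracket_point_estimate(self):
        df = _design_df(seed=7)
        res = ResourceSelectionModel.from_design(df, ModelSpec("warm")).fit()
        out = res.predict(df.iloc[:50], interval=True)
        assert ((out["lower"] < out["p"]) & (out["p"] < out["upper"])).all()
        assert ((out["lower"] > 0) & (out["upper"] < 1)).all()

    def test_quadratic_vertex_matches_numeric_argmax(self):
        rng = np.random.default_rng(8)
        n = 4000
        df = _design_df(n, seed=8)
        d = df["dist_eelgrass_m"]
        eta = -0.3 * d - 0.5 * d**2
        df["response"] = (rng.uniform(size=n) < expit(eta)).astype(float)
        res = ResourceSelectionModel.from_design(
            df, ModelSpec("warm", quad_dist=True)
        ).fit()
        curve = predict_effects(res, df, "dist", n_grid=4001)
        b1 = res.params["dist"]
        b2 = res.params["dist^2"]
        vertex = -b1 / (2 * b2)
        numeric = curve.loc[curve["p"].idxmax(), "dist_eelgrass_m"]
        assert numeric == pytest.approx(vertex, abs=0.01)

    def test_outermost_interval_hull(self):
        df = _design_df(seed=9)
        res = ResourceSelectionModel.from_design(df, ModelSpec("warm")).fit()
        curves = [
            predict_effects(res, df, "depth", scl_cm=s, n_grid=30)
            for s in (60.0, 80.0, 100.0)
        ]
        hull = outermost_interval(curves)
        for c in curves:
            assert (hull["lower"] <= c["lower"] + 1e-12).all()
            assert (hull["upper"] >= c["upper"] - 1e-12).all()


class TestSpatialPrediction:
    def _rasters(self, n=8, cell=500.0):
        from bayrsf.raster import Raster

        rng = np.random.default_rng(12)
        mk = lambda v: Raster(values=v, x0=0.0, y0=0.0, cell=cell)
        return (
            mk(rng.normal(size=(n, n)) * 400),
            mk(rng.uniform(1, 10, size=(n, n))),
            mk(rng.normal(size=(n, n))),
        )

    def test_uniform_rasters_give_uniform_probability(self):
        from bayrsf.raster import Raster
        from bayrsf.rsf import predict_spatial

        df = _design_df(seed=13)
        res = ResourceSelectionModel.from_design(df, ModelSpec("warm")).fit()
        mk = lambda c: Raster(values=np.full((5, 5), c), x0=0.0, y0=0.0, cell=100.0)
        p, lo, hi = predict_spatial(res, mk(0.2), mk(4.0), mk(-0.3), "day", 80.9)
        assert np.nanstd(p.values) == 0.0
        assert np.all(lo.values < p.values) and np.all(p.values < hi.values)

    def test_cell_values_match_effect_prediction(self):
        """Spatial prediction equals predict() evaluated at sampled cells."""
        from bayrsf.rsf import predict_spatial

        df = _design_df(seed=14)
        res = ResourceSelectionModel.from_design(df, ModelSpec("warm")).fit()
        dist, depth, temp = self._rasters()
        p, _, _ = predict_spatial(res, dist, depth, temp, "night", 95.0)
        scen = pd.DataFrame(
            {
                "dist_eelgrass_m": dist.values.ravel(),
                "depth_m": depth.values.ravel(),
                "temp_delta_c": temp.values.ravel(),
                "diel": "night",
                "scl_cm": 95.0,
            }
        )
        np.testing.assert_allclose(p.values.ravel(), res.predict(scen), rtol=1e-12)

    def test_misaligned_rasters_hard_error(self):
        from bayrsf.raster import Raster
        from bayrsf.rsf import predict_spatial

        df = _design_df(seed=15)
        res = ResourceSelectionModel.from_design(df, ModelSpec("warm")).fit()
        dist, depth, temp = self._rasters()
        shifted = Raster(values=depth.values, x0=50.0, y0=0.0, cell=500.0)
        with pytest.raises(ValueError, match="misaligned"):
            predict_spatial(res, dist, shifted, temp, "day", 80.9)

    def test_availability_mask_applied(self):
        from bayrsf.rsf import predict_spatial
        from shapely.geometry import box

        df = _design_df(seed=16)
        res = ResourceSelectionModel.from_design(df, ModelSpec("warm")).fit()
        dist, depth, temp = self._rasters()
        west = box(0, 0, 2000, 4000)  # covers only the left half
        p, _, _ = predict_spatial(res, dist, depth, temp, "day", 80.9, availability=west)
        assert np.isnan(p.values[:, 4:]).all()
        assert np.isfinite(p.values[:, :4]).all()


class TestInvariances:
    def test_aicc_ordering_invariant_to_affine_covariate_rescaling(self):
        df = _design_df(seed=10, night_dist=0.5)
        specs = [
            ModelSpec("warm"),
            ModelSpec("warm", quad_dist=True),
            ModelSpec("warm", diel_interactions={"dist"}),
        ]
        a = [ResourceSelectionModel.from_design(df, s).fit().aicc for s in specs]
        df2 = df.copy()
        df2["dist_eelgrass_m"] = df2["dist_eelgrass_m"] * 750.0
        df2["depth_m"] = df2["depth_m"] * 3.0
        b = [ResourceSelectionModel.from_design(df2, s).fit().aicc for s in specs]
        assert np.argsort(a).tolist() == np.argsort(b).tolist()
        np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_summary_renders(self):
        df = _design_df(seed=11)
        res = ResourceSelectionModel.from_design(df, ModelSpec("warm")).fit()
        text = res.summary()
        assert "AICc" in text and "pseudo-R2" in text and "dist" in text
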