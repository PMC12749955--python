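"""Importance, one-SD sensitivity, ALE and exploratory statistics."""

import numpy as np
import pandas as pd
import pytest

from sdproxy import (
    EnsembleConfig,
    ale_curve,
    ale_with_uncertainty,
    correlation_by_landcover,
    sd_sensitivity,
    sdp_summary_by_landcover,
    train_ensemble,
    variable_importance,
)


def brute_force_ale(f, table, predictor, edges):
    """Literal-definition first-order ALE, deliberately loop-based.

    Bin k spans (z_{k-1}, z_k]; rows at the first edge join bin 1; the
    accumulated curve is centered on its piecewise-linear evaluation at
    the data points.
    """
    x = table[predictor].to_numpy(dtype=float)
    acc = [0.0]
    for k in range(1, len(edges)):
        if k == 1:
            in_bin = x <= edges[1]
        else:
            in_bin = (x > edges[k - 1]) & (x <= edges[k])
        rows = table[in_bin]
        if len(rows) == 0:
            acc.append(acc[-1])
            continue
        hi, lo = rows.copy(), rows.copy()
        hi[predictor] = edges[k]
        lo[predictor] = edges[k - 1]
        acc.append(acc[-1] + float(np.mean(np.asarray(f(hi)) - np.asarray(f(lo)))))
    acc = np.asarray(acc)
    return acc - float(np.mean(np.interp(x, edges, acc)))


class TestImportance:
    def test_shares_sum_to_one(self, tiny_ensemble):
        imp = variable_importance(tiny_ensemble)
        assert imp.sum() == pytest.approx(1.0, abs=1e-12)
        assert (imp >= 0).all()

    def test_single_predictor_takes_all(self, small_sdp_table):
        cfg = EnsembleConfig(n_models=1, n_trees=10, seed=0, predictors=("TEMP30",), categorical=())
        ens = train_ensemble(small_sdp_table, cfg)
        imp = variable_importance(ens)
        assert imp["TEMP30"] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_pure_noise_predictor_ranks_last(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        x1 = rng.uniform(size=n)
        x2 = rng.uniform(size=n)
        noise = rng.uniform(size=n)
        t = pd.DataFrame(
            {"x1": x1, "x2": x2, "noise": noise, "sdp": np.clip(0.6 * x1 + 0.4 * x2, 0, 1)}
        )
        cfg = EnsembleConfig(
            n_models=2, n_trees=40, seed=seed, predictors=("x1", "x2", "noise"), categorical=()
        )
        imp = variable_importance(train_ensemble(t, cfg))
        assert imp.idxmin() == "noise"


class _LinearStub:
    """Analytic predictor f(x) = coef · x over one column."""

    def __init__(self, column, coef):
        self.column, self.coef = column, coef

    def __call__(self, table):
        return self.coef * table[self.column].to_numpy(dtype=float)


class TestSensitivity:
    def test_linear_stub_is_exact(self, rng):
        t = pd.DataFrame({"x": rng.uniform(0, 1, 200), "landcover": "cropland"})
        delta = sd_sensitivity(_LinearStub("x", 2.0), t, "x", sigma=0.5)
        assert delta == pytest.approx(1.0, abs=1e-9)

    def test_linear_stub_delta_equals_coef_times_sigma(self, rng):
        x = rng.normal(0, 3.0, 500)
        t = pd.DataFrame({"x": x, "landcover": "forest"})
        sigma = float(x.std(ddof=0))
        delta = sd_sensitivity(_LinearStub("x", -1.7), t, "x")
        assert delta == pytest.approx(-1.7 * sigma, abs=1e-9)

    def test_constant_model_has_zero_delta(self, rng):
        t = pd.DataFrame({"x": rng.uniform(0, 1, 50), "landcover": "cropland"})
        assert sd_sensitivity(lambda df: np.zeros(len(df)), t, "x", sigma=1.0) == 0.0

    def test_irrelevant_predictor_near_zero(self, small_sdp_table, tiny_ensemble):
        """Perturbing a predictor the generative link ignores moves the
        forest prediction by at most a small noise floor."""
        t = small_sdp_table.copy()
        rng = np.random.default_rng(0)
        t["pure_noise"] = rng.uniform(size=len(t))
        cfg = EnsembleConfig(
            n_models=2,
            n_trees=30,
            seed=0,
            predictors=("TEMP30", "PRCP30", "NDVI", "pure_noise"),
            categorical=(),
        )
        ens = train_ensemble(t, cfg)
        d_noise = abs(sd_sensitivity(ens, t, "pure_noise"))
        d_signal = abs(sd_sensitivity(ens, t, "TEMP30"))
        assert d_noise < 0.02 and d_noise < d_signal

    def test_categorical_predictor_rejected(self, tiny_ensemble, small_sdp_table):
        with pytest.raises(ValueError, match="categorical"):
            sd_sensitivity(tiny_ensemble, small_sdp_table, "landcover")


class TestAle:
    def test_constant_model_gives_zero_curve(self, rng):
        t = pd.DataFrame({"x": rng.uniform(0, 1, 100), "landcover": "cropland"})
        c = ale_curve(lambda df: np.full(len(df), 0.3), t, "x", n_bins=5)
        np.testing.assert_allclose(c.effect, 0.0, atol=1e-12)

    def test_linear_model_closed_form(self, rng):
        x = rng.uniform(0, 10, 400)
        t = pd.DataFrame({"x1": x, "landcover": "cropland"})
        c = ale_curve(_LinearStub("x1", 3.0), t, "x1", n_bins=10)
        np.testing.assert_allclose(c.effect, 3.0 * (c.edges - x.mean()), atol=1e-6)

    def test_correlated_additive_model_matches_brute_force(self, rng):
        """With corr(x1, x2) = 0.8 and f = x1 + x2, the ALE of x1 has unit
        slope (not 1.8): local differences only move x1."""
        n = 500
        z = rng.standard_normal((n, 2))
        x1 = z[:, 0]
        x2 = 0.8 * z[:, 0] + 0.6 * z[:, 1]
        t = pd.DataFrame({"x1": x1, "x2": x2, "landcover": "cropland"})
        f = lambda df: df["x1"].to_numpy(float) + df["x2"].to_numpy(float)
        c = ale_curve(f, t, "x1", n_bins=8)
        oracle = brute_force_ale(f, t, "x1", c.edges)
        np.testing.assert_allclose(c.effect, oracle, atol=1e-9)
        slope = (c.effect[-1] - c.effect[0]) / (c.edges[-1] - c.edges[0])
        assert slope == pytest.approx(1.0, abs=1e-6)

    def test_forest_model_matches_brute_force(self, tiny_ensemble, small_sdp_table):
        for predictor in ("TEMP30", "NDVI"):
            c = ale_curve(tiny_ensemble, small_sdp_table, predictor, n_bins=8)
            oracle = brute_force_ale(
                tiny_ensemble.predict_mean, small_sdp_table, predictor, c.edges
            )
            np.testing.assert_allclose(c.effect, oracle, atol=1e-9)

    def test_centering_invariant(self, tiny_ensemble, small_sdp_table):
        for stratum in (None, "cropland", "forest"):
            c = ale_curve(tiny_ensemble, small_sdp_table, "PRCP30", n_bins=6, stratum=stratum)
            sub = (
                small_sdp_table
                if stratum is None
                else small_sdp_table[small_sdp_table["landcover"] == stratum]
            )
            x = sub["PRCP30"].to_numpy(float)
            assert abs(np.mean(np.interp(x, c.edges, c.effect))) < 1e-9

    def test_invalid_inputs(self, tiny_ensemble, small_sdp_table, rng):
        with pytest.raises(ValueError, match="n_bins"):
            ale_curve(tiny_ensemble, small_sdp_table, "TEMP30", n_bins=1)
        with pytest.raises(ValueError, match="empty stratum"):
            ale_curve(tiny_ensemble, small_sdp_table, "TEMP30", n_bins=4, stratum="desert")

    def test_bootstrap_band_degenerate_for_single_resample(self, rng):
        x = rng.uniform(0, 1, 200)
        t = pd.DataFrame({"x": x, "landcover": "cropland"})
        c = ale_with_uncertainty(_LinearStub("x", 2.0), t, "x", n_bins=5, n_boot=1, seed=3)
        np.testing.assert_allclose(c.ci_low, c.ci_high, atol=1e-12)

    def test_same_seed_identical_bands(self, tiny_ensemble, small_sdp_table):
        a = ale_with_uncertainty(tiny_ensemble, small_sdp_table, "TEMP30", n_bins=5, n_boot=5, seed=11)
        b = ale_with_uncertainty(tiny_ensemble, small_sdp_table, "TEMP30", n_bins=5, n_boot=5, seed=11)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        np.testing.assert_array_equal(a.ci_high, b.ci_high)

    def test_band_width_shrinks_with_sample_size(self):
        """For a deterministic linear model the bootstrap band narrows as the
        sample grows (checked over three sizes)."""
        widths = []
        for n in (200, 800, 3200):
            rng = np.random.default_rng(42)
            t = pd.DataFrame({"x": rng.uniform(0, 1, n), "landcover": "cropland"})
            c = ale_with_uncertainty(_LinearStub("x", 2.0), t, "x", n_bins=5, n_boot=20, seed=1)
            widths.append(float(np.mean(c.ci_high - c.ci_low)))
        assert widths[0] > widths[1] > widths[2]


class TestExploratory:
    def test_sdp_duplicated_as_predictor_has_unit_correlation(self, small_sdp_table):
        t = small_sdp_table.copy()
        t["sdp_copy"] = t["sdp"]
        out = correlation_by_landcover(t, ["sdp_copy"], ["all"])
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_planted_negative_link_recovered_in_stratum(self):
        """A generator preset with a strongly negative NDVI effect yields a
        negative SDP–NDVI correlation within cropland."""
        from sdproxy import SyntheticConfig, build_sdp_table, generate_covariate_grids, generate_survey

        cfg = SyntheticConfig(
            grid_rows=24,
            grid_cols=24,
            years=tuple(range(2014, 2020)),
            survey_years=(2015, 2018),
            n_points_per_year=250,
            seed=2,
            effect_sizes={"NDVI": -1.0},
            noise_sd=0.05,
        )
        stack = generate_covariate_grids(cfg)
        table = build_sdp_table(generate_survey(stack, cfg))
        out = correlation_by_landcover(table, ["NDVI"], ["cropland"])
        assert out["pearson_r"].iloc[0] < 0

    def test_tiny_stratum_rejected(self, small_sdp_table):
        t = small_sdp_table.head(2).copy()
        with pytest.raises(ValueError, match="fewer than 3"):
            correlation_by_landcover(t, ["TEMP30"], ["all"])

    def test_zero_variance_predictor_is_nan(self, small_sdp_table):
        t = small_sdp_table.copy()
        t["flat"] = 1.0
        out = correlation_by_landcover(t, ["flat"], ["all"])
        assert np.isnan(out["pearson_r"].iloc[0])

    def test_summary_counts_and_single_class(self, small_sdp_table):
        out = sdp_summary_by_landcover(small_sdp_table)
        assert out["count"].sum() == len(small_sdp_table)
        assert out["median"].between(0, 1).all()
        single = small_sdp_table[small_sdp_table["landcover"] == "cropland"]
        out1 = sdp_summary_by_landcover(single)
        assert out1["median"].iloc[0] == pytest.approx(single["sdp"].median())
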