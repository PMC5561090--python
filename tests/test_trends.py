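"""Trend estimators: OLS oracle equivalence, subsets, smoothers, model selection."""

import numpy as np
import pandas as pd
import pytest

from ringwue import (
    exclude_small_trees,
    linear_trend,
    mixed_effects_all_species,
    model_selection_aic,
    per_predictor_r2,
    smooth_trend,
    spline_smooth_series,
    threshold_subset_trends,
    time_trend,
)
from ringwue.ring_data import AtmosphericRecord
from ringwue.trends import DegenerateDesignError, TrendFit, significance_stars


def ols_oracle(x, y):
    """Closed-form OLS from sums — independent of the implementation path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    slope = sxy / sxx
    resid = y - (y.mean() + slope * (x - x.mean()))
    s2 = np.sum(resid**2) / (n - 2)
    se = np.sqrt(s2 / sxx)
    r2 = 0.0 if syy == 0 else sxy**2 / (sxx * syy)
    return slope, se, r2


class TestLinearTrend:
    def test_exact_line_in_reporting_units(self):
        x = np.arange(10, 110, 10, dtype=float)  # years
        fit = linear_trend(x, 0.1 * x + 5.0, "age")
        assert fit.slope == pytest.approx(10.0, abs=1e-10)  # ppm per 100 yr
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_response(self):
        fit = linear_trend([1.0, 2.0, 3.0, 4.0], [7.0] * 4, "height")
        assert fit.slope == 0.0 and fit.r_squared == 0.0

    def test_hand_computed_example(self):
        fit = linear_trend([1, 2, 3, 4], [2, 2, 4, 4], "cii")
        assert fit.slope_raw == pytest.approx(0.8, abs=1e-12)  # Sxy/Sxx = 4/5

    def test_height_slope_scaled_per_10m(self):
        h = np.linspace(1, 30, 20)
        fit = linear_trend(h, 1.8 * h + 40.0, "height")
        assert fit.slope == pytest.approx(18.0, abs=1e-9)

    @pytest.mark.parametrize("x,y", [([1.0, 2.0], [1.0, 2.0]), ([3.0] * 5, [1, 2, 3, 4, 5])])
    def test_degenerate_designs_rejected(self, x, y):
        with pytest.raises(DegenerateDesignError):
            linear_trend(x, y, "age")

    def test_matches_closed_form_oracle_on_random_data(self, rng):
        for _ in range(200):
            n = rng.integers(5, 51)
            x = rng.uniform(0, 100, n)
            y = 0.5 * x + rng.normal(0, 10, n)
            fit = linear_trend(x, y, "age")
            slope, se, r2 = ols_oracle(x, y)
            assert fit.slope_raw == pytest.approx(slope, abs=1e-10)
            assert fit.slope_se == pytest.approx(se * 100, rel=1e-10)
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_significance_stars_legend(self):
        assert [significance_stars(p) for p in (0.5, 0.04, 0.009, 0.0009)] == [
            "NS", "*", "**", "***",
        ]


class TestThresholdSubsets:
    def test_subsetting_noop_when_all_data_above_thresholds(self, rng):
        age = rng.uniform(300, 400, 40)
        df = pd.DataFrame({"age_years": age, "wi_ppm": 0.3 * age + rng.normal(0, 2, 40)})
        fits = threshold_subset_trends(df, "age", [25, 50, 100, 200])
        slopes = {f.slope for f in fits}
        assert len(slopes) == 1  # identical fit at every threshold

    def test_piecewise_fixture_isolated_above_threshold(self):
        x_lo = np.linspace(0, 50, 60)
        x_hi = np.linspace(51, 100, 60)
        y = np.concatenate([2.0 * x_lo, 100.0 + 1.0 * (x_hi - 50.0)])
        df = pd.DataFrame({"age_years": np.concatenate([x_lo, x_hi]), "wi_ppm": y})
        full = linear_trend(df["age_years"], df["wi_ppm"], "age")
        sub = threshold_subset_trends(df, "age", [50.0])[0]
        assert sub.slope_raw == pytest.approx(1.0, abs=1e-9)
        assert 1.0 < full.slope_raw < 2.0

    def test_tiny_subset_reported_not_estimable(self):
        df = pd.DataFrame({"age_years": [10, 20, 90, 95.0], "wi_ppm": [50, 55, 80, 81.0]})
        fits = threshold_subset_trends(df, "age", [50.0])
        assert len(fits) == 1 and not fits[0].estimable
        assert fits[0].n == 2 and fits[0].subset_rule == "age > 50"

    def test_unsorted_thresholds_rejected(self):
        df = pd.DataFrame({"age_years": [1.0, 2, 3], "wi_ppm": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            threshold_subset_trends(df, "age", [50, 25])


class TestExcludeSmallTrees:
    def test_boundary_is_kept_strict_inequality(self):
        df = pd.DataFrame({"height_m": [0.5, 1.0, 2.0], "wi_ppm": [1.0, 2, 3]})
        with pytest.warns(UserWarning, match="excluded 1"):
            kept = exclude_small_trees(df)
        assert list(kept["height_m"]) == [1.0, 2.0]

    def test_all_large_unchanged(self):
        df = pd.DataFrame({"height_m": [1.0, 5.0], "wi_ppm": [1.0, 2]})
        assert exclude_small_trees(df).equals(df)

    def test_emptying_warns(self):
        df = pd.DataFrame({"height_m": [0.2, 0.4], "wi_ppm": [1.0, 2]})
        with pytest.warns(UserWarning):
            kept = exclude_small_trees(df)
        assert kept.empty


class TestSmoothTrend:
    def test_reproduces_exact_line(self):
        x = np.linspace(0, 100, 60)
        y = 0.5 * x + 3.0
        fit = smooth_trend(x, y)
        assert np.max(np.abs(fit.mean - (0.5 * fit.grid + 3.0))) < 1e-6

    def test_recovers_smooth_signal_below_noise_level(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 2 * np.pi, 200))
        noise_sd = 0.3
        y = np.sin(x) + rng.normal(0, noise_sd, 200)
        fit = smooth_trend(x, y)
        rmse = np.sqrt(np.mean((fit.mean - np.sin(fit.grid)) ** 2))
        assert rmse < noise_sd

    def test_group_offsets_absorbed(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 10, 80)
        base = 2.0 + 0.1 * x**2
        y1 = base + rng.normal(0, 0.3, 80)
        y2 = base + 10.0 + rng.normal(0, 0.3, 80)
        single = smooth_trend(x, y1)
        fit = smooth_trend(
            np.concatenate([x, x]),
            np.concatenate([y1, y2]),
            groups=np.repeat(["a", "b"], 80),
        )
        assert fit.group_offsets["b"] - fit.group_offsets["a"] == pytest.approx(10.0, abs=0.5)
        # group-a curve (pooled mean + group-a offset) tracks the single-group fit
        group_a = np.interp(single.grid, fit.grid, fit.mean) + fit.group_offsets["a"]
        assert np.all(np.abs(group_a - single.mean) < 2 * (single.se + fit.se.mean()) + 0.3)

    def test_too_few_distinct_points_rejected(self):
        with pytest.raises(DegenerateDesignError, match="linear_trend"):
            smooth_trend([1, 2, 3, 4, 5.0], [1, 2, 3, 4, 5.0])

    def test_cross_check_against_library_smoothing_spline(self):
        # independent engine: GCV natural smoothing spline from scipy
        from scipy.interpolate import make_smoothing_spline

        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 10, 150))
        y = np.cos(x) + rng.normal(0, 0.2, 150)
        fit = smooth_trend(x, y, grid=x)
        ref = make_smoothing_spline(x, y)(x)
        assert np.sqrt(np.mean((fit.mean - ref) ** 2)) < 0.15


class TestPredictorComparison:
    @staticmethod
    def stand_df(rng, n=120, sd=1.0, pure="height"):
        height = rng.uniform(1, 30, n)
        age = height * 3 + rng.normal(0, 5, n)
        cii = np.clip(np.rint(1 + 7 * height / 30 + rng.normal(0, 1, n)), 1, 8)
        wi = {"height": 2.0 * height, "noise": np.zeros(n)}[pure] + rng.normal(0, sd, n)
        return pd.DataFrame(
            {
                "age_years": age,
                "dbh_cm": height * 3.3 + rng.normal(0, 2, n),
                "height_m": height,
                "cii_ordinal": cii,
                "wi_ppm": wi + 50,
            }
        )

    def test_height_generated_wi_gives_height_r2_near_one(self, rng):
        r2 = per_predictor_r2(self.stand_df(rng, sd=0.5))
        assert r2["height"]["r_squared"] > 0.99
        assert r2["age"]["r_squared"] < r2["height"]["r_squared"]

    def test_noise_wi_type_i_error_rate_near_nominal(self):
        hits = total = 0
        for s in range(400):
            rng = np.random.default_rng(10_000 + s)
            df = self.stand_df(rng, n=25, pure="noise")
            res = per_predictor_r2(df[["height_m", "wi_ppm"]].assign())
            hits += res["height"]["p_value"] < 0.05
            total += 1
        assert 0.02 <= hits / total <= 0.09  # nominal 5%

    def test_constant_predictor_flagged(self):
        df = pd.DataFrame(
            {"height_m": [2.0] * 10, "wi_ppm": np.arange(10.0)}
        )
        res = per_predictor_r2(df)
        assert not res["height"]["estimable"]


class TestModelSelection:
    def test_strong_height_light_signal_selects_that_pair(self):
        n_ok = 0
        for s in range(25):
            rng = np.random.default_rng(500 + s)
            height = rng.uniform(1, 30, 150)
            age = height * 3 + rng.normal(0, 8, 150)
            cii = np.clip(np.rint(1 + 7 * height / 30 + rng.normal(0, 0.7, 150)), 1, 8)
            wi = 40 + 1.8 * height + 5 * (cii - 1) + rng.normal(0, 8, 150)
            df = pd.DataFrame(
                {
                    "age_years": age,
                    # nonlinear allometry with noise, as in real stands
                    "dbh_cm": 0.8 * height**1.5 * np.exp(rng.normal(0, 0.1, 150)),
                    "height_m": height,
                    "cii_ordinal": cii,
                    "wi_ppm": wi,
                }
            )
            res = model_selection_aic(df)
            n_ok += res.selected == ("height", "cii")
        assert n_ok >= 20

    def test_pure_noise_favours_intercept_only(self):
        wins = 0
        for s in range(40):
            rng = np.random.default_rng(900 + s)
            df = pd.DataFrame(
                {
                    "age_years": rng.uniform(0, 100, 60),
                    "dbh_cm": rng.uniform(0, 50, 60),
                    "height_m": rng.uniform(0, 30, 60),
                    "cii_ordinal": rng.integers(1, 9, 60),
                    "wi_ppm": rng.normal(80, 8, 60),
                }
            )
            wins += model_selection_aic(df).selected == ()
        assert wins > 20  # majority of seeds

    def test_duplicate_predictors_tie_break_deterministic(self, rng):
        age = rng.uniform(0, 100, 60)
        df = pd.DataFrame(
            {
                "age_years": age,
                "dbh_cm": age,  # identical information → identical AIC
                "height_m": rng.normal(0, 1, 60),
                "cii_ordinal": rng.integers(1, 9, 60),
                "wi_ppm": 2.0 * age + rng.normal(0, 3, 60),
            }
        )
        res = model_selection_aic(df)
        assert res.selected == ("age",)  # smaller set, then lexicographic

    def test_selected_model_within_delta_of_minimum(self, rng):
        df = self_df = TestPredictorComparison.stand_df(rng, sd=5.0)
        res = model_selection_aic(df)
        aic_by_set = {c[0]: c[1] for c in res.candidates}
        assert aic_by_set[res.selected] <= res.min_aic_value + res.parsimony_delta


class TestMixedEffects:
    @staticmethod
    def multispecies_df(rng, species_offsets, slope=1.8, n=60, sd=3.0):
        frames = []
        for sp, off in species_offsets.items():
            height = rng.uniform(1, 30, n)
            frames.append(
                pd.DataFrame(
                    {
                        "species": sp,
                        "age_years": height * 3 + rng.normal(0, 5, n),
                        "dbh_cm": height * 3.3 + rng.normal(0, 2, n),
                        "height_m": height,
                        "cii_ordinal": np.clip(np.rint(1 + 7 * height / 30), 1, 8),
                        "wi_ppm": 40 + off + slope * height + rng.normal(0, sd, n),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_recovers_common_slope_with_species_variance(self, rng):
        df = self.multispecies_df(rng, {"A": -12.0, "B": 0.0, "C": 12.0})
        res = mixed_effects_all_species(df)
        est = res.loc["height", "estimate"]
        se = est / res.loc["height", "t_value"]
        assert abs(est - 1.8) < 3 * se  # injected common slope recovered
        assert res.attrs["random_intercept_var"] > 10.0
        assert res.loc["height", "p_value"] < 0.001

    def test_single_species_falls_back_to_ols(self, rng):
        df = self.multispecies_df(rng, {"A": 0.0})
        with pytest.warns(UserWarning, match="single species"):
            res = mixed_effects_all_species(df)
        assert res.attrs["model"] == "ols-fallback"

    def test_collinearity_can_flip_the_age_sign(self, rng):
        # age tracks height almost perfectly; marginal age trend is positive
        # but the partial age effect absorbs only the (negative) residual part
        height = rng.uniform(1, 30, 400)
        age = height * 3 + rng.normal(0, 0.5, 400)
        wi = 40 + 2.0 * height - 0.3 * (age - 3 * height) + rng.normal(0, 0.5, 400)
        df = pd.DataFrame(
            {
                "species": np.repeat(["A", "B"], 200),
                "age_years": age,
                "dbh_cm": 3.3 * height + rng.normal(0, 2, 400),
                "height_m": height,
                "cii_ordinal": np.clip(np.rint(1 + 7 * height / 30), 1, 8),
                "wi_ppm": wi,
            }
        )
        marginal = linear_trend(df["age_years"], df["wi_ppm"], "age")
        res = mixed_effects_all_species(df)
        assert marginal.slope > 0
        assert res.loc["age", "t_value"] < 0


class TestTimeTrend:
    @staticmethod
    def series_df(slopes, n=20, start=1800):
        frames = []
        for i, sl in enumerate(slopes):
            years = np.arange(start, start + n)
            frames.append(
                pd.DataFrame(
                    {
                        "tree_id": f"S{i}",
                        "calendar_year": years,
                        "wi_ppm": 60 + sl / 100.0 * (years - start),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_constant_series_zero_trend(self, constant_atmos):
        df = self.series_df([0.0, 0.0])
        res = time_trend(df, constant_atmos)
        assert res.trend.slope == pytest.approx(0.0, abs=1e-10)

    def test_weighted_mean_of_series_slopes(self, constant_atmos):
        df = self.series_df([20.0, 0.0])
        res = time_trend(df, constant_atmos, weights={"S0": 3.0, "S1": 1.0})
        assert res.trend.slope == pytest.approx(15.0, abs=1e-9)

    def test_equal_weights_coincide_with_unweighted(self, constant_atmos):
        rng = np.random.default_rng(6)
        df = self.series_df([20.0, 5.0, -3.0])
        df["wi_ppm"] += rng.normal(0, 1, len(df))
        unweighted = time_trend(df, constant_atmos)
        weighted = time_trend(df, constant_atmos, weights={"S0": 2.0, "S1": 2.0, "S2": 2.0})
        assert weighted.trend.slope == unweighted.trend.slope

    def test_d13c_series_converted_against_year_matched_atmosphere(self, preindustrial_span):
        from ringwue import invert_discrimination

        years = np.arange(1800, 1830)
        delta = np.full(30, 18.0)
        df = pd.DataFrame(
            {
                "tree_id": "T",
                "calendar_year": years,
                "d13c_permil": invert_discrimination(delta, -6.4),
            }
        )
        res = time_trend(df, preindustrial_span)
        assert res.trend.slope == pytest.approx(0.0, abs=1e-9)

    def test_short_series_rejected(self, constant_atmos):
        df = pd.DataFrame({"tree_id": "T", "calendar_year": [1800, 1801], "wi_ppm": [1.0, 2.0]})
        with pytest.raises(DegenerateDesignError, match="T"):
            time_trend(df, constant_atmos)

    def test_out_of_span_year_names_the_series(self):
        rec = AtmosphericRecord([1900, 1910], [296.0, 298.0], [-6.6, -6.7])
        df = pd.DataFrame(
            {"tree_id": "X1", "calendar_year": [1850, 1901, 1902], "d13c_permil": [-25.0] * 3}
        )
        with pytest.raises(LookupError, match="X1"):
            time_trend(df, rec)


class TestSplineSmoothSeries:
    def test_linear_series_unchanged(self):
        years = np.arange(1900, 1950)
        vals = 0.2 * (years - 1900) + 60.0
        assert np.max(np.abs(spline_smooth_series(years, vals) - vals)) < 1e-6

    def test_strong_smoothing_reduces_variance(self):
        rng = np.random.default_rng(7)
        years = np.arange(1900, 2000)
        vals = 60 + rng.normal(0, 5, 100)
        sm = spline_smooth_series(years, vals, lam=1e5)
        assert np.var(sm) < np.var(vals)

    def test_short_series_passthrough_with_warning(self):
        with pytest.warns(UserWarning):
            out = spline_smooth_series([1, 2, 3], [5.0, 6.0, 7.0])
        assert list(out) == [5.0, 6.0, 7.0]
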