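import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from phenomatch.intercompare import (
    bias_stats,
    classify_comparison,
    deming_fit,
    pair_transitions,
    pearson_r,
    perpendicular_distance,
    rms_distance,
    summary_table,
    wrap_doy,
)


def _pairs(x, y, direction="rising"):
    return pd.DataFrame({"phenocam_doy": np.asarray(x, float),
                         "modis_doy": np.asarray(y, float),
                         "direction": direction})


def _noisy_line(rng, n=20, slope=1.4, intercept=5.0, sd=8.0):
    x = rng.uniform(50.0, 150.0, n)
    y = intercept + slope * x + rng.normal(0.0, sd, n)
    return _pairs(x, y)


class TestPairing:
    def _cam(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "year", "direction",
                                           "doy", "threshold_fraction",
                                           "veg_type"])

    def _sat(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "year", "direction",
                                           "doy", "igbp"])

    def test_simple_pair_and_delta_sign(self):
        cam = self._cam([("a", 2010, "rising", 100.0, 0.1, "DB")])
        sat = self._sat([("a", 2010, "rising", 120.0, 4)])
        out = pair_transitions(cam, sat)
        assert len(out) == 1
        assert out["delta"].iloc[0] == pytest.approx(20.0)  # modis - phenocam

    def test_90_day_rule_is_strict(self):
        cam = self._cam([("a", 2010, "rising", 100.0, 0.1, "DB")])
        assert len(pair_transitions(cam, self._sat(
            [("a", 2010, "rising", 195.0, 4)]))) == 0  # delta = 95
        assert len(pair_transitions(cam, self._sat(
            [("a", 2010, "rising", 190.0, 4)]))) == 0  # delta = 90, strict <
        assert len(pair_transitions(cam, self._sat(
            [("a", 2010, "rising", 189.0, 4)]))) == 1

    def test_direction_mismatch_not_paired(self):
        cam = self._cam([("a", 2010, "rising", 100.0, 0.1, "DB")])
        sat = self._sat([("a", 2010, "falling", 105.0, 4)])
        assert len(pair_transitions(cam, sat)) == 0

    def test_greedy_one_to_one_matching(self):
        # two camera dates, one satellite date: only the nearest pairs
        cam = self._cam([("a", 2010, "rising", 100.0, 0.1, "DB"),
                         ("a", 2010, "rising", 140.0, 0.1, "DB")])
        sat = self._sat([("a", 2010, "rising", 105.0, 4)])
        out = pair_transitions(cam, sat)
        assert len(out) == 1
        assert out["phenocam_doy"].iloc[0] == 100.0

    def test_cross_year_pairing(self):
        cam = self._cam([("a", 2010, "rising", 360.0, 0.1, "DB")])
        sat = self._sat([("a", 2011, "rising", 10.0, 4)])
        out = pair_transitions(cam, sat)
        assert len(out) == 1
        assert out["delta"].iloc[0] == pytest.approx(15.0, abs=0.5)


class TestWrapDoy:
    @pytest.mark.parametrize("doy, direction, expected", [
        (300.0, "rising", -65.0),
        (50.0, "falling", 415.0),
        (120.0, "rising", 120.0),
        (120.0, "falling", 120.0),
        (271.0, "rising", -94.0),
    ])
    def test_wrap_rules(self, doy, direction, expected):
        assert wrap_doy(doy, direction) == expected

    def test_vectorised(self):
        out = wrap_doy(np.array([300.0, 120.0]), np.array(["rising", "rising"],
                                                          dtype=object))
        np.testing.assert_allclose(out, [-65.0, 120.0])


class TestClassification:
    @pytest.mark.parametrize("veg, igbp, expected", [
        ("DB", 4, "apples"),
        ("DB", 13, "oranges"),   # urban
        ("EN", 5, "apples"),
        ("AG", 12, "apples"),
        ("AG", 5, "oranges"),
        ("GR", 14, "apples"),
    ])
    def test_default_table(self, veg, igbp, expected):
        assert classify_comparison(veg, igbp) == expected

    def test_unknown_veg_type_warns_oranges(self):
        with pytest.warns(UserWarning, match="not in the apples table"):
            assert classify_comparison("WL", 11) == "oranges"


class TestBiasStats:
    def test_identical_dates(self):
        b = bias_stats(_pairs([100, 120], [100, 120]))
        assert b.bias_mean == 0.0 and b.bias_sd == 0.0

    def test_uniform_shift(self):
        b = bias_stats(_pairs([100, 120, 130], [105, 125, 135]))
        assert b.bias_mean == pytest.approx(5.0)
        assert b.bias_sd == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_set(self):
        b = bias_stats(_pairs([100, 120, 130], [110, 118, 140]))
        assert b.bias_mean == pytest.approx(6.0)
        assert b.bias_sd == pytest.approx(6.9282, abs=1e-4)

    def test_role_swap_negates_bias(self, rng):
        p = _noisy_line(rng)
        swapped = p.rename(columns={"phenocam_doy": "modis_doy",
                                    "modis_doy": "phenocam_doy"})
        assert bias_stats(swapped).bias_mean == pytest.approx(
            -bias_stats(p).bias_mean)


class TestPearson:
    def test_exact_lines(self):
        x = np.arange(10.0)
        assert pearson_r(_pairs(x, x + 7)) == pytest.approx(1.0)
        assert pearson_r(_pairs(x, -x), wrap=False) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([100.0, 120.0, 130.0])
        y = np.array([110.0, 118.0, 140.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert pearson_r(_pairs(x, y)) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(pearson_r(_pairs([100, 100, 100], [90, 100, 110])))


class TestDeming:
    def test_exact_line_through_origin(self):
        x = np.linspace(10, 100, 12)
        fit = deming_fit(_pairs(x, 2 * x), lam=1.0)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)

    def test_matches_perpendicular_distance_minimiser(self, rng):
        for _ in range(5):
            p = _noisy_line(rng)
            fit = deming_fit(p, lam=1.0, wrap=False)
            x = p["phenocam_doy"].to_numpy()
            y = p["modis_doy"].to_numpy()

            def total_d(params):
                b0, b1 = params
                return np.sum((y - (b0 + b1 * x)) ** 2 / (1 + b1 ** 2))

            res = minimize(total_d, [0.0, 1.0], method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14,
                                    "maxiter": 10000})
            assert fit.slope == pytest.approx(res.x[1], abs=1e-6)
            assert fit.intercept == pytest.approx(res.x[0], abs=1e-6)

    def test_swap_reciprocity(self, rng):
        p = _noisy_line(rng)
        swapped = p.rename(columns={"phenocam_doy": "modis_doy",
                                    "modis_doy": "phenocam_doy"})
        for lam in (0.25, 1.0, 4.0):
            fwd = deming_fit(p, lam=lam, wrap=False).slope
            rev = deming_fit(swapped, lam=1.0 / lam, wrap=False).slope
            assert fwd == pytest.approx(1.0 / rev, abs=1e-9)

    def test_lambda_limits_are_the_two_ols_slopes(self, rng):
        p = _noisy_line(rng)
        x = p["phenocam_doy"].to_numpy()
        y = p["modis_doy"].to_numpy()
        ols_yx = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        ols_xy_inv = np.var(y, ddof=1) / np.cov(x, y)[0, 1]
        # lambda -> 0: all error in y -> ordinary regression of y on x;
        # lambda -> inf: all error in x -> inverse regression
        assert deming_fit(p, lam=1e-9, wrap=False).slope == pytest.approx(
            ols_yx, rel=1e-6)
        assert deming_fit(p, lam=1e9, wrap=False).slope == pytest.approx(
            ols_xy_inv, rel=1e-6)

    def test_slope_monotone_in_lambda(self, rng):
        p = _noisy_line(rng)
        slopes = [deming_fit(p, lam=lam, wrap=False).slope
                  for lam in (0.25, 0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(slopes, slopes[1:]))

    def test_significance_conclusions_stable_across_lambda(self, rng):
        # well-separated fixture: slope clearly > 0 and clearly > 1
        x = rng.uniform(0, 100, 40)
        p = _pairs(x, 3.0 * x + rng.normal(0, 4, 40))
        for lam in (0.25, 0.5, 1.0, 2.0, 4.0):
            fit = deming_fit(p, lam=lam, wrap=False)
            assert fit.p_slope_zero < 0.05
            assert fit.p_slope_one < 0.05

    def test_rotation_invariance_of_rms_at_lambda_one(self, rng):
        p = _noisy_line(rng)
        x = p["phenocam_doy"].to_numpy()
        y = p["modis_doy"].to_numpy()
        base = deming_fit(p, lam=1.0, wrap=False).rms_distance
        theta = 0.3
        c, s = np.cos(theta), np.sin(theta)
        rotated = _pairs(c * x - s * y, s * x + c * y)
        assert deming_fit(rotated, lam=1.0, wrap=False).rms_distance == \
            pytest.approx(base, rel=1e-9)

    def test_degenerate_zero_covariance_flagged(self):
        p = _pairs([0.0, 0.0, 1.0, 1.0], [0.0, 1.0, 0.0, 1.0])
        with pytest.warns(UserWarning, match="degenerate"):
            fit = deming_fit(p, wrap=False)
        assert fit.degenerate

    def test_invalid_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            deming_fit(_noisy_line(rng), lam=0.0)


class TestDistances:
    def test_point_on_line_is_zero(self):
        assert perpendicular_distance((2.0, 7.0), b0=3.0, b1=2.0) == 0.0

    def test_zero_slope_reduces_to_squared_residual(self):
        assert perpendicular_distance((5.0, 3.0), b0=1.0, b1=0.0) == \
            pytest.approx(4.0)

    def test_unit_slope_geometry(self):
        d = perpendicular_distance((0.0, 1.0), b0=0.0, b1=1.0)
        assert d == pytest.approx(0.5, abs=1e-15)
        assert np.sqrt(d) == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-12)

    def test_sqrt_matches_geometric_point_line_distance(self, rng):
        for _ in range(100):
            b0, b1 = rng.normal(0, 3, 2)
            x, y = rng.normal(0, 50, 2)
            d = perpendicular_distance((x, y), b0, b1)
            geometric = abs(b1 * x - y + b0) / np.sqrt(b1 ** 2 + 1.0)
            assert np.sqrt(d) == pytest.approx(geometric, abs=1e-12)

    def test_rms_zero_on_line(self):
        x = np.array([0.0, 1.0, 2.0])
        assert rms_distance(_pairs(x, 2 * x + 1), b0=1.0, b1=2.0,
                            wrap=False) == 0.0

    def test_rms_single_offline_point(self):
        # three points, one with d = 2: sqrt(2 / (3-2)) = sqrt(2)
        p = _pairs([0.0, 1.0, 2.0], [0.0, 0.0, np.sqrt(2.0)])
        assert rms_distance(p, b0=0.0, b1=0.0, wrap=False) == \
            pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_rms_matches_direct_recomputation(self, rng):
        p = _noisy_line(rng)
        fit = deming_fit(p, wrap=False)
        x = p["phenocam_doy"].to_numpy()
        y = p["modis_doy"].to_numpy()
        d = (y - (fit.intercept + fit.slope * x)) ** 2 / (1 + fit.slope ** 2)
        assert fit.rms_distance == pytest.approx(
            np.sqrt(d.sum() / (len(x) - 2)), abs=1e-12)


class TestSummaryTable:
    def _cohort(self, rng, n=30):
        x = rng.uniform(80, 160, n)
        df = _pairs(x, x + rng.normal(0, 5, n))
        df["veg_type"] = "DB"
        df["igbp"] = np.where(np.arange(n) % 3 == 0, 13, 4)
        df["year"] = 2010
        return df

    def test_single_group_matches_individual_operations(self, rng):
        df = self._cohort(rng)
        df["igbp"] = 4
        main, full = summary_table(df, min_n=3)
        assert len(full) == 1
        row = full.iloc[0]
        fit = deming_fit(df)
        b = bias_stats(df)
        assert row["n"] == len(df)
        assert row["pearson_r"] == pytest.approx(fit.pearson_r)
        assert row["bias"] == pytest.approx(b.bias_mean)
        assert row["rms_distance"] == pytest.approx(fit.rms_distance)
        assert row["slope"] == pytest.approx(fit.slope)

    def test_apples_oranges_partition_sums_to_total(self, rng):
        df = self._cohort(rng)
        _, full = summary_table(df, min_n=3)
        assert full["n"].sum() == len(df)
        assert set(full["comparison"]) == {"apples", "oranges"}

    def test_min_n_filter(self, rng):
        df = self._cohort(rng, n=30)
        main, full = summary_table(df, min_n=25)
        assert len(full) == 2
        assert (main["n"] >= 25).all()

    def test_insignificant_slope_blanked(self, rng):
        x = rng.uniform(80, 160, 12)
        df = _pairs(x, rng.uniform(80, 160, 12))  # uncorrelated
        df["veg_type"] = "DB"
        df["igbp"] = 4
        _, full = summary_table(df, min_n=3)
        fit = deming_fit(df)
        if not fit.significant:
            assert np.isnan(full["slope"].iloc[0])
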