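"""Temperature exposure pairing, curve binning and percentile trends."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from recmort.config import ScenarioConfig, DEFAULT_SUBPERIODS
from recmort.pipeline import compute_thermo, standardize_panels
from recmort.synthetic import generate_scenario
from recmort.thermo import (
    TempMortalityCurve,
    apply_lag,
    fit_curve,
    map_percentiles,
    percentile_trends,
    percentiles,
    subperiod_divisors,
)


class TestApplyLag:
    def test_constant_temperature_yields_constant_exposure(self, year_dates):
        dates = year_dates(2001, 2001)
        out = apply_lag(np.ones(365), np.full(365, 4.5), dates)
        assert np.allclose(out["exposure"], 4.5)

    def test_summer_days_are_unlagged(self, year_dates):
        dates = year_dates(2001, 2001)
        temp = np.arange(365, dtype=float)
        out = apply_lag(np.ones(365), temp, dates)
        july = out[out.index.month == 7]
        doy = july.index.dayofyear.to_numpy()
        assert np.allclose(july["exposure"], temp[doy - 1])

    def test_winter_day_uses_seven_day_trailing_mean(self, year_dates):
        dates = year_dates(2001, 2001)
        temp = np.zeros(365)
        temp[8:15] = [0, 1, 2, 3, 4, 5, 6]  # Jan 9 .. Jan 15
        out = apply_lag(np.ones(365), temp, dates)
        jan15 = out.loc[pd.Timestamp("2001-01-15"), "exposure"]
        assert jan15 == pytest.approx(3.0)

    def test_incomplete_windows_dropped_only_in_lagged_months(self, year_dates):
        dates = year_dates(2001, 2001)
        out = apply_lag(np.ones(365), np.ones(365), dates)
        assert out.index[0] == pd.Timestamp("2001-01-07")  # first 6 days dropped
        dates_summer = pd.date_range("2001-06-01", "2001-06-30", freq="D")
        out2 = apply_lag(np.ones(30), np.ones(30), dates_summer)
        assert len(out2) == 30  # June start: nothing dropped

    def test_shift_scheme_uses_week_old_temperature(self, year_dates):
        dates = year_dates(2001, 2001)
        temp = np.arange(365, dtype=float)
        out = apply_lag(np.ones(365), temp, dates, scheme="shift")
        jan15 = out.loc[pd.Timestamp("2001-01-15"), "exposure"]
        assert jan15 == temp[14 - 7]

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            apply_lag(np.array([]), np.array([]), pd.DatetimeIndex([]))


class TestFitCurve:
    def make_pairs(self, x, y):
        idx = pd.date_range("2001-01-01", periods=len(x), freq="D")
        return pd.DataFrame({"exposure": x, "mortality": y}, index=idx)

    def test_constant_mortality_gives_flat_bins(self, rng):
        pairs = self.make_pairs(rng.uniform(0, 10, 200), np.full(200, 3.3))
        c = fit_curve(pairs, 5)
        assert np.allclose(c.bin_m, 3.3)

    def test_linear_relationship_survives_binning(self, rng):
        x = rng.uniform(-5, 25, 400)
        pairs = self.make_pairs(x, 2.0 * x + 1.0)
        c = fit_curve(pairs, 8)
        assert np.allclose(c.bin_m, 2.0 * c.bin_t + 1.0)

    def test_hand_grouped_example(self):
        pairs = self.make_pairs([0, 1, 9, 10], [10, 10, 30, 30])
        c = fit_curve(pairs, 2)
        assert np.allclose(c.bin_t, [0.5, 9.5])
        assert np.allclose(c.bin_m, [10.0, 30.0])
        assert list(c.bin_n) == [2, 2]

    def test_maximum_belongs_to_last_bin(self):
        pairs = self.make_pairs([0.0, 5.0, 10.0], [1.0, 2.0, 3.0])
        c = fit_curve(pairs, 2)
        assert c.bin_n[-1] == 2  # 5.0 and 10.0 both in the right-closed top bin

    def test_count_weighted_bin_mean_conserves_overall_mean(self, rng):
        x = rng.uniform(0, 1, 333)
        y = rng.normal(10, 2, 333)
        c = fit_curve(self.make_pairs(x, y), 7)
        pooled = (c.bin_m * c.bin_n).sum() / c.bin_n.sum()
        assert pooled == pytest.approx(y.mean(), rel=1e-12)

    def test_strictly_increasing_bin_temperatures(self, rng):
        x = rng.normal(0, 3, 500)
        c = fit_curve(self.make_pairs(x, x * 0 + 1), 20)
        assert (np.diff(c.bin_t) > 0).all()
        assert (c.bin_n >= 1).all()


class TestPercentiles:
    def test_uniform_grid(self):
        t = np.arange(101, dtype=float)
        assert np.allclose(percentiles(t), np.arange(101))

    def test_constant_series(self):
        assert np.allclose(percentiles(np.full(200, 2.0)), 2.0)

    def test_linear_interpolation_median(self):
        # four values padded to reach the minimum length
        t = np.array([0.0, 0.0, 10.0, 10.0])
        assert np.percentile(t, 50, method="linear") == 5.0
        tp = percentiles(np.tile(t, 30))
        assert tp[0] == 0.0 and tp[100] == 10.0

    def test_short_series_is_error(self):
        with pytest.raises(ValueError, match="101"):
            percentiles(np.arange(100))


class TestMapPercentiles:
    def curve(self, t, m):
        return TempMortalityCurve(bin_t=np.array(t, float), bin_m=np.array(m, float),
                                  bin_n=np.ones(len(t), int))

    def test_exact_at_nodes_and_linear_between(self):
        c = self.curve([0, 10], [10, 30])
        assert map_percentiles(c, np.array([0.0])) == 10.0
        assert map_percentiles(c, np.array([2.5])) == pytest.approx(15.0)

    def test_flat_curve_constant(self):
        c = self.curve([0, 5, 10], [7, 7, 7])
        assert np.allclose(map_percentiles(c, np.linspace(-3, 13, 9)), 7.0)

    def test_clamps_outside_node_range(self):
        c = self.curve([0, 10], [10, 30])
        out = map_percentiles(c, np.array([-5.0, 15.0]))
        assert np.allclose(out, [10.0, 30.0])

    def test_single_bin_curve_is_error(self):
        c = self.curve([1.0], [2.0])
        with pytest.raises(ValueError, match=">= 2 bins"):
            map_percentiles(c, np.array([1.0]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=3, max_size=30))
    def test_monotone_curve_maps_monotonically(self, qs):
        c = self.curve([0, 5, 10, 20], [1, 2, 8, 9])
        t = np.sort(np.asarray(qs))
        out = map_percentiles(c, t)
        assert (np.diff(out) >= -1e-12).all()


class TestPercentileTrends:
    def test_equal_profiles_give_zero_trends(self):
        m = np.arange(101.0)
        pre, post, delta = percentile_trends(m, m, m)
        assert np.allclose(pre, 0) and np.allclose(post, 0) and np.allclose(delta, 0)

    def test_hand_example_with_standard_divisors(self):
        pre, post, delta = percentile_trends([100.0], [92.0], [85.0])
        assert pre[0] == pytest.approx(-2.0)
        assert post[0] == pytest.approx(-2.0)
        assert delta[0] == pytest.approx(0.0)

    def test_time_reversal_symmetry_of_delta(self, rng):
        # delta is a (scaled) second difference of the subperiod profiles,
        # so reversing the subperiod order (divisors swapped accordingly)
        # leaves it unchanged while the two trends swap and negate
        m1, m2, m3 = rng.uniform(50, 150, (3, 101))
        pre, post, d = percentile_trends(m1, m2, m3, 4.0, 3.5)
        pre_sw, post_sw, d_sw = percentile_trends(m3, m2, m1, 3.5, 4.0)
        assert np.allclose(d_sw, d)
        assert np.allclose(pre_sw, -post)
        assert np.allclose(post_sw, -pre)

    def test_misaligned_profiles_error(self):
        with pytest.raises(ValueError, match="misaligned"):
            percentile_trends(np.ones(101), np.ones(100), np.ones(101))

    def test_standard_subperiod_divisors(self):
        assert subperiod_divisors((2000, 2003), (2004, 2007), (2008, 2010)) == (4.0, 3.5)


def test_null_scenario_delta_has_no_temperature_gradient():
    """With no GDP coupling and no temperature response, the trend change
    shows no systematic dependence on temperature percentile."""
    slopes = []
    p_grid = np.arange(101)
    for rep in range(50):
        cfg = ScenarioConfig(n_regions=2, pop_size=5e5, beta=0.0, seed=5000 + rep)
        panels = generate_scenario(cfg)
        daily, _, _ = standardize_panels(panels)
        _, _, ptrends = compute_thermo(panels, daily, DEFAULT_SUBPERIODS, n_bins=10)
        for region, grp in ptrends.groupby("region"):
            slopes.append(np.polyfit(p_grid, grp["delta"].to_numpy(), 1)[0])
    mean = np.mean(slopes)
    se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
    assert abs(mean) < 2.6 * se  # CI covers zero
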