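"""Weighted correlations and the within-bin Monte Carlo test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recmort.association import (
    CorrelationResult,
    RegionThermo,
    aggregate_to_countries,
    correlate_all,
    mc_significance,
    pearson_t_pvalue,
    weighted_pearson,
    weighted_spearman,
)
from recmort.config import ScenarioConfig, DEFAULT_WINDOWS
from recmort.pipeline import compute_trend_changes, region_weights, standardize_panels
from recmort.synthetic import generate_scenario
from recmort.thermo import TempMortalityCurve


def brute_force_weighted_pearson(x, y, w):
    """Independent explicit-loop oracle over weighted moments."""
    sw = sum(w)
    mx = sum(wi * xi for wi, xi in zip(w, x)) / sw
    my = sum(wi * yi for wi, yi in zip(w, y)) / sw
    cov = sum(wi * (xi - mx) * (yi - my) for wi, xi, yi in zip(w, x, y)) / sw
    vx = sum(wi * (xi - mx) ** 2 for wi, xi in zip(w, x)) / sw
    vy = sum(wi * (yi - my) ** 2 for wi, yi in zip(w, y)) / sw
    return cov / (vx * vy) ** 0.5


class TestWeightedPearson:
    def test_affine_relation_gives_unity(self, rng):
        x = rng.normal(size=10)
        w = rng.uniform(0.5, 3, size=10)
        assert weighted_pearson(x, 2 * x + 1, w) == pytest.approx(1.0)

    def test_equal_weights_reduce_to_unweighted(self, rng):
        x, y = rng.normal(size=(2, 25))
        r = weighted_pearson(x, y, np.ones(25))
        assert r == pytest.approx(stats.pearsonr(x, y).statistic, rel=1e-12)

    def test_matches_brute_force_oracle(self):
        x, y, w = [0.0, 1.0, 2.0], [0.0, 1.0, 0.0], [1.0, 1.0, 2.0]
        assert weighted_pearson(x, y, w) == pytest.approx(
            brute_force_weighted_pearson(x, y, w), rel=1e-14
        )

    def test_weight_scale_invariance(self, rng):
        x, y = rng.normal(size=(2, 12))
        w = rng.uniform(1, 5, size=12)
        # power-of-two scaling is bit-exact; general scaling to 1e-12
        assert weighted_pearson(x, y, w) == weighted_pearson(x, y, 1024.0 * w)
        assert weighted_pearson(x, y, 17.3 * w) == pytest.approx(
            weighted_pearson(x, y, w), rel=1e-12
        )

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            weighted_pearson([1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [1.0, 1.0, 1.0])

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            weighted_pearson([1, 2], [1, 2], [1, 1])
        with pytest.raises(ValueError, match="positive"):
            weighted_pearson([1, 2, 3], [1, 2, 4], [1, 0, 1])


class TestWeightedSpearman:
    def test_monotone_transform_gives_unity(self, rng):
        x = rng.normal(size=15)
        w = rng.uniform(0.5, 2, size=15)
        assert weighted_spearman(x, np.exp(x), w) == pytest.approx(1.0)

    def test_equal_weights_match_textbook_spearman(self, rng):
        x, y = rng.normal(size=(2, 30))  # continuous: no ties
        rho = weighted_spearman(x, y, np.ones(30))
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic, rel=1e-12)

    def test_ties_use_mid_ranks(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [4.0, 5.0, 6.0, 7.0]
        w = [1.0, 1.0, 1.0, 1.0]
        rx = [1.0, 2.5, 2.5, 4.0]  # explicit mid-rank oracle
        ry = [1.0, 2.0, 3.0, 4.0]
        assert weighted_spearman(x, y, w) == pytest.approx(
            brute_force_weighted_pearson(rx, ry, w), rel=1e-14
        )


def test_t_approximation_matches_scipy(rng):
    x, y = rng.normal(size=(2, 20))
    res = stats.pearsonr(x, y)
    assert pearson_t_pvalue(res.statistic, 20) == pytest.approx(res.pvalue, rel=1e-9)


def test_correlation_result_invariants():
    with pytest.raises(ValueError, match="out of"):
        CorrelationResult(scope="regions", percentile=0, r=1.5, rho=0.0, n=5)
    with pytest.raises(ValueError, match="n must be"):
        CorrelationResult(scope="regions", percentile=0, r=0.5, rho=0.0, n=2)
    with pytest.raises(ValueError, match="out of order"):
        CorrelationResult(scope="regions", percentile=0, r=0.0, rho=0.0, n=5,
                          ci=(0.5, -0.5))


def _toy_region(region, rng, loc, gdp_delta, noise=1.0):
    """A region with three 3-bin curves built from synthetic day values."""
    curves = {}
    for k, sub in enumerate(("P1", "P2", "P3")):
        vals = [rng.normal(loc + k, noise, size=40) for _ in range(3)]
        curves[sub] = TempMortalityCurve(
            region=region, subperiod=sub,
            bin_t=np.array([0.0, 5.0, 10.0]),
            bin_m=np.array([v.mean() for v in vals]),
            bin_n=np.array([40, 40, 40]),
            bin_values=vals,
        )
    t_p = np.linspace(0, 10, 101)
    return RegionThermo(region=region, curves=curves, t_p=t_p,
                        gdp_delta=gdp_delta, weight=1.0)


class TestMonteCarlo:
    def test_same_seed_reproduces_ci_and_p(self, rng):
        regs = [_toy_region(f"R{i}", rng, 10.0 + i, 0.01 * i) for i in range(5)]
        a = mc_significance(regs, [25, 50], n_sims=200, seed=4)
        b = mc_significance(regs, [25, 50], n_sims=200, seed=4)
        for ra, rb in zip(a, b):
            assert ra.ci == rb.ci and ra.p_mc == rb.p_mc

    def test_noise_free_bins_collapse_the_interval(self, rng):
        regs = []
        for i in range(5):
            reg = _toy_region(f"R{i}", rng, 10.0, 0.01 * (i - 2))
            for sub, c in reg.curves.items():
                c.bin_values = [np.full(40, m) for m in c.bin_m]  # identical days
            regs.append(reg)
        res = mc_significance(regs, [50], n_sims=200, seed=1)[0]
        assert res.ci[1] - res.ci[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_day_bin_warns(self, rng):
        reg = _toy_region("R0", rng, 10.0, 0.0)
        reg.curves["P1"].bin_values[0] = np.array([5.0])
        regs = [reg] + [_toy_region(f"R{i}", rng, 10.0, 0.01 * i) for i in (1, 2)]
        with pytest.warns(UserWarning, match="single day"):
            mc_significance(regs, [50], n_sims=100, seed=0)

    def test_doubling_sims_barely_moves_p(self, rng):
        regs = [_toy_region(f"R{i}", rng, 10.0 + 0.2 * i, 0.01 * i, noise=3.0)
                for i in range(6)]
        p1 = mc_significance(regs, [50], n_sims=500, seed=2)[0].p_mc
        p2 = mc_significance(regs, [50], n_sims=1000, seed=3)[0].p_mc
        assert abs(p1 - p2) < 3 * np.sqrt(p1 * (1 - p1) / 500) + 1 / 500


class TestCorrelateAll:
    def test_strongly_coupled_scenario_saturates(self, rng):
        # near-deterministic coupling: r at every percentile -> 1
        units = [f"R{i}" for i in range(6)]
        g = pd.Series(np.linspace(-0.05, -0.01, 6), index=units)
        pdeltas = pd.DataFrame(
            {p: g.to_numpy() * 2 + rng.normal(0, 1e-9, 6) for p in range(0, 101, 25)},
            index=units,
        )
        w = pd.Series(1.0, index=units)
        out = correlate_all(g, g * 1.5, pdeltas, w)
        assert all(res.r > 0.999 for res in out)

    def test_permuting_labels_centres_r_at_zero(self, rng):
        units = [f"R{i}" for i in range(10)]
        g = pd.Series(rng.normal(size=10), index=units)
        y = pd.Series(rng.normal(size=10), index=units)
        w = pd.Series(rng.uniform(1, 2, size=10), index=units)
        rs = []
        for _ in range(500):
            perm = rng.permutation(10)
            rs.append(weighted_pearson(g.to_numpy(), y.to_numpy()[perm], w.to_numpy()))
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs)) + 0.02

    def test_fewer_than_three_units_is_error(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="matched units"):
            correlate_all(s, s, None, s)


def test_null_scenario_mean_absolute_r_is_small():
    """beta=0: across replicates, mean |r| stays below 2/sqrt(n_regions)."""
    n_regions = 6
    rs = []
    for rep in range(50):
        cfg = ScenarioConfig(n_regions=n_regions, pop_size=3e5, beta=0.0,
                             seed=7000 + rep)
        panels = generate_scenario(cfg)
        _, annual, _ = standardize_panels(panels)
        tr = compute_trend_changes(panels, annual, DEFAULT_WINDOWS)
        g = tr.query("variable=='gdp'").set_index("region")["delta"]
        m = tr.query("variable=='mortality'").set_index("region")["delta"]
        w = region_weights(panels)
        rs.append(weighted_pearson(g, m[g.index], w[g.index]))
    assert np.mean(np.abs(rs)) < 2 / np.sqrt(n_regions)


def test_country_aggregation_is_population_weighted():
    rates = pd.DataFrame(
        {"R0": [10.0, 8.0], "R1": [20.0, 16.0], "R2": [5.0, 5.0]},
        index=[2000, 2001],
    )
    pops = pd.Series({"R0": 1e6, "R1": 3e6, "R2": 2e6})
    mapping = {"R0": "A", "R1": "A", "R2": "B"}
    agg, cpops = aggregate_to_countries(rates, pops, mapping)
    assert agg.loc[2000, "A"] == pytest.approx((10 * 1 + 20 * 3) / 4)
    assert agg.loc[2001, "B"] == pytest.approx(5.0)
    assert cpops["A"] == 4e6
    with pytest.raises(ValueError, match="without a country"):
        aggregate_to_countries(rates, pops, {"R0": "A"})
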