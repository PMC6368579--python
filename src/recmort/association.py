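"""Population-weighted association between GDP and mortality trend changes.

Across regions (or countries), the change in the GDP trend is
correlated with the change in the mortality trend, each unit weighted
by the square root of its population.  Correlations are computed at the
annual level and per temperature percentile.

Significance of the temperature-resolved correlations comes from a
Monte Carlo scheme: within every equal-width temperature bin of every
region x subperiod curve, the daily mortality values are resampled with
replacement; bin means, percentile profiles, trend changes and the
weighted Pearson correlation are recomputed per simulation.  The 95%
confidence interval is the [2.5, 97.5] percentile range of the
simulated correlations and the two-sided p-value is

    p = max(1/n_sims, 2 * min(frac(r* <= 0), frac(r* >= 0))),

i.e. the simulated correlation distribution must keep clear of zero.
A classical t-approximation p-value is reported alongside for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .thermo import TempMortalityCurve, map_percentiles

__all__ = [
    "CorrelationResult",
    "RegionThermo",
    "weighted_pearson",
    "weighted_spearman",
    "pearson_t_pvalue",
    "mc_significance",
    "delta_confidence_band",
    "correlate_all",
    "aggregate_to_countries",
]


def _check_xyw(x, y, w):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must share length")
    if len(x) < 3:
        raise ValueError("need at least 3 units")
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    return x, y, w


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation with w-weighted means and moments."""
    x, y, w = _check_xyw(x, y, w)
    wn = w / w.sum()
    dx = x - wn @ x
    dy = y - wn @ y
    vx = wn @ (dx * dx)
    vy = wn @ (dy * dy)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance")
    return float((wn @ (dx * dy)) / np.sqrt(vx * vy))


def weighted_spearman(x, y, w) -> float:
    """Weighted Spearman: weighted Pearson of unweighted mid-ranks.

    Ties receive average ranks; the weights enter only through the
    correlation of the ranks, one of several weighted-Spearman
    conventions.
    """
    x, y, w = _check_xyw(x, y, w)
    return weighted_pearson(stats.rankdata(x), stats.rankdata(y), w)


def pearson_t_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of r under the classical t-approximation."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class CorrelationResult:
    """Weighted correlation across units at one percentile (or annual)."""

    scope: str
    percentile: int | str
    r: float
    rho: float
    n: int
    ci: tuple[float, float] | None = None
    p_mc: float | None = None
    p_t: float | None = None

    def __post_init__(self) -> None:
        tol = 1e-9
        if not (-1.0 - tol <= self.r <= 1.0 + tol):
            raise ValueError(f"r out of [-1, 1]: {self.r}")
        if not (-1.0 - tol <= self.rho <= 1.0 + tol):
            raise ValueError(f"rho out of [-1, 1]: {self.rho}")
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise ValueError("CI bounds out of order")


@dataclass
class RegionThermo:
    """One region's inputs to the temperature-resolved correlation."""

    region: str
    curves: dict[str, TempMortalityCurve]  # keys P1, P2, P3
    t_p: np.ndarray  # full-period percentile temperatures, p = 0..100
    gdp_delta: float
    weight: float
    excluded: frozenset = field(default_factory=frozenset)


def _interp_design(bin_t: np.ndarray, t_sel: np.ndarray):
    """Fixed piecewise-linear interpolation design onto curve nodes.

    Returns (j, w) with ``value = (1 - w) * B[j] + w * B[j + 1]``,
    clamped outside the node range.  Because the Monte Carlo resamples
    mortality only, the temperature nodes — and hence this design — are
    constant across simulations.
    """
    nb = len(bin_t)
    j = np.clip(np.searchsorted(bin_t, t_sel, side="right") - 1, 0, nb - 2)
    denom = bin_t[j + 1] - bin_t[j]
    w = np.clip((t_sel - bin_t[j]) / denom, 0.0, 1.0)
    return j, w


def _bootstrap_bin_means(
    curve: TempMortalityCurve, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    """Within-bin day-level bootstrap of the bin mean mortalities."""
    out = np.empty((curve.n_bins, n_sims))
    for b, vals in enumerate(curve.bin_values):
        n = len(vals)
        if n == 1:
            warnings.warn(
                f"bin with a single day in {curve.region}/{curve.subperiod}; "
                "its resampled mean is degenerate",
                stacklevel=3,
            )
            out[b] = vals[0]
            continue
        idx = rng.integers(0, n, size=(n_sims, n))
        out[b] = vals[idx].mean(axis=1)
    return out


def _weighted_pearson_sims(x: np.ndarray, ysims: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson of fixed x against each column of ysims."""
    wn = w / w.sum()
    dx = x - wn @ x
    dy = ysims - (wn @ ysims)[None, :]
    vx = wn @ (dx * dx)
    vy = wn @ (dy * dy)
    cov = (wn * dx) @ dy
    with np.errstate(invalid="ignore", divide="ignore"):
        return cov / np.sqrt(vx * vy)


def _profile_deltas(
    reg: RegionThermo,
    t_sel: np.ndarray,
    div_pre: float,
    div_post: float,
    n_sims: int | None,
    rng: np.random.Generator | None,
):
    """Observed (and optionally simulated) trend-change profile at t_sel."""
    m_obs, m_sim = {}, {}
    for sub in ("P1", "P2", "P3"):
        curve = reg.curves[sub]
        if curve.n_bins < 2:
            raise ValueError(f"{reg.region}/{sub}: curve has fewer than 2 bins")
        m_obs[sub] = map_percentiles(curve, t_sel)
        if n_sims is not None:
            j, w = _interp_design(curve.bin_t, t_sel)
            b = _bootstrap_bin_means(curve, n_sims, rng)
            m_sim[sub] = (1.0 - w)[:, None] * b[j] + w[:, None] * b[j + 1]
    delta_obs = (m_obs["P3"] - m_obs["P2"]) / div_post - (
        m_obs["P2"] - m_obs["P1"]
    ) / div_pre
    if n_sims is None:
        return delta_obs, None
    delta_sim = (m_sim["P3"] - m_sim["P2"]) / div_post - (
        m_sim["P2"] - m_sim["P1"]
    ) / div_pre
    return delta_obs, delta_sim


def mc_significance(
    regions: list[RegionThermo],
    percentiles_sel,
    n_sims: int = 1000,
    seed: int = 0,
    div_pre: float = 4.0,
    div_post: float = 3.5,
    scope: str = "regions",
) -> list[CorrelationResult]:
    """Monte Carlo CI and p-value of the weighted Pearson per percentile.

    ``percentiles_sel`` are integer percentiles (0..100) at which the
    correlation between the GDP trend change and the temperature-
    resolved mortality trend change is tested.  Deterministic for a
    fixed seed.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    if len(regions) < 3:
        raise ValueError("need at least 3 units")
    p_sel = np.asarray(list(percentiles_sel), dtype=int)
    rng = np.random.default_rng(seed)

    x = np.array([reg.gdp_delta for reg in regions])
    w = np.array([reg.weight for reg in regions])
    d_obs = np.empty((len(regions), len(p_sel)))
    d_sim = np.empty((len(regions), len(p_sel), n_sims))
    for i, reg in enumerate(regions):
        t_sel = reg.t_p[p_sel]
        d_obs[i], d_sim[i] = _profile_deltas(reg, t_sel, div_pre, div_post, n_sims, rng)

    results = []
    for k, p in enumerate(p_sel):
        r_obs = weighted_pearson(x, d_obs[:, k], w)
        rho_obs = weighted_spearman(x, d_obs[:, k], w)
        r_sim = _weighted_pearson_sims(x, d_sim[:, k, :], w)
        r_sim = r_sim[np.isfinite(r_sim)]
        if len(r_sim) == 0:
            # fully degenerate (noise-free) input: all simulations equal
            ci = (r_obs, r_obs)
            p_mc = 1.0 / n_sims
        else:
            ci = tuple(np.percentile(r_sim, [2.5, 97.5]))
            frac_le = (r_sim <= 0).mean()
            frac_ge = (r_sim >= 0).mean()
            p_mc = max(1.0 / n_sims, min(1.0, 2.0 * min(frac_le, frac_ge)))
        results.append(
            CorrelationResult(
                scope=scope, percentile=int(p), r=r_obs, rho=rho_obs,
                n=len(regions), ci=(float(ci[0]), float(ci[1])), p_mc=float(p_mc),
                p_t=pearson_t_pvalue(r_obs, len(regions)),
            )
        )
    return results


def delta_confidence_band(
    reg: RegionThermo,
    n_sims: int = 1000,
    seed: int = 0,
    div_pre: float = 4.0,
    div_post: float = 3.5,
) -> pd.DataFrame:
    """95% Monte Carlo band of one region's trend-change curve.

    Resamples within-bin daily mortality and propagates to the
    percentile-resolved trend change over the full 0..100 grid; the
    dashed-curve band around a region's solid trend-change curve.
    """
    rng = np.random.default_rng(seed)
    t_all = reg.t_p[np.arange(101)]
    d_obs, d_sim = _profile_deltas(reg, t_all, div_pre, div_post, n_sims, rng)
    lo, hi = np.percentile(d_sim, [2.5, 97.5], axis=1)
    return pd.DataFrame(
        {"p": np.arange(101), "delta": d_obs, "ci_lo": lo, "ci_hi": hi}
    ).set_index("p")


def correlate_all(
    gdp_delta: pd.Series,
    mort_delta: pd.Series,
    percentile_deltas: pd.DataFrame | None,
    weights: pd.Series,
    scope: str = "regions",
) -> list[CorrelationResult]:
    """Annual and per-percentile weighted correlations across units.

    ``gdp_delta`` and ``mort_delta`` hold the annual trend changes per
    unit; ``percentile_deltas`` (optional) is indexed by unit with one
    column per integer percentile.  Units are aligned by index; fewer
    than 3 shared units is an error.  p-values here are the classical
    t-approximation; Monte Carlo intervals come from
    :func:`mc_significance`.
    """
    units = gdp_delta.index.intersection(mort_delta.index).intersection(weights.index)
    if percentile_deltas is not None:
        units = units.intersection(percentile_deltas.index)
    if len(units) < 3:
        raise ValueError(f"only {len(units)} matched units; need >= 3")
    x = gdp_delta.loc[units].to_numpy()
    w = weights.loc[units].to_numpy()
    y = mort_delta.loc[units].to_numpy()
    out = [
        CorrelationResult(
            scope=scope, percentile="annual",
            r=weighted_pearson(x, y, w), rho=weighted_spearman(x, y, w),
            n=len(units), p_t=pearson_t_pvalue(weighted_pearson(x, y, w), len(units)),
        )
    ]
    if percentile_deltas is not None:
        for p in percentile_deltas.columns:
            yp = percentile_deltas.loc[units, p].to_numpy()
            r = weighted_pearson(x, yp, w)
            out.append(
                CorrelationResult(
                    scope=scope, percentile=int(p), r=r,
                    rho=weighted_spearman(x, yp, w), n=len(units),
                    p_t=pearson_t_pvalue(r, len(units)),
                )
            )
    return out


def aggregate_to_countries(
    annual_rates: pd.DataFrame,
    populations: pd.Series,
    mapping: dict[str, str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Population-weighted country aggregation of regional annual rates.

    ``annual_rates`` is years x regions (standardized rates);
    ``populations`` gives each region's population; ``mapping`` sends a
    region id to its country.  Returns (years x countries rates,
    country populations).  Country GDP series, when available, are
    provided directly rather than aggregated here.
    """
    missing = [r for r in annual_rates.columns if r not in mapping]
    if missing:
        raise ValueError(f"regions without a country mapping: {missing}")
    countries = sorted(set(mapping[r] for r in annual_rates.columns))
    rates = {}
    pops = {}
    for c in countries:
        members = [r for r in annual_rates.columns if mapping[r] == c]
        wpop = populations.loc[members]
        rates[c] = (annual_rates[members] * wpop).sum(axis=1) / wpop.sum()
        pops[c] = float(wpop.sum())
    return pd.DataFrame(rates), pd.Series(pops)
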