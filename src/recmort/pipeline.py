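"""End-to-end analysis pipeline.

Stages: (simulate | read) -> standardize -> annual trends -> temperature
curves and percentile trends -> weighted correlations with Monte Carlo
significance.  Each stage is a plain function over panels and frames so
it can be used directly; :func:`run_pipeline` chains them, writes the
output CSVs (stamped with the configuration hash and seed) and logs
stage timings and row counts.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import demography, thermo, trend_stats
from .association import RegionThermo, correlate_all, mc_significance
from .config import PipelineConfig
from .io import read_panels, write_csv, write_panels
from .synthetic import SyntheticPanel, generate_scenario

log = logging.getLogger("recmort")

__all__ = [
    "standardize_panels",
    "compute_trend_changes",
    "compute_thermo",
    "compute_correlations",
    "run_pipeline",
]


def standardize_panels(panels: list[SyntheticPanel], ref_year: int = 2005):
    """Daily and annual standardized mortality for every panel.

    Returns ``(daily, annual, ref)`` where ``daily`` is a date x region
    frame of deaths per million, ``annual`` a year x region frame of
    deaths per thousand (excluded region-years absent, i.e. NaN), and
    ``ref`` the pooled reference population.
    """
    ref = demography.ReferencePopulation.from_panels(panels, ref_year=ref_year)
    daily = {}
    annual = {}
    for p in panels:
        pop_daily = demography.interpolate_daily_population(
            p.pop_years, p.populations, p.dates
        )
        rate = demography.standardize_daily(p.deaths, pop_daily, ref)
        daily[p.region] = pd.Series(rate, index=p.dates)
        annual[p.region] = demography.annualize(rate, p.dates, p.excluded_years)
    return pd.DataFrame(daily), pd.DataFrame(annual), ref


def compute_trend_changes(
    panels: list[SyntheticPanel],
    annual: pd.DataFrame,
    windows: dict[str, tuple[int, int]],
) -> pd.DataFrame:
    """Annual trend-change records for GDP and mortality per region."""
    rows = []
    for p in panels:
        gdp = pd.Series(np.asarray(p.gdp, dtype=float), index=p.gdp_years)
        for variable, series, excl in (
            ("gdp", gdp, frozenset()),
            ("mortality", annual[p.region].dropna(), p.excluded_years),
        ):
            rec = trend_stats.trend_change(
                series, pre=windows["pre"], post=windows["post"],
                excluded=excl, region=p.region, variable=variable,
            )
            rows.append({
                "region": p.region, "variable": variable,
                "t_pre": rec.t_pre, "t_post": rec.t_post, "delta": rec.delta,
            })
    return pd.DataFrame(rows)


def compute_thermo(
    panels: list[SyntheticPanel],
    daily: pd.DataFrame,
    subperiods: dict[str, tuple[int, int]],
    n_bins: int = 20,
    lag_scheme: str = "window",
) -> tuple[dict[str, dict[str, thermo.TempMortalityCurve]], dict[str, np.ndarray], pd.DataFrame]:
    """Per-region binned curves, percentile temperatures and trend deltas.

    Returns ``(curves, t_p, ptrends)``: curves keyed region->subperiod,
    full-period percentile temperatures per region, and a long frame
    with one row per region and percentile carrying the mapped
    mortalities, the pre/post trends and their change.
    """
    div_pre, div_post = thermo.subperiod_divisors(
        subperiods["P1"], subperiods["P2"], subperiods["P3"]
    )
    curves: dict[str, dict[str, thermo.TempMortalityCurve]] = {}
    t_p: dict[str, np.ndarray] = {}
    rows = []
    for p in panels:
        mort = daily[p.region].to_numpy()
        pairs = thermo.apply_lag(mort, p.temperature, p.dates, scheme=lag_scheme)
        if p.excluded_years:
            # temperature remains valid in excluded years (lag windows may
            # reach into them); only mortality days there are dropped
            pairs = pairs[~pairs.index.year.isin(sorted(p.excluded_years))]
        t_p[p.region] = thermo.percentiles(p.temperature)
        curves[p.region] = {}
        profiles = {}
        for sub, (y1, y2) in subperiods.items():
            in_sub = (pairs.index.year >= y1) & (pairs.index.year <= y2)
            curve = thermo.fit_curve(
                pairs.loc[in_sub], n_bins, region=p.region, subperiod=sub
            )
            curves[p.region][sub] = curve
            profiles[sub] = thermo.map_percentiles(curve, t_p[p.region])
        pre, post, delta = thermo.percentile_trends(
            profiles["P1"], profiles["P2"], profiles["P3"], div_pre, div_post
        )
        for q in range(101):
            rows.append({
                "region": p.region, "p": q, "t_p": t_p[p.region][q],
                "m_p1": profiles["P1"][q], "m_p2": profiles["P2"][q],
                "m_p3": profiles["P3"][q], "trend_pre": pre[q],
                "trend_post": post[q], "delta": delta[q],
            })
    return curves, t_p, pd.DataFrame(rows)


def region_weights(panels: list[SyntheticPanel], ref_year: int = 2005) -> pd.Series:
    """Square-root-of-population weights at the reference year."""
    out = {}
    for p in panels:
        idx = np.flatnonzero(np.asarray(p.pop_years) == ref_year)[0]
        out[p.region] = float(np.sqrt(p.populations[:, idx].sum()))
    return pd.Series(out)


def compute_correlations(
    panels: list[SyntheticPanel],
    trends: pd.DataFrame,
    ptrends: pd.DataFrame,
    curves,
    t_p,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Weighted correlations (annual and per percentile) plus MC tests."""
    weights = region_weights(panels)
    gdp_delta = trends.query("variable == 'gdp'").set_index("region")["delta"]
    mort_delta = trends.query("variable == 'mortality'").set_index("region")["delta"]
    pdeltas = ptrends.pivot(index="region", columns="p", values="delta")
    results = correlate_all(gdp_delta, mort_delta, pdeltas, weights, scope="regions")
    rows = [
        {
            "scope": res.scope, "percentile": res.percentile, "r": res.r,
            "rho": res.rho, "ci_lo": np.nan, "ci_hi": np.nan,
            "p": np.nan, "p_t": res.p_t, "n": res.n,
        }
        for res in results
    ]
    if cfg.run_mc:
        div_pre, div_post = thermo.subperiod_divisors(
            cfg.subperiods["P1"], cfg.subperiods["P2"], cfg.subperiods["P3"]
        )
        regs = [
            RegionThermo(
                region=p.region, curves=curves[p.region], t_p=t_p[p.region],
                gdp_delta=float(gdp_delta[p.region]),
                weight=float(weights[p.region]),
            )
            for p in panels
        ]
        mc = mc_significance(
            regs, cfg.percentile_subset, n_sims=cfg.n_sims, seed=cfg.seed,
            div_pre=div_pre, div_post=div_post,
        )
        for res in mc:
            rows.append({
                "scope": res.scope, "percentile": res.percentile, "r": res.r,
                "rho": res.rho, "ci_lo": res.ci[0], "ci_hi": res.ci[1],
                "p": res.p_mc, "p_t": res.p_t, "n": res.n,
            })
    return pd.DataFrame(rows)


def _timed(label: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    out = fn(*args, **kwargs)
    log.info("stage %-12s %6.2f s", label, time.perf_counter() - t0)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write all output CSVs under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    stamp = f"config={cfg.digest()} seed={cfg.seed}"

    if cfg.scenario is not None:
        panels = _timed("simulate", generate_scenario, cfg.scenario)
        _timed("write-inputs", write_panels, panels, out / "inputs", stamp)
    else:
        panels = _timed("read", read_panels, cfg.data_dir)
    log.info("%d regions, %d days", len(panels), len(panels[0].dates))

    daily, annual, ref = _timed("standardize", standardize_panels, panels)
    daily_long = daily.stack().rename("rate_per_million").reset_index()
    daily_long.columns = ["date", "region", "rate_per_million"]
    daily_long["date"] = daily_long["date"].dt.strftime("%Y-%m-%d")
    write_csv(daily_long[["region", "date", "rate_per_million"]],
              out / "standardized_daily.csv", stamp)
    annual_long = annual.stack().rename("rate_per_thousand").reset_index()
    annual_long.columns = ["year", "region", "rate_per_thousand"]
    write_csv(annual_long[["region", "year", "rate_per_thousand"]],
              out / "standardized_annual.csv", stamp)

    trends = _timed("trends", compute_trend_changes, panels, annual, cfg.trend_windows)
    write_csv(trends, out / "trend_changes.csv", stamp)

    curves, t_p, ptrends = _timed(
        "curves", compute_thermo, panels, daily, cfg.subperiods,
        cfg.n_bins, cfg.lag_scheme,
    )
    curve_rows = [
        {"region": r, "subperiod": sub, "bin_t": c.bin_t[b],
         "bin_m": c.bin_m[b], "n_days": int(c.bin_n[b])}
        for r, subs in curves.items()
        for sub, c in subs.items()
        for b in range(c.n_bins)
    ]
    write_csv(pd.DataFrame(curve_rows), out / "curves.csv", stamp)
    write_csv(ptrends, out / "percentile_trends.csv", stamp)

    correlations = _timed(
        "correlate", compute_correlations, panels, trends, ptrends, curves, t_p, cfg
    )
    write_csv(correlations, out / "correlations.csv", stamp)

    return {
        "panels": panels, "daily": daily, "annual": annual, "ref": ref,
        "trends": trends, "curves": curves, "t_p": t_p, "ptrends": ptrends,
        "correlations": correlations,
    }
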