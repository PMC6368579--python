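"""Synthetic regional panel generator.

Emulates the data layout of a European regional mortality study around
the 2008 recession: per region, daily all-cause death counts by sex and
5-year age group, annual year-end populations by the same strata, a
daily mean temperature series, and an annual per-capita GDP series with
distinct expansion (through 2007) and recession (2008 on) growth rates.

The statistical structure is the one the downstream analysis assumes:

* death counts are Poisson around a rate surface
  ``pop_g(d) * rate_g * trend(d) * season(d) / 365.25``,
* the log-trend slope is ``m_exp`` before the break year and
  ``m_exp + beta * (g_rec - g_exp)`` from the break year on, so a
  positive coupling ``beta`` turns a larger GDP slowdown into a stronger
  mortality decline (procyclical mortality),
* seasonality is a pure winter-excess harmonic; by default mortality
  does not respond to temperature beyond it, which gives the analysis a
  clean null for the temperature-resolved statistics.

Every region draws from its own RNG substream derived from the master
seed, so outputs are reproducible and adding regions never perturbs
existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .demography import interpolate_daily_population
from .strata import STRATA

__all__ = [
    "RegionParams",
    "SyntheticPanel",
    "region_params",
    "annual_populations",
    "generate_temperature",
    "generate_gdp",
    "generate_deaths",
    "generate_scenario",
]

_DAYS_PER_YEAR = 365.25


def _rng(cfg: ScenarioConfig, region: int, stream: int) -> np.random.Generator:
    """Independent substream for (region, stream) under the master seed.

    Streams: 0 = regional parameters, 1 = temperature, 2 = deaths.
    Keyed by region index only, so the substream does not depend on
    ``n_regions``.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(region, stream))
    )


@dataclass(frozen=True)
class RegionParams:
    """Realized per-region scalars of the scenario."""

    g_exp: float
    g_rec: float
    m_exp: float
    gdp_start: float


def region_params(cfg: ScenarioConfig, region: int) -> RegionParams:
    """Resolve (drawing if unspecified) the scalars for one region."""
    rng = _rng(cfg, region, 0)
    # Draws happen in a fixed order so that fixing one field never
    # shifts the others' values.
    u = rng.uniform(size=3)
    if cfg.g_exp is None:
        g_exp = 0.007 + u[0] * (0.052 - 0.007)
    else:
        g_exp = cfg.g_exp if np.isscalar(cfg.g_exp) else cfg.g_exp[region]
    if cfg.g_rec is None:
        g_rec = g_exp + (-0.073 + u[1] * (-0.012 - -0.073))
    else:
        g_rec = cfg.g_rec if np.isscalar(cfg.g_rec) else cfg.g_rec[region]
    m_exp = cfg.m_exp if np.isscalar(cfg.m_exp) else cfg.m_exp[region]
    if cfg.gdp_start is None:
        gdp0 = float(np.exp(np.log(8000.0) + u[2] * (np.log(45000.0) - np.log(8000.0))))
    else:
        gdp0 = cfg.gdp_start if np.isscalar(cfg.gdp_start) else cfg.gdp_start[region]
    return RegionParams(float(g_exp), float(g_rec), float(m_exp), float(gdp0))


@dataclass
class SyntheticPanel:
    """One region's full panel: deaths, populations, temperature, GDP.

    ``deaths`` is (n_strata, n_days); ``populations`` is (n_strata,
    n_anchor_years) of year-end counts for years ``pop_years`` (which
    start one year before the daily axis so every day lies between two
    anchors); ``gdp`` is per-capita GDP for ``gdp_years``.
    """

    region: str
    dates: pd.DatetimeIndex
    strata: tuple = STRATA
    deaths: np.ndarray = None
    pop_years: np.ndarray = None
    populations: np.ndarray = None
    temperature: np.ndarray = None
    gdp_years: np.ndarray = None
    gdp: np.ndarray = None
    excluded_years: frozenset = frozenset()
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        n_days = len(self.dates)
        expected = pd.date_range(self.dates[0], self.dates[-1], freq="D")
        if not self.dates.equals(expected):
            raise ValueError(f"{self.region}: date axis is not contiguous daily")
        if self.deaths.shape != (len(self.strata), n_days):
            raise ValueError(f"{self.region}: deaths shape {self.deaths.shape}")
        if (self.deaths < 0).any():
            raise ValueError(f"{self.region}: negative death counts")
        if self.populations.shape != (len(self.strata), len(self.pop_years)):
            raise ValueError(f"{self.region}: populations shape mismatch")
        if (self.populations <= 0).any():
            raise ValueError(f"{self.region}: non-positive populations")
        if len(self.gdp) != len(self.gdp_years):
            raise ValueError(f"{self.region}: one GDP value per year required")
        if (np.asarray(self.gdp) <= 0).any():
            raise ValueError(f"{self.region}: GDP must be strictly positive")
        if len(self.temperature) != n_days:
            raise ValueError(f"{self.region}: temperature length mismatch")


def _date_axis(cfg: ScenarioConfig) -> pd.DatetimeIndex:
    return pd.date_range(f"{cfg.start_year}-01-01", f"{cfg.end_year}-12-31", freq="D")


def annual_populations(cfg: ScenarioConfig, region: int) -> tuple[np.ndarray, np.ndarray]:
    """Year-end stratum populations for years (start_year-1)..end_year.

    Deterministic: total ``pop_size`` split by the configured stratum
    shares at the end of (start_year-1), then uniform growth
    ``pop_growth`` per year.  Returns ``(years, populations)`` with
    populations shaped (n_strata, n_years).
    """
    years = np.arange(cfg.start_year - 1, cfg.end_year + 1)
    shares = np.array([cfg.pop_shares[s] for s in STRATA])
    growth = (1.0 + cfg.pop_growth) ** (years - (cfg.start_year - 1))
    pops = cfg.pop_size * shares[:, None] * growth[None, :]
    return years, pops


def generate_temperature(cfg: ScenarioConfig, region: int) -> np.ndarray:
    """Daily mean temperature: annual harmonic plus AR(1) noise.

    ``T(d) = temp_mean - temp_amplitude*cos(2*pi*doy/365.25) + e(d)``
    with ``e`` a stationary AR(1) of sd ``temp_sd`` and lag-1
    autocorrelation ``temp_ar1`` (innovation sd scaled accordingly).
    """
    dates = _date_axis(cfg)
    doy = dates.dayofyear.to_numpy()
    seasonal = cfg.temp_mean - cfg.temp_amplitude * np.cos(
        2.0 * np.pi * doy / _DAYS_PER_YEAR
    )
    if cfg.temp_sd == 0.0:
        return seasonal
    rng = _rng(cfg, region, 1)
    phi = cfg.temp_ar1
    innov_sd = cfg.temp_sd * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=len(dates))
    noise = np.empty(len(dates))
    noise[0] = rng.normal(0.0, cfg.temp_sd)  # draw from the stationary law
    for i in range(1, len(dates)):
        noise[i] = phi * noise[i - 1] + eps[i]
    return seasonal + noise


def generate_gdp(cfg: ScenarioConfig, region: int) -> tuple[np.ndarray, np.ndarray]:
    """Annual per-capita GDP with an expansion/recession growth switch.

    ``GDP(y+1) = GDP(y) * (1 + g_exp)`` for transitions starting before
    ``break_year - 1`` and ``* (1 + g_rec)`` from then on, i.e. growth
    over 2007->2008 is already at the recession rate for the default
    break year 2008.  Returns ``(years, gdp)``.
    """
    p = region_params(cfg, region)
    years = np.arange(cfg.start_year, cfg.end_year + 1)
    gdp = np.empty(len(years))
    gdp[0] = p.gdp_start
    for i, y in enumerate(years[:-1]):
        g = p.g_exp if y < cfg.break_year - 1 else p.g_rec
        gdp[i + 1] = gdp[i] * (1.0 + g)
    if (gdp <= 0).any():
        raise ValueError("GDP became non-positive; growth rates below -100%?")
    return years, gdp


def _expected_rate_surface(
    cfg: ScenarioConfig, region: int, temperature: np.ndarray
) -> np.ndarray:
    """Poisson mean per stratum and day, lambda_g(d)."""
    dates = _date_axis(cfg)
    if len(temperature) != len(dates):
        raise ValueError("temperature does not cover the full date axis")
    p = region_params(cfg, region)
    years, pops = annual_populations(cfg, region)
    pop_daily = interpolate_daily_population(years, pops, dates)

    rates = np.array([cfg.baseline_rates[s] for s in STRATA])

    t = (dates - pd.Timestamp(cfg.start_year, 1, 1)).days.to_numpy() / _DAYS_PER_YEAR
    t_break = (
        pd.Timestamp(cfg.break_year, 1, 1) - pd.Timestamp(cfg.start_year, 1, 1)
    ).days / _DAYS_PER_YEAR
    m_post = p.m_exp + cfg.beta * (p.g_rec - p.g_exp)
    log_trend = np.where(
        t < t_break, p.m_exp * t, p.m_exp * t_break + m_post * (t - t_break)
    )
    trend = np.exp(log_trend)

    doy = dates.dayofyear.to_numpy()
    season = 1.0 + cfg.seasonal_amplitude * np.cos(2.0 * np.pi * doy / _DAYS_PER_YEAR)

    excess = 1.0
    if cfg.temp_coupling != 0.0:
        excess = 1.0 + cfg.temp_coupling * ((temperature - cfg.temp_optimum) / 10.0) ** 2

    lam = pop_daily * rates[:, None] * (trend * season * excess)[None, :] / _DAYS_PER_YEAR
    if (lam < 0).any():
        raise ValueError("negative Poisson mean; check amplitudes and coupling")
    return lam


def generate_deaths(
    cfg: ScenarioConfig, region: int, temperature: np.ndarray
) -> np.ndarray:
    """Per-stratum daily death counts, Poisson around the rate surface."""
    lam = _expected_rate_surface(cfg, region, temperature)
    rng = _rng(cfg, region, 2)
    return rng.poisson(lam)


def generate_scenario(cfg: ScenarioConfig) -> list[SyntheticPanel]:
    """Generate the full multi-region scenario."""
    dates = _date_axis(cfg)
    width = max(2, len(str(cfg.n_regions)))
    panels = []
    for i in range(cfg.n_regions):
        temp = generate_temperature(cfg, i)
        deaths = generate_deaths(cfg, i, temp)
        pop_years, pops = annual_populations(cfg, i)
        gdp_years, gdp = generate_gdp(cfg, i)
        p = region_params(cfg, i)
        panel = SyntheticPanel(
            region=f"R{i:0{width}d}",
            dates=dates,
            deaths=deaths,
            pop_years=pop_years,
            populations=pops,
            temperature=temp,
            gdp_years=gdp_years,
            gdp=gdp,
            params={
                "g_exp": p.g_exp,
                "g_rec": p.g_rec,
                "m_exp": p.m_exp,
                "gdp_start": p.gdp_start,
                "beta": cfg.beta,
            },
        )
        panel.validate()
        panels.append(panel)
    return panels
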