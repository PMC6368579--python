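"""Scenario and pipeline configuration.

``ScenarioConfig`` fixes every knob of the synthetic study: the regional
panel layout (years, strata, population), the daily temperature process,
the mortality process (baseline age-specific rates, seasonality, secular
trend), the macroeconomic process (expansion/recession growth rates),
and the coupling ``beta`` that maps a region's GDP slowdown onto a
strengthening of its declining mortality trend — the procyclical
structure the downstream statistics are designed to detect.

``PipelineConfig`` wires a scenario (or a set of input CSVs) into the
analysis stages and fixes the analysis parameters: subperiod windows,
temperature-bin count, exposure lag scheme, Monte Carlo size and seed.
Both round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .strata import STRATA, default_rates, default_shares

__all__ = ["ScenarioConfig", "PipelineConfig"]


def _per_region(value, n: int, name: str) -> list[float]:
    """Broadcast a scalar or validate a length-``n`` sequence."""
    if value is None:
        raise ValueError(f"{name} is None and no draw rule applies")
    if isinstance(value, (int, float)):
        return [float(value)] * n
    vals = [float(v) for v in value]
    if len(vals) != n:
        raise ValueError(f"{name} has length {len(vals)}, expected {n}")
    return vals


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic regional panel generator.

    Parameters
    ----------
    n_regions
        Number of regions (independent RNG substreams), >= 2.
    start_year, end_year
        Inclusive calendar span of the daily record (default 2000-2010).
    break_year
        First calendar year of the recession regime (default 2008); the
        mortality log-trend slope and the GDP growth rate change here.
    pop_size
        Total population per region (persons).
    pop_growth
        Uniform annual population growth applied to all strata
        (fraction/year); uniform growth leaves the age structure fixed.
    seasonal_amplitude
        Relative amplitude of the winter mortality excess, in [0, 1).
        ``season(d) = 1 + a*cos(2*pi*doy/365.25)`` peaks in early January.
    temp_mean, temp_amplitude, temp_sd, temp_ar1
        Daily-mean temperature process (degrees C): annual harmonic with
        winter minimum plus AR(1) noise of stationary sd ``temp_sd`` and
        lag-1 autocorrelation ``temp_ar1``.
    g_exp, g_rec
        Per-region annual GDP growth in the expansion and recession
        phases (fraction/year).  Scalars broadcast; sequences must have
        length ``n_regions``; ``None`` draws heterogeneous values per
        region: ``g_exp ~ U(0.007, 0.052)`` and ``g_rec = g_exp +
        U(-0.073, -0.012)`` (the spread of national expansion rates and
        recession slowdowns observed across Europe around 2008).
    m_exp
        Baseline mortality log-trend in expansion (fraction/year,
        negative: mortality declines).
    beta
        Coupling from GDP trend change to mortality trend change: the
        post-break mortality slope is ``m_exp + beta*(g_rec - g_exp)``,
        so ``beta > 0`` makes a larger slowdown strengthen the decline.
    gdp_start
        Per-capita GDP at ``start_year``; ``None`` draws
        ``exp(U(ln 8000, ln 45000))`` per region.
    baseline_rates, pop_shares
        Per-stratum annual death rates and population shares; default to
        the built-in European-like schedules.
    temp_coupling, temp_optimum
        Optional U-shaped temperature excess-mortality factor
        ``1 + temp_coupling*((T - temp_optimum)/10)**2``; the default
        ``temp_coupling = 0`` disables it (the analysis's null).
    seed
        Master RNG seed; identical config + seed gives identical output.
    """

    n_regions: int = 15
    start_year: int = 2000
    end_year: int = 2010
    break_year: int = 2008
    pop_size: float = 2_000_000.0
    pop_growth: float = 0.003
    seasonal_amplitude: float = 0.15
    temp_mean: float = 10.0
    temp_amplitude: float = 8.0
    temp_sd: float = 2.0
    temp_ar1: float = 0.7
    g_exp: float | Sequence[float] | None = None
    g_rec: float | Sequence[float] | None = None
    m_exp: float | Sequence[float] = -0.022
    beta: float = 1.0
    gdp_start: float | Sequence[float] | None = None
    baseline_rates: dict[tuple[str, str], float] = field(default_factory=default_rates)
    pop_shares: dict[tuple[str, str], float] = field(default_factory=default_shares)
    temp_coupling: float = 0.0
    temp_optimum: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.end_year < self.start_year:
            raise ValueError("end_year before start_year")
        if not (self.start_year <= self.break_year <= self.end_year + 1):
            raise ValueError("break_year outside the year range")
        if self.pop_size <= 0:
            raise ValueError("pop_size must be > 0")
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ValueError("seasonal_amplitude must be in [0, 1)")
        if self.temp_sd < 0:
            raise ValueError("temp_sd must be >= 0")
        if not -1.0 < self.temp_ar1 < 1.0:
            raise ValueError("temp_ar1 must be in (-1, 1)")
        if set(self.baseline_rates) != set(STRATA):
            raise ValueError("baseline_rates must cover exactly the 34 strata")
        if set(self.pop_shares) != set(STRATA):
            raise ValueError("pop_shares must cover exactly the 34 strata")
        if any(r < 0 for r in self.baseline_rates.values()):
            raise ValueError("baseline_rates must be >= 0")
        if any(s <= 0 for s in self.pop_shares.values()):
            raise ValueError("pop_shares must be > 0")

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuple keys are not YAML/JSON friendly
        d["baseline_rates"] = {f"{s}|{a}": v for (s, a), v in self.baseline_rates.items()}
        d["pop_shares"] = {f"{s}|{a}": v for (s, a), v in self.pop_shares.items()}
        for k in ("g_exp", "g_rec", "m_exp", "gdp_start"):
            v = d[k]
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("baseline_rates", "pop_shares"):
            if key in d and d[key] is not None:
                d[key] = {tuple(k.split("|")): float(v) for k, v in d[key].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Short stable hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


#: analysis subperiods for the temperature-resolved trends
DEFAULT_SUBPERIODS: dict[str, tuple[int, int]] = {
    "P1": (2000, 2003),
    "P2": (2004, 2007),
    "P3": (2008, 2010),
}

#: expansion/recession windows for the annual trend-change statistic
DEFAULT_WINDOWS: dict[str, tuple[int, int]] = {"pre": (2001, 2007), "post": (2008, 2010)}
ALT_WINDOWS: dict[str, tuple[int, int]] = {"pre": (2001, 2005), "post": (2006, 2010)}


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    Either ``scenario`` (simulate) or ``data_dir`` (read the four input
    CSVs) must be set.  ``windows`` selects the annual trend-change
    split: "default" (2001-2007 vs 2008-2010) or "alt" (2001-2005 vs
    2006-2010).
    """

    scenario: ScenarioConfig | None = None
    data_dir: str | None = None
    out_dir: str = "out"
    n_bins: int = 20
    lag_scheme: str = "window"  # window | shift | none
    windows: str = "default"  # default | alt
    subperiods: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SUBPERIODS)
    )
    percentile_subset: tuple[int, ...] = (10, 25, 40, 60, 75, 90)
    n_sims: int = 1000
    run_mc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario is None and self.data_dir is None:
            raise ValueError("either scenario or data_dir must be given")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.lag_scheme not in ("window", "shift", "none"):
            raise ValueError(f"unknown lag_scheme {self.lag_scheme!r}")
        if self.windows not in ("default", "alt"):
            raise ValueError(f"unknown windows {self.windows!r}")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if set(self.subperiods) != {"P1", "P2", "P3"}:
            raise ValueError("subperiods must define P1, P2 and P3")
        bad = [p for p in self.percentile_subset if not 0 <= int(p) <= 100]
        if bad:
            raise ValueError(f"percentiles outside 0..100: {bad}")

    @property
    def trend_windows(self) -> dict[str, tuple[int, int]]:
        return dict(DEFAULT_WINDOWS if self.windows == "default" else ALT_WINDOWS)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"] = None if self.scenario is None else self.scenario.to_dict()
        d["subperiods"] = {k: list(v) for k, v in self.subperiods.items()}
        d["percentile_subset"] = list(self.percentile_subset)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("scenario") is not None:
            d["scenario"] = ScenarioConfig.from_dict(d["scenario"])
        if "subperiods" in d:
            d["subperiods"] = {k: tuple(v) for k, v in d["subperiods"].items()}
        if "percentile_subset" in d:
            d["percentile_subset"] = tuple(d["percentile_subset"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
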