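"""Temperature-resolved mortality trends.

The seasonal strength of the procyclical mortality signal is expressed
as a function of the daily temperature distribution rather than of
calendar months.  Per region and subperiod (P1 = 2000-2003,
P2 = 2004-2007, P3 = 2008-2010):

1. each mortality day is paired with a lagged temperature exposure
   (7-day trailing mean from October to May, same-day from June to
   September, the lag that tracks the delayed impact of cold);
2. the exposure axis is cut into equal-width bins and exposure and
   mortality averaged per bin, giving a binned temperature->expected
   mortality curve;
3. integer percentiles T_p (p = 0..100) of the full-period temperature
   series are mapped through each subperiod's curve by piecewise-linear
   interpolation between bin nodes (clamped outside the node range),
   giving expected mortality M_p per subperiod;
4. consecutive-subperiod differences scaled by the spacing of subperiod
   midpoints give pre-crisis and post-crisis mortality trends per
   percentile, (M_P2 - M_P1)/4 and (M_P3 - M_P2)/3.5, and their
   difference is the temperature-resolved trend change.

Curves retain the individual day values per bin so that the Monte Carlo
significance test can resample them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TempMortalityCurve",
    "PercentileProfile",
    "apply_lag",
    "fit_curve",
    "percentiles",
    "map_percentiles",
    "percentile_trends",
    "subperiod_divisors",
]

#: months whose mortality responds to the previous week's temperatures
LAGGED_MONTHS = frozenset({10, 11, 12, 1, 2, 3, 4, 5})


def apply_lag(
    mortality: np.ndarray,
    temperature: np.ndarray,
    dates: pd.DatetimeIndex,
    scheme: str = "window",
) -> pd.DataFrame:
    """Pair each mortality day with its temperature exposure.

    Exposure for a day whose month falls in October-May is the trailing
    7-day mean temperature over [d-6, d] (``scheme="window"``) or the
    temperature 7 days earlier (``scheme="shift"``); June-September days
    use the same-day temperature.  ``scheme="none"`` disables lagging
    entirely.  Days whose lag window exits the record are dropped.

    Returns a frame indexed by date with columns ``exposure`` and
    ``mortality``.
    """
    mortality = np.asarray(mortality, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if not (len(mortality) == len(temperature) == len(dates)):
        raise ValueError("mortality, temperature and dates must align")
    if len(dates) == 0:
        raise ValueError("empty overlap between mortality and temperature")
    if scheme not in ("window", "shift", "none"):
        raise ValueError(f"unknown lag scheme {scheme!r}")

    temp = pd.Series(temperature, index=dates)
    if scheme == "none":
        exposure = temp.to_numpy()
        valid = np.ones(len(dates), dtype=bool)
    else:
        if scheme == "window":
            lagged = temp.rolling(window=7, min_periods=7).mean()
        else:
            lagged = temp.shift(7)
        is_lagged_month = dates.month.isin(LAGGED_MONTHS)
        exposure = np.where(is_lagged_month, lagged.to_numpy(), temp.to_numpy())
        valid = ~(is_lagged_month & lagged.isna().to_numpy())
    out = pd.DataFrame(
        {"exposure": exposure[valid], "mortality": mortality[valid]},
        index=dates[valid],
    )
    if out.empty:
        raise ValueError("no days left after dropping incomplete lag windows")
    return out


@dataclass
class TempMortalityCurve:
    """Binned daily temperature -> expected mortality relationship.

    ``bin_t``/``bin_m`` are per-bin means of exposure temperature and
    standardized mortality, ``bin_n`` the day counts; empty bins are
    omitted so ``bin_t`` is strictly increasing.  ``bin_values`` keeps
    the individual daily mortality values of each bin for resampling.
    """

    region: str = ""
    subperiod: str = ""
    bin_t: np.ndarray = None
    bin_m: np.ndarray = None
    bin_n: np.ndarray = None
    bin_values: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.bin_t)


def fit_curve(
    pairs: pd.DataFrame, n_bins: int, region: str = "", subperiod: str = ""
) -> TempMortalityCurve:
    """Group (exposure, mortality) days into equal-width exposure bins.

    Bin edges are equally spaced over the subperiod's [min, max]
    exposure; interior bins are left-closed and the last bin is
    right-closed so the maximum belongs to the top bin.  Bins holding
    no days are dropped.
    """
    if len(pairs) < 1:
        raise ValueError("at least one (exposure, mortality) pair required")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = pairs["exposure"].to_numpy(dtype=float)
    y = pairs["mortality"].to_numpy(dtype=float)
    lo, hi = x.min(), x.max()
    if lo == hi:
        idx = np.zeros(len(x), dtype=int)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    bt, bm, bn, bv = [], [], [], []
    for b in range(n_bins):
        m = idx == b
        if not m.any():
            continue
        bt.append(x[m].mean())
        bm.append(y[m].mean())
        bn.append(int(m.sum()))
        bv.append(y[m].copy())
    return TempMortalityCurve(
        region=region, subperiod=subperiod,
        bin_t=np.array(bt), bin_m=np.array(bm), bin_n=np.array(bn), bin_values=bv,
    )


def percentiles(temperature: np.ndarray) -> np.ndarray:
    """Integer percentiles 0..100 of a full-period daily series.

    Linear-interpolation empirical quantiles; percentile 0 is the
    minimum and 100 the maximum.  Requires at least 101 days so the
    grid is meaningfully resolved.
    """
    temperature = np.asarray(temperature, dtype=float)
    if len(temperature) < 101:
        raise ValueError(f"need >= 101 days, got {len(temperature)}")
    return np.percentile(temperature, np.arange(101), method="linear")


def map_percentiles(curve: TempMortalityCurve, t_p: np.ndarray) -> np.ndarray:
    """Expected mortality at given temperatures via the binned curve.

    Piecewise-linear between bin (mean T, mean M) nodes; temperatures
    beyond the outer nodes clamp to the nearest node's mortality.
    """
    if curve.n_bins < 2:
        raise ValueError("curve needs >= 2 bins to interpolate")
    return np.interp(np.asarray(t_p, dtype=float), curve.bin_t, curve.bin_m)


def subperiod_divisors(
    p1: tuple[int, int], p2: tuple[int, int], p3: tuple[int, int]
) -> tuple[float, float]:
    """Year spacings between consecutive subperiod midpoints.

    For the standard subperiods 2000-2003 / 2004-2007 / 2008-2010 this
    yields (4.0, 3.5): mortality differences between consecutive
    subperiods are divided by these spacings to express trends per
    year.
    """
    mid = [0.5 * (a + b) for a, b in (p1, p2, p3)]
    if not mid[0] < mid[1] < mid[2]:
        raise ValueError("subperiod midpoints must be increasing")
    return mid[1] - mid[0], mid[2] - mid[1]


def percentile_trends(
    m_p1: np.ndarray,
    m_p2: np.ndarray,
    m_p3: np.ndarray,
    div_pre: float = 4.0,
    div_post: float = 3.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre/post-crisis mortality trends and their change, per percentile.

    ``trend_pre = (M_P2 - M_P1)/div_pre``, ``trend_post =
    (M_P3 - M_P2)/div_post`` (daily deaths per million per year), and
    ``delta = trend_post - trend_pre``.
    """
    m1, m2, m3 = (np.asarray(m, dtype=float) for m in (m_p1, m_p2, m_p3))
    if not (m1.shape == m2.shape == m3.shape):
        raise ValueError("percentile profiles are misaligned")
    trend_pre = (m2 - m1) / div_pre
    trend_post = (m3 - m2) / div_post
    return trend_pre, trend_post, trend_post - trend_pre


@dataclass
class PercentileProfile:
    """Per-region temperature-percentile profile of the trend change.

    ``t_p`` are the full-period temperature percentiles; ``m`` maps
    subperiod name -> expected mortality per percentile; trends follow
    ``percentile_trends``.
    """

    region: str
    t_p: np.ndarray
    m: dict[str, np.ndarray]
    trend_pre: np.ndarray
    trend_post: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.trend_post - self.trend_pre
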