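"""Daily population estimation and direct age-sex standardization.

Annual stratum populations are anchored at 31 December of each year and
linearly interpolated to a daily axis.  Daily standardized mortality is
the direct-standardization weighted sum of stratum-specific crude rates,

    rate(d) = sum_g [ref_g / sum_g ref_g] * deaths_g(d) / pop_g(d),

reported as daily deaths per million of reference population.  Annual
standardized mortality is the calendar-year sum of the daily per-person
rates, reported as annual deaths per thousand, so leap years contribute
366 daily terms naturally.

The reference population is the pooled stratum population of all
regions at the end of a reference year (default 2005), mirroring the
convention of standardizing against the residents of the whole study
area on 31 December 2005.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReferencePopulation",
    "interpolate_daily_population",
    "standardize_daily",
    "standardize_annual",
    "annualize",
]


def interpolate_daily_population(
    years: np.ndarray, values: np.ndarray, dates: pd.DatetimeIndex
) -> np.ndarray:
    """Linear-in-time interpolation of year-end populations to days.

    Parameters
    ----------
    years
        Consecutive anchor years; the anchor date of year ``y`` is
        31 December of ``y``.
    values
        Anchored populations, shape ``(..., len(years))``.
    dates
        Daily axis; every date must lie within the anchored span.

    Returns
    -------
    ndarray of shape ``(..., len(dates))``.

    Raises
    ------
    ValueError
        If anchor years are not consecutive (a missing year inside the
        span) or any date falls outside the anchored span.
    """
    years = np.asarray(years)
    values = np.asarray(values, dtype=float)
    if len(years) < 2:
        raise ValueError("need at least two consecutive annual anchors")
    if not (np.diff(years) == 1).all():
        raise ValueError(f"anchor years must be consecutive, got {years.tolist()}")
    if values.shape[-1] != len(years):
        raise ValueError("values last dimension must match years")

    origin = pd.Timestamp(int(years[0]), 12, 31)
    anchor_t = np.array(
        [(pd.Timestamp(int(y), 12, 31) - origin).days for y in years], dtype=float
    )
    t = (dates - origin).days.to_numpy().astype(float)
    if t.min() < anchor_t[0] or t.max() > anchor_t[-1]:
        raise ValueError(
            f"dates span {dates[0].date()}..{dates[-1].date()} outside anchored "
            f"span {origin.date()}..{pd.Timestamp(int(years[-1]), 12, 31).date()}"
        )

    j = np.clip(np.searchsorted(anchor_t, t, side="right") - 1, 0, len(years) - 2)
    w = (t - anchor_t[j]) / (anchor_t[j + 1] - anchor_t[j])
    return values[..., j] * (1.0 - w) + values[..., j + 1] * w


@dataclass(frozen=True)
class ReferencePopulation:
    """Fixed reference population by stratum.

    ``counts`` follows the same stratum order as the panels it will be
    applied to.  ``weights`` are the stratum shares used in direct
    standardization.
    """

    strata: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (len(self.strata),):
            raise ValueError("one count per stratum required")
        if (counts < 0).any() or counts.sum() <= 0:
            raise ValueError("reference counts must be >= 0 with positive total")
        object.__setattr__(self, "counts", counts)

    @property
    def weights(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @classmethod
    def from_panels(cls, panels, ref_year: int = 2005) -> "ReferencePopulation":
        """Pool all regions' year-end populations of ``ref_year``."""
        strata = panels[0].strata
        total = np.zeros(len(strata))
        for p in panels:
            if tuple(p.strata) != tuple(strata):
                raise ValueError("panels disagree on stratum sets")
            idx = np.flatnonzero(np.asarray(p.pop_years) == ref_year)
            if idx.size != 1:
                raise ValueError(f"{p.region}: no population anchor for {ref_year}")
            total += p.populations[:, idx[0]]
        return cls(strata=tuple(strata), counts=total)


def standardize_daily(
    deaths: np.ndarray, pop: np.ndarray, ref: ReferencePopulation
) -> np.ndarray:
    """Directly standardized daily mortality, deaths per million.

    ``deaths`` and ``pop`` are (n_strata, n_days) in the reference's
    stratum order.  A zero population is an error wherever deaths were
    observed; strata with zero population and zero deaths contribute 0.
    """
    deaths = np.asarray(deaths, dtype=float)
    pop = np.asarray(pop, dtype=float)
    if deaths.shape != pop.shape:
        raise ValueError("deaths and populations must share shape")
    if deaths.shape[0] != len(ref.strata):
        raise ValueError("stratum mismatch between data and reference")
    bad = (pop <= 0) & (deaths > 0)
    if bad.any():
        g, d = np.argwhere(bad)[0]
        raise ValueError(
            f"zero population with {deaths[g, d]:.0f} deaths in stratum "
            f"{ref.strata[g]} at day index {d}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        crude = np.where(pop > 0, deaths / np.where(pop > 0, pop, 1.0), 0.0)
    return 1e6 * (ref.weights[:, None] * crude).sum(axis=0)


def annualize(
    daily_rate_per_million: np.ndarray,
    dates: pd.DatetimeIndex,
    excluded_years: set[int] | frozenset[int] = frozenset(),
) -> pd.Series:
    """Annual standardized mortality (deaths per thousand) per year.

    Sums daily per-person rates over each complete calendar year and
    scales to per-thousand.  A partially covered year is an error unless
    listed in ``excluded_years``, in which case it is dropped from the
    output (the treatment of region-years without usable death data).
    """
    rates = np.asarray(daily_rate_per_million, dtype=float)
    if len(rates) != len(dates):
        raise ValueError("rates and dates must align")
    s = pd.Series(rates, index=dates)
    out = {}
    for year, chunk in s.groupby(s.index.year):
        n_expected = pd.Timestamp(year, 12, 31).dayofyear
        if len(chunk) != n_expected:
            if int(year) in excluded_years:
                continue
            raise ValueError(
                f"year {year} has {len(chunk)} of {n_expected} days and is "
                "not flagged excluded"
            )
        if int(year) in excluded_years:
            continue
        out[int(year)] = chunk.sum() / 1e6 * 1000.0
    return pd.Series(out, dtype=float).sort_index()


def standardize_annual(
    deaths: np.ndarray,
    pop_daily: np.ndarray,
    dates: pd.DatetimeIndex,
    ref: ReferencePopulation,
    excluded_years: set[int] | frozenset[int] = frozenset(),
) -> pd.Series:
    """Direct standardization of yearly aggregated counts (alternative).

    Aggregates deaths and person-years per calendar year and stratum,
    then applies the reference weights:
    ``sum_g w_g * D_g(year) / mean_pop_g(year)``, per thousand.  Kept as
    a cross-check on ``annualize(standardize_daily(...))``; the two
    agree up to the within-year covariance of rates and populations.
    """
    years = dates.year.to_numpy()
    out = {}
    for year in np.unique(years):
        if int(year) in excluded_years:
            continue
        m = years == year
        if m.sum() != pd.Timestamp(int(year), 12, 31).dayofyear:
            raise ValueError(f"year {year} incomplete")
        d_g = np.asarray(deaths, dtype=float)[:, m].sum(axis=1)
        p_g = np.asarray(pop_daily, dtype=float)[:, m].mean(axis=1)
        if ((p_g <= 0) & (d_g > 0)).any():
            raise ValueError(f"year {year}: zero population with deaths")
        rate_g = np.where(p_g > 0, d_g / np.where(p_g > 0, p_g, 1.0), 0.0)
        out[int(year)] = float((ref.weights * rate_g).sum() * 1000.0)
    return pd.Series(out, dtype=float).sort_index()
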