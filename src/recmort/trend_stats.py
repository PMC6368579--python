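"""Annual trend statistics for GDP and standardized mortality.

Two distinct statistics are provided and never substituted for one
another:

* ``mean_relative_change`` — the average of relative year-to-year
  changes over a window, each change normalized by the midpoint of the
  two years,

      t_{y1,y2}(v) = mean_{y in [y1, y2]} (v_y - v_{y-1}) / ((v_y + v_{y-1}) / 2).

  ``trend_change`` differences this statistic between a post-crisis and
  a pre-crisis window (default 2008-2010 minus 2001-2007); this is the
  quantity correlated across regions.

* ``endpoint_relative_change`` — the simpler percentage-per-year change
  between two endpoint years relative to the first,

      100 * (v_{y2} - v_{y1}) / (v_{y1} * (y2 - y1)),

  the convention of printed national summary tables.

Year-pairs touching an excluded year (regions with unusable early
years) are dropped from both the numerator and the averaging count.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "TrendChangeRecord",
    "mean_relative_change",
    "endpoint_relative_change",
    "trend_change",
]


def _value(series: pd.Series, year: int) -> float | None:
    try:
        return float(series.loc[year])
    except KeyError:
        return None


def mean_relative_change(
    series: pd.Series,
    y1: int,
    y2: int,
    excluded: set[int] | frozenset[int] = frozenset(),
) -> float:
    """Midpoint-normalized year-to-year change averaged over [y1, y2].

    ``series`` is indexed by calendar year.  Every year in
    ``[y1 - 1, y2]`` must be present unless listed in ``excluded``;
    pairs touching an excluded (or excluded-and-absent) year are
    dropped and the averaging denominator shrinks accordingly.
    """
    if y1 > y2:
        raise ValueError("y1 must be <= y2")
    terms = []
    for y in range(y1, y2 + 1):
        if y in excluded or (y - 1) in excluded:
            continue
        v_now, v_prev = _value(series, y), _value(series, y - 1)
        if v_now is None or v_prev is None:
            missing = y if v_now is None else y - 1
            raise ValueError(f"year {missing} missing and not flagged excluded")
        mid = 0.5 * (v_now + v_prev)
        if mid == 0.0:
            raise ValueError(f"zero midpoint between years {y - 1} and {y}")
        terms.append((v_now - v_prev) / mid)
    if not terms:
        raise ValueError(f"no valid year-pair in [{y1}, {y2}]")
    return sum(terms) / len(terms)


def endpoint_relative_change(series: pd.Series, y1: int, y2: int) -> float:
    """Percent-per-year change between endpoint years, base-year relative."""
    if y1 == y2:
        raise ValueError("endpoint years must differ")
    v1, v2 = _value(series, y1), _value(series, y2)
    if v1 is None or v2 is None:
        raise ValueError(f"endpoint year missing: {y1 if v1 is None else y2}")
    if v1 <= 0:
        raise ValueError("base-year value must be positive")
    return 100.0 * (v2 - v1) / (v1 * (y2 - y1))


@dataclass(frozen=True)
class TrendChangeRecord:
    """Pre/post-crisis trends (fraction/year) and their difference."""

    region: str
    variable: str
    t_pre: float
    t_post: float
    pre: tuple[int, int]
    post: tuple[int, int]

    @property
    def delta(self) -> float:
        return self.t_post - self.t_pre


def trend_change(
    series: pd.Series,
    pre: tuple[int, int] = (2001, 2007),
    post: tuple[int, int] = (2008, 2010),
    excluded: set[int] | frozenset[int] = frozenset(),
    region: str = "",
    variable: str = "",
) -> TrendChangeRecord:
    """Post- minus pre-crisis change in the mean relative trend.

    The default windows average year-to-year changes over 2001-2007
    (expansion) and 2008-2010 (recession); the alternative robustness
    split 2001-2005 / 2006-2010 is obtained by passing those windows.
    """
    t_pre = mean_relative_change(series, *pre, excluded=excluded)
    t_post = mean_relative_change(series, *post, excluded=excluded)
    return TrendChangeRecord(
        region=region, variable=variable, t_pre=t_pre, t_post=t_post,
        pre=tuple(pre), post=tuple(post),
    )
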