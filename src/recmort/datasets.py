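"""Published national endpoint tables for 15 European countries.

Real per-capita GDP (euros, 2010 reference prices) and age-sex-
standardized mortality (annual deaths per thousand) at the endpoint
years 2000, 2007 and 2010, as printed in national summary tables of
the European study period, together with the printed percent-per-year
change columns (expansion 2000-2007, recession 2007-2010, full period
2000-2010).

For Croatia and the United Kingdom, sex/age-resolved mortality was
unusable in 2000-2001, so their series effectively start in 2002: the
first-column values are 2002 values and ``first_year`` records that.
The printed change columns are consistent with the endpoint values
under the base-year-relative convention (see ``trend_stats``) once the
endpoint rounding of the printed values is propagated; the published
changes were evidently computed from unrounded endpoints, so recomputed
cells can differ from printed ones by a few units in the last digit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trend_stats import endpoint_relative_change

__all__ = [
    "load_gdp_table",
    "load_mortality_table",
    "computed_changes",
    "procyclical_countries",
    "round_half_away",
]

# country: (acronym, first_year, v_first, v_2007, v_2010,
#           printed expansion, recession, full-period %/yr)
_GDP = {
    "Austria":        ("AT", 2000, 31700, 35900, 35400, 1.9, -0.5, 1.2),
    "Belgium":        ("BE", 2000, 30300, 33900, 33500, 1.7, -0.4, 1.1),
    "Czech Republic": ("CZ", 2000, 11200, 15200, 14900, 5.1, -0.7, 3.3),
    "Germany":        ("DE", 2000, 29000, 32100, 32100, 1.5, 0.0, 1.1),
    "Denmark":        ("DK", 2000, 42200, 46200, 43800, 1.4, -1.7, 0.4),
    "Spain":          ("ES", 2000, 21400, 24500, 23200, 2.1, -1.8, 0.8),
    "France":         ("FR", 2000, 28900, 31400, 30700, 1.2, -0.7, 0.6),
    "Croatia":        ("HR", 2002, 8900, 11200, 10500, 5.2, -2.1, 2.2),
    "Italy":          ("IT", 2000, 27300, 28700, 26800, 0.7, -2.2, -0.2),
    "Luxembourg":     ("LU", 2000, 70500, 84400, 79200, 2.8, -2.1, 1.2),
    "Netherlands":    ("NL", 2000, 35100, 39100, 38500, 1.6, -0.5, 1.0),
    "Poland":         ("PL", 2000, 6400, 8500, 9400, 4.7, 3.5, 4.7),
    "Portugal":       ("PT", 2000, 16200, 17200, 17000, 0.9, -0.4, 0.5),
    "Slovenia":       ("SI", 2000, 14000, 18600, 17700, 4.7, -1.6, 2.6),
    "United Kingdom": ("UK", 2002, 28000, 31100, 29500, 2.2, -1.7, 0.7),
}

_MORTALITY = {
    "Austria":        ("AT", 2000, 10.756, 8.804, 8.588, -2.593, -0.815, -2.015),
    "Belgium":        ("BE", 2000, 11.636, 8.811, 8.531, -3.469, -1.061, -2.669),
    "Czech Republic": ("CZ", 2000, 14.168, 11.576, 11.097, -2.613, -1.380, -2.168),
    "Germany":        ("DE", 2000, 10.866, 9.062, 8.873, -2.372, -0.694, -1.834),
    "Denmark":        ("DK", 2000, 11.915, 10.575, 9.996, -1.606, -1.826, -1.611),
    "Spain":          ("ES", 2000, 9.543, 8.327, 7.560, -1.820, -3.070, -2.078),
    "France":         ("FR", 2000, 9.763, 7.849, 7.614, -2.800, -0.999, -2.201),
    "Croatia":        ("HR", 2002, 13.981, 12.904, 12.085, -1.540, -2.117, -1.695),
    "Italy":          ("IT", 2000, 9.576, 8.183, 7.755, -2.079, -1.742, -1.902),
    "Luxembourg":     ("LU", 2000, 10.458, 9.123, 8.141, -1.823, -3.589, -2.215),
    "Netherlands":    ("NL", 2000, 10.896, 8.997, 8.594, -2.490, -1.494, -2.113),
    "Poland":         ("PL", 2000, 14.348, 12.255, 11.480, -2.084, -2.107, -1.999),
    "Portugal":       ("PT", 2000, 11.288, 9.453, 8.952, -2.322, -1.765, -2.069),
    "Slovenia":       ("SI", 2000, 12.607, 10.067, 9.189, -2.878, -2.905, -2.711),
    "United Kingdom": ("UK", 2002, 11.266, 10.049, 9.433, -2.159, -2.046, -2.034),
}

_COLUMNS = [
    "acronym", "first_year", "v_first", "v_2007", "v_2010",
    "printed_expansion", "printed_recession", "printed_full",
]


def _table(raw: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(raw, orient="index", columns=_COLUMNS)
    df.index.name = "country"
    return df


def load_gdp_table() -> pd.DataFrame:
    """National real per-capita GDP endpoints (euros) and printed changes."""
    return _table(_GDP)


def load_mortality_table() -> pd.DataFrame:
    """National standardized mortality endpoints (per thousand) and changes."""
    return _table(_MORTALITY)


def computed_changes(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute the three %-per-year change columns from the endpoints.

    Uses the base-year-relative endpoint statistic with each country's
    actual first year (2002 for Croatia and the UK, 2000 otherwise).
    """
    rows = {}
    for country, row in table.iterrows():
        series = pd.Series(
            {int(row.first_year): row.v_first, 2007: row.v_2007, 2010: row.v_2010}
        )
        rows[country] = {
            "expansion": endpoint_relative_change(series, int(row.first_year), 2007),
            "recession": endpoint_relative_change(series, 2007, 2010),
            "full": endpoint_relative_change(series, int(row.first_year), 2010),
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[table.index]


def procyclical_countries(table: pd.DataFrame | None = None) -> frozenset[str]:
    """Countries whose recession-period mortality decline is the larger.

    Compares the expansion (first_year->2007) and recession
    (2007->2010) mortality changes recomputed from the endpoint values;
    a country is procyclical in this per-country sense when the
    recession change is more negative than the expansion change.
    """
    if table is None:
        table = load_mortality_table()
    chg = computed_changes(table)
    return frozenset(chg.index[chg["recession"] < chg["expansion"]])


def round_half_away(x, decimals: int):
    """Round half away from zero, the convention of the printed tables."""
    x = np.asarray(x, dtype=float)
    scale = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale
    return out.item() if out.ndim == 0 else out
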