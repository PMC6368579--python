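"""CSV schemas, validated readers and stamped writers.

Input dialects (one file each, regions stacked):

* ``deaths.csv``       — region, date (ISO-8601), sex, age_group, deaths
* ``population.csv``   — region, year, sex, age_group, population
* ``temperature.csv``  — region, date, tmean_c
* ``gdp.csv``          — region, year, gdp_per_capita

Region-years entirely absent from ``deaths.csv`` are flagged as
excluded (the treatment of regions whose early years lack usable
sex/age-resolved mortality); any other gap in the daily axis is an
error.  Every written CSV starts with a comment line stamping the
configuration hash and seed; readers skip ``#`` lines.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .strata import STRATA
from .synthetic import SyntheticPanel

log = logging.getLogger("recmort")

_SCHEMAS = {
    "deaths.csv": ["region", "date", "sex", "age_group", "deaths"],
    "population.csv": ["region", "year", "sex", "age_group", "population"],
    "temperature.csv": ["region", "date", "tmean_c"],
    "gdp.csv": ["region", "year", "gdp_per_capita"],
}


def _read_csv(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"{name}: {path} does not exist")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _SCHEMAS[name] if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing column(s) {missing}")
    return df


def _stamp(stamp: str | None) -> str:
    return f"# recmort {stamp}\n" if stamp else ""


def write_csv(df: pd.DataFrame, path: str | Path, stamp: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_stamp(stamp))
        df.to_csv(fh, index=False, lineterminator="\n")


def write_panels(panels: list[SyntheticPanel], out_dir: str | Path,
                 stamp: str | None = None) -> None:
    """Write the four input CSVs for a list of panels."""
    out = Path(out_dir)
    deaths, pops, temps, gdps = [], [], [], []
    for p in panels:
        date_str = p.dates.strftime("%Y-%m-%d")
        for g, (sex, age) in enumerate(p.strata):
            deaths.append(pd.DataFrame({
                "region": p.region, "date": date_str, "sex": sex,
                "age_group": age, "deaths": p.deaths[g].astype(int),
            }))
            pops.append(pd.DataFrame({
                "region": p.region, "year": p.pop_years, "sex": sex,
                "age_group": age, "population": p.populations[g],
            }))
        temps.append(pd.DataFrame({
            "region": p.region, "date": date_str, "tmean_c": p.temperature,
        }))
        gdps.append(pd.DataFrame({
            "region": p.region, "year": p.gdp_years, "gdp_per_capita": p.gdp,
        }))
    write_csv(pd.concat(deaths, ignore_index=True), out / "deaths.csv", stamp)
    write_csv(pd.concat(pops, ignore_index=True), out / "population.csv", stamp)
    write_csv(pd.concat(temps, ignore_index=True), out / "temperature.csv", stamp)
    write_csv(pd.concat(gdps, ignore_index=True), out / "gdp.csv", stamp)


def _panel_from_frames(region: str, d: pd.DataFrame, po: pd.DataFrame,
                       te: pd.DataFrame, gd: pd.DataFrame) -> SyntheticPanel:
    dates = pd.DatetimeIndex(pd.to_datetime(te["date"])).sort_values()
    full = pd.date_range(dates[0], dates[-1], freq="D")
    if not dates.equals(full):
        raise ValueError(f"temperature.csv: non-contiguous dates for region {region}")
    temp = te.set_index(pd.to_datetime(te["date"]))["tmean_c"].reindex(dates).to_numpy()

    # deaths: pivot to strata x days; whole missing years -> excluded
    d = d.copy()
    d["date"] = pd.to_datetime(d["date"])
    if (d["deaths"] < 0).any():
        raise ValueError(f"deaths.csv: negative deaths for region {region}")
    wide = d.pivot_table(index=["sex", "age_group"], columns="date",
                         values="deaths", aggfunc="sum")
    try:
        wide = wide.reindex(pd.MultiIndex.from_tuples(STRATA))
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"deaths.csv: unknown stratum for region {region}: {e}")
    if wide.isna().all(axis=1).any():
        missing = [s for s, row in wide.iterrows() if row.isna().all()]
        raise ValueError(f"deaths.csv: region {region} lacks strata {missing}")
    present = wide.columns
    missing_days = full.difference(present)
    excluded = set()
    if len(missing_days):
        for year in sorted(set(missing_days.year)):
            year_days = full[full.year == year]
            if len(missing_days[missing_days.year == year]) != len(year_days):
                raise ValueError(
                    f"deaths.csv: region {region} has a partial gap inside "
                    f"year {year} (non-contiguous dates)"
                )
            excluded.add(int(year))
        log.info("region %s: years %s flagged excluded", region, sorted(excluded))
    deaths = wide.reindex(columns=full).fillna(0.0).to_numpy()

    po = po.copy()
    years = np.sort(po["year"].unique())
    pop_wide = po.pivot_table(index=["sex", "age_group"], columns="year",
                              values="population")
    pop_wide = pop_wide.reindex(pd.MultiIndex.from_tuples(STRATA))
    if pop_wide.isna().any().any():
        raise ValueError(f"population.csv: incomplete strata/years for {region}")

    gd = gd.sort_values("year")
    panel = SyntheticPanel(
        region=region, dates=full, deaths=deaths,
        pop_years=years, populations=pop_wide[years].to_numpy(),
        temperature=temp, gdp_years=gd["year"].to_numpy(),
        gdp=gd["gdp_per_capita"].to_numpy(),
        excluded_years=frozenset(excluded),
    )
    panel.validate()
    return panel


def read_panels(data_dir: str | Path) -> list[SyntheticPanel]:
    """Read and validate the four input CSVs into typed panels."""
    data_dir = Path(data_dir)
    frames = {name: _read_csv(data_dir / name, name) for name in _SCHEMAS}
    regions = sorted(frames["temperature.csv"]["region"].unique())
    panels = []
    for region in regions:
        panels.append(_panel_from_frames(
            region,
            frames["deaths.csv"][frames["deaths.csv"]["region"] == region],
            frames["population.csv"][frames["population.csv"]["region"] == region],
            frames["temperature.csv"][frames["temperature.csv"]["region"] == region],
            frames["gdp.csv"][frames["gdp.csv"]["region"] == region],
        ))
    return panels
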