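# recmort

Analysis of **procyclical mortality**: the recurrent observation that
mortality rates decline *faster* during economic recessions and more
slowly during expansions. The package implements the full pipeline used
to study how the 2008 Great Recession changed European mortality
trends — from daily stratified death counts to population-weighted
correlations between GDP slowdowns and mortality-trend changes — and a
synthetic regional panel generator that emulates the study design, so
every stage is testable even though the underlying regional mortality
microdata cannot be redistributed.

It is aimed at epidemiologists and health economists who work with
daily all-cause mortality, annual population strata, daily temperature
series and annual per-capita GDP at the regional or national level.

## What it computes

**Standardization.** Daily death counts by sex × 5-year age group
(0–4 … 80+) are converted to directly standardized rates against a
fixed reference population (the pooled study-area population at the end
of 2005):

```
rate(d) = Σ_g (ref_g / Σ ref_g) · deaths_g(d) / pop_g(d)        [per million]
```

with daily stratum populations linearly interpolated between year-end
anchors. Annual rates are calendar-year sums of the daily per-person
rates (deaths per thousand).

**Annual trend changes.** The trend of a variable *v* over years
[y₁, y₂] is the mean midpoint-relative year-to-year change

```
t_{y1,y2}(v) = mean_{y}  (v_y − v_{y−1}) / ((v_y + v_{y−1})/2)
```

and the crisis effect is Δt = t_post − t_pre with default windows
2001–2007 (expansion) and 2008–2010 (recession). A simpler
endpoint-relative statistic, `100·(v_{y2} − v_{y1})/(v_{y1}·(y2−y1))`,
reproduces the convention of printed national summary tables; the two
statistics are deliberately kept distinct.

**Temperature-resolved trends.** Each mortality day is paired with a
lagged temperature exposure (7-day trailing mean October–May, same-day
June–September), exposure is cut into equal-width bins per subperiod
(P1 2000–2003, P2 2004–2007, P3 2008–2010), and integer percentiles
T_p of the full-period temperature series are mapped through each
subperiod's binned curve. Consecutive-subperiod differences scaled by
midpoint spacings, (M_P2 − M_P1)/4 and (M_P3 − M_P2)/3.5, give
pre/post-crisis trends per percentile and their change Δt̂(p).

**Association.** Across regions (or countries), Δt(GDP) is correlated
with Δt(M) — annually and per temperature percentile — with every unit
weighted by √population (Pearson and rank-based Spearman).
Significance comes from a Monte Carlo test that bootstraps the daily
mortality values within every temperature bin and recomputes the whole
chain 1000 times; the classical t-approximation is reported alongside.

## Worked example

```python
import numpy as np
from recmort import ScenarioConfig, generate_scenario, weighted_pearson, weighted_spearman
from recmort.config import DEFAULT_WINDOWS
from recmort.pipeline import standardize_panels, compute_trend_changes, region_weights

cfg = ScenarioConfig(n_regions=15, beta=1.0, seed=42)   # coupled scenario
panels = generate_scenario(cfg)
daily, annual, ref = standardize_panels(panels)
trends = compute_trend_changes(panels, annual, DEFAULT_WINDOWS)
g = trends.query("variable=='gdp'").set_index("region")["delta"]
m = trends.query("variable=='mortality'").set_index("region")["delta"]
w = region_weights(panels)
print(f"weighted Pearson r  = {weighted_pearson(g, m[g.index], w[g.index]):.3f}")
print(f"weighted Spearman   = {weighted_spearman(g, m[g.index], w[g.index]):.3f}")
```

prints

```
weighted Pearson r  = 0.959
weighted Spearman   = 0.879
```

Annual standardized mortality for the first region of this scenario
declines from 9.713 to 8.272 deaths per thousand over 2000–2007
(≈ −2.3 %/yr) and then to 6.966 by 2010 (≈ −5.6 %/yr): the generator's
coupling `beta = 1` turned that region's GDP slowdown (Δt(GDP) =
−0.042/yr) into a strengthened mortality decline (Δt(M) = −0.034/yr),
and across the 15 regions the weighted correlation between the two
trend changes is 0.96 — the procyclical signal the pipeline is built to
detect. With `beta = 0` the same pipeline returns correlations
scattered around zero.

The same run is available from the shell:

```
recmort run-all --config examples/demo.yaml --out out/demo
```

which writes `standardized_daily.csv`, `standardized_annual.csv`,
`trend_changes.csv`, `curves.csv`, `percentile_trends.csv` and
`correlations.csv`, each stamped with the config hash and seed.

## Published national tables

`recmort.datasets` ships the published endpoint values of real GDP
(euros) and standardized mortality (deaths per thousand) for 15
European countries at 2000/2007/2010, with the printed %-per-year
change columns. `computed_changes` recomputes those columns from the
endpoints (using the shortened 2002-based spans for Croatia and the
United Kingdom, whose 2000–2001 mortality was unusable) and
`procyclical_countries()` returns the six countries — Denmark, Spain,
Croatia, Luxembourg, Poland, Slovenia — whose mortality fell faster
during the recession than during the expansion.

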