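# Methods

This note documents the models, conventions and numerical choices
behind `recmort`, in the spirit of a model-description chapter: what is
computed, under which assumptions, and what the synthetic experiments
do and do not demonstrate.

## The synthetic regional panel generator

The generator emulates the *study design* of a European multi-region
mortality analysis spanning 2000–2010 with a macroeconomic break at
2008 — not any particular country's demography or climate.

**Death counts.** Daily deaths in stratum *g* (sex × 5-year age group,
34 strata) are Poisson with mean

```
λ_g(d) = pop_g(d) · rate_g · trend(d) · season(d) / 365.25
```

* `pop_g(d)`: the stratum population linearly interpolated between
  year-end anchors (see below), with uniform annual growth
  (default 0.3 %/yr) so the age structure stays fixed;
* `rate_g`: baseline annual death rates following a Gompertz-like
  age schedule (0.0001/yr at ages 5–9 up to 0.11/yr at 80+, males
  ×1.35 relative to females), calibrated so the crude rate of the
  default pyramid is ≈ 10 per thousand — the magnitude of European
  national rates in the 2000s;
* `season(d) = 1 + a·cos(2π·doy/365.25)` with default amplitude
  `a = 0.15`, a winter mortality excess peaking in early January;
* `trend(d)`: a piecewise log-linear secular trend with slope `m_exp`
  (default −2.2 %/yr, the order of observed standardized-mortality
  declines) before 1 January of the break year and
  `m_exp + beta·(g_rec − g_exp)` afterwards.

The coupling `beta` is the scientific heart of the generator: with
`beta > 0` a region whose GDP growth slows by more has its mortality
decline strengthened by proportionally more — the procyclical
structure the downstream statistics are designed to detect. `beta = 0`
is the exact null: mortality trends are then independent of the
macroeconomy.

Poisson noise was chosen because it is the standard model for death
counts and gives closed-form means for oracle tests. No public
variance information exists for the regional microdata, so the noise
scale is effectively set by the per-region population (default
2 million, about the mean regional population of a 400-million-person,
~140-region study area); this is a choice made for test power, not a
claim of realism.

**Temperature.** Daily mean temperature is an annual harmonic (mean
10 °C, amplitude 8 °C, winter minimum) plus stationary AR(1) noise
(sd 2 °C, lag-1 autocorrelation 0.7, innovation sd scaled so the
stationary sd is exact). By default mortality does *not* respond to
temperature beyond the shared seasonality — deliberately, so the
temperature-resolved trend change has a flat expectation and tests can
assert the absence of spurious temperature structure. An optional
quadratic excess factor `1 + c·((T − 18)/10)²` can switch a U-shaped
temperature response on.

**GDP.** Per-capita GDP compounds at `g_exp` per year through 2007 and
at `g_rec` from the 2007→2008 transition on. When not specified,
per-region rates are drawn as `g_exp ~ U(0.007, 0.052)` and
`g_rec = g_exp + U(−0.073, −0.012)`: the ranges of national expansion
rates and recession slowdowns observed across the 15 countries in the
published tables (0.7–5.2 %/yr expansion; slowdowns from −1.2 to −7.3
percentage points). Every region therefore slows down, but by a
heterogeneous amount — the cross-sectional spread that the correlation
analysis consumes.

**Reproducibility.** Each (region, purpose) pair gets its own RNG
substream keyed by the master seed and the region index only, so
identical configs give byte-identical output and adding regions never
perturbs existing ones.

**What the generator does not emulate:** real demographic pyramids and
their aging, influenza epidemics and heat waves (no overdispersion, no
spikes), E-OBS-like spatial temperature correlation between regions,
within-country correlation of GDP shocks. Passing tests therefore show
the *statistics* behave correctly under the stated model, not that the
model captures every feature of real mortality data.

## Daily populations and standardization

Annual populations are anchored at 31 December and interpolated
linearly in days; anchors are emitted for (start_year − 1)…end_year so
the first year's days always lie between two anchors. The refined
lexis-diagram allocation sometimes used for open-ended old-age strata
is *not* reproduced: linear interpolation is applied to all strata.
This is a documented simplification — the 80+ refinement is
second-order for trend statistics, which difference rates across
periods.

Direct standardization uses the pooled all-region population at the
end of 2005 as the reference. Two constructions of the annual rate are
implemented: the default (calendar-year sum of daily standardized
per-person rates, which handles leap years naturally) and a
cross-check (direct standardization of yearly aggregated counts over
mean person-years); on synthetic panels they agree within 1 %, the
difference being interpolation-induced within-year covariance.

Region-years without usable death data (the Croatia/UK 2000–2001
situation) are flagged *excluded*: annualization skips them, trend
averaging drops the year-pairs touching them (shrinking the averaging
denominator), and temperature-curve fitting drops their mortality days
while still allowing lag windows to reach into them for temperature.

## Trend statistics

The midpoint-relative mean change and the endpoint-relative change are
different statistics and are never substituted: the former (midpoint
denominator, averaged over year-pairs) feeds the cross-regional
correlation; the latter (base-year denominator over a span) matches
the printed national tables. For a geometric series with rate *g* the
midpoint statistic equals 2g/(2+g) exactly, so it agrees with *g* to
first order with gap g²/(2+g).

Reproduction of the printed tables deserves a note: recomputing the
change columns from the printed endpoint values reproduces all 45 GDP
cells exactly and 40/45 mortality cells to one unit in the last
printed digit. The five deviating cells (all in the 2007→2010 column,
up to 3 units) are consistent with the printed endpoints once the
endpoints' own rounding (±0.0005) is propagated through the small
3-year denominator — i.e. the published columns were computed from
unrounded endpoints. The interval-consistency check is part of the
test suite. Rounding for comparison is half-away-from-zero, the
printed tables' convention. For Croatia and the UK the first-column
values are 2002 values and spans are 5/3/8 years; with the naive
2000-based spans the printed cells are *not* recoverable (e.g.
Croatia's +5.2 %/yr expansion cell requires the 5-year span).

## Temperature-resolved trends

The exposure lag is "1 week October–May, unlagged June–September",
read as a 7-day trailing-mean window [d−6, d] (a pure 7-day shift is
available behind `lag_scheme="shift"`); the window variant is the
common practice for cold-related mortality and explained more variance
in pilot synthetic runs. The lag season is chosen by the mortality
day's month, and days whose window exits the record are dropped.

The bin count is not externally fixed; the default is 20 equal-width
bins per subperiod, which resolves the curve while keeping roughly 70+
days per bin in a 4-year subperiod. Bins are computed on each
subperiod's own exposure range; percentiles are always taken from the
*full* 2000–2010 daily series. Mapping percentile temperatures through
a curve uses piecewise-linear interpolation between bin nodes with
clamping outside the outer nodes (no extrapolation); a single-bin
curve is an error. Trends divide consecutive-subperiod differences by
the spacing of subperiod midpoints — 4 years (P1→P2) and 3.5 years
(P2→P3) for the standard subperiods; the implementation derives the
divisors from the midpoints so alternative subperiod definitions
remain consistent.

The percentile-resolved trend change is a scaled second difference of
the three subperiod profiles; it is invariant (not antisymmetric)
under reversing the subperiod order with divisors swapped, a property
the test suite asserts.

## Weighted association and the Monte Carlo test

Correlations across units use √population weights supplied by the
caller. Weighted Spearman applies the weighted Pearson formula to
unweighted mid-ranks — one of several weighted-Spearman conventions,
chosen for simplicity and exact reduction to the textbook statistic
under equal weights. Weight rescaling leaves both statistics invariant
(bit-exactly for power-of-two factors; to rounding error otherwise).

The Monte Carlo test resamples, within every temperature bin of every
region × subperiod curve, the retained daily mortality values with
replacement, then recomputes bin means → percentile profiles → trend
changes → weighted Pearson per simulation. Because only mortality is
resampled, the interpolation design onto the temperature nodes is
fixed and the whole chain vectorizes across simulations. The 95% CI is
the [2.5, 97.5] percentile range of the simulated correlations and the
two-sided p-value is `max(1/n_sims, 2·min(frac(r*≤0), frac(r*≥0)))`.
A parametric (normal within-bin) alternative was considered and
rejected: the nonparametric bootstrap uses exactly the within-bin
distribution and needs no variance model. The classical t-approximation
p-value is reported alongside for comparison. Single-day bins make the
resampled mean degenerate; they are allowed with a warning.

Calibration was verified by simulation: with `beta = 0`, 10 regions,
10 bins, populations of 10⁶ and 500 simulations per test, the
rejection rate at α = 0.05 over 200 independent replicates falls
inside the exact binomial 95% band — the test suite recomputes this.
The problem sizes (regions, bins, replicate counts) used in tests and
in `scripts/acceptance.py` are scaled-down study analogues chosen to
keep the default runs short on a single CPU; the statistics themselves
are size-agnostic.

Country-level analysis aggregates member regions' standardized rates
by population weight before the trend statistics (country GDP is taken
as provided, not aggregated); the aggregation order is a convention.

## Known limitations

* Linear interpolation for old-age daily populations (see above).
* The generator's noise model is Poisson-only; real daily mortality is
  overdispersed during epidemics and heat waves.
* The MC test quantifies within-region mortality noise, not sampling
  of regions; with few units the cross-sectional spread of a null
  correlation (sd ≈ 1/√(n−1)) dominates and is *not* shrunk by more
  simulations.
* No distributed-lag nonlinear modelling and no attributable-fraction
  estimation: the temperature axis is used to *resolve* the trend
  change seasonally, not to attribute deaths to temperature.
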