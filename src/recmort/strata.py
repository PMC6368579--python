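"""Demographic strata: sex by 5-year age group.

The analysis stratifies every death count and population figure by sex
(F/M) and seventeen 5-year age groups from 0-4 up to the open-ended 80+
group, i.e. 34 strata in total.  Stratum order is fixed (females first,
ages ascending) so that arrays indexed by stratum are comparable across
modules without re-alignment.
"""

from __future__ import annotations

SEXES: tuple[str, ...] = ("F", "M")

AGE_GROUPS: tuple[str, ...] = (
    "00-04", "05-09", "10-14", "15-19", "20-24", "25-29", "30-34",
    "35-39", "40-44", "45-49", "50-54", "55-59", "60-64", "65-69",
    "70-74", "75-79", "80+",
)

#: canonical stratum order: (sex, age_group), females first, ages ascending
STRATA: tuple[tuple[str, str], ...] = tuple(
    (sex, age) for sex in SEXES for age in AGE_GROUPS
)

N_STRATA = len(STRATA)

# Approximate all-cause death rates per person-year by age group (both
# sexes pooled), Gompertz-like above age 40; the male/female ratio is
# applied on top.  Chosen so the crude rate of the default age structure
# is close to 10 deaths per thousand per year, the order of magnitude of
# European national rates in the 2000s.
_BASE_RATES: dict[str, float] = {
    "00-04": 0.0012, "05-09": 0.00012, "10-14": 0.00015, "15-19": 0.00045,
    "20-24": 0.00055, "25-29": 0.0006, "30-34": 0.0007, "35-39": 0.0010,
    "40-44": 0.0016, "45-49": 0.0025, "50-54": 0.0040, "55-59": 0.0062,
    "60-64": 0.0095, "65-69": 0.0150, "70-74": 0.0240, "75-79": 0.0420,
    "80+": 0.1100,
}

_SEX_FACTOR = {"F": 0.85, "M": 1.15}

# Approximate population shares by age group (fraction of total, both
# sexes pooled; normalized at import).  A mildly aged European pyramid.
_BASE_SHARES: dict[str, float] = {
    "00-04": 0.051, "05-09": 0.052, "10-14": 0.056, "15-19": 0.060,
    "20-24": 0.063, "25-29": 0.067, "30-34": 0.072, "35-39": 0.075,
    "40-44": 0.075, "45-49": 0.070, "50-54": 0.066, "55-59": 0.063,
    "60-64": 0.054, "65-69": 0.050, "70-74": 0.043, "75-79": 0.034,
    "80+": 0.043,
}


def default_rates() -> dict[tuple[str, str], float]:
    """Annual death rate (deaths per person-year) for each stratum."""
    return {
        (sex, age): _BASE_RATES[age] * _SEX_FACTOR[sex] for sex, age in STRATA
    }


def default_shares() -> dict[tuple[str, str], float]:
    """Population share of each stratum (sums to 1 across all 34)."""
    total = sum(_BASE_SHARES.values())
    return {
        (sex, age): 0.5 * _BASE_SHARES[age] / total for sex, age in STRATA
    }
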