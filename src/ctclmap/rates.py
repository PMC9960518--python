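"""Descriptive incidence epidemiology.

Crude and age-specific rates, direct age-standardization to the 2000 US
standard population (19 age groups) with gamma confidence intervals
(Fay-Feuer construction, the registry convention), SES quartile assignment,
and count/percentage tabulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: The 19 age-group labels of the 2000 US standard population.
AGE_GROUPS_19 = (
    "0", "1-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34",
    "35-39", "40-44", "45-49", "50-54", "55-59", "60-64", "65-69",
    "70-74", "75-79", "80-84", "85+",
)


@dataclass(frozen=True)
class StandardPopulation:
    """External standard age distribution used for direct standardization."""

    age_groups: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if len(self.age_groups) != counts.size:
            raise ValueError("age_groups and counts differ in length")
        if np.any(counts <= 0):
            raise ValueError("standard population counts must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def weights(self) -> np.ndarray:
        """Normalized weights (sum to 1)."""
        return self.counts / self.counts.sum()

    @classmethod
    def us2000_19ages(cls) -> "StandardPopulation":
        """The 2000 US Census standard million in 19 age groups."""
        ref = resources.files("ctclmap.data").joinpath(
            "us2000_standard_population_19ages.csv"
        )
        with ref.open() as fh:
            tab = pd.read_csv(fh)
        return cls(
            age_groups=tuple(tab["age_group"].astype(str)),
            counts=tab["standard_population"].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path) -> "StandardPopulation":
        tab = pd.read_csv(path)
        return cls(
            age_groups=tuple(tab["age_group"].astype(str)),
            counts=tab["standard_population"].to_numpy(float),
        )


@dataclass(frozen=True)
class RateEstimate:
    """Incidence rate per ``per`` person-years with a 95% gamma interval."""

    rate: float
    lower: float
    upper: float
    cases: float
    person_years: float
    per: float = 1e5

    def __post_init__(self):
        if not (0.0 <= self.lower <= self.rate <= self.upper):
            raise ValueError(
                f"inconsistent rate interval: {self.lower} <= {self.rate} "
                f"<= {self.upper} violated"
            )


def crude_rate(
    cases: float, person_years: float, per: float = 1e5, level: float = 0.95
) -> RateEstimate:
    """Crude rate with an exact Poisson (gamma) confidence interval.

    The gamma interval for a single Poisson count ``c`` observed over ``n``
    person-years is ``[qgamma(a/2; c, 1), qgamma(1-a/2; c+1, 1)] / n``,
    equivalently chi-square quantiles; the lower bound is 0 when ``c = 0``.
    """
    if person_years <= 0:
        raise ValueError(f"person_years must be positive, got {person_years}")
    if cases < 0:
        raise ValueError("cases must be nonnegative")
    alpha = 1.0 - level
    lower = (
        0.0 if cases == 0 else stats.gamma.ppf(alpha / 2, a=cases, scale=1.0)
    )
    upper = stats.gamma.ppf(1 - alpha / 2, a=cases + 1, scale=1.0)
    scale = per / person_years
    return RateEstimate(
        rate=cases * scale,
        lower=lower * scale,
        upper=upper * scale,
        cases=cases,
        person_years=person_years,
        per=per,
    )


def direct_standardized_rate(
    age_specific: pd.DataFrame,
    standard: StandardPopulation,
    per: float = 1e5,
    level: float = 0.95,
) -> RateEstimate:
    """Directly age-standardized rate with a Fay-Feuer gamma interval.

    ``age_specific`` needs columns ``age_group``, ``cases``, ``person_years``,
    one row per age group, covering the standard's groups exactly. The point
    estimate is the weighted mean of age-specific rates with the standard's
    normalized weights; the interval is the gamma interval for weighted sums
    of Poisson counts.
    """
    tab = age_specific.set_index(age_specific["age_group"].astype(str))
    missing = [g for g in standard.age_groups if g not in tab.index]
    if missing:
        raise ValueError(f"age group(s) missing from data: {missing}")
    extra = [g for g in tab.index if g not in set(standard.age_groups)]
    if extra:
        raise ValueError(f"age group(s) not in the standard: {extra}")
    tab = tab.loc[list(standard.age_groups)]
    cases = tab["cases"].to_numpy(float)
    py = tab["person_years"].to_numpy(float)
    if np.any((py <= 0) & (cases > 0)):
        bad = [g for g, n, c in zip(standard.age_groups, py, cases) if n <= 0 and c > 0]
        raise ValueError(f"zero person-years with nonzero cases in group(s): {bad}")

    w = standard.weights
    # Per-group weight on each count; groups with no person-years and no
    # cases contribute nothing.
    with np.errstate(divide="ignore", invalid="ignore"):
        wn = np.where(py > 0, w / py, 0.0)
    y = float(np.sum(wn * cases))  # standardized rate per 1 person-year
    v = float(np.sum(wn**2 * cases))
    w_max = float(np.max(wn)) if np.any(py > 0) else 0.0

    alpha = 1.0 - level
    if y > 0 and v > 0:
        lower = stats.gamma.ppf(alpha / 2, a=y**2 / v, scale=v / y)
    else:
        lower = 0.0
    y_up = y + w_max
    v_up = v + w_max**2
    if y_up > 0 and v_up > 0:
        upper = stats.gamma.ppf(1 - alpha / 2, a=y_up**2 / v_up, scale=v_up / y_up)
    else:
        upper = 0.0
    return RateEstimate(
        rate=y * per,
        lower=lower * per,
        upper=upper * per,
        cases=float(cases.sum()),
        person_years=float(py.sum()),
        per=per,
    )


QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def assign_quartiles(
    tract_values: pd.Series,
    method: str = "case-weighted",
    case_counts: pd.Series | None = None,
) -> pd.Series:
    """Assign tracts to quartiles Q1 (lowest values) .. Q4 (highest values).

    Labels always follow value order — for income Q4 is richest, for a
    poverty percentage Q4 is the poorest exposure; mapping to display
    vocabulary ("Very High income", "High poverty") is the caller's concern.

    method='tract' places cutpoints at the 25/50/75% quantiles of the tract
    values; method='case-weighted' places them at case-count-weighted
    quantiles, so roughly a quarter of *cases* falls in each quartile. A tied
    value sitting exactly on a cutpoint goes to the lower quartile.
    """
    values = tract_values.astype(float)
    if values.isna().any():
        raise ValueError(
            f"missing SES values for tract(s): {list(values.index[values.isna()])}"
        )
    if values.nunique() == 1:
        raise ValueError("all tract values identical; quartiles undefined")

    probs = np.array([0.25, 0.5, 0.75])
    if method == "tract":
        cuts = np.quantile(values.to_numpy(), probs)
    elif method == "case-weighted":
        if case_counts is None:
            raise ValueError("case-weighted method requires case_counts")
        cc = case_counts.reindex(values.index).fillna(0.0).to_numpy(float)
        order = np.argsort(values.to_numpy(), kind="stable")
        v_sorted = values.to_numpy()[order]
        cum = np.cumsum(cc[order])
        if cum[-1] <= 0:
            raise ValueError("case_counts sum to zero")
        cdf = cum / cum[-1]
        cuts = np.array([v_sorted[np.searchsorted(cdf, p, side="left")] for p in probs])
    else:
        raise ValueError(f"unknown quartile method: {method!r}")

    # number of cutpoints strictly below the value -> 0..3; ties at a
    # cutpoint fall to the lower quartile
    idx = np.searchsorted(cuts, values.to_numpy(), side="left")
    labels = np.asarray(QUARTILE_LABELS)[idx]
    return pd.Series(labels, index=values.index, name="quartile")


def age_specific_table(
    counts: pd.DataFrame, per: float = 1e5, level: float = 0.95
) -> pd.DataFrame:
    """Age-specific case counts, percentages, and crude rates (Table-1 style)."""
    agg = counts.groupby("age_group", observed=True)[["cases", "person_years"]].sum()
    agg = agg.reindex([g for g in AGE_GROUPS_19 if g in agg.index])
    total = agg["cases"].sum()
    rows = []
    for age, rec in agg.iterrows():
        est = crude_rate(rec["cases"], rec["person_years"], per=per, level=level)
        rows.append(
            {
                "level": age,
                "n": rec["cases"],
                "percent": 100.0 * rec["cases"] / total if total else 0.0,
                "rate": est.rate,
                "ci_low": est.lower,
                "ci_high": est.upper,
            }
        )
    return pd.DataFrame(rows)


def age_adjusted_rates_by(
    counts: pd.DataFrame,
    factor: str,
    standard: StandardPopulation,
    per: float = 1e5,
    level: float = 0.95,
) -> pd.DataFrame:
    """Directly age-adjusted rate per level of a factor (Table-2 style).

    Each level's cases and person-years are aggregated over the 19 age
    groups and standardized to ``standard``; ``percent`` is the level's
    share of all cases in the table.
    """
    total = counts["cases"].sum()
    rows = []
    for lvl, sub in counts.groupby(factor, observed=True):
        agg = (
            sub.groupby("age_group", observed=True)[["cases", "person_years"]]
            .sum()
            .reindex(standard.age_groups, fill_value=0.0)
            .reset_index()
            .rename(columns={"index": "age_group"})
        )
        est = direct_standardized_rate(agg, standard, per=per, level=level)
        rows.append(
            {
                "level": lvl,
                "n": sub["cases"].sum(),
                "percent": 100.0 * sub["cases"].sum() / total if total else 0.0,
                "rate": est.rate,
                "ci_low": est.lower,
                "ci_high": est.upper,
            }
        )
    return pd.DataFrame(rows)


def tabulate(
    case_table: pd.DataFrame,
    by: Sequence[str] | str,
    cases_col: str | None = None,
    exclude: Mapping[str, Sequence] | None = None,
) -> pd.DataFrame:
    """Counts and percentages by one or more factors.

    ``case_table`` is either one row per case or a stratified count table
    (then ``cases_col`` names the count column). ``exclude`` drops listed
    levels of a factor from the analytic total before percentages are taken
    (e.g. cases of "Other" race with no matching population denominator).
    Percentages are 100 * n / analytic total, unrounded.
    """
    if isinstance(by, str):
        by = [by]
    tab = case_table.copy()
    if exclude:
        for factor, levels in exclude.items():
            tab = tab[~tab[factor].isin(list(levels))]
    if cases_col is None:
        grouped = tab.groupby(list(by), observed=True).size().rename("n")
    else:
        grouped = tab.groupby(list(by), observed=True)[cases_col].sum().rename("n")
    out = grouped.reset_index()
    total = out["n"].sum()
    out["percent"] = 100.0 * out["n"] / total if total > 0 else 0.0
    return out
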