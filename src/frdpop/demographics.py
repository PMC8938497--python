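"""Demographic comparison of city and suburb dog populations.

Works from sighting records: unadjusted 2x2 odds ratios (city vs suburb by a
binary attribute) with Woolf log-method confidence intervals, and a Pearson
goodness-of-fit chi-square for where dogs are observed within the city.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import LOCATION_CATEGORIES, as_frame


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts laid out as exposure rows (city, suburb) x outcome columns
    (level of interest, reference): a=city/interest, b=city/reference,
    c=suburb/interest, d=suburb/reference."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if isinstance(v, bool) or not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty (grand total 0)")


@dataclass(frozen=True)
class OddsRatioResult:
    or_point: float
    ci_low: float
    ci_high: float
    method: str  # "woolf" or "woolf_haldane_corrected"


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def odds_ratio_2x2(table: ContingencyTable2x2, z: float = 1.96) -> OddsRatioResult:
    """Odds ratio (a*d)/(b*c) with a Woolf log-scale confidence interval.

    A zero cell makes the OR or its variance undefined; then 0.5 is added to
    every cell (Haldane-Anscombe) and the method is flagged accordingly.  A
    zero margin (an empty row or column) leaves the odds undefined and is an
    error.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    for total, label in [
        (a + b, "city row"),
        (c + d, "suburb row"),
        (a + c, "interest column"),
        (b + d, "reference column"),
    ]:
        if total == 0:
            raise ValueError(f"odds ratio undefined: {label} total is 0")
    method = "woolf"
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "woolf_haldane_corrected"
    or_point = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_point)
    return OddsRatioResult(
        or_point=float(or_point),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        method=method,
    )


def chisq_goodness_of_fit(
    observed: Sequence[float], expected_proportions: Sequence[float]
) -> ChiSquareResult:
    """Pearson chi-square of observed counts against expected proportions."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected_proportions must have the same length")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"expected proportions must sum to 1, got {props.sum()!r}")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be positive")
    expected = total * props
    if np.any((expected == 0) & (obs > 0)):
        raise ValueError("expected count of 0 with nonzero observed count")
    keep = expected > 0
    stat, p = stats.chisquare(obs[keep], f_exp=expected[keep], ddof=0)
    df = int(obs.size - 1)
    # scipy uses df = k_kept - 1; recompute p for the full category count
    p = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    return ChiSquareResult(statistic=float(stat), df=df, p_value=p)


def location_distribution(records) -> tuple[pd.Series, ChiSquareResult]:
    """Proportion of sightings per location category and a uniform-null GOF.

    Only the five named within-city categories enter; records with other or
    unknown locations are excluded listwise.
    """
    frame = as_frame(records)
    known = frame[frame["location_category"].isin(LOCATION_CATEGORIES)]
    if known.empty:
        raise ValueError("no records with a known location category")
    counts = (
        known["location_category"].value_counts().reindex(LOCATION_CATEGORIES).fillna(0)
    )
    proportions = counts / counts.sum()
    k = len(LOCATION_CATEGORIES)
    chi = chisq_goodness_of_fit(counts.to_numpy(), np.full(k, 1.0 / k))
    return proportions, chi


# -- building Table-style 2x2 comparisons from raw records -------------------

_COMPARISONS = {
    # variable: (level of interest, reference level)
    "sex": ("female", "male"),
    "age_class": ("adult", "pup_young"),
    "body_condition": ("ideal_overweight", "thin_emaciated"),
}


def table_from_records(records, variable: str, interest: str, reference: str) -> ContingencyTable2x2:
    """City-vs-suburb 2x2 for one binary attribute, unknowns excluded."""
    frame = as_frame(records)
    sub = frame[frame[variable].isin([interest, reference])]
    if sub.empty:
        raise ValueError(f"no records with known {variable}")

    def cell(domain, level):
        return int(((sub["domain"] == domain) & (sub[variable] == level)).sum())

    return ContingencyTable2x2(
        a=cell("city", interest),
        b=cell("city", reference),
        c=cell("suburb", interest),
        d=cell("suburb", reference),
    )


def pregnant_lactating_fraction(records) -> float:
    """Share of female dogs recorded pregnant or lactating, of those with a
    known reproductive status."""
    frame = as_frame(records)
    females = frame[
        (frame["sex"] == "female")
        & frame["female_status"].isin(["pregnant", "lactating", "non_pregnant"])
    ]
    if females.empty:
        raise ValueError("no female records with known reproductive status")
    return float(females["female_status"].isin(["pregnant", "lactating"]).mean())


def demographics_report(records) -> dict:
    """Full city-vs-suburb demographic summary from sighting records."""
    frame = as_frame(records)
    report: dict = {"n_records": int(len(frame))}
    counts: dict = {}
    for variable in ("sex", "age_class", "body_condition", "social_org"):
        counts[variable] = (
            frame.groupby("domain")[variable].value_counts().unstack(fill_value=0).to_dict()
        )
    report["counts"] = counts
    ors: dict = {}
    for variable, (interest, reference) in _COMPARISONS.items():
        try:
            table = table_from_records(frame, variable, interest, reference)
            res = odds_ratio_2x2(table)
        except ValueError:
            continue
        ors[variable] = {
            "interest": interest,
            "reference": reference,
            "table": [table.a, table.b, table.c, table.d],
            "or": round(res.or_point, 1),
            "ci": [round(res.ci_low, 1), round(res.ci_high, 1)],
            "method": res.method,
        }
    report["odds_ratios"] = ors
    try:
        props, chi = location_distribution(frame)
        report["location"] = {
            "proportions_pct": {k: round(100 * v, 1) for k, v in props.items()},
            "chi2": round(chi.statistic, 2),
            "df": chi.df,
            "p_value": chi.p_value,
        }
    except ValueError:
        pass
    try:
        report["pregnant_or_lactating_pct"] = round(
            100 * pregnant_lactating_fraction(frame), 1
        )
    except ValueError:
        pass
    return report
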