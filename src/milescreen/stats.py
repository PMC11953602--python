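"""Summary statistics over evaluation records.

Implements every aggregate the screening study design calls for:
latest-per-child filtering, suggestion distributions, stratified rates,
evaluator concordance (accuracy), domain-level answer distributions, the
birth-quarter (relative-age) analysis, assessments-per-child, and the
finite-population sample-size calculator.

Percentage conventions: stratified tables use the full record count as the
base for every cell (so cells of a table share one denominator) and round
to one decimal; the accuracy rate is reported to two decimals.  Raw counts
and fractions are always emitted alongside rounded percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .kb import LanguageDomain, SuggestionType
from .records import EvaluationRecordSet

__all__ = [
    "AGE_BANDS",
    "age_band",
    "latest_per_child",
    "suggestion_distribution",
    "rate_by",
    "AccuracyResult",
    "accuracy",
    "domain_response_distribution",
    "birth_quarter_analysis",
    "assessments_per_child",
    "SampleSizeSpec",
    "sample_size",
]

#: Age bands matching the three preschool grades (months, inclusive).
AGE_BANDS = (("<=12", 1, 12), ("13-24", 13, 24), ("25-36", 25, 36))


def age_band(age_months: int) -> str:
    """Band an age in completed months into the three preschool grades.

    Ages above 36 months fall into the top band (a handful of enrolled
    children can be marginally older than the grade's nominal range).
    """
    if age_months <= 12:
        return "<=12"
    if age_months <= 24:
        return "13-24"
    return "25-36"


_GROUPERS = {
    "gender": lambda s: s["gender"],
    "center": lambda s: s["center"],
    "age_band": lambda s: s["age_months"].map(age_band),
    "month": lambda s: s["age_months"],
    "severity": lambda s: s["severity_class"],
    "suggestion": lambda s: s["suggestion"],
}


def latest_per_child(records: EvaluationRecordSet) -> EvaluationRecordSet:
    """Keep only each child's most recent assessment.

    Output has exactly one row per distinct child; answers are filtered to
    the retained sessions.
    """
    s = records.sessions.copy()
    s["_date"] = pd.to_datetime(s["evaluation_date"])
    idx = s.groupby("child_id")["_date"].idxmax()
    kept = s.loc[idx].drop(columns="_date").sort_index()
    if len(records.answers):
        key = set(zip(kept["child_id"], kept["evaluation_date"].astype(str)))
        a = records.answers
        mask = [
            (c, str(d)) in key
            for c, d in zip(a["child_id"], a["evaluation_date"].astype(str))
        ]
        answers = a.loc[mask].reset_index(drop=True)
    else:
        answers = records.answers
    return EvaluationRecordSet(sessions=kept.reset_index(drop=True),
                               answers=answers)


def suggestion_distribution(records: EvaluationRecordSet) -> pd.DataFrame:
    """Counts and percentages of each suggestion type.

    Returns a frame indexed by suggestion with columns ``count``,
    ``fraction`` and ``pct`` (one decimal, base = number of records);
    empty input yields an empty frame.
    """
    n = len(records)
    if n == 0:
        return pd.DataFrame(columns=["count", "fraction", "pct"])
    counts = records.sessions["suggestion"].value_counts()
    counts = counts.reindex([s.value for s in SuggestionType], fill_value=0)
    counts = counts[counts > 0] if counts.sum() else counts
    out = pd.DataFrame({"count": counts})
    out["fraction"] = out["count"] / n
    out["pct"] = (out["fraction"] * 100).round(1)
    out.index.name = "suggestion"
    return out


def rate_by(
    records: EvaluationRecordSet,
    by: Union[str, Sequence[str]],
) -> pd.DataFrame:
    """Stratified counts of records by one or more grouping keys.

    Valid keys: ``gender``, ``center``, ``age_band``, ``month``,
    ``severity``, ``suggestion``.  Cell counts conserve the grand total;
    percentages use the full record count as base for every cell.
    """
    keys = [by] if isinstance(by, str) else list(by)
    unknown = [k for k in keys if k not in _GROUPERS]
    if unknown:
        raise KeyError(
            f"unknown grouping key(s) {unknown}; valid: {sorted(_GROUPERS)}")
    n = len(records)
    s = records.sessions
    if n == 0:
        return pd.DataFrame(columns=keys + ["count", "fraction", "pct"])
    frame = pd.DataFrame({k: _GROUPERS[k](s) for k in keys})
    out = (frame.groupby(keys, observed=True).size()
           .rename("count").reset_index())
    out["fraction"] = out["count"] / n
    out["pct"] = (out["fraction"] * 100).round(1)
    assert out["count"].sum() == n, "stratified cells must conserve the total"
    return out


@dataclass(frozen=True)
class AccuracyResult:
    """Evaluator concordance: accepted suggestions over all suggestions."""

    accepted: int
    declined: int

    @property
    def total(self) -> int:
        return self.accepted + self.declined

    @property
    def fraction(self) -> float:
        return self.accepted / self.total

    @property
    def pct(self) -> float:
        """Accuracy as a percentage, two decimals."""
        return round(100 * self.fraction, 2)


def accuracy(
    records: EvaluationRecordSet,
    by: Optional[Union[str, Sequence[str]]] = None,
) -> Union[AccuracyResult, pd.DataFrame]:
    """Proportion of suggestions the evaluator accepted.

    With ``by`` unset, returns an :class:`AccuracyResult` for the whole
    record set.  With ``by`` (e.g. ``"suggestion"``), returns a breakdown
    frame with accepted/declined counts and percentages of the full total
    per cell.
    """
    s = records.sessions
    if len(s) == 0:
        raise ValueError("accuracy undefined for an empty record set")
    if s["accepted"].isna().any():
        raise ValueError("accepted flag missing on some records")
    if by is None:
        acc = int(s["accepted"].sum())
        return AccuracyResult(accepted=acc, declined=len(s) - acc)
    keys = [by] if isinstance(by, str) else list(by)
    unknown = [k for k in keys if k not in _GROUPERS]
    if unknown:
        raise KeyError(f"unknown grouping key(s) {unknown}")
    frame = pd.DataFrame({k: _GROUPERS[k](s) for k in keys})
    frame["accepted"] = s["accepted"].astype(bool).values
    n = len(s)
    g = frame.groupby(keys, observed=True)["accepted"]
    out = pd.DataFrame({
        "accepted": g.sum().astype(int),
        "declined": (g.count() - g.sum()).astype(int),
    }).reset_index()
    out["accepted_pct"] = (100 * out["accepted"] / n).round(1)
    out["declined_pct"] = (100 * out["declined"] / n).round(2)
    return out


def domain_response_distribution(
    records: EvaluationRecordSet,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-age-band, per-domain counts of yes/no/don't-know answers.

    Returns ``(table, warnings)``; warnings flag sensory-reception answers
    recorded outside the first-year band, which a valid KB cannot produce.
    """
    a = records.answers
    if len(a) == 0:
        return (pd.DataFrame(columns=["age_band", "domain", "answer", "count"]),
                [])
    merged = a.merge(
        records.sessions[["child_id", "evaluation_date", "age_months"]],
        on=["child_id", "evaluation_date"], how="left")
    merged["age_band"] = merged["age_months"].map(age_band)
    out = (merged.groupby(["age_band", "domain", "answer"], observed=True)
           .size().rename("count").reset_index())
    assert out["count"].sum() == len(a)
    warnings = []
    bad = merged[(merged["domain"] == LanguageDomain.sensory_reception.value)
                 & (merged["age_months"] > 12)]
    for _, row in bad.iterrows():
        warnings.append(
            f"sensory-reception answer for question {row['question_id']} "
            f"recorded at age {row['age_months']} months (child "
            f"{row['child_id']})")
    return out, warnings


def birth_quarter_analysis(records: EvaluationRecordSet) -> pd.DataFrame:
    """Suggestion distribution by calendar birth quarter within birth year.

    Children in the same class are grouped by birth year; within a year,
    quarter-4 children are the youngest of their class and tend to show
    higher alarm rates purely through relative immaturity.
    """
    s = records.sessions.copy()
    bd = pd.to_datetime(s["birth_date"])
    s["birth_year"] = bd.dt.year
    s["birth_quarter"] = bd.dt.quarter
    out = (s.groupby(["birth_year", "birth_quarter", "suggestion"],
                     observed=True)
           .size().rename("count").reset_index())
    totals = out.groupby(["birth_year", "birth_quarter"])["count"].transform("sum")
    out["fraction"] = out["count"] / totals
    return out


def assessments_per_child(records: EvaluationRecordSet) -> tuple[float, float]:
    """Mean and SD of the number of assessments per child."""
    if len(records) == 0:
        raise ValueError("assessments_per_child undefined for empty records")
    counts = records.sessions.groupby("child_id").size()
    return float(counts.mean()), float(counts.std(ddof=1)) if len(counts) > 1 else 0.0


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the finite-population sample-size formula.

    ``population`` may be ``None`` (or ``inf``) for the infinite-population
    limit, in which case no finite-population correction applies.
    """

    population: Optional[float]
    prevalence: float
    z: float = 1.96
    margin: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie strictly between 0 and 1")
        if self.margin <= 0:
            raise ValueError("margin of error must be positive")
        if self.z <= 0:
            raise ValueError("z quantile must be positive")
        if self.population is not None and self.population < 1:
            raise ValueError("population must be >= 1")


def sample_size(spec: SampleSizeSpec) -> int:
    """Minimum sample size for estimating a prevalence, with FPC.

    Computes n0 = z^2 p (1-p) / e^2, then applies the finite-population
    correction n = n0 / (1 + (n0 - 1)/N), and returns the ceiling.  The
    correction never increases n; as N grows, n approaches n0.
    """
    p, z, e = spec.prevalence, spec.z, spec.margin
    n0 = z * z * p * (1 - p) / (e * e)
    N = spec.population
    if N is None or math.isinf(N):
        return math.ceil(n0)
    n = n0 / (1 + (n0 - 1) / N)
    return math.ceil(n)
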