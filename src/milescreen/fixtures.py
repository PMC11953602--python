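"""Packaged study tables and a maximum-agreement record reconstruction.

The field study's child-level data are not deposited; what is printed are
aggregate tables: the cohort composition, the distribution of final
suggestions, severity by gender, the alarm month/centre/gender matrix,
control-information outcomes, evaluator acceptance by suggestion type, and
the decline reasons.  This module ships those tables as packaged CSV/JSON
files (checksummed), validates their internal consistency at load time,
and reconstructs a synthetic 270-row evaluation record set whose marginals
reproduce every encoded table exactly.

The reconstructed child-level rows are **synthetic**: cells no printed
table pins down (which individual child carries which month, evaluation
dates, the per-question answers) are filled by a deterministic greedy
allocator under a seed.  They support exercising and testing the
statistics layer; they are not the study's real data.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .kb import LanguageDomain, SuggestionType
from .records import ANSWER_COLUMNS, SESSION_COLUMNS, EvaluationRecordSet
from .records import suggestion_severity
from .stats import age_band

__all__ = ["StudyFixture", "FixtureConsistencyError",
           "InfeasibleMarginalsError", "load_fixture", "reconstruct_records"]

_DATA_FILES = [
    "table_cohort.csv", "table_suggestions.csv", "table_gender.csv",
    "table_alarms_by_month.csv", "table_control.csv", "table_acceptance.csv",
    "table_decline_reasons.csv", "constants.json",
]


class FixtureConsistencyError(ValueError):
    """The packaged tables disagree with each other or were tampered with."""


class InfeasibleMarginalsError(ValueError):
    """The encoded tables admit no child-level record set."""


@dataclass(frozen=True)
class StudyFixture:
    """The encoded printed tables plus scalar constants."""

    cohort: pd.DataFrame           # centre x gender x age-band head counts
    suggestions: pd.DataFrame      # final-suggestion distribution (latest)
    gender: pd.DataFrame           # severity x gender counts (latest)
    alarms: pd.DataFrame           # alarm counts by centre x gender x month
    control: pd.DataFrame          # control-information outcome counts
    acceptance: pd.DataFrame       # accepted/declined by suggestion (all rows)
    decline_reasons: pd.DataFrame  # individual decline justifications
    constants: dict

    @property
    def n_children(self) -> int:
        return int(self.constants["distinct_children"])

    @property
    def n_assessments(self) -> int:
        return int(self.constants["total_assessments"])


def _read_packaged(name: str, base: Optional[Path] = None) -> bytes:
    if base is not None:
        return (base / name).read_bytes()
    return (resources.files("milescreen") / "data" / name).read_bytes()


def load_fixture(base: Optional[Union[str, Path]] = None) -> StudyFixture:
    """Load the packaged tables, verifying checksums and consistency.

    ``base`` overrides the packaged data directory (used to load edited
    copies in tests); checksum verification is skipped then, consistency
    checks are not.
    """
    base_path = Path(base) if base is not None else None
    raw = {name: _read_packaged(name, base_path) for name in _DATA_FILES}

    if base_path is None:
        manifest = json.loads(_read_packaged("manifest.json"))
        for name, digest in manifest["files"].items():
            actual = hashlib.sha256(raw[name]).hexdigest()
            if actual != digest:
                raise FixtureConsistencyError(
                    f"checksum mismatch for packaged file {name}")

    import io

    def csv(name: str) -> pd.DataFrame:
        return pd.read_csv(io.BytesIO(raw[name]))

    fx = StudyFixture(
        cohort=csv("table_cohort.csv"),
        suggestions=csv("table_suggestions.csv"),
        gender=csv("table_gender.csv"),
        alarms=csv("table_alarms_by_month.csv"),
        control=csv("table_control.csv"),
        acceptance=csv("table_acceptance.csv"),
        decline_reasons=csv("table_decline_reasons.csv"),
        constants=json.loads(raw["constants.json"]),
    )
    _check_consistency(fx)
    return fx


def _check_consistency(fx: StudyFixture) -> None:
    errors: list[str] = []
    n_children = fx.n_children
    n_assessments = fx.n_assessments

    if fx.cohort["count"].sum() != n_children:
        errors.append("cohort table head counts do not sum to the child total")
    if fx.suggestions["count"].sum() != n_children:
        errors.append("final-suggestion counts do not sum to the child total")
    if fx.gender["count"].sum() != n_children:
        errors.append("gender-severity counts do not sum to the child total")

    refer = int(fx.suggestions.set_index("suggestion").loc[
        SuggestionType.refer_early_intervention.value, "count"])
    gender_alarms = int(
        fx.gender.loc[fx.gender["severity"] == "alarm", "count"].sum())
    if gender_alarms != refer:
        errors.append(
            f"gender-table alarms ({gender_alarms}) != referral count ({refer})")
    if int(fx.alarms["count"].sum()) != refer:
        errors.append(
            f"alarm month matrix sums to {int(fx.alarms['count'].sum())}, "
            f"expected {refer}")

    warn_total = int(
        fx.gender.loc[fx.gender["severity"] == "warning", "count"].sum())
    repeats = int(fx.suggestions.loc[
        fx.suggestions["suggestion"].str.startswith("repeat"), "count"].sum())
    if warn_total != repeats:
        errors.append("gender-table warnings != repeat-suggestion count")

    acc = fx.acceptance
    if int((acc["accepted"] + acc["declined"]).sum()) != n_assessments:
        errors.append("acceptance table does not sum to the assessment total")
    if int(acc["declined"].sum()) != int(fx.constants["declined"]):
        errors.append("declined count disagrees with constants")
    if int(acc["accepted"].sum()) != int(fx.constants["accepted"]):
        errors.append("accepted count disagrees with constants")
    if len(fx.decline_reasons) != int(acc["declined"].sum()):
        errors.append("decline reasons do not match the declined count")
    reason_counts = fx.decline_reasons.groupby("suggestion").size()
    for _, row in acc.iterrows():
        if int(row["declined"]) != int(reason_counts.get(row["suggestion"], 0)):
            errors.append(
                f"decline reasons for {row['suggestion']} disagree with the "
                f"acceptance table")

    # every suggestion's all-assessment count must cover its latest count
    latest = fx.suggestions.set_index("suggestion")["count"]
    full = acc.set_index("suggestion")
    for sug, n_latest in latest.items():
        total = int(full.loc[sug, "accepted"] + full.loc[sug, "declined"])
        if total < n_latest:
            errors.append(
                f"{sug}: {total} assessments overall but {n_latest} finals")

    m18 = int(fx.alarms.loc[fx.alarms["month"] == 18, "count"].sum())
    if m18 != int(fx.constants["month18_alarms"]):
        errors.append("month-18 alarms disagree between matrix and constants")
    m24 = int(fx.alarms.loc[fx.alarms["month"] == 24, "count"].sum())
    if m24 != int(fx.constants["month24_alarms"]):
        errors.append("month-24 alarms disagree between matrix and constants")

    if errors:
        raise FixtureConsistencyError("; ".join(errors))


# ---------------------------------------------------------------------------
# Record reconstruction
# ---------------------------------------------------------------------------

_REPEATS = [SuggestionType.repeat_3mo, SuggestionType.repeat_2mo,
            SuggestionType.repeat_1mo]

_BAND_MONTHS = {"<=12": list(range(6, 13)),
                "13-24": list(range(13, 25)),
                "25-36": list(range(25, 37))}


def _largest_remainder(total: int, weights: list[int]) -> list[int]:
    """Split ``total`` across items proportionally to ``weights``."""
    s = sum(weights)
    if s == 0:
        return [0] * len(weights)
    raw = [total * w / s for w in weights]
    base = [int(x) for x in raw]
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i],
                   reverse=True)
    for i in order[: total - sum(base)]:
        base[i] += 1
    return base


def reconstruct_records(fx: StudyFixture, seed: int = 0) -> EvaluationRecordSet:
    """Build a synthetic record set whose marginals reproduce the tables.

    Deterministic under ``seed`` and idempotent.  Alarm children take their
    centre, gender and month straight from the alarm matrix; warning and
    typical children are allocated greedily to centres and age bands so the
    cohort cross-tabulation holds where the tables pin it; declined rows
    are matched to the individual decline reasons; the assessments beyond
    each child's final one are attached to non-typical children first.
    Raises :class:`InfeasibleMarginalsError` when the tables conflict.
    """
    rng = np.random.default_rng(seed)
    consts = fx.constants

    # remaining capacity per (center, gender, band) from the cohort table
    capacity: dict[tuple[str, str, str], int] = {
        (r["center"], r["gender"], r["band"]): int(r["count"])
        for _, r in fx.cohort.iterrows()}

    children: list[dict] = []  # gender, center, age, suggestion, declined, reason

    def take_capacity(center: str, gender: str, band: str, what: str) -> None:
        key = (center, gender, band)
        if capacity.get(key, 0) <= 0:
            raise InfeasibleMarginalsError(
                f"cohort table has no remaining capacity for {what} in "
                f"cell {key} (alarm matrix or constants conflict with the "
                f"cohort table)")
        capacity[key] -= 1

    # --- 1. alarm children straight from the month matrix ----------------
    for _, row in fx.alarms.iterrows():
        for _ in range(int(row["count"])):
            take_capacity(row["center"], row["gender"],
                          age_band(int(row["month"])), "an alarm child")
            children.append({
                "gender": row["gender"], "center": row["center"],
                "age": int(row["month"]),
                "suggestion": SuggestionType.refer_early_intervention,
                "declined": False, "reason": ""})

    # match individual refer declines to alarm children by gender and month
    for _, row in fx.decline_reasons.iterrows():
        if row["suggestion"] != SuggestionType.refer_early_intervention.value:
            continue
        match = next(
            (c for c in children
             if c["suggestion"] is SuggestionType.refer_early_intervention
             and c["gender"] == row["gender"] and c["age"] == int(row["month"])
             and not c["declined"]), None)
        if match is None:
            raise InfeasibleMarginalsError(
                f"decline reason for a {row['gender']} referral at month "
                f"{row['month']} matches no alarm-matrix cell")
        match["declined"] = True
        match["reason"] = row["reason"]

    # --- 2. per-gender warning split across repeat types ------------------
    repeat_counts = [int(fx.suggestions.set_index("suggestion")
                         .loc[s.value, "count"]) for s in _REPEATS]
    female_warn = int(fx.gender.set_index(["gender", "severity"])
                      .loc[("female", "warning"), "count"])
    female_split = _largest_remainder(female_warn, repeat_counts)
    male_split = [c - f for c, f in zip(repeat_counts, female_split)]
    if any(m < 0 for m in male_split):
        raise InfeasibleMarginalsError(
            "gender warning totals cannot be split across repeat types")

    typical_by_gender = {
        g: int(fx.gender.set_index(["gender", "severity"])
               .loc[(g, "none"), "count"]) for g in ("female", "male")}

    # pending non-alarm children per gender: list of suggestion types
    pending: dict[str, list[SuggestionType]] = {}
    for gender, split in (("female", female_split), ("male", male_split)):
        lst: list[SuggestionType] = []
        for s, k in zip(_REPEATS, split):
            lst.extend([s] * k)
        lst.extend([SuggestionType.typical_development]
                   * typical_by_gender[gender])
        pending[gender] = lst

    def pop_pending(gender: str, suggestion: SuggestionType, what: str
                    ) -> SuggestionType:
        try:
            pending[gender].remove(suggestion)
        except ValueError:
            raise InfeasibleMarginalsError(
                f"no remaining {suggestion.value} slot for a {gender} child "
                f"({what})") from None
        return suggestion

    def place_special(gender: str, suggestion: SuggestionType, month: int,
                      declined: bool, reason: str, what: str) -> None:
        pop_pending(gender, suggestion, what)
        band = age_band(month)
        for center in ("nursery_school", "psychopedagogical_center"):
            if capacity.get((center, gender, band), 0) > 0:
                capacity[(center, gender, band)] -= 1
                children.append({
                    "gender": gender, "center": center, "age": month,
                    "suggestion": suggestion, "declined": declined,
                    "reason": reason})
                return
        raise InfeasibleMarginalsError(
            f"no cohort capacity for {what} ({gender}, month {month})")

    # --- 3. non-alarm declines pinned by the decline-reason table ---------
    for _, row in fx.decline_reasons.iterrows():
        sug = SuggestionType(row["suggestion"])
        if sug is SuggestionType.refer_early_intervention:
            continue
        place_special(row["gender"], sug, int(row["month"]), True,
                      row["reason"], "a declined repeat suggestion")

    # --- 4. filler finals pinning the month-18 / month-24 denominators ----
    for month_key in (18, 24):
        want = int(consts[f"month{month_key}_evaluations"])
        have = sum(1 for c in children if c["age"] == month_key)
        genders = ["male", "female"]
        for j in range(want - have):
            gender = genders[j % 2]
            if SuggestionType.typical_development not in pending[gender]:
                gender = genders[(j + 1) % 2]
            place_special(gender, SuggestionType.typical_development,
                          month_key, False, "",
                          f"a month-{month_key} denominator filler")

    # --- 5. remaining non-alarm children: centre then band ----------------
    pinned_months = {18, 24}
    for gender in ("female", "male"):
        lst = pending[gender]
        order = rng.permutation(len(lst))
        for suggestion in (lst[int(k)] for k in order):
            placed = False
            for center in ("psychopedagogical_center", "nursery_school"):
                bands = [b for b in _BAND_MONTHS
                         if capacity.get((center, gender, b), 0) > 0]
                if not bands:
                    continue
                band = bands[int(rng.integers(len(bands)))]
                months = [m for m in _BAND_MONTHS[band]
                          if m not in pinned_months]
                age = int(months[int(rng.integers(len(months)))])
                capacity[(center, gender, band)] -= 1
                children.append({
                    "gender": gender, "center": center, "age": age,
                    "suggestion": suggestion, "declined": False, "reason": ""})
                placed = True
                break
            if not placed:
                raise InfeasibleMarginalsError(
                    f"no cohort capacity left for a {gender} "
                    f"{suggestion.value} child")
        pending[gender] = []

    if sum(capacity.values()) != 0:
        raise InfeasibleMarginalsError(
            "cohort table capacity not exhausted: the suggestion and cohort "
            "tables disagree on the child total")

    # --- 6. extra (non-final) assessments ---------------------------------
    extra_pool: list[SuggestionType] = []
    latest = fx.suggestions.set_index("suggestion")["count"]
    for _, row in fx.acceptance.iterrows():
        total = int(row["accepted"] + row["declined"])
        extra = total - int(latest.get(row["suggestion"], 0))
        extra_pool.extend([SuggestionType(row["suggestion"])] * extra)
    if len(extra_pool) != fx.n_assessments - fx.n_children:
        raise InfeasibleMarginalsError(
            "acceptance vs final-suggestion tables disagree on the number "
            "of non-final assessments")

    severity_rank = {
        SuggestionType.refer_early_intervention: 0,
        SuggestionType.repeat_1mo: 1, SuggestionType.repeat_2mo: 2,
        SuggestionType.repeat_3mo: 3, SuggestionType.typical_development: 4}
    recipients = sorted(range(len(children)),
                        key=lambda i: (severity_rank[children[i]["suggestion"]], i))
    if len(extra_pool) > len(children):
        raise InfeasibleMarginalsError(
            "more non-final assessments than children at one extra "
            "assessment per child")
    extras: dict[int, SuggestionType] = {
        i: s for i, s in zip(recipients, extra_pool)}

    # --- 7. materialize rows ----------------------------------------------
    session_rows: list[dict] = []
    answer_rows: list[dict] = []
    for i, child in enumerate(children):
        child_id = f"fx{i + 1:04d}"
        has_extra = i in extras
        if has_extra:
            final_date = dt.date(2023, 6, 1) + dt.timedelta(
                days=int(rng.integers(0, 25)))
        else:
            final_date = dt.date(2023, 3, 1) + dt.timedelta(
                days=int(rng.integers(0, 110)))
        birth = _birth_for_age(final_date, child["age"], rng)
        base = {
            "child_id": child_id, "center": child["center"],
            "gender": child["gender"], "birth_date": birth.isoformat()}
        session_rows.append({
            **base,
            "evaluation_date": final_date.isoformat(),
            "age_months": child["age"],
            "suggestion": child["suggestion"].value,
            "severity_class": suggestion_severity(child["suggestion"]),
            "accepted": not child["declined"],
            "decline_reason": child["reason"],
        })
        answer_rows.extend(_synthetic_answers(
            child_id, final_date, child["age"], child["suggestion"], rng))
        if has_extra:
            prev_date = final_date - dt.timedelta(days=61)
            prev_age = max(1, child["age"] - 2)
            prev_sug = extras[i]
            session_rows.append({
                **base,
                "evaluation_date": prev_date.isoformat(),
                "age_months": prev_age,
                "suggestion": prev_sug.value,
                "severity_class": suggestion_severity(prev_sug),
                "accepted": True,
                "decline_reason": "",
            })
            answer_rows.extend(_synthetic_answers(
                child_id, prev_date, prev_age, prev_sug, rng))

    out = EvaluationRecordSet(
        sessions=pd.DataFrame(session_rows, columns=SESSION_COLUMNS),
        answers=pd.DataFrame(answer_rows, columns=ANSWER_COLUMNS))

    assert len(out) == fx.n_assessments
    assert out.n_children == fx.n_children
    return out


def _birth_for_age(ref: dt.date, age: int, rng: np.random.Generator) -> dt.date:
    month = ref.month - 1 - age
    year = ref.year + month // 12
    month = month % 12 + 1
    day = min(ref.day, 28)
    jitter = int(rng.integers(0, day))
    return dt.date(year, month, day - jitter)


_FAIL_COUNTS = {
    SuggestionType.typical_development: 0,
    SuggestionType.repeat_3mo: 1,
    SuggestionType.repeat_2mo: 2,
    SuggestionType.repeat_1mo: 3,
    SuggestionType.refer_early_intervention: 1,
}


def _synthetic_answers(child_id: str, date: dt.date, age: int,
                       suggestion: SuggestionType,
                       rng: np.random.Generator) -> list[dict]:
    """Per-question rows consistent with the session's suggestion.

    Synthetic filler: question identities and domains are invented (first
    question is sensory-reception for first-year children, mirroring the
    hearing check), only the failure pattern is forced by the suggestion.
    """
    n_fail = _FAIL_COUNTS[suggestion]
    alarm_fail = suggestion is SuggestionType.refer_early_intervention
    n_questions = max(4, n_fail + 2)
    domains = [LanguageDomain.language_perception, LanguageDomain.production,
               LanguageDomain.pragmatics]
    sensory_first = age <= 12  # first-year sessions open with a hearing item
    fail_slots = set(range(n_questions - n_fail, n_questions))
    rows = []
    for j in range(n_questions):
        if j == 0 and sensory_first:
            domain = LanguageDomain.sensory_reception
        else:
            domain = domains[int(rng.integers(len(domains)))]
        failed = j in fail_slots
        # the referral is triggered by exactly one failed alarm-class item
        qclass = ("alarm" if (alarm_fail and j == n_questions - n_fail)
                  else "warning")
        rows.append({
            "child_id": child_id,
            "evaluation_date": date.isoformat(),
            "question_id": f"fxq-{domain.value[:4]}-{int(rng.integers(900)) + 100}",
            "domain": domain.value,
            "question_class": qclass,
            "answer": "no" if failed else "yes",
        })
    return rows
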