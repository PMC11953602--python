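"""Adaptive screening sessions: question selection, decision rule, reports.

One session evaluates one child at their current age in completed months.
The form combines the age-month's questions with any question the child
failed at the previous session that is still inside its applicability
window.  Answers are yes / no / don't-know; the decision rule maps failures
to a graded suggestion: any failed *alarm* item means direct referral,
otherwise the number of failed *warning* items selects a repeat interval
(more failures, sooner follow-up), and no failures means typical
development.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
from typing import Optional, Sequence, Union

from pydantic import BaseModel, Field, model_validator

from .kb import (
    KnowledgeBase,
    MonthOutOfRangeError,
    Question,
    SeverityClass,
    SuggestionType,
    questions_for_month,
)

__all__ = [
    "Answer",
    "Gender",
    "Center",
    "BirthComplication",
    "ChildProfile",
    "DecisionPolicy",
    "SuggestionResult",
    "ScreeningSession",
    "IncompleteSessionError",
    "age_in_months",
    "select_questions",
    "decide",
    "record_evaluator_response",
    "render_report",
]


class Answer(str, enum.Enum):
    """Evaluator's response to one question."""

    yes = "yes"
    no = "no"
    dk = "dk"  # do not know / no answer


class Gender(str, enum.Enum):
    female = "female"
    male = "male"


class Center(str, enum.Enum):
    """Recruiting centre: a nursery school (children with no prior concern)
    or a psychopedagogical centre (children with suspected NDD)."""

    nursery_school = "nursery_school"
    psychopedagogical_center = "psychopedagogical_center"


class BirthComplication(str, enum.Enum):
    prenatal = "prenatal"
    perinatal = "perinatal"
    preterm = "preterm"


#: Gestational age below which a birth counts as preterm (weeks).
PRETERM_WEEK_THRESHOLD = 37.0


class ChildProfile(BaseModel):
    """Demographics and control data for one screened child.

    ``child_id`` must be a random, non-identifying token.  Control data
    (gestation, birth complications, family history of neurodevelopmental
    disorder, bilingual context) is collected as baseline information; the
    default decision policy does not alter suggestions on it.
    """

    child_id: str
    birth_date: dt.date
    gender: Gender
    center: Center
    gestational_weeks: Optional[float] = Field(default=None, gt=0)
    birth_complications: set[BirthComplication] = Field(default_factory=set)
    family_history_ndd: Optional[bool] = None
    bilingual: Optional[bool] = None

    @model_validator(mode="after")
    def _derive_preterm(self) -> "ChildProfile":
        if (self.gestational_weeks is not None
                and self.gestational_weeks < PRETERM_WEEK_THRESHOLD):
            self.birth_complications = set(self.birth_complications) | {
                BirthComplication.preterm}
        return self


class DecisionPolicy(BaseModel):
    """Configurable mapping from answer failures to a suggestion.

    ``warning_ladder`` maps a warning-failure count to a repeat interval;
    counts at or above the largest key use its interval.  The default ladder
    is 1 failure -> repeat in 3 months, 2 -> 2 months, >=3 -> 1 month.
    ``dk_counts_as_fail`` controls whether don't-know answers count toward
    the failure tally (default: they never do — missing observation never
    escalates).
    """

    warning_ladder: dict[int, SuggestionType] = Field(
        default_factory=lambda: {
            1: SuggestionType.repeat_3mo,
            2: SuggestionType.repeat_2mo,
            3: SuggestionType.repeat_1mo,
        })
    dk_counts_as_fail: bool = False

    @model_validator(mode="after")
    def _ladder_ok(self) -> "DecisionPolicy":
        if not self.warning_ladder:
            raise ValueError("warning_ladder may not be empty")
        for k, v in self.warning_ladder.items():
            if k < 1:
                raise ValueError("ladder keys are failure counts >= 1")
            if v.repeat_interval_months is None:
                raise ValueError("ladder values must be repeat suggestions")
        return self

    def repeat_suggestion(self, n_warning_failures: int) -> SuggestionType:
        assert n_warning_failures >= 1
        keys = sorted(self.warning_ladder)
        applicable = [k for k in keys if k <= n_warning_failures]
        return self.warning_ladder[applicable[-1] if applicable else keys[0]]


class SuggestionResult(BaseModel):
    """Outcome of one decided session."""

    type: SuggestionType
    triggered_by: list[str] = Field(default_factory=list)
    low_information: bool = False

    @property
    def severity_class(self) -> str:
        """'none' for typical development, 'alarm' for referral,
        'warning' for the repeat suggestions."""
        if self.type is SuggestionType.typical_development:
            return "none"
        if self.type is SuggestionType.refer_early_intervention:
            return "alarm"
        return "warning"


class IncompleteSessionError(ValueError):
    """Decision requested while asked questions are still unanswered."""


class ScreeningSession(BaseModel):
    """One evaluation of one child on one date."""

    child_id: str
    evaluation_date: dt.date
    age_months: int = Field(ge=0)
    asked: list[str] = Field(default_factory=list)
    answers: dict[str, Answer] = Field(default_factory=dict)
    suggestion: Optional[SuggestionResult] = None
    evaluator_accepted: Optional[bool] = None
    decline_reason: str = ""

    @model_validator(mode="after")
    def _consistent(self) -> "ScreeningSession":
        extra = set(self.answers) - set(self.asked)
        if extra:
            raise ValueError(f"answers for questions never asked: {sorted(extra)}")
        if self.evaluator_accepted is False and not self.decline_reason.strip():
            raise ValueError("a declined suggestion requires a decline reason")
        return self

    @property
    def complete(self) -> bool:
        return set(self.asked) <= set(self.answers)

    def failed_question_ids(self) -> list[str]:
        return [qid for qid in self.asked
                if self.answers.get(qid) is Answer.no]


def age_in_months(birth_date: dt.date, evaluation_date: dt.date) -> int:
    """Completed calendar months between birth and evaluation (floor)."""
    if evaluation_date < birth_date:
        raise ValueError(
            f"evaluation date {evaluation_date} precedes birth date {birth_date}")
    months = ((evaluation_date.year - birth_date.year) * 12
              + evaluation_date.month - birth_date.month)
    if evaluation_date.day < birth_date.day:
        months -= 1
    return months


def select_questions(
    kb: KnowledgeBase,
    child: ChildProfile,
    evaluation_date: dt.date,
    history: Sequence[ScreeningSession] = (),
) -> list[str]:
    """Choose the question ids for a session, adapting to age and history.

    The base form is the age-month's node.  Questions answered "no" in the
    child's most recent prior session are re-asked when the current age is
    still inside their applicability window.  Month-node order comes first;
    carried-over items follow in their prior order; duplicates collapse.
    """
    age = age_in_months(child.birth_date, evaluation_date)
    if not kb.covers(age):
        raise MonthOutOfRangeError(
            f"child aged {age} months outside KB coverage "
            f"{list(kb.coverage_range)}")
    selected = [q.id for q in questions_for_month(kb, age)]
    if history:
        last = max(history, key=lambda s: s.evaluation_date)
        for qid in last.failed_question_ids():
            q = kb.questions.get(qid)
            if q is not None and age in q.applicable_months and qid not in selected:
                selected.append(qid)
    return selected


def decide(
    kb: KnowledgeBase,
    session: ScreeningSession,
    policy: DecisionPolicy | None = None,
) -> SuggestionResult:
    """Apply the warning/alarm decision rule to a completed session.

    Any alarm-class question answered "no" forces referral.  Otherwise the
    count of warning-class "no" answers walks the policy's repeat ladder;
    zero failures means typical development.  Don't-know answers never count
    under the default policy; a session answered entirely with don't-know is
    flagged ``low_information``.
    """
    policy = policy or DecisionPolicy()
    unanswered = [qid for qid in session.asked if qid not in session.answers]
    if unanswered:
        raise IncompleteSessionError(
            f"unanswered questions: {sorted(unanswered)}")

    alarm_fails: list[str] = []
    warning_fails: list[str] = []
    informative = 0
    for qid in session.asked:
        q = kb.questions[qid]
        ans = session.answers[qid]
        if ans is not Answer.dk:
            informative += 1
        failed = ans is Answer.no or (
            ans is Answer.dk and policy.dk_counts_as_fail)
        if not failed:
            continue
        if q.severity_class is SeverityClass.alarm:
            alarm_fails.append(qid)
        else:
            warning_fails.append(qid)

    low_info = bool(session.asked) and informative == 0
    if alarm_fails:
        return SuggestionResult(
            type=SuggestionType.refer_early_intervention,
            triggered_by=alarm_fails + warning_fails,
            low_information=low_info)
    if warning_fails:
        return SuggestionResult(
            type=policy.repeat_suggestion(len(warning_fails)),
            triggered_by=list(warning_fails),
            low_information=low_info)
    return SuggestionResult(type=SuggestionType.typical_development,
                            low_information=low_info)


def record_evaluator_response(
    session: ScreeningSession,
    accepted: bool,
    reason: str = "",
) -> ScreeningSession:
    """Record whether the evaluator accepted the suggestion.

    Declining requires a non-empty justification.
    """
    if session.suggestion is None:
        raise ValueError("cannot record concordance before a suggestion exists")
    if not accepted and not reason.strip():
        raise ValueError("a declined suggestion requires a written reason")
    return session.model_copy(update={
        "evaluator_accepted": accepted,
        "decline_reason": reason.strip() if not accepted else "",
    })


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _follow_up_date(evaluation_date: dt.date, months: int) -> dt.date:
    month = evaluation_date.month - 1 + months
    year = evaluation_date.year + month // 12
    month = month % 12 + 1
    # clamp day into the target month
    for day in (evaluation_date.day, 30, 29, 28):
        try:
            return dt.date(year, month, day)
        except ValueError:
            continue
    raise AssertionError("unreachable")


def render_report(
    child: ChildProfile,
    session: ScreeningSession,
    kb: KnowledgeBase,
    fmt: str = "markdown",
) -> Union[str, dict]:
    """Render the psychopedagogical screening report for a finalized session.

    Contains the profile and control-data summary, each question with its
    domain and answer, per-domain pass/fail tallies, the suggestion with its
    severity, and the follow-up date for repeat outcomes.  ``fmt`` is
    ``"markdown"`` or ``"json"`` (the JSON form returns a dict).
    """
    if session.suggestion is None or not session.complete:
        raise ValueError("report requires a completed, decided session")

    rows = []
    domain_tally: dict[str, dict[str, int]] = {}
    for qid in session.asked:
        q = kb.questions[qid]
        ans = session.answers[qid]
        rows.append({"question_id": qid, "text": q.text,
                     "domain": q.domain.value,
                     "severity_class": q.severity_class.value,
                     "answer": ans.value})
        tally = domain_tally.setdefault(
            q.domain.value, {"yes": 0, "no": 0, "dk": 0})
        tally[ans.value] += 1

    suggestion = session.suggestion
    interval = suggestion.type.repeat_interval_months
    follow_up = (_follow_up_date(session.evaluation_date, interval)
                 if interval else None)

    doc = {
        "child": {
            "child_id": child.child_id,
            "gender": child.gender.value,
            "center": child.center.value,
            "age_months": session.age_months,
            "gestational_weeks": child.gestational_weeks,
            "birth_complications": sorted(
                c.value for c in child.birth_complications),
            "family_history_ndd": child.family_history_ndd,
            "bilingual": child.bilingual,
        },
        "evaluation_date": session.evaluation_date.isoformat(),
        "questions": rows,
        "domain_tally": domain_tally,
        "suggestion": {
            "type": suggestion.type.value,
            "severity_class": suggestion.severity_class,
            "triggered_by": suggestion.triggered_by,
            "low_information": suggestion.low_information,
        },
        "follow_up_date": follow_up.isoformat() if follow_up else None,
        "evaluator_accepted": session.evaluator_accepted,
        "decline_reason": session.decline_reason or None,
    }
    if fmt == "json":
        return doc
    if fmt != "markdown":
        raise ValueError(f"unknown report format {fmt!r}")

    lines = [
        f"# Screening report — child {child.child_id}",
        "",
        f"- Evaluation date: {doc['evaluation_date']}",
        f"- Age: {session.age_months} completed months",
        f"- Gender: {child.gender.value}; centre: {child.center.value}",
        f"- Gestational weeks: {child.gestational_weeks}",
        f"- Birth complications: "
        f"{', '.join(doc['child']['birth_complications']) or 'none reported'}",
        f"- Family history of NDD: {child.family_history_ndd}",
        f"- Bilingual context: {child.bilingual}",
        "",
        "## Questions",
        "",
        "| Question | Domain | Class | Answer |",
        "|---|---|---|---|",
    ]
    for r in rows:
        lines.append(f"| {r['text']} | {r['domain']} | "
                     f"{r['severity_class']} | {r['answer']} |")
    lines += ["", "## Domain summary", ""]
    for domain, tally in domain_tally.items():
        lines.append(f"- {domain}: {tally['yes']} yes, {tally['no']} no, "
                     f"{tally['dk']} don't-know")
    lines += [
        "",
        "## Suggestion",
        "",
        f"- Outcome: **{suggestion.type.value}** "
        f"(severity: {suggestion.severity_class})",
    ]
    if suggestion.triggered_by:
        lines.append(f"- Triggered by: {', '.join(suggestion.triggered_by)}")
    if suggestion.low_information:
        lines.append("- Note: all answers were don't-know — low information.")
    if follow_up:
        lines.append(f"- Follow-up assessment due: {follow_up.isoformat()}")
    if session.evaluator_accepted is not None:
        lines.append(
            f"- Evaluator accepted: {session.evaluator_accepted}"
            + (f" (reason: {session.decline_reason})"
               if session.decline_reason else ""))
    return "\n".join(lines) + "\n"


def session_to_json(session: ScreeningSession) -> str:
    """Serialize one session to the structured JSON dialect."""
    return json.dumps(session.model_dump(mode="json"), indent=2) + "\n"


def session_from_json(text: str) -> ScreeningSession:
    return ScreeningSession.model_validate(json.loads(text))
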