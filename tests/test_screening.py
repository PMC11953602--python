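"""Session flow: age computation, adaptive selection, the decision rule."""

import datetime as dt
import itertools

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from milescreen.kb import SeverityClass, SuggestionType
from milescreen.screening import (
    Answer,
    ChildProfile,
    DecisionPolicy,
    IncompleteSessionError,
    ScreeningSession,
    age_in_months,
    decide,
    record_evaluator_response,
    render_report,
    select_questions,
)
from milescreen.kb import MonthOutOfRangeError


@pytest.mark.parametrize("birth, eval_, expected", [
    (dt.date(2021, 3, 10), dt.date(2021, 10, 10), 7),
    (dt.date(2021, 3, 11), dt.date(2021, 10, 10), 6),
    (dt.date(2021, 1, 31), dt.date(2021, 2, 28), 0),
    (dt.date(2020, 6, 1), dt.date(2023, 6, 1), 36),
])
def test_age_in_completed_months(birth, eval_, expected):
    assert age_in_months(birth, eval_) == expected


def test_age_rejects_reversed_dates():
    with pytest.raises(ValueError):
        age_in_months(dt.date(2021, 3, 10), dt.date(2021, 3, 9))


def _session(kb_month_ids, answers, date=dt.date(2023, 3, 15), age=12):
    return ScreeningSession(
        child_id="c1", evaluation_date=date, age_months=age,
        asked=list(kb_month_ids),
        answers={q: a for q, a in zip(kb_month_ids, answers)})


class TestSelectQuestions:
    def _child(self, age, ref=dt.date(2023, 3, 15)):
        month = ref.month - 1 - age
        birth = dt.date(ref.year + month // 12, month % 12 + 1, ref.day)
        return ChildProfile(child_id="k", birth_date=birth, gender="female",
                            center="nursery_school")

    def test_no_history_gives_month_node(self, mixed_kb):
        child = self._child(12)
        asked = select_questions(mixed_kb, child, dt.date(2023, 3, 15))
        assert asked == ["s1", "s2", "s3"]

    def test_prior_failure_reappears_when_still_applicable(self, mixed_kb):
        child = self._child(14)
        prior = _session(["s1", "s2", "s3"],
                         [Answer.no, Answer.yes, Answer.yes], age=12,
                         date=dt.date(2023, 1, 15))
        asked = select_questions(mixed_kb, child, dt.date(2023, 3, 15),
                                 history=[prior])
        # s1 is already on the month-14 node; it appears once
        assert asked.count("s1") == 1
        # a failure outside its window (s2 only applies at 12) is dropped
        assert "s2" not in asked

    def test_prior_failure_outside_month_node_is_appended(self, mixed_kb):
        child = self._child(13)
        prior = _session(["s1", "s2", "s3"],
                         [Answer.no, Answer.yes, Answer.yes], age=12,
                         date=dt.date(2023, 2, 15))
        asked = select_questions(mixed_kb, child, dt.date(2023, 3, 15),
                                 history=[prior])
        assert asked[:3] == ["t1", "t2", "t3"]
        # s1 applies at 12 and 14 but not 13
        assert "s1" not in asked

    def test_clean_history_gives_exactly_month_node(self, mixed_kb):
        child = self._child(14)
        prior = _session(["s1", "s2", "s3"],
                         [Answer.yes, Answer.yes, Answer.yes], age=12,
                         date=dt.date(2023, 1, 15))
        asked = select_questions(mixed_kb, child, dt.date(2023, 3, 15),
                                 history=[prior])
        assert asked == ["u1", "u2", "u3", "s1"]

    def test_age_outside_coverage_rejected(self, mixed_kb):
        child = self._child(20)
        with pytest.raises(MonthOutOfRangeError):
            select_questions(mixed_kb, child, dt.date(2023, 3, 15))


class TestDecide:
    def test_all_yes_is_typical(self, mixed_kb):
        s = _session(["s1", "s2", "s3"], [Answer.yes] * 3)
        result = decide(mixed_kb, s)
        assert result.type is SuggestionType.typical_development
        assert result.severity_class == "none"
        assert result.triggered_by == []

    def test_single_alarm_failure_forces_referral(self, mixed_kb):
        s = _session(["s1", "s2", "s3"], [Answer.yes, Answer.yes, Answer.no])
        result = decide(mixed_kb, s)  # s3 is alarm-class
        assert result.type is SuggestionType.refer_early_intervention
        assert result.severity_class == "alarm"
        assert "s3" in result.triggered_by

    def test_two_warning_failures_repeat_in_two_months(self, mixed_kb):
        s = _session(["u1", "u2", "u3", "s1"],
                     [Answer.no, Answer.yes, Answer.no, Answer.yes], age=14)
        assert decide(mixed_kb, s).type is SuggestionType.repeat_2mo

    def test_all_dk_is_typical_but_low_information(self, mixed_kb):
        s = _session(["s1", "s2", "s3"], [Answer.dk] * 3)
        result = decide(mixed_kb, s)
        assert result.type is SuggestionType.typical_development
        assert result.low_information

    def test_dk_counts_when_policy_says_so(self, mixed_kb):
        s = _session(["s1", "s2", "s3"], [Answer.dk, Answer.dk, Answer.yes])
        policy = DecisionPolicy(dk_counts_as_fail=True)
        assert decide(mixed_kb, s, policy).type is SuggestionType.repeat_2mo

    def test_incomplete_session_rejected(self, mixed_kb):
        s = ScreeningSession(child_id="c1",
                             evaluation_date=dt.date(2023, 3, 15),
                             age_months=12, asked=["s1", "s2", "s3"],
                             answers={"s1": Answer.yes})
        with pytest.raises(IncompleteSessionError):
            decide(mixed_kb, s)


def _oracle(questions, answers, dk_counts=False):
    """Independent brute-force restatement of the decision table."""
    fails = [q for q, a in zip(questions, answers)
             if a is Answer.no or (a is Answer.dk and dk_counts)]
    if any(q.severity_class is SeverityClass.alarm for q in fails):
        return SuggestionType.refer_early_intervention
    w = sum(1 for q in fails if q.severity_class is SeverityClass.warning)
    return {0: SuggestionType.typical_development,
            1: SuggestionType.repeat_3mo,
            2: SuggestionType.repeat_2mo}.get(w, SuggestionType.repeat_1mo)


@pytest.mark.parametrize("dk_counts", [False, True])
def test_decide_matches_exhaustive_enumeration(mixed_kb, dk_counts):
    """All 3^k answer vectors on every month node with k <= 4 questions."""
    policy = DecisionPolicy(dk_counts_as_fail=dk_counts)
    for month, node in mixed_kb.months.items():
        qs = [mixed_kb.questions[qid] for qid in node.question_ids]
        assert len(qs) <= 4
        for vector in itertools.product(list(Answer), repeat=len(qs)):
            s = _session(node.question_ids, vector, age=month)
            got = decide(mixed_kb, s, policy).type
            assert got is _oracle(qs, vector, dk_counts), \
                f"month {month}, answers {[a.value for a in vector]}"


@settings(max_examples=200, deadline=None, derandomize=True,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(data=st.data())
def test_flipping_no_to_yes_never_raises_severity(mixed_kb, data):
    month = data.draw(st.sampled_from(sorted(mixed_kb.months)))
    node = mixed_kb.months[month]
    vector = data.draw(st.lists(st.sampled_from(list(Answer)),
                                min_size=len(node.question_ids),
                                max_size=len(node.question_ids)))
    before = decide(mixed_kb, _session(node.question_ids, vector, age=month))
    for i, a in enumerate(vector):
        if a is not Answer.no:
            continue
        improved = list(vector)
        improved[i] = Answer.yes
        after = decide(mixed_kb,
                       _session(node.question_ids, improved, age=month))
        assert after.type <= before.type


class TestEvaluatorResponse:
    def _decided(self, mixed_kb):
        s = _session(["s1", "s2", "s3"], [Answer.yes, Answer.no, Answer.yes])
        return s.model_copy(update={"suggestion": decide(mixed_kb, s)})

    def test_accept(self, mixed_kb):
        s = record_evaluator_response(self._decided(mixed_kb), True)
        assert s.evaluator_accepted is True
        assert s.decline_reason == ""

    def test_decline_stores_reason(self, mixed_kb):
        reason = "questions do not align with developmental stage"
        s = record_evaluator_response(self._decided(mixed_kb), False, reason)
        assert s.evaluator_accepted is False
        assert s.decline_reason == reason

    def test_decline_without_reason_rejected(self, mixed_kb):
        with pytest.raises(ValueError):
            record_evaluator_response(self._decided(mixed_kb), False, "  ")

    def test_response_before_suggestion_rejected(self, mixed_kb):
        s = _session(["s1", "s2", "s3"], [Answer.yes] * 3)
        with pytest.raises(ValueError):
            record_evaluator_response(s, True)


class TestReport:
    def _finalized(self, kb, ids, answers, age=14):
        s = _session(ids, answers, age=age)
        return s.model_copy(update={"suggestion": decide(kb, s)})

    def test_repeat_follow_up_date(self, mixed_kb, child):
        s = self._finalized(mixed_kb, ["u1", "u2", "u3", "s1"],
                            [Answer.no, Answer.yes, Answer.no, Answer.yes])
        doc = render_report(child, s, mixed_kb, fmt="json")
        assert doc["suggestion"]["type"] == "repeat_2mo"
        assert doc["follow_up_date"] == "2023-05-15"

    def test_refer_report_flags_alarm_and_trigger(self, mixed_kb, child):
        s = self._finalized(mixed_kb, ["s1", "s2", "s3"],
                            [Answer.yes, Answer.yes, Answer.no], age=12)
        text = render_report(child, s, mixed_kb)
        assert "refer_early_intervention" in text
        assert "alarm" in text
        assert "s3" in text

    def test_report_lists_one_row_per_question(self, mixed_kb, child):
        s = self._finalized(mixed_kb, ["u1", "u2", "u3", "s1"],
                            [Answer.yes] * 4)
        doc = render_report(child, s, mixed_kb, fmt="json")
        assert len(doc["questions"]) == 4
        assert doc["follow_up_date"] is None

    def test_pending_session_rejected(self, mixed_kb, child):
        s = _session(["s1", "s2", "s3"], [Answer.yes] * 3)
        with pytest.raises(ValueError):
            render_report(child, s, mixed_kb)


def test_preterm_flag_derived_from_gestation():
    p = ChildProfile(child_id="x", birth_date=dt.date(2022, 5, 1),
                     gender="male", center="psychopedagogical_center",
                     gestational_weeks=35.0)
    assert any(c.value == "preterm" for c in p.birth_complications)
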