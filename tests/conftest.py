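import datetime as dt

import pytest

from milescreen.kb import (
    KnowledgeBase,
    LanguageDomain,
    MonthNode,
    Question,
    SeverityClass,
)
from milescreen.screening import Center, ChildProfile, Gender
from milescreen.simulate import KbGenConfig, gen_kb
from milescreen.fixtures import load_fixture, reconstruct_records


def make_kb(spec, coverage=None):
    """Build a small KB from {month: [(qid, domain, months, severity), ...]}.

    Quotas are derived from the question list so the KB validates.
    """
    questions = {}
    months = {}
    for month, entries in spec.items():
        ids = []
        for qid, domain, applicable, severity in entries:
            if qid not in questions:
                questions[qid] = Question(
                    id=qid, text=f"toy item {qid}", domain=domain,
                    applicable_months=list(applicable),
                    severity_class=severity)
            ids.append(qid)
        months[month] = MonthNode(month=month, question_ids=ids)
    quotas = {d: 0 for d in LanguageDomain}
    for q in questions.values():
        quotas[q.domain] += 1
    if coverage is None:
        coverage = (min(months), max(months))
    return KnowledgeBase(coverage_range=coverage, quotas=quotas,
                         questions=questions, months=months)


@pytest.fixture
def toy_kb():
    """Two months, three single-month warning questions each."""
    W = SeverityClass.warning
    P = LanguageDomain.production
    return make_kb({
        1: [("a1", LanguageDomain.sensory_reception, [1], W),
            ("a2", P, [1], W), ("a3", LanguageDomain.pragmatics, [1], W)],
        2: [("b1", P, [2], W), ("b2", P, [2], W),
            ("b3", LanguageDomain.language_perception, [2], W)],
    })


@pytest.fixture
def mixed_kb():
    """Months 12 and 14 with a shared question and an alarm item."""
    W, A = SeverityClass.warning, SeverityClass.alarm
    P = LanguageDomain.production
    L = LanguageDomain.language_perception
    G = LanguageDomain.pragmatics
    return make_kb({
        12: [("s1", P, [12, 14], W), ("s2", L, [12], W),
             ("s3", G, [12], A)],
        13: [("t1", P, [13], W), ("t2", L, [13], W), ("t3", G, [13], W)],
        14: [("u1", P, [14], W), ("u2", L, [14], A),
             ("u3", G, [14], W), ("s1", P, [12, 14], W)],
    }, coverage=(12, 14))


@pytest.fixture(scope="session")
def synth_kb():
    return gen_kb(KbGenConfig(seed=7))


@pytest.fixture(scope="session")
def study_fixture():
    return load_fixture()


@pytest.fixture(scope="session")
def study_records(study_fixture):
    return reconstruct_records(study_fixture, seed=0)


@pytest.fixture
def child():
    return ChildProfile(
        child_id="test-child", birth_date=dt.date(2022, 1, 10),
        gender=Gender.female, center=Center.nursery_school,
        gestational_weeks=39.0)
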