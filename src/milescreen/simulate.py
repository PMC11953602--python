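"""Synthetic knowledge bases and child cohorts.

The real screening content and the study's child-level data are not
published, so everything downstream is exercised against synthetic
stand-ins: a KB generator that emits valid milestone graphs with the
documented shape (coverage, 3-6 questions per month, per-domain quotas,
first-year-only hearing items, multi-month links), and a cohort generator
that reproduces the study's demographic composition exactly by stratified
assignment while drawing latent abilities at random.

The answer model is a one-parameter-per-child logistic (item-response
style) curve: a child with latent ability theta answers "yes" to question
q at age t with probability

    P(yes) = logistic(a * (t - m_q + b) + theta - delta * impaired)

where m_q is the first month the question is asked, b the attainment lag
(milestones are typically attained about b months before screening probes
them), a the age slope, and delta the developmental shift of impaired
children.  Probabilities increase strictly with age.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .kb import (
    DEFAULT_QUOTAS,
    MAX_QUESTIONS_PER_MONTH,
    MIN_QUESTIONS_PER_MONTH,
    SENSORY_MAX_MONTH,
    KnowledgeBase,
    LanguageDomain,
    MonthNode,
    Question,
    SeverityClass,
    SuggestionType,
    validate_kb,
)
from .records import ANSWER_COLUMNS, SESSION_COLUMNS, EvaluationRecordSet
from .screening import (
    Answer,
    BirthComplication,
    Center,
    ChildProfile,
    DecisionPolicy,
    Gender,
    ScreeningSession,
    age_in_months,
    decide,
    select_questions,
)

__all__ = [
    "KbGenConfig",
    "CohortCell",
    "CohortConfig",
    "Cohort",
    "AbilityModel",
    "gen_kb",
    "gen_cohort",
    "simulate_study",
    "DEFAULT_COHORT_CELLS",
]


# ---------------------------------------------------------------------------
# Knowledge-base generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KbGenConfig:
    """Parameters of the synthetic-KB generator.

    Defaults emulate the documented KB shape: coverage months 1-36, domain
    quotas 3/32/48/25 (108 questions), 3-6 questions per month, a modest
    fraction of alarm-class items, and a quarter of questions linked to
    more than one consecutive month.
    """

    coverage_range: tuple[int, int] = (1, 36)
    quotas: dict[LanguageDomain, int] = field(
        default_factory=lambda: dict(DEFAULT_QUOTAS))
    questions_per_month: tuple[int, int] = (
        MIN_QUESTIONS_PER_MONTH, MAX_QUESTIONS_PER_MONTH)
    alarm_fraction: float = 0.15
    multi_month_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.coverage_range
        if lo < 1 or hi < lo:
            raise ValueError("coverage_range must satisfy 1 <= min <= max")
        qlo, qhi = self.questions_per_month
        if not (MIN_QUESTIONS_PER_MONTH <= qlo <= qhi <= MAX_QUESTIONS_PER_MONTH):
            raise ValueError(
                f"questions_per_month must lie within "
                f"[{MIN_QUESTIONS_PER_MONTH}, {MAX_QUESTIONS_PER_MONTH}]")
        for frac in (self.alarm_fraction, self.multi_month_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if any(v < 0 for v in self.quotas.values()):
            raise ValueError("quotas must be non-negative")


def gen_kb(config: KbGenConfig | None = None) -> KnowledgeBase:
    """Generate a valid synthetic knowledge base.

    Raises ``ValueError`` when the quotas cannot populate the coverage
    range (fewer questions than 3 per month, more than 6 per month, or
    sensory items with no first-year months to live in).
    """
    config = config or KbGenConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.coverage_range
    months = list(range(lo, hi + 1))
    n_questions = sum(config.quotas.values())
    qlo, qhi = config.questions_per_month

    if n_questions < qlo * len(months):
        raise ValueError(
            f"quotas sum to {n_questions} questions but covering "
            f"{len(months)} months needs at least {qlo * len(months)}")
    if n_questions > MAX_QUESTIONS_PER_MONTH * len(months):
        raise ValueError(
            f"quotas sum to {n_questions} questions but {len(months)} months "
            f"can host at most {MAX_QUESTIONS_PER_MONTH * len(months)}")
    sensory_quota = config.quotas.get(LanguageDomain.sensory_reception, 0)
    sensory_months = [m for m in months if m <= SENSORY_MAX_MONTH]
    if sensory_quota > 0 and not sensory_months:
        raise ValueError(
            "sensory-reception quota > 0 but coverage has no months <= 12")

    def allowed_months(domain: LanguageDomain) -> list[int]:
        return sensory_months if domain is LanguageDomain.sensory_reception \
            else months

    # pool of unplaced questions, shuffled once
    pool: list[LanguageDomain] = []
    for domain in LanguageDomain:
        pool.extend([domain] * config.quotas.get(domain, 0))
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]

    home: dict[int, list[int]] = {m: [] for m in months}  # month -> pool idx
    placed = [False] * len(pool)

    # place the domain-restricted (first-year) items first so they are
    # never stranded once later months have consumed the free pool
    for i, domain in enumerate(pool):
        if domain is not LanguageDomain.sensory_reception:
            continue
        open_m = [m for m in sensory_months
                  if len(home[m]) < MAX_QUESTIONS_PER_MONTH]
        if not open_m:
            raise ValueError("no first-year capacity left for a "
                             "sensory-reception question")
        fewest = min(len(home[m]) for m in open_m)
        m = int(rng.choice([m for m in open_m if len(home[m]) == fewest]))
        placed[i] = True
        home[m].append(i)

    # phase A: give every month its minimum of home questions
    for m in rng.permutation(months):
        while len(home[m]) < qlo:
            eligible = [i for i, d in enumerate(pool)
                        if not placed[i] and m in allowed_months(d)]
            if not eligible:
                raise ValueError(
                    f"cannot satisfy the per-month minimum at month {m}")
            i = int(rng.choice(eligible))
            placed[i] = True
            home[m].append(i)

    # phase B: distribute the remainder wherever capacity remains
    for i, domain in enumerate(pool):
        if placed[i]:
            continue
        open_months = [m for m in allowed_months(domain)
                       if len(home[m]) < MAX_QUESTIONS_PER_MONTH]
        if not open_months:
            raise ValueError(
                f"no remaining capacity for a {domain.value} question")
        m = int(rng.choice(open_months))
        placed[i] = True
        home[m].append(i)

    # materialize questions; extend a fraction to consecutive months
    month_lists: dict[int, list[str]] = {m: [] for m in months}
    ext_into: dict[int, int] = {m: 0 for m in months}  # links beyond home
    questions: dict[str, Question] = {}
    counter = 0
    for m in months:
        for i in home[m]:
            counter += 1
            qid = f"q{counter:03d}"
            domain = pool[i]
            applicable = [m]
            if rng.random() < config.multi_month_fraction:
                nxt = m + 1
                while (nxt in month_lists
                       and nxt in allowed_months(domain)
                       and (len(home[nxt]) + ext_into[nxt]
                            < MAX_QUESTIONS_PER_MONTH)
                       and nxt - m < 3):
                    applicable.append(nxt)
                    ext_into[nxt] += 1
                    if rng.random() >= 0.5:
                        break
                    nxt += 1
            severity = (SeverityClass.alarm
                        if rng.random() < config.alarm_fraction
                        else SeverityClass.warning)
            questions[qid] = Question(
                id=qid,
                text=(f"Synthetic {domain.value.replace('_', ' ')} "
                      f"milestone item {qid} (anchor month {m})"),
                domain=domain,
                applicable_months=applicable,
                severity_class=severity,
            )
            for am in applicable:
                month_lists[am].append(qid)

    kb = KnowledgeBase(
        version=f"synthetic-seed{config.seed}",
        coverage_range=(lo, hi),
        quotas=dict(config.quotas),
        questions=questions,
        months={m: MonthNode(month=m, question_ids=ids)
                for m, ids in month_lists.items()},
    )
    violations = validate_kb(kb)
    assert not violations, f"generator emitted an invalid KB: {violations[:3]}"
    return kb


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortCell:
    """One stratum: centre x gender x age band, with its exact head count."""

    center: Center
    gender: Gender
    band: str  # "<=12", "13-24", "25-36"
    n: int


#: Default composition: the centre x gender x age-band cross-tabulation of
#: the study cohort (218 children; 134 nursery school / 84 psychopedagogical
#: centre; 99 girls / 119 boys; bands 26 / 102 / 84).
DEFAULT_COHORT_CELLS: tuple[CohortCell, ...] = (
    CohortCell(Center.nursery_school, Gender.female, "<=12", 10),
    CohortCell(Center.nursery_school, Gender.female, "13-24", 22),
    CohortCell(Center.nursery_school, Gender.female, "25-36", 31),
    CohortCell(Center.nursery_school, Gender.male, "<=12", 8),
    CohortCell(Center.nursery_school, Gender.male, "13-24", 24),
    CohortCell(Center.nursery_school, Gender.male, "25-36", 39),
    CohortCell(Center.psychopedagogical_center, Gender.female, "<=12", 5),
    CohortCell(Center.psychopedagogical_center, Gender.female, "13-24", 22),
    CohortCell(Center.psychopedagogical_center, Gender.female, "25-36", 9),
    CohortCell(Center.psychopedagogical_center, Gender.male, "<=12", 3),
    CohortCell(Center.psychopedagogical_center, Gender.male, "13-24", 34),
    CohortCell(Center.psychopedagogical_center, Gender.male, "25-36", 11),
)

_BAND_RANGES = {"<=12": (6, 12), "13-24": (13, 24), "25-36": (25, 36)}


@dataclass(frozen=True)
class CohortConfig:
    """Composition of a synthetic cohort.

    Demographics are assigned exactly (stratified assignment, not
    sampling); only abilities, answers, and which children carry risk
    factors are random.  Defaults reproduce the study composition: 218
    children, 8 preterm, 13 with any birth complication, 2 with a family
    history of NDD, 10 bilingual (7 girls + 3 boys, nursery school only).
    """

    cells: tuple[CohortCell, ...] = DEFAULT_COHORT_CELLS
    preterm_count: int = 8
    birth_complication_count: int = 13
    family_history_count: int = 2
    bilingual_female: int = 7
    bilingual_male: int = 3
    impairment_prevalence: float = 0.0
    reference_date: dt.date = dt.date(2023, 3, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.impairment_prevalence <= 1):
            raise ValueError("impairment_prevalence must lie in [0, 1]")
        if any(c.n < 0 for c in self.cells):
            raise ValueError("cell counts must be non-negative")
        if any(c.band not in _BAND_RANGES for c in self.cells):
            raise ValueError(f"bands must be one of {sorted(_BAND_RANGES)}")
        if self.birth_complication_count < self.preterm_count:
            raise ValueError(
                "birth_complication_count must include the preterm count")
        if self.preterm_count > self.n_children:
            raise ValueError("more preterm children than children")

    @property
    def n_children(self) -> int:
        return sum(c.n for c in self.cells)

    @classmethod
    def with_size(cls, n_children: int, **kwargs) -> "CohortConfig":
        """Scale the default composition to ``n_children`` (proportional
        allocation, largest-remainder rounding)."""
        total = sum(c.n for c in DEFAULT_COHORT_CELLS)
        raw = [n_children * c.n / total for c in DEFAULT_COHORT_CELLS]
        base = [int(x) for x in raw]
        rem = n_children - sum(base)
        order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i],
                       reverse=True)
        for i in order[:rem]:
            base[i] += 1
        cells = tuple(dataclasses.replace(c, n=b)
                      for c, b in zip(DEFAULT_COHORT_CELLS, base))
        scale = n_children / total
        defaults = dict(
            preterm_count=round(8 * scale),
            birth_complication_count=max(round(13 * scale), round(8 * scale)),
            family_history_count=round(2 * scale),
            bilingual_female=round(7 * scale),
            bilingual_male=round(3 * scale),
        )
        defaults.update(kwargs)
        return cls(cells=cells, **defaults)


@dataclass
class Cohort:
    """A generated cohort: profiles plus the latent impairment labels."""

    children: list[ChildProfile]
    impaired: dict[str, bool]
    reference_date: dt.date

    def __len__(self) -> int:
        return len(self.children)


def _birth_date_for_age(ref: dt.date, age: int, rng: np.random.Generator) -> dt.date:
    """A birth date giving exactly ``age`` completed months at ``ref``."""
    month = ref.month - 1 - age
    year = ref.year + month // 12
    month = month % 12 + 1
    day = min(ref.day, 28)
    jitter = int(rng.integers(0, day))  # earlier in the month, same age
    return dt.date(year, month, day - jitter)


def gen_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a cohort whose demographic margins match the config exactly.

    Ages are drawn uniformly inside each band; gestational weeks are drawn
    so that exactly ``preterm_count`` children fall below 37 weeks; latent
    impairment labels are Bernoulli(``impairment_prevalence``).
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    children: list[ChildProfile] = []
    impaired: dict[str, bool] = {}

    idx = 0
    for cell in config.cells:
        a_lo, a_hi = _BAND_RANGES[cell.band]
        for _ in range(cell.n):
            idx += 1
            child_id = f"ch{idx:04d}-{rng.integers(16**6):06x}"
            age = int(rng.integers(a_lo, a_hi + 1))
            children.append(ChildProfile(
                child_id=child_id,
                birth_date=_birth_date_for_age(
                    config.reference_date, age, rng),
                gender=cell.gender,
                center=cell.center,
                gestational_weeks=None,
            ))
            impaired[child_id] = bool(rng.random() < config.impairment_prevalence)

    n = len(children)
    if n == 0:
        return Cohort(children=[], impaired={},
                      reference_date=config.reference_date)

    # gestation: exactly preterm_count below the 37-week threshold
    preterm_idx = set(rng.choice(n, size=config.preterm_count, replace=False)
                      .tolist())
    other_complications = config.birth_complication_count - config.preterm_count
    non_preterm = [i for i in range(n) if i not in preterm_idx]
    compl_idx = (rng.choice(len(non_preterm), size=min(other_complications,
                                                       len(non_preterm)),
                            replace=False).tolist()
                 if other_complications and non_preterm else [])
    fh_pool = rng.permutation(n)[:config.family_history_count]

    for i, child in enumerate(children):
        if i in preterm_idx:
            weeks = float(rng.uniform(30.0, 36.9))
        else:
            weeks = float(np.clip(rng.normal(39.5, 1.3), 37.0, 42.0))
        complications = set(child.birth_complications)
        if i in {non_preterm[j] for j in compl_idx}:
            complications.add(BirthComplication.prenatal if rng.random() < 0.5
                              else BirthComplication.perinatal)
        children[i] = child.model_copy(update={
            "gestational_weeks": round(weeks, 1),
            "birth_complications": complications,
            "family_history_ndd": i in set(fh_pool.tolist()),
        })
        # re-run the preterm derivation lost by model_copy
        children[i] = ChildProfile.model_validate(children[i].model_dump())

    # bilingual context is only recorded at the nursery school
    for gender, count in ((Gender.female, config.bilingual_female),
                          (Gender.male, config.bilingual_male)):
        pool = [i for i, c in enumerate(children)
                if c.center is Center.nursery_school and c.gender is gender]
        chosen = set(rng.choice(pool, size=min(count, len(pool)),
                                replace=False).tolist()) if pool else set()
        for i in pool:
            children[i] = children[i].model_copy(
                update={"bilingual": i in chosen})

    return Cohort(children=children, impaired=impaired,
                  reference_date=config.reference_date)


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbilityModel:
    """Latent-ability logistic answer model (see module docstring).

    ``slope`` is the logit gain per month past the expected attainment
    age; ``impairment_shift`` the downward logit shift of impaired
    children; ``attainment_lag`` the number of months before a question's
    first applicable month at which a typically developing child is
    expected to attain the milestone; ``dk_rate`` the probability any
    answer is replaced by don't-know.
    """

    slope: float = 5.0
    impairment_shift: float = 10.0
    attainment_lag: float = 1.0
    dk_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.impairment_shift < 0:
            raise ValueError("impairment_shift must be non-negative")
        if not (0 <= self.dk_rate < 1):
            raise ValueError("dk_rate must lie in [0, 1)")

    def p_yes(self, age_months: float, anchor_month: float, theta: float,
              impaired: bool) -> float:
        x = (self.slope * (age_months - anchor_month + self.attainment_lag)
             + theta - (self.impairment_shift if impaired else 0.0))
        return float(1.0 / (1.0 + np.exp(-x)))


def simulate_study(
    kb: KnowledgeBase,
    cohort: Cohort,
    ability: AbilityModel | None = None,
    policy: DecisionPolicy | None = None,
    accept_model: Optional[dict[SuggestionType, float]] = None,
    max_sessions: int = 2,
    seed: int = 0,
) -> EvaluationRecordSet:
    """Run the full screening workflow over a synthetic cohort.

    Every child is screened once at the cohort's reference date; a repeat
    suggestion triggers one follow-up session after the suggested interval
    while the child remains inside KB coverage and under ``max_sessions``.
    ``accept_model`` maps suggestion types to the probability the evaluator
    declines (default: always accept); declined records carry a placeholder
    reason.  Deterministic under (cohort, seed).
    """
    ability = ability or AbilityModel()
    policy = policy or DecisionPolicy()
    accept_model = accept_model or {}
    rng = np.random.default_rng(seed)

    session_rows: list[dict] = []
    answer_rows: list[dict] = []
    for child in cohort.children:
        theta = float(rng.normal())
        is_impaired = cohort.impaired.get(child.child_id, False)
        eval_date = cohort.reference_date
        history: list[ScreeningSession] = []
        for _ in range(max_sessions):
            age = age_in_months(child.birth_date, eval_date)
            if not kb.covers(age):
                break
            asked = select_questions(kb, child, eval_date, history)
            answers: dict[str, Answer] = {}
            for qid in asked:
                q = kb.questions[qid]
                p = ability.p_yes(age, q.anchor_month, theta, is_impaired)
                ans = Answer.yes if rng.random() < p else Answer.no
                if ability.dk_rate and rng.random() < ability.dk_rate:
                    ans = Answer.dk
                answers[qid] = ans
            session = ScreeningSession(
                child_id=child.child_id, evaluation_date=eval_date,
                age_months=age, asked=asked, answers=answers)
            result = decide(kb, session, policy)
            decline_p = accept_model.get(result.type, 0.0)
            declined = bool(rng.random() < decline_p)
            session_rows.append({
                "child_id": child.child_id,
                "center": child.center.value,
                "gender": child.gender.value,
                "birth_date": child.birth_date.isoformat(),
                "evaluation_date": eval_date.isoformat(),
                "age_months": age,
                "suggestion": result.type.value,
                "severity_class": result.severity_class,
                "accepted": not declined,
                "decline_reason": ("simulated evaluator disagreement"
                                   if declined else ""),
            })
            for qid in asked:
                q = kb.questions[qid]
                answer_rows.append({
                    "child_id": child.child_id,
                    "evaluation_date": eval_date.isoformat(),
                    "question_id": qid,
                    "domain": q.domain.value,
                    "question_class": q.severity_class.value,
                    "answer": answers[qid].value,
                })
            interval = result.type.repeat_interval_months
            if interval is None:
                break
            history.append(session)
            month = eval_date.month - 1 + interval
            eval_date = dt.date(eval_date.year + month // 12, month % 12 + 1,
                                min(eval_date.day, 28))

    sessions = pd.DataFrame(session_rows, columns=SESSION_COLUMNS)
    answers_df = pd.DataFrame(answer_rows, columns=ANSWER_COLUMNS)
    return EvaluationRecordSet(sessions=sessions, answers=answers_df)
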