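"""Milestone knowledge base: the month -> question -> suggestion graph.

The screening content is a closed range of age months (completed months,
1-based).  Each month node carries an ordered list of 3-6 questions; each
question belongs to exactly one of four language domains, may be linked to
several (usually consecutive) months, and is typed either *warning* (a failure
prompts a repeat assessment) or *alarm* (a failure prompts direct referral to
an early-intervention centre).  Sensory-reception questions probe hearing and
are only administered in the first year of life.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

from pydantic import BaseModel, Field, field_validator

__all__ = [
    "LanguageDomain",
    "SeverityClass",
    "SuggestionType",
    "Question",
    "MonthNode",
    "KnowledgeBase",
    "Violation",
    "KBSchemaError",
    "KBValidationError",
    "MonthOutOfRangeError",
    "load_kb",
    "loads_kb",
    "write_kb",
    "dumps_kb",
    "validate_kb",
    "questions_for_month",
    "export_graph",
    "MIN_QUESTIONS_PER_MONTH",
    "MAX_QUESTIONS_PER_MONTH",
    "SENSORY_MAX_MONTH",
    "DEFAULT_QUOTAS",
]

#: Expert rule: an adequate screen asks between 3 and 6 questions per month.
MIN_QUESTIONS_PER_MONTH = 3
MAX_QUESTIONS_PER_MONTH = 6

#: Sensory-reception (hearing) items are confined to the first year of life.
SENSORY_MAX_MONTH = 12


class LanguageDomain(str, enum.Enum):
    """The four assessed areas of speech and language development."""

    sensory_reception = "sensory_reception"
    language_perception = "language_perception"
    production = "production"
    pragmatics = "pragmatics"


#: Default per-domain question quotas (sum = 108).
DEFAULT_QUOTAS: dict[LanguageDomain, int] = {
    LanguageDomain.sensory_reception: 3,
    LanguageDomain.language_perception: 32,
    LanguageDomain.production: 48,
    LanguageDomain.pragmatics: 25,
}


class SeverityClass(str, enum.Enum):
    """Severity type of a question: warning -> repeat, alarm -> refer."""

    warning = "warning"
    alarm = "alarm"


class SuggestionType(str, enum.Enum):
    """Graded screening outcomes, totally ordered by severity.

    ``typical_development`` is the least severe outcome and
    ``refer_early_intervention`` (direct referral to early childhood care)
    the most severe; the three repeat intervals sit in between, a shorter
    interval meaning a more pressing follow-up.
    """

    typical_development = "typical_development"
    repeat_3mo = "repeat_3mo"
    repeat_2mo = "repeat_2mo"
    repeat_1mo = "repeat_1mo"
    refer_early_intervention = "refer_early_intervention"

    @property
    def severity_rank(self) -> int:
        return _SEVERITY_ORDER[self]

    # severity comparisons (override str's lexicographic ordering)
    def __lt__(self, other: object) -> bool:
        if not isinstance(other, SuggestionType):
            return NotImplemented
        return self.severity_rank < other.severity_rank

    def __le__(self, other: object) -> bool:
        if not isinstance(other, SuggestionType):
            return NotImplemented
        return self.severity_rank <= other.severity_rank

    def __gt__(self, other: object) -> bool:
        if not isinstance(other, SuggestionType):
            return NotImplemented
        return self.severity_rank > other.severity_rank

    def __ge__(self, other: object) -> bool:
        if not isinstance(other, SuggestionType):
            return NotImplemented
        return self.severity_rank >= other.severity_rank

    @property
    def repeat_interval_months(self) -> int | None:
        """Follow-up interval in months for repeat outcomes, else ``None``."""
        return _REPEAT_INTERVALS.get(self)


_SEVERITY_ORDER: dict[SuggestionType, int] = {
    SuggestionType.typical_development: 0,
    SuggestionType.repeat_3mo: 1,
    SuggestionType.repeat_2mo: 2,
    SuggestionType.repeat_1mo: 3,
    SuggestionType.refer_early_intervention: 4,
}

_REPEAT_INTERVALS: dict[SuggestionType, int] = {
    SuggestionType.repeat_3mo: 3,
    SuggestionType.repeat_2mo: 2,
    SuggestionType.repeat_1mo: 1,
}


class Question(BaseModel):
    """One milestone screening item.

    Parameters
    ----------
    id
        Stable string key, unique within a knowledge base.
    text
        Human-readable prompt shown to the evaluator.
    domain
        Language domain the item probes.
    applicable_months
        Months (completed, 1-based) at which the item may be asked.  Items
        linked to several months model milestones whose attainment window
        spans more than one month.
    severity_class
        ``warning`` items trigger repeat assessments, ``alarm`` items direct
        referral.
    """

    id: str
    text: str
    domain: LanguageDomain
    applicable_months: list[int] = Field(min_length=1)
    severity_class: SeverityClass

    @field_validator("applicable_months")
    @classmethod
    def _months_positive_sorted(cls, v: list[int]) -> list[int]:
        if any(m < 1 for m in v):
            raise ValueError("applicable_months must be >= 1")
        return sorted(set(v))

    @property
    def anchor_month(self) -> int:
        """Earliest month the question is asked (the milestone's anchor)."""
        return self.applicable_months[0]


class MonthNode(BaseModel):
    """One age-month node with its ordered question list."""

    month: int = Field(ge=1)
    question_ids: list[str]


class KnowledgeBase(BaseModel):
    """The complete screening content for a coverage range of months."""

    version: str = "1"
    coverage_range: tuple[int, int]
    quotas: dict[LanguageDomain, int]
    questions: dict[str, Question]
    months: dict[int, MonthNode]
    milestone_groups: dict[str, list[str]] | None = None

    @field_validator("coverage_range")
    @classmethod
    def _range_ok(cls, v: tuple[int, int]) -> tuple[int, int]:
        lo, hi = v
        if lo < 1 or hi < lo:
            raise ValueError("coverage_range must satisfy 1 <= min <= max")
        return v

    @property
    def n_questions(self) -> int:
        return len(self.questions)

    def covers(self, month: int) -> bool:
        lo, hi = self.coverage_range
        return lo <= month <= hi


@dataclass(frozen=True)
class Violation:
    """A single validation finding: the rule broken and where."""

    rule: str
    location: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.location}: {self.message}"


class KBSchemaError(ValueError):
    """The document does not conform to the knowledge-base schema."""


class KBValidationError(ValueError):
    """A structurally well-formed KB breaks content invariants."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            "knowledge base failed validation:\n"
            + "\n".join(str(v) for v in violations)
        )


class MonthOutOfRangeError(ValueError):
    """A month index outside the KB's coverage range was requested."""


# ---------------------------------------------------------------------------
# Serialization (JSON dialect)
# ---------------------------------------------------------------------------

def _kb_to_document(kb: KnowledgeBase) -> dict:
    doc = {
        "version": kb.version,
        "coverage_range": list(kb.coverage_range),
        "quotas": {d.value: n for d, n in kb.quotas.items()},
        "questions": [
            {
                "id": q.id,
                "text": q.text,
                "domain": q.domain.value,
                "applicable_months": q.applicable_months,
                "severity_class": q.severity_class.value,
            }
            for q in kb.questions.values()
        ],
        "months": [
            {"month": node.month, "question_ids": node.question_ids}
            for node in sorted(kb.months.values(), key=lambda n: n.month)
        ],
    }
    if kb.milestone_groups is not None:
        doc["milestone_groups"] = kb.milestone_groups
    return doc


def dumps_kb(kb: KnowledgeBase) -> str:
    """Serialize a knowledge base to its canonical JSON text."""
    return json.dumps(_kb_to_document(kb), indent=2, sort_keys=False) + "\n"


def write_kb(kb: KnowledgeBase, path: Union[str, Path]) -> None:
    Path(path).write_text(dumps_kb(kb), encoding="utf-8")


def loads_kb(text: str) -> KnowledgeBase:
    """Parse KB JSON text; see :func:`load_kb`."""
    if not text.strip():
        raise KBSchemaError("empty document")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise KBSchemaError(f"not valid JSON: {exc}") from exc
    return _kb_from_document(doc)


def _kb_from_document(doc: object) -> KnowledgeBase:
    if not isinstance(doc, Mapping):
        raise KBSchemaError("top level must be an object")
    missing = {"coverage_range", "quotas", "questions", "months"} - set(doc)
    if missing:
        raise KBSchemaError(f"missing top-level keys: {sorted(missing)}")

    try:
        questions: dict[str, Question] = {}
        for entry in doc["questions"]:
            q = Question(**entry)
            if q.id in questions:
                raise KBSchemaError(f"duplicate question id {q.id!r}")
            questions[q.id] = q
        months: dict[int, MonthNode] = {}
        for entry in doc["months"]:
            node = MonthNode(**entry)
            if node.month in months:
                raise KBSchemaError(f"duplicate month node {node.month}")
            months[node.month] = node
        kb = KnowledgeBase(
            version=str(doc.get("version", "1")),
            coverage_range=tuple(doc["coverage_range"]),
            quotas={LanguageDomain(k): int(v) for k, v in doc["quotas"].items()},
            questions=questions,
            months=months,
            milestone_groups=doc.get("milestone_groups"),
        )
    except KBSchemaError:
        raise
    except (TypeError, ValueError, KeyError) as exc:
        raise KBSchemaError(f"malformed knowledge base document: {exc}") from exc

    for node in kb.months.values():
        for qid in node.question_ids:
            if qid not in kb.questions:
                raise KBSchemaError(
                    f"month {node.month} references undefined question {qid!r}"
                )
    return kb


def load_kb(source: Union[str, Path]) -> KnowledgeBase:
    """Load a knowledge base from a JSON file.

    Raises
    ------
    KBSchemaError
        If the document is empty, malformed, or contains a dangling question
        reference; the error names the offending node.
    """
    return loads_kb(Path(source).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_kb(kb: KnowledgeBase) -> list[Violation]:
    """Check every content invariant; violations are data, not exceptions.

    Rules checked:

    * every month inside the coverage range has a month node;
    * every month node lists between 3 and 6 questions;
    * every listed question id resolves, and the question is applicable at
      that month;
    * question applicability windows lie inside the coverage range;
    * per-domain question counts equal the declared quotas;
    * sensory-reception questions are confined to months 1-12.
    """
    out: list[Violation] = []
    lo, hi = kb.coverage_range

    for month in range(lo, hi + 1):
        if month not in kb.months:
            out.append(Violation(
                "coverage", f"month {month}",
                "month inside coverage range has no month node"))

    for node in sorted(kb.months.values(), key=lambda n: n.month):
        loc = f"month {node.month}"
        if not (lo <= node.month <= hi):
            out.append(Violation("coverage", loc,
                                 "month node outside coverage range"))
            continue
        n = len(node.question_ids)
        if not (MIN_QUESTIONS_PER_MONTH <= n <= MAX_QUESTIONS_PER_MONTH):
            out.append(Violation(
                "questions_per_month", loc,
                f"{n} questions listed; the rule requires "
                f"{MIN_QUESTIONS_PER_MONTH}-{MAX_QUESTIONS_PER_MONTH}"))
        seen: set[str] = set()
        for qid in node.question_ids:
            if qid in seen:
                out.append(Violation("duplicate_listing", loc,
                                     f"question {qid!r} listed twice"))
            seen.add(qid)
            q = kb.questions.get(qid)
            if q is None:
                out.append(Violation("dangling_reference", loc,
                                     f"undefined question id {qid!r}"))
            elif node.month not in q.applicable_months:
                out.append(Violation(
                    "applicability", loc,
                    f"question {qid!r} not applicable at this month"))

    month_index: dict[int, set[str]] = {
        m: set(node.question_ids) for m, node in kb.months.items()
    }
    for q in kb.questions.values():
        loc = f"question {q.id}"
        bad = [m for m in q.applicable_months if not (lo <= m <= hi)]
        if bad:
            out.append(Violation(
                "applicability_range", loc,
                f"applicable months {bad} outside coverage {list(kb.coverage_range)}"))
        if q.domain is LanguageDomain.sensory_reception:
            late = [m for m in q.applicable_months if m > SENSORY_MAX_MONTH]
            if late:
                out.append(Violation(
                    "sensory_window", loc,
                    f"sensory-reception item applicable at months {late} "
                    f"(> {SENSORY_MAX_MONTH})"))
        unlisted = [m for m in q.applicable_months
                    if lo <= m <= hi and q.id not in month_index.get(m, set())]
        if unlisted:
            out.append(Violation(
                "listing", loc,
                f"applicable at months {unlisted} but not listed there"))

    counts = {d: 0 for d in LanguageDomain}
    for q in kb.questions.values():
        counts[q.domain] += 1
    for domain in LanguageDomain:
        declared = kb.quotas.get(domain, 0)
        if counts[domain] != declared:
            out.append(Violation(
                "domain_quota", f"domain {domain.value}",
                f"{counts[domain]} questions present, quota declares {declared}"))
    return out


def questions_for_month(kb: KnowledgeBase, month: int) -> list[Question]:
    """Return the questions of one month node, in KB order.

    A question linked to several months is returned for each of them.
    """
    if not kb.covers(month):
        raise MonthOutOfRangeError(
            f"month {month} outside coverage range {list(kb.coverage_range)}")
    node = kb.months.get(month)
    if node is None:
        raise MonthOutOfRangeError(f"no month node for month {month}")
    return [kb.questions[qid] for qid in node.question_ids]


# ---------------------------------------------------------------------------
# Graph export (Cypher-style CREATE statements)
# ---------------------------------------------------------------------------

def export_graph(kb: KnowledgeBase) -> str:
    """Render the KB as plain-text Cypher-style ``CREATE`` statements.

    One node per month, one per question, one per suggestion type;
    a ``HAS_QUESTION`` edge for each (month, question) link and one
    ``CAN_TRIGGER`` edge per question pointing at the referral node for
    alarm items and at the mildest repeat node for warning items.

    Refuses to export an invalid KB (raises :class:`KBValidationError`).
    """
    violations = validate_kb(kb)
    if violations:
        raise KBValidationError(violations)

    lines: list[str] = []
    for month in sorted(kb.months):
        lines.append(f"CREATE (:Month {{month: {month}}});")
    for q in kb.questions.values():
        lines.append(
            "CREATE (:Question {id: %s, domain: %s, severity: %s});"
            % (_cy(q.id), _cy(q.domain.value), _cy(q.severity_class.value)))
    for s in SuggestionType:
        lines.append(
            "CREATE (:Suggestion {type: %s, rank: %d});"
            % (_cy(s.value), s.severity_rank))
    for month in sorted(kb.months):
        for qid in kb.months[month].question_ids:
            lines.append(
                "MATCH (m:Month {month: %d}), (q:Question {id: %s}) "
                "CREATE (m)-[:HAS_QUESTION]->(q);" % (month, _cy(qid)))
    for q in kb.questions.values():
        target = (SuggestionType.refer_early_intervention
                  if q.severity_class is SeverityClass.alarm
                  else SuggestionType.repeat_3mo)
        lines.append(
            "MATCH (q:Question {id: %s}), (s:Suggestion {type: %s}) "
            "CREATE (q)-[:CAN_TRIGGER]->(s);" % (_cy(q.id), _cy(target.value)))
    return "\n".join(lines) + "\n"


def _cy(value: str) -> str:
    """Quote a string literal for a Cypher statement."""
    return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'


_NODE_RE = re.compile(r"^CREATE \(:(\w+) \{(.+)\}\);$")
_EDGE_RE = re.compile(
    r"^MATCH \((\w+):(\w+) \{(.+?)\}\), \((\w+):(\w+) \{(.+?)\}\) "
    r"CREATE \(\1\)-\[:(\w+)\]->\(\4\);$")


def parse_graph_export(text: str) -> tuple[list[tuple], list[tuple]]:
    """Parse exported statements back into node and edge tuples.

    Returns ``(nodes, edges)`` where nodes are ``(label, properties)`` and
    edges ``(src_label, src_props, rel, dst_label, dst_props)``; used to
    check exports round-trip to the same multiset.
    """
    nodes, edges = [], []
    for line in text.splitlines():
        if not line.strip():
            continue
        m = _NODE_RE.match(line)
        if m:
            nodes.append((m.group(1), m.group(2)))
            continue
        m = _EDGE_RE.match(line)
        if m:
            edges.append((m.group(2), m.group(3), m.group(7),
                          m.group(5), m.group(6)))
            continue
        raise ValueError(f"unparseable statement: {line!r}")
    return nodes, edges
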