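"""Tidy evaluation records: the table every summary statistic consumes.

An :class:`EvaluationRecordSet` holds one row per screening session plus a
long table of per-question answers.  It is the interchange object between
the simulator, the fixture reconstruction, and the statistics layer, and
serializes to plain CSV (one file per table) and JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd

from .kb import SuggestionType

__all__ = ["EvaluationRecordSet", "SESSION_COLUMNS", "ANSWER_COLUMNS",
           "suggestion_severity"]

SESSION_COLUMNS = [
    "child_id", "center", "gender", "birth_date", "evaluation_date",
    "age_months", "suggestion", "severity_class", "accepted",
    "decline_reason",
]

ANSWER_COLUMNS = [
    "child_id", "evaluation_date", "question_id", "domain",
    "question_class", "answer",
]


def suggestion_severity(suggestion: Union[str, SuggestionType]) -> str:
    """Map a suggestion type to its severity class (none/warning/alarm)."""
    s = SuggestionType(suggestion)
    if s is SuggestionType.typical_development:
        return "none"
    if s is SuggestionType.refer_early_intervention:
        return "alarm"
    return "warning"


@dataclass
class EvaluationRecordSet:
    """Sessions plus per-question answers, in tidy form.

    ``sessions`` has one row per (child, evaluation date) with demographics,
    the suggestion, its severity class, and evaluator concordance.
    ``answers`` has one row per answered question with domain labels; it may
    be empty when only session-level statistics are needed.
    """

    sessions: pd.DataFrame
    answers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=ANSWER_COLUMNS))

    def __post_init__(self) -> None:
        missing = set(SESSION_COLUMNS) - set(self.sessions.columns)
        if missing:
            raise ValueError(f"sessions table missing columns: {sorted(missing)}")
        missing = set(ANSWER_COLUMNS) - set(self.answers.columns)
        if missing:
            raise ValueError(f"answers table missing columns: {sorted(missing)}")
        dup = self.sessions.duplicated(["child_id", "evaluation_date"])
        if dup.any():
            raise ValueError("duplicate (child_id, evaluation_date) rows")
        expected = self.sessions["suggestion"].map(suggestion_severity)
        bad = self.sessions.loc[
            expected != self.sessions["severity_class"], "child_id"]
        if len(bad):
            raise ValueError(
                f"severity_class inconsistent with suggestion for "
                f"children {sorted(set(bad))[:5]}")

    def __len__(self) -> int:
        return len(self.sessions)

    @property
    def n_children(self) -> int:
        return self.sessions["child_id"].nunique()

    # -- serialization ----------------------------------------------------

    def to_csv(self, directory: Union[str, Path]) -> None:
        """Write ``sessions.csv`` and ``answers.csv`` into a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.sessions.to_csv(directory / "sessions.csv", index=False)
        self.answers.to_csv(directory / "answers.csv", index=False)

    @classmethod
    def from_csv(cls, directory: Union[str, Path]) -> "EvaluationRecordSet":
        directory = Path(directory)
        sessions = pd.read_csv(
            directory / "sessions.csv",
            dtype={"child_id": str, "decline_reason": str},
            keep_default_na=False, na_values=[""])
        sessions["decline_reason"] = sessions["decline_reason"].fillna("")
        sessions["accepted"] = sessions["accepted"].astype("boolean")
        answers_path = directory / "answers.csv"
        if answers_path.exists() and answers_path.stat().st_size > 0:
            try:
                answers = pd.read_csv(answers_path, dtype={"child_id": str})
            except pd.errors.EmptyDataError:
                answers = pd.DataFrame(columns=ANSWER_COLUMNS)
        else:
            answers = pd.DataFrame(columns=ANSWER_COLUMNS)
        return cls(sessions=sessions, answers=answers)

    def to_json(self) -> str:
        return json.dumps({
            "sessions": self.sessions.to_dict(orient="records"),
            "answers": self.answers.to_dict(orient="records"),
        }, indent=2, default=str) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "EvaluationRecordSet":
        doc = json.loads(text)
        sessions = pd.DataFrame(doc["sessions"], columns=SESSION_COLUMNS)
        answers = pd.DataFrame(doc.get("answers", []), columns=ANSWER_COLUMNS)
        return cls(sessions=sessions, answers=answers)
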