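"""Behavioural rating tables: participant x stimulus x question responses.

The rating design has 11 questions per stimulus: nine 7-point scale
questions — four kinematic (amount of movement, fast movement, vertical
movement, forward/away direction), two postural (contraction, symmetry)
and three emotion-related (intensity, valence, familiarity) — plus two
forced-choice questions (emotion category, action category).
"""

from __future__ import annotations

from dataclasses import dataclass
import pandas as pd

__all__ = [
    "SCALE_QUESTIONS",
    "CATEGORICAL_QUESTIONS",
    "ALL_QUESTIONS",
    "KINEMATIC_POSTURAL_QUESTIONS",
    "RatingTable",
    "IncompleteRatingsError",
]

#: Seven-point scale questions, in presentation order.
SCALE_QUESTIONS = (
    "amount", "fast", "vertical", "forward_away", "contraction", "symmetry",
    "intensity", "valence", "familiarity",
)
#: The six scale questions with computed-feature counterparts.
KINEMATIC_POSTURAL_QUESTIONS = SCALE_QUESTIONS[:6]
#: Forced-choice questions.
CATEGORICAL_QUESTIONS = ("emotion", "action")
ALL_QUESTIONS = SCALE_QUESTIONS + CATEGORICAL_QUESTIONS


class IncompleteRatingsError(ValueError):
    """A participant x stimulus cell is missing for a question."""


@dataclass
class RatingTable:
    """Long-format rating data plus the true emotion of each stimulus.

    ``data`` columns: participant, stimulus_id, question, response.
    Scale responses are floats in [1, 7]; forced-choice responses are
    category strings.
    """

    data: pd.DataFrame
    emotions: pd.Series  # stimulus_id -> true emotion

    def __post_init__(self) -> None:
        required = {"participant", "stimulus_id", "question", "response"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"rating data missing columns {sorted(missing)}")
        unknown = set(self.data["question"]) - set(ALL_QUESTIONS)
        if unknown:
            raise ValueError(f"unknown questions {sorted(unknown)}")

    @property
    def participants(self) -> list:
        return sorted(self.data["participant"].unique())

    @property
    def stimulus_ids(self) -> list[str]:
        return list(self.emotions.index)

    @property
    def questions(self) -> list[str]:
        return [q for q in ALL_QUESTIONS if q in set(self.data["question"])]

    def is_scale(self, question: str) -> bool:
        return question in SCALE_QUESTIONS

    def pivot(self, question: str) -> pd.DataFrame:
        """Participant x stimulus response matrix for one question.

        Raises :class:`IncompleteRatingsError` listing the missing
        participant/stimulus cells; no imputation is performed.
        """
        sub = self.data[self.data["question"] == question]
        wide = sub.pivot_table(
            index="participant", columns="stimulus_id", values="response",
            aggfunc="first",
        )
        wide = wide.reindex(columns=self.stimulus_ids)
        if wide.isna().any().any():
            holes = [
                (p, s)
                for p in wide.index
                for s in wide.columns[wide.loc[p].isna()]
            ]
            raise IncompleteRatingsError(
                f"question {question!r}: missing responses for "
                f"{holes[:10]}{'...' if len(holes) > 10 else ''}"
            )
        if self.is_scale(question):
            return wide.astype(float)
        return wide

    def stimulus_means(self, questions=SCALE_QUESTIONS) -> pd.DataFrame:
        """Stimulus x question matrix of across-participant mean ratings."""
        cols = {q: self.pivot(q).mean(axis=0) for q in questions}
        return pd.DataFrame(cols).loc[self.stimulus_ids]

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df["true_emotion"] = df["stimulus_id"].map(self.emotions)
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        df = pd.read_csv(path, float_precision="round_trip")
        emotions = (
            df.drop_duplicates("stimulus_id")
            .set_index("stimulus_id")["true_emotion"]
        )
        df = df.drop(columns="true_emotion")
        scale = df["question"].isin(SCALE_QUESTIONS)
        df.loc[scale, "response"] = df.loc[scale, "response"].astype(float)
        return cls(df, emotions)
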