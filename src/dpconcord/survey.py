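"""Likert-scale survey aggregation and marginal-matching synthesis.

The survey instrument has 17 questions over three fields — attitude toward
digital sign-out, confidence in using the digital tools, satisfaction with
them — scored 1 (strongly disagree) to 5 (strongly agree) by every rater.
Reported quantities are the per-score proportions and the "very good"
proportion (scores 4-5), with its numerator and denominator.

The per-field question counts default to 4/7/6 (attitude/confidence/
satisfaction).  These are inferred from the published high-score
denominators (68, 119, 102) divided by the 17 raters — exact divisibility
makes the inference compelling, but the split is not stated outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .data_model import ValidationError

__all__ = [
    "FIELDS",
    "LikertResponse",
    "SurveyConfig",
    "FieldAggregate",
    "aggregate",
    "aggregate_all",
    "synthesize_survey",
]

FIELDS: tuple[str, ...] = ("attitude", "confidence", "satisfaction")
_SCORES = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class LikertResponse:
    """One survey answer."""

    participant_id: str
    field: str
    question_id: int
    score: int

    def __post_init__(self) -> None:
        if self.field not in FIELDS:
            raise ValidationError(f"unknown survey field {self.field!r}")
        if self.score not in _SCORES:
            raise ValidationError(
                f"score must be an integer 1-5, got {self.score!r} "
                f"(participant {self.participant_id}, question {self.question_id})"
            )


@dataclass(frozen=True)
class SurveyConfig:
    """Synthesis targets: question counts per field and high-score counts."""

    n_participants: int = 17
    questions_per_field: dict[str, int] = field(
        default_factory=lambda: {"attitude": 4, "confidence": 7, "satisfaction": 6}
    )
    high_counts: dict[str, int] = field(
        default_factory=lambda: {"attitude": 44, "confidence": 75, "satisfaction": 56}
    )
    total_questions: int = 17

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("need at least one participant")
        if set(self.questions_per_field) != set(FIELDS):
            raise ValidationError(f"question counts must cover exactly the fields {FIELDS}")
        total = sum(self.questions_per_field.values())
        if total != self.total_questions:
            raise ValidationError(
                f"the survey has {self.total_questions} questions; "
                f"per-field counts sum to {total}"
            )
        for f in FIELDS:
            denom = self.questions_per_field[f] * self.n_participants
            high = self.high_counts.get(f, 0)
            if not 0 <= high <= denom:
                raise ValidationError(
                    f"{f}: target high-score count {high} infeasible for {denom} responses"
                )


@dataclass(frozen=True)
class FieldAggregate:
    """Score distribution for one survey field."""

    field: str
    counts: dict[int, int]           # score -> count
    n_high: int                      # scores 4-5
    n_total: int

    @property
    def proportions(self) -> dict[int, float]:
        return {s: c / self.n_total for s, c in self.counts.items()}

    @property
    def high_proportion(self) -> float:
        return self.n_high / self.n_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"field": self.field, "score": s, "count": self.counts[s],
                 "proportion": self.counts[s] / self.n_total}
                for s in _SCORES
            ]
        )


def aggregate(responses: Sequence[LikertResponse], survey_field: str) -> FieldAggregate:
    """Score counts, proportions and the very-good (4-5) proportion for a field."""
    if survey_field not in FIELDS:
        raise ValidationError(f"unknown survey field {survey_field!r}")
    scores = [r.score for r in responses if r.field == survey_field]
    if not scores:
        raise ValidationError(f"no responses for field {survey_field!r}")
    counts = {s: scores.count(s) for s in _SCORES}
    n_high = counts[4] + counts[5]
    return FieldAggregate(
        field=survey_field, counts=counts, n_high=n_high, n_total=len(scores)
    )


def aggregate_all(responses: Sequence[LikertResponse]) -> dict[str, FieldAggregate]:
    return {f: aggregate(responses, f) for f in FIELDS}


def synthesize_survey(config: SurveyConfig | None = None, seed: int = 0) -> list[LikertResponse]:
    """A seeded response set hitting the configured marginals exactly.

    High scores are split randomly between 4 and 5, the rest between 1-3,
    and placed uniformly over the (participant, question) grid, so repeated
    aggregation reproduces the targets while the per-rater pattern varies
    with the seed.
    """
    config = config or SurveyConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    responses: list[LikertResponse] = []
    qid = 1
    for f in FIELDS:
        n_q = config.questions_per_field[f]
        denom = n_q * config.n_participants
        high = config.high_counts.get(f, 0)
        scores = np.concatenate(
            [
                rng.choice([4, 5], size=high),
                rng.choice([1, 2, 3], size=denom - high),
            ]
        )
        rng.shuffle(scores)
        k = 0
        for q in range(qid, qid + n_q):
            for p in range(1, config.n_participants + 1):
                responses.append(
                    LikertResponse(
                        participant_id=f"P{p}", field=f, question_id=q, score=int(scores[k])
                    )
                )
                k += 1
        qid += n_q
    return responses
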