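"""Scoring of the modified Worker's Living Activity-time Questionnaire (m-WLAQ).

The m-WLAQ asks workers about sitting time in four domains of daily life
(commuting, working, leisure on a workday, non-workday) and about intentional
physical activity: frequency (Q8, Q13), duration (Q9, Q14) and intensity
(Q6, Q10, Q15).  Seven of these items carry point weights, with intensity
weighted most heavily; their sum is the PA score on a 0-44 point scale, which
downstream regression models use as a predictor of maximal oxygen consumption.

Skip logic: respondents who report no leisure-time activity on workdays
(Q8 = option 1) do not answer Q9/Q10, and those items score zero; the same
rule ties Q13 to Q14/Q15 for holidays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "ValidationError",
    "PointsTable",
    "DEFAULT_POINTS",
    "WLAQResponse",
    "PAScore",
    "score_pa",
    "total_sitting_time",
    "load_points_table",
]

#: questions that carry PA-score points, in scale order
SCORED_QUESTIONS = ("q6", "q8", "q9", "q10", "q13", "q14", "q15")

#: gate question -> items skipped (and scored zero) when the gate is option 1
SKIP_RULES = {"q8": ("q9", "q10"), "q13": ("q14", "q15")}

MINUTES_PER_DAY = 1440.0


class ValidationError(ValueError):
    """A questionnaire record violates the m-WLAQ answer contract."""


@dataclass(frozen=True)
class PointsTable:
    """Point weights per answer option (options are 1-based, four per question).

    The default weights give intensity items (Q6, Q10, Q15) a 0/3/5/10 scale,
    frequency items (Q8, Q13) 0/1/2/3 and duration items (Q9, Q14) 1/2/3/4,
    so the per-question maxima sum to 44.
    """

    points: dict[str, tuple[int, int, int, int]]

    def __post_init__(self) -> None:
        missing = set(SCORED_QUESTIONS) - set(self.points)
        if missing:
            raise ValidationError(f"points table missing questions: {sorted(missing)}")
        for q, vals in self.points.items():
            if len(vals) != 4:
                raise ValidationError(f"{q}: expected 4 option weights, got {len(vals)}")
            if any((not isinstance(v, int)) or v < 0 for v in vals):
                raise ValidationError(f"{q}: option weights must be non-negative integers")
            if list(vals) != sorted(vals):
                raise ValidationError(f"{q}: option weights must be non-decreasing")

    def lookup(self, question: str, option: int) -> int:
        if option not in (1, 2, 3, 4):
            raise ValidationError(f"{question}: option index {option} outside 1-4")
        return self.points[question][option - 1]

    @property
    def max_score(self) -> int:
        return sum(v[-1] for v in self.points.values())


DEFAULT_POINTS = PointsTable(
    {
        "q6": (0, 3, 5, 10),
        "q8": (0, 1, 2, 3),
        "q9": (1, 2, 3, 4),
        "q10": (0, 3, 5, 10),
        "q13": (0, 1, 2, 3),
        "q14": (1, 2, 3, 4),
        "q15": (0, 3, 5, 10),
    }
)


def load_points_table(path: str | Path) -> PointsTable:
    """Load an alternative weighting from a YAML mapping question -> 4 weights."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PointsTable({q: tuple(int(v) for v in vals) for q, vals in raw.items()})


@dataclass
class WLAQResponse:
    """One participant's scored m-WLAQ answers.

    Option indices are 1-based as printed on the questionnaire.  ``None`` marks
    a legitimately skipped item (distinct from an option worth 0 points, so
    audit output can tell "skipped" from "answered none/almost none").
    Sitting times are minutes per day.
    """

    q6: int
    q8: int
    q13: int
    q9: Optional[int] = None
    q10: Optional[int] = None
    q14: Optional[int] = None
    q15: Optional[int] = None
    sit_commute_min: float = 0.0
    sit_work_min: float = 0.0
    sit_leisure_workday_min: float = 0.0
    sit_nonworkday_min: float = 0.0

    def validate(self) -> None:
        for q in ("q6", "q8", "q13"):
            v = getattr(self, q)
            if v not in (1, 2, 3, 4):
                raise ValidationError(f"{q}: option index {v} outside 1-4")
        for gate, dependents in SKIP_RULES.items():
            gate_val = getattr(self, gate)
            for dep in dependents:
                v = getattr(self, dep)
                if gate_val > 1 and v is None:
                    raise ValidationError(f"{dep} required when {gate}>1")
                if v is not None and v not in (1, 2, 3, 4):
                    raise ValidationError(f"{dep}: option index {v} outside 1-4")
        for name in (
            "sit_commute_min",
            "sit_work_min",
            "sit_leisure_workday_min",
            "sit_nonworkday_min",
        ):
            v = getattr(self, name)
            if not (0 <= v <= MINUTES_PER_DAY):
                raise ValidationError(f"{name}: {v} outside [0, {MINUTES_PER_DAY:.0f}] min/day")
        workday = self.sit_commute_min + self.sit_work_min + self.sit_leisure_workday_min
        if workday > MINUTES_PER_DAY:
            raise ValidationError(
                f"workday sitting (commute+work+leisure) {workday:.0f} exceeds "
                f"{MINUTES_PER_DAY:.0f} min/day"
            )


@dataclass(frozen=True)
class PAScore:
    """Total PA points and the per-question breakdown (Q6,Q8,Q9,Q10,Q13,Q14,Q15)."""

    value: int
    per_question_points: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.per_question_points and sum(self.per_question_points) != self.value:
            raise ValidationError("PA score must equal the sum of per-question points")


def question_points(response: WLAQResponse, points: PointsTable = DEFAULT_POINTS) -> dict[str, int]:
    """Per-question point contributions with the skip rule applied.

    Q9/Q10 contribute zero whenever Q8 = 1 (and Q14/Q15 whenever Q13 = 1),
    even if an answer was stored for the skipped item.
    """
    response.validate()
    skipped = set()
    for gate, dependents in SKIP_RULES.items():
        if getattr(response, gate) == 1:
            skipped.update(dependents)
    contrib: dict[str, int] = {}
    for q in SCORED_QUESTIONS:
        v = getattr(response, q)
        contrib[q] = 0 if (q in skipped or v is None) else points.lookup(q, v)
    return contrib


def score_pa(response: WLAQResponse, points: PointsTable = DEFAULT_POINTS) -> PAScore:
    """Compute the 0-44 point PA score for one response."""
    contrib = question_points(response, points)
    per_q = tuple(contrib[q] for q in SCORED_QUESTIONS)
    return PAScore(value=sum(per_q), per_question_points=per_q)


def total_sitting_time(response: WLAQResponse) -> float:
    """Daily sitting minutes summed over the four m-WLAQ domains."""
    response.validate()
    return (
        response.sit_commute_min
        + response.sit_work_min
        + response.sit_leisure_workday_min
        + response.sit_nonworkday_min
    )
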