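"""Cohort file I/O and record validation.

A cohort is a delimited text file, one row per participant, with the fixed
header: id, age, sex, height_cm, weight_kg, bmi, wg_cm, pct_fat, vo2max,
q6, q8, q9, q10, q13, q14, q15, sit_commute_min, sit_work_min,
sit_leisure_workday_min, sit_nonworkday_min.  Sex is F/M or 0/1 with
0 = women, 1 = men; vo2max and the skip-gated questions may be blank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .scoring import (
    DEFAULT_POINTS,
    PointsTable,
    ValidationError,
    WLAQResponse,
    score_pa,
    total_sitting_time,
)

__all__ = ["Participant", "RejectedRow", "validate_cohort", "read_cohort", "write_cohort",
           "cohort_frame", "COHORT_COLUMNS"]

COHORT_COLUMNS = [
    "id", "age", "sex", "height_cm", "weight_kg", "bmi", "wg_cm", "pct_fat",
    "vo2max", "q6", "q8", "q9", "q10", "q13", "q14", "q15",
    "sit_commute_min", "sit_work_min", "sit_leisure_workday_min", "sit_nonworkday_min",
]

SEX_CODES = {"F": 0, "M": 1, "0": 0, "1": 1, "f": 0, "m": 1}

#: tolerated gap between a supplied BMI column and weight/(height in m)^2
BMI_TOLERANCE = 0.1


@dataclass
class Participant:
    """Demographics, anthropometrics and scored questionnaire for one worker."""

    id: str
    age: float
    sex: int  # 0 = women, 1 = men
    height_cm: Optional[float]
    weight_kg: Optional[float]
    bmi: float
    wg_cm: float
    pct_fat: float
    response: WLAQResponse
    vo2max: Optional[float] = None
    pa_score: int = 0
    total_sitting_min: float = 0.0

    def derive(self, points: PointsTable = DEFAULT_POINTS) -> "Participant":
        self.pa_score = score_pa(self.response, points).value
        self.total_sitting_min = total_sitting_time(self.response)
        return self


@dataclass(frozen=True)
class RejectedRow:
    id: str
    reason: str


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_option(value, name: str) -> Optional[int]:
    v = _opt_float(value)
    if v is None:
        return None
    if v != int(v):
        raise ValidationError(f"{name}: option index {value} is not an integer")
    return int(v)


def _parse_row(row: pd.Series, points: PointsTable) -> Participant:
    sex_raw = str(row["sex"]).strip()
    if sex_raw not in SEX_CODES:
        raise ValidationError(f"sex: unrecognized code {sex_raw!r} (use F/M or 0/1)")
    resp = WLAQResponse(
        q6=_opt_option(row["q6"], "q6"),
        q8=_opt_option(row["q8"], "q8"),
        q13=_opt_option(row["q13"], "q13"),
        q9=_opt_option(row["q9"], "q9"),
        q10=_opt_option(row["q10"], "q10"),
        q14=_opt_option(row["q14"], "q14"),
        q15=_opt_option(row["q15"], "q15"),
        sit_commute_min=float(row["sit_commute_min"]),
        sit_work_min=float(row["sit_work_min"]),
        sit_leisure_workday_min=float(row["sit_leisure_workday_min"]),
        sit_nonworkday_min=float(row["sit_nonworkday_min"]),
    )
    height = _opt_float(row.get("height_cm"))
    weight = _opt_float(row.get("weight_kg"))
    bmi = _opt_float(row.get("bmi"))
    if height is not None and weight is not None:
        recomputed = weight / (height / 100.0) ** 2
        if bmi is None:
            bmi = recomputed
        elif abs(bmi - recomputed) > BMI_TOLERANCE:
            raise ValidationError(
                f"bmi: supplied {bmi:.2f} disagrees with weight/height^2 = "
                f"{recomputed:.2f} (tolerance {BMI_TOLERANCE})"
            )
    if bmi is None:
        raise ValidationError("bmi: missing and not derivable from height/weight")
    p = Participant(
        id=str(row["id"]),
        age=float(row["age"]),
        sex=SEX_CODES[sex_raw],
        height_cm=height,
        weight_kg=weight,
        bmi=bmi,
        wg_cm=float(row["wg_cm"]),
        pct_fat=float(row["pct_fat"]),
        vo2max=_opt_float(row.get("vo2max")),
        response=resp,
    )
    return p.derive(points)


def validate_cohort(
    rows: pd.DataFrame, points: PointsTable = DEFAULT_POINTS
) -> tuple[list[Participant], list[RejectedRow]]:
    """Validate raw cohort rows; return accepted participants and rejections.

    Rows failing any answer or anthropometric invariant are rejected with a
    machine-readable reason naming the offending field; accepted rows carry
    the derived PA score and total sitting time.
    """
    accepted: list[Participant] = []
    rejected: list[RejectedRow] = []
    seen: set[str] = set()
    for _, row in rows.iterrows():
        rid = str(row.get("id", ""))
        if rid in seen:
            raise ValidationError(f"duplicated participant identifier {rid!r}")
        seen.add(rid)
        try:
            accepted.append(_parse_row(row, points))
        except (ValidationError, ValueError, TypeError, KeyError) as exc:
            rejected.append(RejectedRow(id=rid, reason=str(exc)))
    return accepted, rejected


def read_cohort(
    path: str | Path, sep: str = ",", points: PointsTable = DEFAULT_POINTS
) -> tuple[list[Participant], list[RejectedRow]]:
    """Read and validate a cohort file."""
    rows = pd.read_csv(path, sep=sep, dtype={"id": str, "sex": str})
    missing = set(COHORT_COLUMNS) - set(rows.columns)
    if missing:
        raise ValidationError(f"cohort file missing columns: {sorted(missing)}")
    return validate_cohort(rows, points)


def write_cohort(participants: list[Participant], path: str | Path, sep: str = ",") -> None:
    """Write participants in the cohort file format (round-trips through read_cohort)."""
    recs = []
    for p in participants:
        r = p.response
        recs.append(
            {
                "id": p.id,
                "age": round(p.age, 1),
                "sex": p.sex,
                "height_cm": None if p.height_cm is None else round(p.height_cm, 1),
                "weight_kg": None if p.weight_kg is None else round(p.weight_kg, 2),
                "bmi": round(p.bmi, 2),
                "wg_cm": round(p.wg_cm, 1),
                "pct_fat": round(p.pct_fat, 1),
                "vo2max": None if p.vo2max is None else round(p.vo2max, 2),
                "q6": r.q6, "q8": r.q8, "q9": r.q9, "q10": r.q10,
                "q13": r.q13, "q14": r.q14, "q15": r.q15,
                "sit_commute_min": round(r.sit_commute_min, 1),
                "sit_work_min": round(r.sit_work_min, 1),
                "sit_leisure_workday_min": round(r.sit_leisure_workday_min, 1),
                "sit_nonworkday_min": round(r.sit_nonworkday_min, 1),
            }
        )
    df = pd.DataFrame.from_records(recs, columns=COHORT_COLUMNS)
    df["q9"] = df["q9"].astype("Int64")
    df["q10"] = df["q10"].astype("Int64")
    df["q14"] = df["q14"].astype("Int64")
    df["q15"] = df["q15"].astype("Int64")
    df.to_csv(path, sep=sep, index=False)


def cohort_frame(participants: list[Participant]) -> pd.DataFrame:
    """Analysis table: one row per participant with derived predictors."""
    return pd.DataFrame(
        {
            "id": [p.id for p in participants],
            "age": [p.age for p in participants],
            "sex": [p.sex for p in participants],
            "bmi": [p.bmi for p in participants],
            "wg": [p.wg_cm for p in participants],
            "pct_fat": [p.pct_fat for p in participants],
            "pa_score": [p.pa_score for p in participants],
            "total_sitting": [p.total_sitting_min for p in participants],
            "vo2max": [p.vo2max for p in participants],
        }
    )
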