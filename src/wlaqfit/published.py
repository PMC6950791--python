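"""Published VO2max prediction equations.

Six non-exercise regression models estimate maximal oxygen consumption
(ml·kg⁻¹·min⁻¹) from age, sex (0 = women, 1 = men), one body-fat-related
variable (BMI, waist girth, or %fat) and optionally the 0-44 point m-WLAQ PA
score.  The recommended everyday model is BMI with the PA score:

    VO2max = 59.96 - 0.23*age + 7.39*sex - 0.79*BMI + 0.33*PA

Reported fit statistics (adjusted R², SEE, %SEE) and leave-one-out
cross-validation statistics (R²p, SEEp) are carried with each equation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

__all__ = ["PublishedModel", "PUBLISHED_MODELS", "get_model", "predict_vo2max"]


@dataclass(frozen=True)
class PublishedModel:
    label: str
    body_fat_variable: str  # "bmi" | "wg" | "pct_fat"
    includes_pa: bool
    intercept: float
    age: float
    sex: float
    body_fat: float
    pa_score: Optional[float]
    adj_r2: float
    see: float
    pct_see: float
    r2p: float
    seep: float

    @property
    def predictors(self) -> tuple[str, ...]:
        base = ("age", "sex", self.body_fat_variable)
        return base + (("pa_score",) if self.includes_pa else base[:0])


PUBLISHED_MODELS: dict[str, PublishedModel] = {
    m.label: m
    for m in [
        PublishedModel("bmi", "bmi", False, 63.90, -0.25, 8.02, -0.79, None,
                       0.43, 5.04, 13.1, 0.42, 5.08),
        PublishedModel("bmi+pa", "bmi", True, 59.96, -0.23, 7.39, -0.79, 0.33,
                       0.59, 4.29, 11.2, 0.58, 4.33),
        PublishedModel("wg", "wg", False, 70.39, -0.22, 8.82, -0.33, None,
                       0.49, 4.78, 12.5, 0.48, 4.82),
        PublishedModel("wg+pa", "wg", True, 64.70, -0.21, 8.02, -0.29, 0.29,
                       0.61, 4.17, 10.9, 0.60, 4.22),
        PublishedModel("fat", "pct_fat", False, 62.45, -0.25, 2.95, -0.54, None,
                       0.51, 4.69, 12.2, 0.49, 4.74),
        PublishedModel("fat+pa", "pct_fat", True, 57.50, -0.24, 2.83, -0.48, 0.28,
                       0.62, 4.13, 10.8, 0.61, 4.18),
    ]
}

_ALIASES = {
    "%fat": "fat", "%fat+pa": "fat+pa", "pct_fat": "fat", "pct_fat+pa": "fat+pa",
}


def get_model(label: str) -> PublishedModel:
    key = label.lower().strip()
    key = _ALIASES.get(key, key)
    if key not in PUBLISHED_MODELS:
        raise KeyError(
            f"unknown model {label!r}; choose from {sorted(PUBLISHED_MODELS)}"
        )
    return PUBLISHED_MODELS[key]


def predict_vo2max(
    model: PublishedModel,
    age: float,
    sex: int,
    body_fat_value: float,
    pa_score: Optional[float] = None,
) -> float:
    """Estimate VO2max (ml·kg⁻¹·min⁻¹) from a published equation.

    ``body_fat_value`` is BMI, waist girth (cm) or %fat according to the
    model.  Out-of-range age or PA score warns but does not block: the
    equations are linear and callers may extrapolate knowingly.  The output
    is never truncated; implausibly low estimates (< 10) warn.
    """
    if sex not in (0, 1):
        raise ValueError("sex must be 0 (women) or 1 (men)")
    if body_fat_value is None or body_fat_value <= 0:
        raise ValueError(f"{model.body_fat_variable} value must be positive")
    if model.includes_pa:
        if pa_score is None:
            raise ValueError(f"model {model.label!r} requires a PA score")
        if not (0 <= pa_score <= 44):
            warnings.warn(f"PA score {pa_score} outside the 0-44 scale", stacklevel=2)
    elif pa_score is not None:
        raise ValueError(f"model {model.label!r} does not use a PA score")
    if not (30 <= age <= 60):
        warnings.warn(f"age {age} outside the 30-60 y development range", stacklevel=2)
    est = model.intercept + model.age * age + model.sex * sex + model.body_fat * body_fat_value
    if model.includes_pa:
        est += model.pa_score * pa_score
    if est < 10:
        warnings.warn(f"estimated VO2max {est:.1f} below 10 ml·kg⁻¹·min⁻¹", stacklevel=2)
    return est
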