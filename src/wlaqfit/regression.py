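"""Multiple linear regression for VO2max prediction, with PRESS cross-validation.

Models are ordinary least squares fits of measured VO2max on subsets of
{age, sex, BMI, WG, %fat, PA score, total sitting time}.  Fit quality is
summarised by R², adjusted R², the standard error of the estimate
SEE = sqrt(SSE/(n-p-1)) and %SEE = 100·SEE/mean(VO2max).  Internal validity
is assessed with the PRESS statistic — the sum of squared leave-one-out
prediction errors, computed exactly from the hat-matrix leverages as
e_i/(1-h_ii) without refitting — yielding R²p = 1 - PRESS/SS_total and
SEEp = sqrt(PRESS/N).  Note SEEp divides by N (the conventional reporting
formula here), not by the residual degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Participant, cohort_frame

__all__ = [
    "ModelSpec",
    "FitResult",
    "PressResult",
    "MODEL_FAMILY",
    "fit_ols",
    "percent_see",
    "press",
    "fit_model_family",
]

ALLOWED_PREDICTORS = ("age", "sex", "bmi", "wg", "pct_fat", "pa_score", "total_sitting")

#: designs with condition number beyond this are refused rather than solved
MAX_CONDITION = 1e8


@dataclass(frozen=True)
class ModelSpec:
    """Outcome VO2max regressed on a named predictor subset."""

    label: str
    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("at least one predictor is required")
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("duplicate predictors")
        unknown = set(self.predictors) - set(ALLOWED_PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictors: {sorted(unknown)}")


#: the six-model grid: each body-fat variable with and without the PA score
MODEL_FAMILY = [
    ModelSpec("bmi", ("age", "sex", "bmi")),
    ModelSpec("bmi+pa", ("age", "sex", "bmi", "pa_score")),
    ModelSpec("wg", ("age", "sex", "wg")),
    ModelSpec("wg+pa", ("age", "sex", "wg", "pa_score")),
    ModelSpec("fat", ("age", "sex", "pct_fat")),
    ModelSpec("fat+pa", ("age", "sex", "pct_fat", "pa_score")),
]


@dataclass
class FitResult:
    """OLS coefficients and fit metrics for one model specification."""

    spec: ModelSpec
    intercept: float
    coef: dict[str, float]
    n: int
    p: int
    r2: float
    adj_r2: float
    see: float
    percent_see: float
    residuals: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    bse: dict[str, float] = field(default_factory=dict, repr=False)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        out = np.full(len(data), self.intercept, dtype=float)
        for name, b in self.coef.items():
            out += b * data[name].to_numpy(dtype=float)
        return out


@dataclass(frozen=True)
class PressResult:
    """Leave-one-out cross-validation statistics for a fitted model."""

    spec: ModelSpec
    press_statistic: float
    r2p: float
    seep: float


def _as_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        return cohort
    if cohort and isinstance(cohort[0], Participant):
        return cohort_frame(cohort)
    raise TypeError("cohort must be a DataFrame or a list of Participant")


def _design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    cols = list(spec.predictors)
    if data["vo2max"].isna().any():
        raise ValueError("every participant needs a measured vo2max")
    y = data["vo2max"].to_numpy(dtype=float)
    X = sm.add_constant(data[cols].to_numpy(dtype=float), has_constant="add")
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n = {n} rows cannot identify {k - 1} predictors plus intercept")
    if np.linalg.matrix_rank(X) < k or np.linalg.cond(X) > MAX_CONDITION:
        raise ValueError(
            f"design is rank-deficient or ill-conditioned; check collinearity among {cols}"
        )
    return y, X


def fit_ols(cohort, spec: ModelSpec) -> FitResult:
    """Ordinary least squares fit of VO2max on the spec's predictors."""
    data = _as_frame(cohort)
    y, X = _design(data, spec)
    n, k = X.shape
    p = k - 1
    res = sm.OLS(y, X).fit()
    sse = float(res.ssr)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0.0:
        warnings.warn("constant outcome: R² reported as 0", stacklevel=2)
        r2, adj_r2 = 0.0, 0.0
    else:
        r2 = 1.0 - sse / ss_total
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    see = float(np.sqrt(sse / (n - p - 1)))
    ymean = float(y.mean())
    # %SEE is only meaningful on a positive-mean outcome scale
    pct = percent_see(see, ymean) if ymean > 0 else float("nan")
    names = ["intercept"] + list(spec.predictors)
    return FitResult(
        spec=spec,
        intercept=float(res.params[0]),
        coef=dict(zip(spec.predictors, map(float, res.params[1:]))),
        n=n,
        p=p,
        r2=r2,
        adj_r2=adj_r2,
        see=see,
        percent_see=pct,
        residuals=np.asarray(res.resid, dtype=float),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        bse=dict(zip(names, map(float, res.bse))),
    )


def percent_see(see: float, outcome_mean: float) -> float:
    """SEE as a percentage of the mean outcome: 100·SEE/mean."""
    if outcome_mean <= 0:
        raise ValueError("outcome mean must be positive")
    return 100.0 * see / outcome_mean


def press(cohort, spec: ModelSpec) -> PressResult:
    """PRESS statistic and derived R²p, SEEp via the leverage identity.

    The leave-one-out prediction error for row i equals e_i/(1-h_ii), where
    h_ii is the hat-matrix diagonal — exact, no refits.
    """
    data = _as_frame(cohort)
    y, X = _design(data, spec)
    n = len(y)
    res = sm.OLS(y, X).fit()
    hat = res.get_influence().hat_matrix_diag
    near_one = np.flatnonzero(1.0 - hat <= 1e-12)
    if near_one.size:
        raise ValueError(
            f"leverage 1 at row(s) {near_one.tolist()}: these points determine "
            "their own fit and have no leave-one-out prediction"
        )
    loo_err = res.resid / (1.0 - hat)
    press_stat = float(np.sum(loo_err**2))
    ss_total = float(np.sum((y - y.mean()) ** 2))
    r2p = 1.0 - press_stat / ss_total if ss_total > 0 else 0.0
    return PressResult(
        spec=spec,
        press_statistic=press_stat,
        r2p=r2p,
        seep=float(np.sqrt(press_stat / n)),
    )


def fit_model_family(cohort, specs: list[ModelSpec] = MODEL_FAMILY) -> pd.DataFrame:
    """Fit the six-model grid and tabulate coefficients with fit and PRESS columns.

    Returns one row per model in the published layout (intercept, age, sex,
    bmi, wg, pct_fat, pa_score, adj_r2, see, pct_see, r2p, seep) plus the
    gain in adjusted R² from adding the PA score to each body-fat model.
    """
    data = _as_frame(cohort)
    rows = []
    for spec in specs:
        fit = fit_ols(data, spec)
        cv = press(data, spec)
        row = {"model": spec.label, "intercept": fit.intercept}
        for name in ("age", "sex", "bmi", "wg", "pct_fat", "pa_score"):
            row[name] = fit.coef.get(name, np.nan)
        row.update(
            adj_r2=fit.adj_r2,
            see=fit.see,
            pct_see=fit.percent_see,
            r2p=cv.r2p,
            seep=cv.seep,
        )
        rows.append(row)
    grid = pd.DataFrame(rows).set_index("model")
    for base in ("bmi", "wg", "fat"):
        with_pa = f"{base}+pa"
        if base in grid.index and with_pa in grid.index:
            grid.loc[with_pa, "adj_r2_gain"] = (
                grid.loc[with_pa, "adj_r2"] - grid.loc[base, "adj_r2"]
            )
    return grid
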