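"""Reliability and criterion-validity statistics.

Covers the validation toolkit around the VO2max prediction models:

* Pearson correlations, unpaired Student's t and Pearson chi-squared tests
  for describing the cohort (thin wrappers over scipy with the classical,
  uncorrected variants pinned as defaults);
* constant error (CE) — mean(measured − predicted) VO2max — tabulated for
  subgroups of sex, age decade and fitness tertile, where a positive CE is
  systematic underestimation and a negative CE overestimation;
* test–retest reliability via the intraclass correlation coefficient.  The
  default estimator is the two-way mixed-effects, absolute-agreement,
  single-measurement ICC (McGraw & Wong A,1) with an F-distribution 95% CI,
  classified with the Rosner thresholds: < 0.40 poor, 0.40–0.75 fair-to-good,
  > 0.75 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import WLAQResponse, question_points, score_pa, total_sitting_time

__all__ = [
    "CEReport",
    "ReliabilityReport",
    "pearson_r",
    "two_sample_t",
    "chi_square",
    "constant_error",
    "icc",
    "classify_icc",
    "reliability_table",
    "RELIABILITY_MEASURES",
]


# ---------------------------------------------------------------- basic tests

def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(x: Sequence[float], y: Sequence[float], equal_var: bool = True) -> tuple[float, float]:
    """Unpaired Student's t-test (classical equal-variance; Welch via flag)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def chi_square(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-squared test on an r×c contingency table, no Yates correction."""
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


# ------------------------------------------------------------- constant error

@dataclass(frozen=True)
class CEReport:
    """Constant error for one subgroup: mean(measured − predicted) VO2max."""

    partition: str
    subgroup: str
    n: int
    pct: float
    measured_mean: float
    measured_sd: float
    predicted_mean: float
    predicted_sd: float
    ce: float
    ce_sd: float
    defined: bool = True


def _ce_row(partition: str, label: str, measured: np.ndarray, predicted: np.ndarray,
            total_n: int) -> CEReport:
    n = len(measured)
    if n == 0:
        return CEReport(partition, label, 0, 0.0, np.nan, np.nan, np.nan, np.nan,
                        np.nan, np.nan, defined=False)
    diff = measured - predicted
    sd = lambda a: float(np.std(a, ddof=1)) if n > 1 else np.nan
    return CEReport(
        partition, label, n, 100.0 * n / total_n,
        float(measured.mean()), sd(measured),
        float(predicted.mean()), sd(predicted),
        float(diff.mean()), sd(diff),
    )


def fitness_tertiles(measured: np.ndarray) -> np.ndarray:
    """Equal-count Low/Middle/High thirds of measured VO2max rank.

    Ties are broken by stable input order, so a 198-row cohort always splits
    66/66/66.
    """
    order = np.argsort(measured, kind="stable")
    labels = np.empty(len(measured), dtype=object)
    for name, idx in zip(("Low", "Middle", "High"), np.array_split(order, 3)):
        labels[idx] = name
    return labels


def constant_error(cohort, model, partitions=("sex", "age_decade", "fitness_tertile")) -> list[CEReport]:
    """CE by subgroup for a fitted (or published) model's predictions.

    ``cohort`` is a DataFrame (see ``cohort_frame``) or list of Participant;
    ``model`` is anything with a ``predict(DataFrame) -> array`` method.
    The whole-cohort CE is reported alongside; for a model fitted by OLS on
    this same cohort it is zero to numerical precision.
    """
    from .cohort import Participant, cohort_frame  # local import avoids a cycle

    if not isinstance(cohort, pd.DataFrame):
        if cohort and isinstance(cohort[0], Participant):
            cohort = cohort_frame(cohort)
        else:
            raise TypeError("cohort must be a DataFrame or a list of Participant")
    measured = cohort["vo2max"].to_numpy(dtype=float)
    if np.isnan(measured).any():
        raise ValueError("every row needs a measured vo2max")
    predicted = np.asarray(model.predict(cohort), dtype=float)
    total_n = len(measured)

    groups: dict[str, list[tuple[str, np.ndarray]]] = {}
    if "sex" in partitions:
        sex = cohort["sex"].to_numpy()
        groups["sex"] = [("Women", sex == 0), ("Men", sex == 1)]
    if "age_decade" in partitions:
        age = cohort["age"].to_numpy(dtype=float)
        # age 60 (inclusion bound) falls in the top bin
        groups["age_decade"] = [
            ("30-39", age < 40),
            ("40-49", (age >= 40) & (age < 50)),
            ("50-59", age >= 50),
        ]
    if "fitness_tertile" in partitions:
        tert = fitness_tertiles(measured)
        groups["fitness_tertile"] = [(t, tert == t) for t in ("Low", "Middle", "High")]

    reports = [_ce_row("all", "All", measured, predicted, total_n)]
    for part, subsets in groups.items():
        for label, mask in subsets:
            reports.append(_ce_row(part, label, measured[mask], predicted[mask], total_n))
    return reports


# ----------------------------------------------------------------------- ICC

@dataclass(frozen=True)
class ReliabilityReport:
    measure: str
    icc: float
    ci_low: float
    ci_high: float
    qualitative: str
    n: int


def classify_icc(value: float) -> str:
    """Rosner-style repeatability class for an ICC point estimate."""
    if value < 0.40:
        return "poor"
    if value <= 0.75:
        return "fair-to-good"
    return "excellent"


def icc(
    visit1: Sequence[float],
    visit2: Sequence[float],
    measure: str = "score",
    model: str = "two_way_mixed_absolute",
    alpha: float = 0.05,
) -> ReliabilityReport:
    """Test–retest ICC of two visits with an F-distribution confidence interval.

    The default is the two-way mixed-effects, absolute-agreement,
    single-measurement form ICC(A,1) — the conventional choice when every
    subject is measured on the same fixed pair of occasions.  A one-way
    random-effects form ICC(1) is available for sensitivity analyses.
    Pairs must be complete: any NaN is an error rather than silently dropped.
    """
    y1 = np.asarray(visit1, dtype=float)
    y2 = np.asarray(visit2, dtype=float)
    if len(y1) != len(y2):
        raise ValueError("visit vectors must be the same length")
    if np.isnan(y1).any() or np.isnan(y2).any():
        raise ValueError("incomplete pair: ICC requires complete cases")
    n = len(y1)
    if n < 5:
        raise ValueError("need at least 5 complete pairs")
    k = 2
    Y = np.column_stack([y1, y2])
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_total = float(((Y - grand) ** 2).sum())
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = ss_total - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    if model == "two_way_mixed_absolute":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        if denom == 0:
            raise ValueError("no variance in the data: ICC undefined")
        est = (msr - mse) / denom
        if mse == 0 and msc == 0:
            lo = hi = est  # perfect agreement: degenerate interval
        else:
            fc = msc / mse if mse > 0 else np.inf
            a = (k * est) / (n * (1 - est)) if est < 1 else np.inf
            if np.isinf(fc) or np.isinf(a):
                lo = hi = est
            else:
                vn = (k - 1) * (n - 1) * (k * est * fc + n * (1 + (k - 1) * est) - k * est) ** 2
                vd = (n - 1) * k**2 * est**2 * fc**2 + (n * (1 + (k - 1) * est) - k * est) ** 2
                v = vn / vd
                f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
                f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
                lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
                hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    elif model == "one_way_random":
        msw = (ss_total - ssr) / (n * (k - 1))
        denom = msr + (k - 1) * msw
        if denom == 0:
            raise ValueError("no variance in the data: ICC undefined")
        est = (msr - msw) / denom
        if msw == 0:
            lo = hi = est
        else:
            fobs = msr / msw
            f_l = fobs / stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
            f_u = fobs * stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
            lo = (f_l - 1) / (f_l + k - 1)
            hi = (f_u - 1) / (f_u + k - 1)
    else:
        raise ValueError(f"unknown ICC model {model!r}")

    lo = float(min(max(lo, -1.0), est))
    hi = float(max(min(hi, 1.0), est))
    return ReliabilityReport(measure, float(est), lo, hi, classify_icc(float(est)), n)


# --------------------------------------------------------- reliability table

#: measure name -> function of one response; mirrors the published row set
RELIABILITY_MEASURES: dict[str, callable] = {
    "sitting_commuting": lambda r: r.sit_commute_min,
    "sitting_working": lambda r: r.sit_work_min,
    "sitting_leisure_workday": lambda r: r.sit_leisure_workday_min,
    "sitting_nonworkday": lambda r: r.sit_nonworkday_min,
    "sitting_total": total_sitting_time,
    "exercise_frequency_workday": lambda r: question_points(r)["q8"],
    "exercise_frequency_nonworkday": lambda r: question_points(r)["q13"],
    "exercise_duration_workday": lambda r: question_points(r)["q9"],
    "exercise_duration_nonworkday": lambda r: question_points(r)["q14"],
    "intensity_working": lambda r: question_points(r)["q6"],
    "intensity_workday": lambda r: question_points(r)["q10"],
    "intensity_nonworkday": lambda r: question_points(r)["q15"],
    "pa_score": lambda r: score_pa(r).value,
}


def reliability_table(
    pairs: Sequence[tuple[WLAQResponse, WLAQResponse]],
    model: str = "two_way_mixed_absolute",
) -> list[ReliabilityReport]:
    """One ICC report per questionnaire-derived value from paired visits.

    Rows: the four domain sitting times and their total, the point values of
    the exercise frequency/duration/intensity items (skip rule applied, so a
    gated item scores 0 when unanswered), and the PA score.
    """
    if not pairs:
        raise ValueError("no pairs supplied")
    reports = []
    for name, fn in RELIABILITY_MEASURES.items():
        v1 = [float(fn(a)) for a, _ in pairs]
        v2 = [float(fn(b)) for _, b in pairs]
        reports.append(icc(v1, v2, measure=name, model=model))
    return reports
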