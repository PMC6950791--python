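"""Synthetic worker cohorts for exercising the VO2max estimation pipeline.

The real questionnaire study's raw data are not public, so every stage of
the pipeline runs on simulated participants instead.  The generator draws,
per sex, truncated-normal anthropometrics and domain sitting times
calibrated to the study population's published means/SDs, questionnaire
answers from the published answer-option frequencies (honouring the skip
logic: duration/intensity items are drawn only when the frequency gate is
above "none"), and sets measured VO2max from one of the published
prediction equations plus Gaussian residual noise — so an OLS refit on a
large synthetic cohort recovers the published coefficients, and the
noiseless limit recovers them exactly.

A companion retest generator produces a second questionnaire visit with
ordinal answer drift and within-subject sitting-time noise, and
``simulate_score_pairs`` draws continuous test–retest pairs whose population
intraclass correlation equals a requested between-subject variance share.

For variables whose truncation is mild (age, height, BMI, WG, %fat) the
parent normal parameters are moment-matched so the *truncated* distribution
hits the target mean and SD.  Sitting times keep the printed parameters as
parent parameters: a mean of 12 ± 18 min/day cannot be the moments of any
non-negative truncated normal, so their sample means sit slightly above the
printed ones — real commute-sitting data are zero-inflated and skewed, which
a truncated normal only caricatures.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import optimize, stats

from .cohort import Participant
from .published import get_model
from .scoring import MINUTES_PER_DAY, WLAQResponse, score_pa, total_sitting_time

__all__ = [
    "CohortSpec",
    "RetestSpec",
    "default_cohort_spec",
    "generate_cohort",
    "generate_retest",
    "simulate_score_pairs",
    "spec_to_yaml",
    "spec_from_yaml",
]

WOMEN, MEN = 0, 1

#: plausibility bounds; sampling truncates here
TRUNCATION = {
    "age": (30.0, 60.0),
    "height": (130.0, 210.0),
    "bmi": (15.0, 45.0),
    "wg": (50.0, 130.0),
    "pct_fat": (5.0, 55.0),
    "sit_commute": (0.0, MINUTES_PER_DAY),
    "sit_work": (0.0, MINUTES_PER_DAY),
    "sit_leisure_workday": (0.0, MINUTES_PER_DAY),
    "sit_nonworkday": (0.0, MINUTES_PER_DAY),
}

#: variables whose truncated distribution is moment-matched to the target
CALIBRATED_VARS = ("age", "height", "bmi", "wg", "pct_fat")

MARGINAL_VARS = tuple(TRUNCATION)

VO2MAX_FLOOR = 10.0

# study-population marginals: sex -> variable -> (mean, sd)
_DEFAULT_MARGINALS = {
    WOMEN: {
        "age": (46.7, 7.5), "height": (158.8, 5.2), "weight": (54.2, 8.1),
        "bmi": (21.5, 2.9), "wg": (75.8, 8.9), "pct_fat": (29.0, 5.6),
        "sit_commute": (12.0, 18.0), "sit_work": (382.0, 147.0),
        "sit_leisure_workday": (241.0, 103.0), "sit_nonworkday": (513.0, 166.0),
    },
    MEN: {
        "age": (47.1, 7.1), "height": (171.2, 5.6), "weight": (68.7, 9.1),
        "bmi": (23.4, 2.9), "wg": (82.9, 8.3), "pct_fat": (22.5, 5.3),
        "sit_commute": (16.0, 21.0), "sit_work": (435.0, 162.0),
        "sit_leisure_workday": (183.0, 85.0), "sit_nonworkday": (566.0, 192.0),
    },
}

# answer-option frequencies per sex; q9/q10 (q14/q15) are conditional on the
# frequency gate q8 (q13) being above option 1
_DEFAULT_OPTION_COUNTS = {
    WOMEN: {
        "q6": (81, 7, 5, 0),
        "q8": (45, 6, 27, 15),
        "q9": (1, 12, 25, 10),
        "q10": (15, 29, 4, 0),
        "q13": (39, 17, 24, 13),
        "q14": (2, 4, 27, 21),
        "q15": (10, 38, 6, 0),
    },
    MEN: {
        "q6": (76, 19, 9, 1),
        "q8": (54, 18, 18, 15),
        "q9": (2, 6, 22, 21),
        "q10": (4, 32, 14, 1),
        "q13": (36, 23, 32, 14),
        "q14": (2, 8, 27, 32),
        "q15": (10, 41, 17, 1),
    },
}

_STUDY_N = {WOMEN: 93, MEN: 105}


def _normalise(counts: Sequence[float]) -> tuple[float, ...]:
    total = float(sum(counts))
    return tuple(c / total for c in counts)


@dataclass
class CohortSpec:
    """Everything needed to draw a synthetic cohort reproducibly."""

    n: int = 198
    sex_fraction_male: float = _STUDY_N[MEN] / (_STUDY_N[WOMEN] + _STUDY_N[MEN])
    marginals: dict = field(
        default_factory=lambda: {s: dict(v) for s, v in _DEFAULT_MARGINALS.items()}
    )
    option_probs: dict = field(
        default_factory=lambda: {
            s: {q: _normalise(c) for q, c in qs.items()}
            for s, qs in _DEFAULT_OPTION_COUNTS.items()
        }
    )
    model: str = "bmi+pa"
    residual_sd: float = 4.29
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.sex_fraction_male <= 1.0):
            raise ValueError("sex_fraction_male must be in [0, 1]")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        get_model(self.model)  # raises on unknown label
        for sex in (WOMEN, MEN):
            for var in MARGINAL_VARS:
                m, s = self.marginals[sex][var]
                if s < 0:
                    raise ValueError(f"sd of {var} (sex={sex}) must be >= 0")
            for q, probs in self.option_probs[sex].items():
                if len(probs) != 4:
                    raise ValueError(f"{q} (sex={sex}): need 4 option probabilities")
                if any(p < 0 or p > 1 for p in probs):
                    raise ValueError(f"{q} (sex={sex}): probabilities outside [0, 1]")
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ValueError(f"{q} (sex={sex}): probabilities must sum to 1")


@dataclass
class RetestSpec:
    """Second-visit noise model for test–retest reliability studies.

    ``stay_probability`` is the chance a categorical answer is unchanged at
    retest (otherwise it drifts to an adjacent option, reflecting at the
    ends); ``sitting_within_sd`` is the within-subject SD (min/day) of
    re-reported sitting times; ``variance_share`` is the between-subject
    share of total variance for continuous score pairs, i.e. the population
    ICC built by ``simulate_score_pairs``.
    """

    stay_probability: float = 0.85
    sitting_within_sd: float = 70.0
    variance_share: float = 0.87
    seed: Optional[int] = None

    def validate(self) -> None:
        if not (0.0 <= self.stay_probability <= 1.0):
            raise ValueError("stay_probability must be in [0, 1]")
        if self.sitting_within_sd < 0:
            raise ValueError("sitting_within_sd must be >= 0")
        if not (0.0 < self.variance_share < 1.0):
            raise ValueError("variance_share must be in (0, 1)")


@functools.lru_cache(maxsize=None)
def _matched_parent(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-truncated normal has the given moments."""
    if sd == 0:
        return mean, 0.0

    def moments_gap(params):
        mu, log_sig = params
        sig = np.exp(log_sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(moments_gap, x0=[mean, np.log(sd)], tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"moment matching failed for mean={mean}, sd={sd} on [{lo}, {hi}]")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _draw_truncated(
    rng: np.random.Generator, size: int, var: str, mean: float, sd: float
) -> np.ndarray:
    lo, hi = TRUNCATION[var]
    if sd == 0:
        return np.full(size, mean)
    mu, sig = (_matched_parent(mean, sd, lo, hi) if var in CALIBRATED_VARS else (mean, sd))
    a, b = (lo - mu) / sig, (hi - mu) / sig
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sig, size=size, random_state=rng)


def _draw_options(rng: np.random.Generator, size: int, probs: Sequence[float]) -> np.ndarray:
    return rng.choice(4, size=size, p=np.asarray(probs, dtype=float)) + 1


def _draw_responses(
    rng: np.random.Generator, size: int, probs: dict, marg: dict
) -> list[WLAQResponse]:
    q6 = _draw_options(rng, size, probs["q6"])
    q8 = _draw_options(rng, size, probs["q8"])
    q13 = _draw_options(rng, size, probs["q13"])
    q9 = np.where(q8 > 1, _draw_options(rng, size, probs["q9"]), 0)
    q10 = np.where(q8 > 1, _draw_options(rng, size, probs["q10"]), 0)
    q14 = np.where(q13 > 1, _draw_options(rng, size, probs["q14"]), 0)
    q15 = np.where(q13 > 1, _draw_options(rng, size, probs["q15"]), 0)

    sit = {}
    for var in ("sit_commute", "sit_work", "sit_leisure_workday", "sit_nonworkday"):
        sit[var] = _draw_truncated(rng, size, var, *marg[var])
    # enforce the physical cap on workday sitting by resampling violators
    while True:
        bad = np.flatnonzero(
            sit["sit_commute"] + sit["sit_work"] + sit["sit_leisure_workday"]
            > MINUTES_PER_DAY
        )
        if bad.size == 0:
            break
        for var in ("sit_commute", "sit_work", "sit_leisure_workday"):
            sit[var][bad] = _draw_truncated(rng, bad.size, var, *marg[var])

    out = []
    for i in range(size):
        out.append(
            WLAQResponse(
                q6=int(q6[i]),
                q8=int(q8[i]),
                q13=int(q13[i]),
                q9=int(q9[i]) if q8[i] > 1 else None,
                q10=int(q10[i]) if q8[i] > 1 else None,
                q14=int(q14[i]) if q13[i] > 1 else None,
                q15=int(q15[i]) if q13[i] > 1 else None,
                sit_commute_min=float(sit["sit_commute"][i]),
                sit_work_min=float(sit["sit_work"][i]),
                sit_leisure_workday_min=float(sit["sit_leisure_workday"][i]),
                sit_nonworkday_min=float(sit["sit_nonworkday"][i]),
            )
        )
    return out


def default_cohort_spec(**overrides) -> CohortSpec:
    """The study-calibrated cohort specification, optionally overridden."""
    return replace(CohortSpec(), **overrides) if overrides else CohortSpec()


def generate_cohort(spec: CohortSpec, rng: Optional[np.random.Generator] = None) -> list[Participant]:
    """Draw a synthetic cohort; deterministic given (spec, seed)."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    model = get_model(spec.model)
    sexes = (rng.random(spec.n) < spec.sex_fraction_male).astype(int)
    participants: list[Optional[Participant]] = [None] * spec.n
    for sex in (WOMEN, MEN):
        idx = np.flatnonzero(sexes == sex)
        if idx.size == 0:
            continue
        marg = spec.marginals[sex]
        age = _draw_truncated(rng, idx.size, "age", *marg["age"])
        height = _draw_truncated(rng, idx.size, "height", *marg["height"])
        bmi = _draw_truncated(rng, idx.size, "bmi", *marg["bmi"])
        wg = _draw_truncated(rng, idx.size, "wg", *marg["wg"])
        fat = _draw_truncated(rng, idx.size, "pct_fat", *marg["pct_fat"])
        weight = bmi * (height / 100.0) ** 2  # consistent with the BMI cross-check
        responses = _draw_responses(rng, idx.size, spec.option_probs[sex], marg)
        noise = rng.normal(0.0, spec.residual_sd, size=idx.size) if spec.residual_sd > 0 else 0.0
        body_fat = {"bmi": bmi, "wg": wg, "pct_fat": fat}[model.body_fat_variable]
        for j, i in enumerate(idx):
            resp = responses[j]
            pa = score_pa(resp).value
            structural = (
                model.intercept
                + model.age * age[j]
                + model.sex * sex
                + model.body_fat * body_fat[j]
                + (model.pa_score * pa if model.includes_pa else 0.0)
            )
            vo2 = structural + (noise[j] if spec.residual_sd > 0 else 0.0)
            participants[i] = Participant(
                id=f"S{i + 1:05d}",
                age=float(age[j]),
                sex=sex,
                height_cm=float(height[j]),
                weight_kg=float(weight[j]),
                bmi=float(bmi[j]),
                wg_cm=float(wg[j]),
                pct_fat=float(fat[j]),
                vo2max=float(max(vo2, VO2MAX_FLOOR)),
                response=resp,
            ).derive()
    return participants


def _drift_option(rng: np.random.Generator, value: int, stay_p: float) -> int:
    if rng.random() < stay_p:
        return value
    step = 1 if rng.random() < 0.5 else -1
    moved = value + step
    if moved < 1:
        moved = 2
    elif moved > 4:
        moved = 3
    return moved


def _retest_sitting(rng: np.random.Generator, resp: WLAQResponse, sd: float) -> dict[str, float]:
    fields = (
        "sit_commute_min",
        "sit_work_min",
        "sit_leisure_workday_min",
        "sit_nonworkday_min",
    )
    for _ in range(100):
        new = {
            f: float(np.clip(getattr(resp, f) + rng.normal(0.0, sd), 0.0, MINUTES_PER_DAY))
            for f in fields
        } if sd > 0 else {f: getattr(resp, f) for f in fields}
        workday = new["sit_commute_min"] + new["sit_work_min"] + new["sit_leisure_workday_min"]
        if workday <= MINUTES_PER_DAY:
            return new
    # pathological baseline near the cap: shrink proportionally instead
    scale = MINUTES_PER_DAY / workday
    for f in ("sit_commute_min", "sit_work_min", "sit_leisure_workday_min"):
        new[f] *= scale
    return new


def generate_retest(
    cohort: Sequence[Participant],
    spec: RetestSpec,
    rng: Optional[np.random.Generator] = None,
    cohort_spec: Optional[CohortSpec] = None,
) -> list[tuple[WLAQResponse, WLAQResponse]]:
    """Second-visit responses for each participant; returns (visit1, visit2) pairs.

    Categorical answers stay put with probability ``stay_probability``, else
    drift to an adjacent option; gated items are re-drawn from the
    answer-option distributions when the gate newly opens, and dropped when
    it closes.  Sitting times get within-subject Gaussian noise, clipped to
    the valid range.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if cohort_spec is None:
        cohort_spec = default_cohort_spec()

    pairs = []
    for p in cohort:
        r1 = p.response
        probs = cohort_spec.option_probs[p.sex]
        q6 = _drift_option(rng, r1.q6, spec.stay_probability)
        q8 = _drift_option(rng, r1.q8, spec.stay_probability)
        q13 = _drift_option(rng, r1.q13, spec.stay_probability)

        def gated(gate2: int, old: Optional[int], q: str) -> Optional[int]:
            if gate2 == 1:
                return None
            if old is None:
                return int(_draw_options(rng, 1, probs[q])[0])
            return _drift_option(rng, old, spec.stay_probability)

        sit = _retest_sitting(rng, r1, spec.sitting_within_sd)
        r2 = WLAQResponse(
            q6=q6,
            q8=q8,
            q13=q13,
            q9=gated(q8, r1.q9, "q9"),
            q10=gated(q8, r1.q10, "q10"),
            q14=gated(q13, r1.q14, "q14"),
            q15=gated(q13, r1.q15, "q15"),
            **sit,
        )
        r2.validate()
        pairs.append((r1, r2))
    return pairs


def simulate_score_pairs(
    n: int,
    variance_share: float,
    mean: float = 0.0,
    total_sd: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous test–retest pairs with population ICC = ``variance_share``.

    Each subject gets a latent trait drawn with variance ``variance_share``
    (times total variance) and two visits adding independent noise with the
    complementary variance, so the between-subject share of total variance —
    the population intraclass correlation — equals ``variance_share``.
    """
    if not (0.0 < variance_share < 1.0):
        raise ValueError("variance_share must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    subject = rng.normal(mean, total_sd * np.sqrt(variance_share), size=n)
    e1 = rng.normal(0.0, total_sd * np.sqrt(1.0 - variance_share), size=n)
    e2 = rng.normal(0.0, total_sd * np.sqrt(1.0 - variance_share), size=n)
    return subject + e1, subject + e2


# ------------------------------------------------------------- serialization

def spec_to_yaml(spec: CohortSpec | RetestSpec, path: str | Path) -> None:
    """Write a spec as a human-editable YAML file."""
    if isinstance(spec, CohortSpec):
        payload = {
            "kind": "cohort",
            "n": spec.n,
            "sex_fraction_male": spec.sex_fraction_male,
            "marginals": {int(s): {k: list(v) for k, v in m.items()} for s, m in spec.marginals.items()},
            "option_probs": {int(s): {k: list(v) for k, v in q.items()} for s, q in spec.option_probs.items()},
            "model": spec.model,
            "residual_sd": spec.residual_sd,
            "seed": spec.seed,
        }
    else:
        payload = {
            "kind": "retest",
            "stay_probability": spec.stay_probability,
            "sitting_within_sd": spec.sitting_within_sd,
            "variance_share": spec.variance_share,
            "seed": spec.seed,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def spec_from_yaml(path: str | Path) -> CohortSpec | RetestSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kind = raw.pop("kind", "cohort")
    if kind == "cohort":
        raw["marginals"] = {int(s): {k: tuple(v) for k, v in m.items()} for s, m in raw["marginals"].items()}
        raw["option_probs"] = {int(s): {k: tuple(v) for k, v in q.items()} for s, q in raw["option_probs"].items()}
        return CohortSpec(**raw)
    if kind == "retest":
        return RetestSpec(**raw)
    raise ValueError(f"unknown spec kind {kind!r}")
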