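# Methods

## The PA score

Seven m-WLAQ items carry points: work-time activity intensity (Q6), and for
each of the two leisure domains (workday, holiday) an activity-frequency gate
(Q8, Q13), a duration item (Q9, Q14) and an intensity item (Q10, Q15). Every
item has four ordered options; intensity items are weighted 0/3/5/10,
frequency 0/1/2/3 and duration 1/2/3/4, so intensity dominates the composite
— the weighting choice that makes the score track VO2max rather than activity
volume. The per-question maxima sum to 44, the top of the scale.

Skip logic: when a frequency gate is at option 1 ("none/almost none"), the
domain's duration and intensity items are unanswered and contribute zero
points — and they contribute zero even if a value was stored, so stray
answers cannot inflate the score. Internally a skipped item is a `None`
sentinel, distinct from "answered the 0-point option", which keeps audit
output unambiguous. The weights live in a YAML config
(`wlaqfit/data/points_default.yaml`); alternative weightings can be explored
without code changes.

Validation bounds not inherent to the questionnaire: each domain sitting time
must lie in [0, 1440] min/day and the three workday domains must sum to at
most 1440 — physical-impossibility caps, applied at cohort validation. A
supplied BMI column is cross-checked against weight/(height m)² with
tolerance 0.1 and the row rejected on disagreement.

## Regression and cross-validation

Models are OLS fits of measured VO2max on subsets of {age, sex, BMI, WG,
%fat, PA score, total sitting time}; the canonical grid is the six models
crossing the three body-fat variables with presence/absence of the PA score.
Fit statistics: R², adjusted R² = 1 − (1−R²)(n−1)/(n−p−1),
SEE = √(SSE/(n−p−1)), %SEE = 100·SEE/mean(VO2max).

Internal validity uses the PRESS statistic: the sum of squared leave-one-out
prediction errors, computed exactly through the leverage identity
e_i/(1−h_ii) with h_ii the hat-matrix diagonal (a test verifies the identity
against literal n-refit leave-one-out to 1e-10 relative). Derived statistics
follow the conventional reporting formulas: R²p = 1 − PRESS/SS_total and
SEEp = √(PRESS/N). Note the deliberate asymmetry — SEEp divides by N while
SEE divides by the residual degrees of freedom n−p−1; both are kept as such.
R²p is not further adjusted for p.

Numerical choices: the design is solved by statsmodels' QR-based OLS;
rank-deficient designs or condition numbers above 1e8 are refused with an
error naming the predictors rather than silently regularised. A constant
outcome reports R² = 0 with a warning instead of NaN. %SEE is NaN when the
outcome mean is non-positive (it is a ratio to a positive scale). No variable
selection is implemented: the six specifications are fixed by design.

## Constant-error validation

CE = mean(measured − predicted) per subgroup; positive CE is systematic
underestimation. Partitions: sex; age decades 30–39/40–49/50–59 (the cohort
admits age 60, which falls in the top bin so the partition is exhaustive);
and equal-count thirds of measured VO2max rank with ties broken by stable
input order (a 198-row cohort splits exactly 66/66/66). For a model fitted
on the same cohort the whole-cohort CE is zero by the OLS residual-mean
property, and the n-weighted subgroup CEs reproduce it as an arithmetic
identity (tested). Grouping on the outcome itself guarantees
regression-to-the-mean: the low-fitness tertile is overestimated (CE < 0)
and the high tertile underestimated (CE > 0) — the structural pattern the
validation is designed to expose. Empty subgroups are reported with n = 0
and an undefined flag, not raised.

## Test–retest reliability

The ICC estimator is the two-way mixed-effects, absolute-agreement,
single-measurement form (McGraw & Wong A,1), the conventional choice when
all subjects are measured on the same fixed pair of occasions; a one-way
random-effects form is available for sensitivity. Confidence intervals use
the F-distribution formulas for each form; both the point estimates and CIs
are cross-checked against pingouin in the test suite. Degenerate perfect
agreement (zero within-subject and zero occasion variance) returns a
point-mass interval rather than NaN. Classification uses the Rosner-style
thresholds with both boundary values assigned to the middle class:
ICC < 0.40 poor, 0.40–0.75 fair-to-good, > 0.75 excellent.

The reliability table reports one row per questionnaire-derived value:
the four domain sitting times and their total, the exercise frequency,
duration and intensity point values per domain (skip rule applied, so a
gated item scores 0 when unanswered — pairs are always complete), and the
PA score: 13 rows.

## The synthetic cohort generator

The generator emulates the study conditions so the pipeline runs end to end
without the original (request-only) data. Defaults:

- **Cohort structure.** n = 198, P(man) = 105/198; sex drawn Bernoulli.
- **Marginals** (per sex, truncated normal): age 46.7±7.5 / 47.1±7.1 y,
  height 158.8±5.2 / 171.2±5.6 cm, BMI 21.5±2.9 / 23.4±2.9,
  WG 75.8±8.9 / 82.9±8.3 cm, %fat 29.0±5.6 / 22.5±5.3 (women / men), and the
  four sitting domains (e.g. work 382±147 / 435±162 min/day). Truncation
  bounds: age [30, 60] (the inclusion criterion), BMI [15, 45], %fat
  [5, 55], WG [50, 130], height [130, 210], sitting [0, 1440] with the
  workday triple resampled to respect the 1440 cap.
- **Moment matching.** For age, height, BMI, WG and %fat the parent normal
  parameters are solved (once, cached) so the *truncated* distribution has
  the target mean and SD; a 20 000-participant draw reproduces each target
  mean within 3 standard errors (tested). Sitting times keep the printed
  parameters as parent parameters instead: a commute-sitting mean of 12 ± 18
  min/day cannot be the moments of any non-negative truncated normal — real
  commute data are zero-inflated and skewed — so those sample means sit
  slightly above the printed values.
- **Weight** is derived as BMI·(height/100)², not drawn, so the validator's
  BMI cross-check holds by construction; the implied means match the target
  weights (women ≈ 54.2 kg, men ≈ 68.6 kg vs 68.7 printed).
- **Questionnaire answers** are drawn per sex from the published option
  frequencies, with the gated duration/intensity items drawn from their
  conditional (gate-open) frequencies only when the gate is above option 1.
  The implied PA-score means, 8.8 (women) and 10.7 (men), reproduce the
  study's printed means — a consequence of the calibration, verified against
  an independent expectation oracle in the tests.
- **VO2max** is structural: the chosen published equation (default BMI+PA)
  evaluated on the drawn predictors plus Normal(0, residual SD) noise with
  residual SD 4.29 ml·kg⁻¹·min⁻¹, the published SEE of that model; floored
  at 10 ml·kg⁻¹·min⁻¹ (≈ 5σ below the mean, so the floor is effectively
  never active). With residual SD 0, VO2max equals the equation exactly and
  an OLS refit recovers the published coefficients to numerical precision.
- **Predictors are independent within sex.** The study reports no
  predictor–predictor correlations, so none are invented (an explicit design
  choice). Consequences: the refit of the *generating* model recovers its
  coefficients and SEE, but the grid's other models (WG, %fat) carry no real
  signal from their body-fat variable beyond chance, and predictor–outcome
  correlations on synthetic data match the structural signs (PA positive,
  age negative) but not the study's magnitudes. Passing tests therefore
  demonstrate estimator correctness and calibration of what was calibrated —
  not that synthetic data reproduce the study's full joint distribution.

### Retest generator

Second-visit categorical answers stay put with probability 0.85, else move
to an adjacent option (reflecting at the scale ends — drift preserves the
ordinal structure; uniform resampling would not). When a frequency gate
newly opens, the gated items are drawn from their conditional distributions;
when it closes they are dropped. Sitting times add within-subject
Normal(0, 70 min) noise, clipped to the valid range. The stay probability
and within-SD are fixed realistic mid-range values consistent with the
study's reported reliability span (ICCs 0.48–0.94); they are not fitted to
any published number. For continuous scores, `simulate_score_pairs` builds
pairs whose population ICC equals a requested between-subject variance
share exactly (subject trait variance ρ, visit noise variance 1−ρ); the
0.87 default mirrors the published PA-score ICC and underlies the recovery
checks.

## Problem sizes

Recovery simulations use n = 5000 (coefficients/SEE) and 2000 pairs (ICC) —
large enough that Monte-Carlo error is well inside the assertion tolerances;
the PRESS oracle uses 20 cohorts of n ≤ 50 where literal leave-one-out
refitting is cheap; bias checks average 60–100 replicates at the study's
n = 198 or at n = 2000.

## Known limitations

- Only marginals and one structural equation are calibrated; joint structure
  (predictor correlations, the published correlation matrix, the non-BMI
  models' fit statistics) is intentionally out of the generator's scope.
- The published CIs of the reliability table cannot be matched numerically
  (the study does not state its ICC software form); only estimator
  self-consistency and recovery of constructed variance shares are testable.
- Domain sitting minutes are taken as direct inputs; deriving them from the
  questionnaire's raw time-diary items is outside the package.
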