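#!/usr/bin/env python
"""Fit the six VO2max prediction models and cross-validate them with PRESS.

Writes the model grid (coefficients, adjusted R², SEE, %SEE, R²p, SEEp) and,
for each model, a measured-vs-estimated scatter export for external plotting.
"""

from pathlib import Path

from wlaqfit import MODEL_FAMILY, cohort_frame, fit_model_family, fit_ols, read_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    participants, _ = read_cohort(RESULTS / "cohort.csv")
    df = cohort_frame(participants)

    grid = fit_model_family(df)
    grid.round(4).to_csv(RESULTS / "model_grid.csv")
    print(grid.round(3).to_string())
    print("\nadjusted-R² gain from adding the PA score:")
    print(grid["adj_r2_gain"].dropna().round(3).to_string())

    for spec in MODEL_FAMILY:
        fit = fit_ols(df, spec)
        scatter = df[["id", "vo2max"]].assign(vo2max_estimated=fit.predict(df).round(3))
        safe = spec.label.replace("+", "_")
        scatter.to_csv(RESULTS / f"scatter_{safe}.csv", index=False)
    print(f"\nwrote scatter exports for {len(MODEL_FAMILY)} models")


if __name__ == "__main__":
    main()
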