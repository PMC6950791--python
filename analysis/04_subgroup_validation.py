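#!/usr/bin/env python
"""Constant-error validation by sex, age decade and fitness tertile.

For each with-PA model, tabulates CE = mean(measured - predicted) VO2max per
subgroup.  Expected structure: whole-cohort CE ~ 0 (the model is fitted on
this cohort), small CEs for sex/age subgroups, overestimation (CE < 0) in the
low-fitness tertile and underestimation (CE > 0) in the high tertile.
"""

from pathlib import Path

import pandas as pd

from wlaqfit import MODEL_FAMILY, cohort_frame, constant_error, fit_ols, read_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    participants, _ = read_cohort(RESULTS / "cohort.csv")
    df = cohort_frame(participants)

    frames = []
    for spec in MODEL_FAMILY:
        if not spec.label.endswith("+pa"):
            continue
        fit = fit_ols(df, spec)
        reports = constant_error(df, fit)
        frame = pd.DataFrame([r.__dict__ for r in reports]).assign(model=spec.label)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True).round(3)
    table.to_csv(RESULTS / "constant_error.csv", index=False)

    bmi_pa = table[table.model == "bmi+pa"]
    print(bmi_pa.drop(columns="model").to_string(index=False))
    tert = bmi_pa[bmi_pa.partition == "fitness_tertile"].set_index("subgroup")
    print(f"\nBMI+PA tertile pattern: Low CE {tert.loc['Low', 'ce']:+.2f} "
          f"(overestimated), High CE {tert.loc['High', 'ce']:+.2f} (underestimated)")


if __name__ == "__main__":
    main()
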