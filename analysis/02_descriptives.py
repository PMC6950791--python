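#!/usr/bin/env python
"""Describe the cohort: sex-stratified means/SDs, group tests, correlations.

Reads results/cohort.csv, validates every row, and writes two tables:
sex-stratified descriptive statistics with Student-t p-values, and Pearson
correlations of every candidate predictor with measured VO2max.
"""

from pathlib import Path

import pandas as pd

from wlaqfit import cohort_frame, pearson_r, read_cohort, two_sample_t

RESULTS = Path(__file__).resolve().parent.parent / "results"

DESCRIPTIVE_VARS = ["age", "bmi", "wg", "pct_fat", "pa_score", "total_sitting", "vo2max"]


def main() -> None:
    participants, rejected = read_cohort(RESULTS / "cohort.csv")
    print(f"{len(participants)} accepted, {len(rejected)} rejected")
    df = cohort_frame(participants)

    rows = []
    for var in DESCRIPTIVE_VARS:
        w = df.loc[df.sex == 0, var]
        m = df.loc[df.sex == 1, var]
        _, p = two_sample_t(w, m)
        rows.append(
            {"variable": var,
             "women_mean": w.mean(), "women_sd": w.std(ddof=1),
             "men_mean": m.mean(), "men_sd": m.std(ddof=1), "p": p}
        )
    desc = pd.DataFrame(rows).round(3)
    desc.to_csv(RESULTS / "descriptives.csv", index=False)
    print(desc.to_string(index=False))

    corr_rows = []
    for var in ("age", "sex", "bmi", "wg", "pct_fat", "pa_score", "total_sitting"):
        r, p = pearson_r(df[var], df["vo2max"])
        corr_rows.append({"variable": var, "r": round(r, 3), "p": round(p, 4)})
    corr = pd.DataFrame(corr_rows)
    corr.to_csv(RESULTS / "correlations.csv", index=False)
    print("\ncorrelations with measured VO2max:")
    print(corr.to_string(index=False))


if __name__ == "__main__":
    main()
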