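#!/usr/bin/env python
"""Draw the synthetic study cohort and its test-retest replicate.

Generates 198 participants (the study's sample size) with sex-stratified
anthropometrics, questionnaire answers and structural-equation VO2max, writes
them in the standard cohort file format, and produces second-visit
questionnaire files for the reliability analysis.
"""

from pathlib import Path

import numpy as np

from wlaqfit import (
    RetestSpec,
    default_cohort_spec,
    generate_cohort,
    generate_retest,
    write_cohort,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20

def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = default_cohort_spec(n=198, seed=SEED)
    cohort = generate_cohort(spec)
    write_cohort(cohort, RESULTS / "cohort.csv")
    n_w = sum(p.sex == 0 for p in cohort)
    print(f"wrote {len(cohort)} participants ({n_w} women, {len(cohort) - n_w} men) "
          f"to results/cohort.csv (seed {SEED})")

    pairs = generate_retest(cohort, RetestSpec(),
                            rng=np.random.default_rng(SEED + 1), cohort_spec=spec)
    for visit, tag in ((0, "visit1"), (1, "visit2")):
        replicate = [
            type(p)(**{**p.__dict__, "response": pair[visit]}).derive()
            for p, pair in zip(cohort, pairs)
        ]
        write_cohort(replicate, RESULTS / f"retest_{tag}.csv")
    print("wrote retest files results/retest_visit1.csv, results/retest_visit2.csv")


if __name__ == "__main__":
    main()
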