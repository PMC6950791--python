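import itertools

import numpy as np
import pytest

from wlaqfit import WLAQResponse, default_cohort_spec, generate_cohort


def enumerate_valid_responses():
    """Every combination of scored answers respecting the skip logic.

    Sitting times are irrelevant to the PA score and left at zero.
    """
    workday = [(1, None, None)] + [
        (q8, q9, q10) for q8 in (2, 3, 4) for q9 in (1, 2, 3, 4) for q10 in (1, 2, 3, 4)
    ]
    holiday = [(1, None, None)] + [
        (q13, q14, q15) for q13 in (2, 3, 4) for q14 in (1, 2, 3, 4) for q15 in (1, 2, 3, 4)
    ]
    for q6, (q8, q9, q10), (q13, q14, q15) in itertools.product((1, 2, 3, 4), workday, holiday):
        yield WLAQResponse(q6=q6, q8=q8, q9=q9, q10=q10, q13=q13, q14=q14, q15=q15)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """400 participants whose VO2max is exactly the published BMI+PA equation."""
    return generate_cohort(default_cohort_spec(n=400, residual_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_cohort():
    """A moderately large cohort with the study's residual noise level."""
    return generate_cohort(default_cohort_spec(n=1500, seed=23))


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
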