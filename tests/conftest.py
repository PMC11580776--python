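"""Shared fixtures: small synthetic cohorts at a reduced sampling rate.

All analysis quantities of interest live below 6 Hz, so unit tests run the
generator at 25 Hz to keep the suite fast; acceptance tests use the full
600 Hz preset rate where the criterion pins it.
"""

import numpy as np
import pytest

import pupresp as pr

FS_FAST = 25.0


@pytest.fixture(scope="session")
def rest_cohort_small():
    """rest_default cohort, n=8, reduced rate."""
    return pr.generate_cohort("rest_default", 8, seed=11, fs=FS_FAST)


@pytest.fixture(scope="session")
def rest_subject(rest_cohort_small):
    return rest_cohort_small.subjects[0]


@pytest.fixture(scope="session")
def clean_subject(rest_subject):
    return pr.preprocess_recording(rest_subject.respiration,
                                   rest_subject.pupil)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
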