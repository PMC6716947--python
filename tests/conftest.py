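import numpy as np
import pytest

from cannonlearn import TaskConfig, generate_session
from cannonlearn.task import CHANGEPOINT, ODDBALL


@pytest.fixture(scope="session")
def changepoint_session():
    return generate_session(TaskConfig(condition=CHANGEPOINT, rng_seed=11))


@pytest.fixture(scope="session")
def oddball_session():
    return generate_session(TaskConfig(condition=ODDBALL, rng_seed=12))


@pytest.fixture(scope="session")
def small_cohort():
    """Ten behavior-only synthetic subjects shared across regression tests."""
    from cannonlearn import build_cohort

    return build_cohort(n_subjects=10, master_seed=5, with_epochs=False)


@pytest.fixture(scope="session")
def eeg_cohort():
    """Twelve subjects with epochs on a 16-channel montage."""
    from cannonlearn import build_cohort

    return build_cohort(n_subjects=12, master_seed=42, n_channels=16)
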