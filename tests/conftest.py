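import numpy as np
import pytest

from fpseq import hazard, paradigm


@pytest.fixture(scope="session")
def actual_session():
    """One participant's session with a sampled ('actual') trial configuration."""
    return paradigm.generate_session(1, seed=7, mode="actual")


@pytest.fixture(scope="session")
def idealized_session():
    """One participant's session drawn from the smooth design profiles."""
    return paradigm.generate_session(1, seed=7, mode="idealized")


@pytest.fixture(scope="session")
def study_hazards():
    """Design-level HF_U and per-(block, FP1-category) HF_C."""
    return hazard.idealized_hazards()


@pytest.fixture()
def rng():
    """Fresh, deterministically seeded generator per test."""
    return np.random.default_rng(20259)
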