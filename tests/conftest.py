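import numpy as np
import pytest
from hypothesis import settings

import emoeeg as e

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def subject_segments():
    """One default synthetic subject (80 trials, fixed seed)."""
    return e.generate_subject(e.default_subject_spec(seed=42))


@pytest.fixture(scope="session")
def feature_tables(subject_segments):
    """All three family tables for the session subject."""
    return e.extract_feature_tables(subject_segments)


@pytest.fixture(scope="session")
def ei_table(feature_tables):
    return feature_tables["ei"]
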