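import numpy as np
import pytest

from emgtune import (
    FilterSpec,
    SyntheticSpec,
    apply_preprocessing,
    extract_feature_matrix,
    generate_records,
)


@pytest.fixture(scope="session")
def small_spec():
    """A fast synthetic world: 6 gestures, 2 channels, 6 s per task."""
    return SyntheticSpec(task_duration_s=6.0, seed=7)


@pytest.fixture(scope="session")
def small_records(small_spec):
    return generate_records(small_spec)


@pytest.fixture(scope="session")
def small_features(small_records):
    fspec = FilterSpec(fs=small_records[0].fs)
    clean = [apply_preprocessing(r, fspec) for r in small_records]
    return extract_feature_matrix(clean)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
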