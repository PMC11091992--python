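import numpy as np
import pytest

from imckit import ClassifierConfig, CurveSpec, generate_trial, study_counts
from imckit.preprocess import preprocess_trial


@pytest.fixture(scope="session")
def counts():
    """The packaged pattern-by-injury contingency table."""
    return study_counts()


@pytest.fixture(scope="session")
def default_config():
    return ClassifierConfig()


@pytest.fixture(scope="session")
def clean_trials():
    """Noise-free preprocessed trials, one per pattern (session-cached)."""
    out = {}
    for pattern in ("Normal", "Valley", "Drop", "Shaking"):
        spec = CurveSpec(pattern=pattern, noise_sd=0.0, seed=3)
        out[pattern] = preprocess_trial(generate_trial(spec))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
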