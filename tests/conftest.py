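import numpy as np
import pytest
from hypothesis import settings

from gcsrasch.registry import apply_exclusions, to_response_matrix
from gcsrasch.synthetic import GeneratorConfig, generate_registry

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_registry():
    """The full-scale registry-mimic fixture at seed 1 (generated once)."""
    return generate_registry(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def cohort(default_registry):
    """Complete adult sample plus its exclusion log."""
    return apply_exclusions(default_registry)


@pytest.fixture(scope="session")
def cohort_matrix(cohort):
    rs, _ = cohort
    return to_response_matrix(rs)


@pytest.fixture(scope="session")
def gcs_like_thresholds():
    """True PCM thresholds for 3 items with maxima (2, 3, 3), centred to
    mean item location zero."""
    truth = (
        np.array([-1.0, 1.0]),
        np.array([-1.5, 0.0, 1.5]),
        np.array([-0.8, 0.15, 0.85]),
    )
    shift = np.mean([t.mean() for t in truth])
    return tuple(t - shift for t in truth)
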