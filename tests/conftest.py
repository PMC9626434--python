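import numpy as np
import pytest

from shoulderkin.synth import (
    AnatomyParams,
    TaskProgram,
    default_template,
    generate_anatomy,
    generate_task,
    synthesize_markers,
)


@pytest.fixture(scope="session")
def truth_anatomy():
    """One synthetic participant: (landmarks, gh_centre, truth model)."""
    return generate_anatomy(AnatomyParams(), seed=1)


@pytest.fixture(scope="session")
def truth_model(truth_anatomy):
    return truth_anatomy[2]


@pytest.fixture(scope="session")
def template_model():
    return default_template()


@pytest.fixture(scope="session")
def aa_trial(truth_model):
    """Noiseless abduction/adduction trial: (q_trajectory, phases, markers)."""
    q, phases = generate_task(TaskProgram("AA"))
    markers = synthesize_markers(truth_model, q, phases, noise=None)
    return q, phases, markers


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
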