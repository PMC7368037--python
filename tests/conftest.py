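import numpy as np
import pytest

from neuromodes import SimulationConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick two-mode cohort used by several modules' tests."""
    config = SimulationConfig(
        n_subjects=80,
        n_rois=30,
        n_modes=2,
        mode_strengths=(0.6, 0.65),
        u_sparsity=0.1,
        seed=42,
    )
    return generate_cohort(config)
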