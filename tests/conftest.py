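import numpy as np
import pytest

from gaitsemg import CONDITIONS, MUSCLES, SimulationConfig, make_activation_template


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast cohort: low sampling rate, short strides, few subjects."""
    templates = {
        cond: {
            m: make_activation_template(m, 55.0, 15.0, 20.0 * f, 2.0)
            for m in MUSCLES
        }
        for cond, f in zip(CONDITIONS, (1.0, 1.5, 1.3))
    }
    return SimulationConfig(
        n_subjects={"patient": 2, "healthy": 2},
        strides_per_subject=8,
        fs_emg=500.0,
        fs_video=50.0,
        templates=templates,
        seed=7,
    )
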