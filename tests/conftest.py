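import numpy as np
import pytest

from crossfreq.synthetic import (
    CouplingSpec,
    Leadfield,
    generate_coupled_signal,
    generate_leadfield,
)

FS = 500.0


@pytest.fixture(scope="session")
def coupled_signal() -> np.ndarray:
    """60 s at 500 Hz with a strong planted (6 Hz, 40 Hz) coupling."""
    return generate_coupled_signal(
        CouplingSpec(phase_freq=6.0, amp_freq=40.0, modulation_depth=0.9),
        duration_s=60.0,
        fs=FS,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_leadfield() -> Leadfield:
    """32 sensors, 12 sources, 6 ROIs."""
    return generate_leadfield(32, 12, 6, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
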