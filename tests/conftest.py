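import numpy as np
import pytest

import filmcal as fc


@pytest.fixture(scope="session")
def truth():
    return fc.default_truth()


@pytest.fixture(scope="session")
def clean_p1(truth):
    """Noise-free 12-level, 3-repetition measurement set."""
    return fc.simulate_measurement_set(noise=fc.NoiseSpec(0, 0, 0, seed=1))


@pytest.fixture(scope="session")
def noisy_p1(truth):
    """Default-noise 12-level, 3-repetition measurement set."""
    return fc.simulate_measurement_set(noise=fc.NoiseSpec(seed=7))


@pytest.fixture(scope="session")
def two_level_train(clean_p1):
    """Training subset: 0.75 and 12 Gy levels (dose ratio 16)."""
    return [m for m in clean_p1 if m.k in (0.75, 12.0)]


@pytest.fixture()
def identity_cal():
    """Polynomial d(o) = o with unit scales."""
    return fc.CalibrationFunction(
        "polynomial", np.array([0.0, 1.0, 0.0, 0.0, 0.0]),
        valid_od_range=(0.01, 2.0),
    )
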