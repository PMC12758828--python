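import numpy as np
import pytest

from coreplasma import (
    ChannelGeometry,
    CorePlasmaParams,
    FlowCondition,
    SyntheticSpec,
    simulate_profile,
)

#: 25 um radius, 10 mm long capillary at 180 mbar: the reference bench
#: condition used throughout the suite
DP = 18000.0


@pytest.fixture
def geom():
    return ChannelGeometry(radius=25e-6, length=10e-3)


@pytest.fixture
def condition():
    return FlowCondition(delta_p=DP)


@pytest.fixture
def twophase_truth():
    """Ground-truth two-phase parameters with a 5 um cell-free layer."""
    return CorePlasmaParams(mu_p=1.5e-3, K_cp=3.0e-3, n_cp=0.9, delta=5e-6)


@pytest.fixture
def twophase_profile(geom, twophase_truth):
    """Noiseless 60-point half-profile from the two-phase forward model."""
    spec = SyntheticSpec(
        model_kind="coreplasma", params=twophase_truth, geometry=geom,
        delta_p=DP, n_points=60, noise_sigma=0.0, seed=0,
    )
    return simulate_profile(spec)


def relerr(a, b):
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    scale = np.maximum(np.abs(b), 1e-300)
    return np.max(np.abs(a - b) / scale)
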