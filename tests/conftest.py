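import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import epidcal as ec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def beam():
    return ec.BeamModel()


@pytest.fixture(scope="session")
def truth_gains():
    """Ground-truth gain map: 2% smooth structure plus 0.5% pixel spread."""
    return ec.make_true_gain_map(
        ec.TrueGainMapSpec(grid_size=46, smooth_amplitude=0.02,
                           pixel_sigma=0.005, seed=11)
    )


@pytest.fixture(scope="session")
def symmetric_gains():
    """Noiseless gain map symmetric about the reference row/column, the
    regime the output-factor correction assumes."""
    return ec.make_true_gain_map(
        ec.TrueGainMapSpec(grid_size=46, smooth_amplitude=0.02,
                           pixel_sigma=0.0, seed=11, symmetrize=True)
    )


@pytest.fixture(scope="session")
def noiseless_set(beam, truth_gains):
    """Five acquisitions with no perturbation of any kind."""
    return ec.simulate_calibration_set(
        beam, truth_gains, ec.PerturbationSpec.none()
    )
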