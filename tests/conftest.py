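import numpy as np
import pytest

from spermtrack.io import Calibration
from spermtrack.synthetic import simulate_video, well_separated_scene


@pytest.fixture(scope="session")
def desk_calibration():
    return Calibration(um_per_px=0.5, fps=30.0)


@pytest.fixture(scope="session")
def well_separated():
    """One well-separated simulated scene, shared across tests (read-only)."""
    return simulate_video(well_separated_scene(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
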