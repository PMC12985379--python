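import numpy as np
import pytest

from ciondose.beamlets import BeamletSpec, generate_ground_truth
from ciondose.grids import CTVolume
from ciondose.phantoms import generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def water_ct():
    """A 48x48x300 all-water phantom (identity medium: WED = depth)."""
    return CTVolume(hu=np.zeros((48, 48, 300), dtype=np.float32))


@pytest.fixture(scope="session")
def small_water_ct():
    """A reduced water phantom matching the test-preset grid."""
    return CTVolume(hu=np.zeros((16, 16, 120), dtype=np.float32))


@pytest.fixture(scope="session")
def water_beamlet(water_ct):
    """Ground-truth volumes for a 160 MeV/u beamlet in water."""
    spec = BeamletSpec(energy=160.0)
    dose, alpha, beta = generate_ground_truth(water_ct, spec)
    return {"ct": water_ct, "spec": spec, "dose": dose,
            "alpha": alpha, "beta": beta}


@pytest.fixture(scope="session")
def mixed_beamlet():
    """Ground truth on a heterogeneous phantom (bone slabs + air cavity)."""
    ct = generate_phantom(7, "mixed")
    spec = BeamletSpec(energy=180.0)
    dose, alpha, beta = generate_ground_truth(ct, spec)
    return {"ct": ct, "spec": spec, "dose": dose, "alpha": alpha, "beta": beta}
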