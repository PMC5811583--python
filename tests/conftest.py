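import numpy as np
import pytest

from scoutdose import (
    PatientSceneSpec,
    PhantomSpec,
    calibrate_phantom,
    generate_patient_scene,
    generate_phantom,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Default noiseless six-sphere phantom image + ground truth."""
    spec = PhantomSpec()
    image, truth = generate_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def default_sweep():
    """Threshold sweep + selection on the default noiseless phantom."""
    return calibrate_phantom()


@pytest.fixture(scope="session")
def default_scene():
    """Default noiseless patient scene (3.7 MBq deposition into 15.3 ml)."""
    return generate_patient_scene(PatientSceneSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
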