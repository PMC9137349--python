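import numpy as np
import pytest

from thermotriage import FaceSpec, RadiometricImage, default_template


@pytest.fixture(scope="session")
def eye_nose_template():
    return default_template("eye_nose_circles")


@pytest.fixture(scope="session")
def clean_spec():
    """Zero-noise, zero-blur face spec: detectors should be exact on it."""
    return FaceSpec(noise_sigma=0.0, blur_sigma=0.0)


@pytest.fixture
def flat_image():
    """A uniform 33 C frame, large enough for the default template."""
    return RadiometricImage(np.full((120, 160), 33.0))


def make_image(temps):
    return RadiometricImage(np.asarray(temps, dtype=float))


@pytest.fixture
def uniform_small():
    """A 20x20 uniform 30 C frame for hand-built extremum cases."""
    return np.full((20, 20), 30.0)
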