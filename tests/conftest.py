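import numpy as np
import pytest

from golgiring.synth import ImagingParams


@pytest.fixture
def imaging():
    """Default optics: 133 nm pixels, 266 nm PSF FWHM, moderate noise."""
    return ImagingParams()


@pytest.fixture
def imaging_clean():
    """Same optics with all noise sources disabled."""
    return ImagingParams(photon_scale=0.0, read_noise_sd=0.0)


@pytest.fixture
def profile_grid():
    """Standard transect sampling: 66.5 nm step over a 2.66 um window."""
    return (np.arange(41) - 20) * 66.5
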