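import numpy as np
import pytest

from algafp.io_formats import ProfileSpectrum
from algafp.synthetic_data import NoiseModel, StrainTemplate, make_template


@pytest.fixture
def flat_spectrum():
    mz = np.arange(2000.0, 3000.0, 1.0)
    return ProfileSpectrum(mz=mz, intensity=np.full(len(mz), 5.0), sample_id="flat")


@pytest.fixture
def gaussian_spectrum():
    """Single Gaussian at m/z 5000, height 1000, FWHM 10, zero noise."""
    mz = np.arange(2000.0, 20001.0, 1.0)
    sigma = 10.0 / 2.3548
    intensity = 1000.0 * np.exp(-0.5 * ((mz - 5000.0) / sigma) ** 2)
    return ProfileSpectrum(mz=mz, intensity=intensity, sample_id="g")


@pytest.fixture
def template() -> StrainTemplate:
    return make_template(seed=1, n_peaks=20, strain_id="strainA")


@pytest.fixture
def noise_model() -> NoiseModel:
    return NoiseModel(seed=7)
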