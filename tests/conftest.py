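"""Shared fixtures: sealed-truth synthetic experiments and spectrum factories."""

import numpy as np
import pytest

from shgsorb import default_truth, simulate_experiment
from shgsorb.spectral import Spectrum


@pytest.fixture(scope="session")
def zero_noise_truth():
    return default_truth(seed=1, noise_multiplicative=0.0, noise_additive=0.0)


@pytest.fixture(scope="session")
def zero_noise_dataset(zero_noise_truth):
    return simulate_experiment(zero_noise_truth)


@pytest.fixture
def gaussian_spectrum():
    """Factory for analytic Gaussian spectra on a dense grid."""

    def make(amplitude=1.0, center=400.0, sigma=None, fwhm=None, baseline=0.0,
             lo=380.0, hi=420.0, step=0.1, meta=None):
        if sigma is None:
            fwhm = 4.7 if fwhm is None else fwhm
            sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        lam = np.arange(lo, hi + step / 2, step)
        counts = baseline + amplitude * np.exp(-0.5 * ((lam - center) / sigma) ** 2)
        return Spectrum(wavelengths=lam, counts=counts, meta=meta or {})

    return make
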