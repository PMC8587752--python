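import numpy as np
import pytest

from ftirage.io_spectra import SampleMeta, SpectraSet, Spectrum
from ftirage.synthetic_data import CohortConfig, generate_cohort


def make_spectrum(wavenumbers, absorbance, tissue="cardiac", age=6, bio=1, tech=1,
                  sample_id="s1"):
    return Spectrum(
        np.asarray(wavenumbers, float),
        np.asarray(absorbance, float),
        SampleMeta(sample_id, tissue, age, bio, tech),
    )


@pytest.fixture
def gaussian_spectrum():
    """Single Gaussian band (a=1, sigma=10) on a 2 cm^-1 grid, no baseline."""
    x = np.arange(1500.0, 1801.0, 2.0)
    y = np.exp(-((x - 1650.0) ** 2) / (2.0 * 10.0**2))
    return make_spectrum(x, y)


@pytest.fixture
def small_cohort():
    """Reduced cohort (2 tissues x 4 ages x 3 animals x 2 replicates)."""
    return generate_cohort(CohortConfig(n_bio=3, n_tech=2, seed=42))


@pytest.fixture
def quiet_cohort():
    """Noiseless, scatter-free cohort: one animal per cell."""
    return generate_cohort(
        CohortConfig(
            n_bio=1,
            n_tech=1,
            noise_sd=0.0,
            scale_jitter_sd=0.0,
            bio_amplitude_sd=0.0,
            baseline_coeffs_sd=(0.0, 0.0, 0.0),
            seed=0,
        )
    )
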