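import numpy as np
import pytest

from ramanlre import simulate as sim


@pytest.fixture(scope="session")
def axis():
    return sim.default_axis()


@pytest.fixture(scope="session")
def library():
    return sim.default_component_library()


@pytest.fixture(scope="session")
def pure_spectra(axis, library):
    return np.vstack([sim.component_spectrum(axis, peaks) for peaks in library])


@pytest.fixture(scope="session")
def small_noise_free():
    """30-sample noise-free three-component mixture dataset."""
    _, truth = sim.tablet_dataset(seed=0, n_samples=30, noise=False)
    return truth


@pytest.fixture(scope="session")
def low_snr_dataset():
    """One realization of the shipped low-SNR benchmark fixture."""
    noisy, truth = sim.tablet_dataset(seed=0)
    return noisy, truth
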