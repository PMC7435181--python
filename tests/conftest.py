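import numpy as np
import pytest

from angulai.spectra_io import AngularSpectraSet, Dataset, WavelengthGrid


def make_spectra(reflectance, wavelengths=None, vza=0.0, ids=None) -> AngularSpectraSet:
    """Build an AngularSpectraSet from a raw matrix for toy tests."""
    reflectance = np.asarray(reflectance, dtype=float)
    n, b = reflectance.shape
    if wavelengths is None:
        wavelengths = np.linspace(400, 900, b)
    if ids is None:
        ids = [f"s{i + 1:03d}" for i in range(n)]
    return AngularSpectraSet(
        vza=vza, grid=WavelengthGrid(np.asarray(wavelengths, float)),
        reflectance=reflectance, sample_ids=ids,
    )


def make_dataset(reflectance, lai, wavelengths=None, vza=0.0) -> Dataset:
    return Dataset(spectra=make_spectra(reflectance, wavelengths, vza), lai=np.asarray(lai, float))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset(rng):
    """20 samples x 10 bands with LAI linearly tied to two bands plus noise."""
    n, b = 20, 10
    refl = np.clip(rng.uniform(0.05, 0.6, size=(n, b)), 0, 1)
    lai = np.clip(2 + 5 * refl[:, 7] - 3 * refl[:, 2] + rng.normal(0, 0.2, n), 0.1, None)
    return make_dataset(refl, lai, wavelengths=np.arange(400, 500, 10))
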