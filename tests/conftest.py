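import numpy as np
import pytest

from incepspect.simulate import (
    MixtureDesign,
    NoiseModel,
    default_grid,
    simulate_dataset,
)
from incepspect.spectra_core import SpectraSet, WavelengthGrid


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    return WavelengthGrid(np.linspace(1000.0, 2400.0, 25))


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 samples, 25 wavelengths, light noise: fast but non-trivial."""
    design = MixtureDesign(
        levels=tuple(np.round(np.linspace(0.0, 1.0, 6), 3)),
        adulterants=("corn_flour", "wheat_bran"),
        replicates_per_level=5,
    )
    return simulate_dataset(design, NoiseModel(seed=7),
                            grid=WavelengthGrid(np.linspace(1000, 2400, 25)))


@pytest.fixture(scope="session")
def noiseless_series():
    """One adulterant, 21 levels, noise-free."""
    design = MixtureDesign(adulterants=("rice_bran",), replicates_per_level=2)
    return simulate_dataset(design, NoiseModel.silent(seed=3),
                            grid=WavelengthGrid(np.linspace(1000, 2400, 40)))


def make_set(X, y, labels=None, grid=None) -> SpectraSet:
    """Assemble a SpectraSet from raw arrays (test plumbing)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if grid is None:
        grid = WavelengthGrid(np.linspace(1000.0, 2400.0, p))
    if labels is None:
        labels = np.array(["corn_flour"] * n, dtype=object)
    return SpectraSet(grid=grid, absorbance=X, target=np.asarray(y, dtype=float),
                      adulterant=np.asarray(labels, dtype=object))
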