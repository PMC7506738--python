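import numpy as np
import pytest

from anthonir.spectra_io import SpectrumSet, default_grid
from anthonir.synthdata import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def coarse_grid():
    """Sparser 16 cm^-1 lattice for cheap simulation-heavy tests."""
    return np.arange(10_000.0, 4000.0 - 2.0, -16.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def make_spectrumset(intensities, grid_, sample_ids=None, replicate_ids=None,
                     mode="reflectance"):
    intensities = np.asarray(intensities, dtype=float)
    n = intensities.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    if replicate_ids is None:
        replicate_ids = np.zeros(n, dtype=int)
    return SpectrumSet(
        wavenumbers=grid_,
        sample_ids=np.asarray(sample_ids, dtype=object),
        replicate_ids=np.asarray(replicate_ids, dtype=int),
        intensities=intensities,
        mode=mode,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset (27 samples x 9 replicates)."""
    cfg = SyntheticConfig(seed=3)
    return generate_dataset(cfg)
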