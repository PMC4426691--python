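import numpy as np
import pytest

from eemfac import (
    ConcentrationDesign,
    FitConfig,
    NoiseModel,
    WavelengthGrid,
    default_grid,
    reference_library,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def coarse_grid():
    """Small grid for fast fits: 24 ex x 61 em points."""
    return WavelengthGrid(
        ex=np.arange(220.0, 451.0, 10.0), em=np.arange(250.0, 551.0, 5.0)
    )


@pytest.fixture(scope="session")
def library():
    return reference_library()


@pytest.fixture(scope="session")
def fast_config():
    return FitConfig(n_starts=2, max_iter=400, seed=0)


@pytest.fixture(scope="session")
def ds3(library, coarse_grid):
    """Noiseless 3-component dataset on the coarse grid, with truth."""
    return simulate_dataset(
        library,
        ["G2", "G6", "G7"],
        ConcentrationDesign(n_samples=24, seed=11),
        grid=coarse_grid,
    )


@pytest.fixture(scope="session")
def ds3_noisy(library, coarse_grid):
    return simulate_dataset(
        library,
        ["G2", "G6", "G7"],
        ConcentrationDesign(n_samples=30, seed=11),
        grid=coarse_grid,
        noise=NoiseModel(additive_sigma=0.01, seed=5),
    )


@pytest.fixture(scope="session")
def model3(ds3, fast_config):
    from eemfac import fit

    dataset, _ = ds3
    return fit(dataset, 3, fast_config)
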