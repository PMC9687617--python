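import numpy as np
import pytest

from mwtbreast import (DatasetSpec, ExperimentConfig, ImagingGrid,
                       MeasurementConfig, build_dataset)


@pytest.fixture(scope="session")
def config():
    return MeasurementConfig()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for solver unit tests (fast dense comparisons)."""
    return ImagingGrid(side=0.15, n=16)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but complete database: 20 phantoms/class on a 32-pixel grid."""
    spec = DatasetSpec(n_per_class=20, master_seed=42,
                       grid=ImagingGrid(n=32), config=MeasurementConfig())
    return build_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
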