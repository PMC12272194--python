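import numpy as np
import pytest

from parcelrsa import (CVScheme, DesignSpec, GeneratorParams, ParcelSpec,
                       generate_experiment, simulate_parcel_responses)


@pytest.fixture(scope="session")
def full_design():
    return DesignSpec()


@pytest.fixture(scope="session")
def full_sequences(full_design):
    return generate_experiment(full_design, rng_seed=11)


@pytest.fixture(scope="session")
def small_design():
    """Six runs (3 sessions x 2), 1200 trials: enough structure for batch and
    run analyses at a fraction of the full-experiment cost."""
    return DesignSpec(runs_per_session=2)


@pytest.fixture(scope="session")
def small_sequences(small_design):
    return generate_experiment(small_design, rng_seed=7)


@pytest.fixture(scope="session")
def small_parcel():
    return ParcelSpec(n_voxels=20, n_timepoints=3)


@pytest.fixture(scope="session")
def small_dataset(small_sequences, small_parcel):
    ds, gt = simulate_parcel_responses(small_sequences, small_parcel,
                                       GeneratorParams(), rng_seed=3)
    return ds, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quick_scheme():
    return CVScheme(n_repeats=3)
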