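import warnings

import pytest

from lythrum.synthetic_data import (
    DesignConfig,
    default_calibration,
    generate_experiment,
)


@pytest.fixture(scope="session")
def calib():
    return default_calibration()


@pytest.fixture(scope="session")
def null_calib(calib):
    return calib.equalized()


@pytest.fixture(scope="session")
def default_ds():
    """One default-calibrated experiment (seed 0), heights included."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_experiment(DesignConfig(rng_seed=0))


@pytest.fixture(scope="session")
def small_ds():
    """A reduced experiment (8 families) for fast pipeline tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_experiment(DesignConfig(n_families=8, rng_seed=3))


def make_dataset(seed, calibration=None, heights=True, n_families=29):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_experiment(
            DesignConfig(n_families=n_families, rng_seed=seed),
            calibration,
            include_heights=heights,
        )
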