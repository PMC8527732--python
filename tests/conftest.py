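import logging

import numpy as np
import pytest

from retinaquant.synthetic_data import (
    AngiogramPhantomSpec,
    BScanPhantomSpec,
    CohortSpec,
    generate_angiogram,
    generate_bscan,
    generate_cohort,
)

logging.getLogger("retinaquant").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def clean_bscan():
    """Noise-free default phantom with ground truth."""
    spec = BScanPhantomSpec(noise_sd=0.0, seed=1)
    bscan, truth = generate_bscan(spec)
    return spec, bscan, truth


@pytest.fixture(scope="session")
def default_angiogram():
    """One mid-density angiogram phantom (slow to build: session scope)."""
    spec = AngiogramPhantomSpec(target_skeleton_density=0.062, seed=3, ssi=55.0)
    angiogram, truth = generate_angiogram(spec)
    return spec, angiogram, truth


@pytest.fixture(scope="session")
def small_cohort():
    df, truth = generate_cohort(CohortSpec(seed=7))
    return df, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
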