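import numpy as np
import pytest

from bpsokit import (
    FitnessSpec,
    SubsetFitness,
    SyntheticFeatureSpec,
    generate_feature_table,
)


@pytest.fixture(scope="session")
def small_table():
    """60 samples, 2 informative + 4 noise features: cheap but learnable."""
    return generate_feature_table(
        SyntheticFeatureSpec(n_samples=60, n_informative=2, n_noise=4, effect_size=2.0, seed=3)
    )


@pytest.fixture(scope="session")
def small_fitness(small_table):
    return SubsetFitness(small_table.values, small_table.labels, FitnessSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def disc_image():
    """Disc of radius 50, level 0.7 over 0.2 background, with its mask."""
    yy, xx = np.mgrid[0:128, 0:128]
    mask = (xx - 64) ** 2 + (yy - 64) ** 2 <= 50**2
    return np.where(mask, 0.7, 0.2), mask
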