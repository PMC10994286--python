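import numpy as np
import pytest

from sorsvf import (
    FieldDataset,
    GridSpec,
    build_24_2_grid,
    build_prior,
    generate_fields,
)


@pytest.fixture(scope="session")
def grid24():
    return build_24_2_grid()


@pytest.fixture(scope="session")
def train200():
    """Synthetic training sample used for priors and normative values."""
    return generate_fields(200, seed=11)


@pytest.fixture(scope="session")
def small60():
    """Small mixed-severity dataset (60 independent fields)."""
    return generate_fields(60, seed=3)


@pytest.fixture(scope="session")
def prior200(train200):
    return build_prior(train200)


@pytest.fixture(scope="session")
def preset278():
    """The default-scale longitudinal preset: 278 eyes x 5 visits."""
    from sorsvf import GeneratorConfig, generate

    return generate(GeneratorConfig())


@pytest.fixture(scope="session")
def rank1_dataset(grid24):
    """Planted one-factor data: x = mu + c * v, random scalars c."""
    rng = np.random.default_rng(42)
    mu = 20 + 5 * rng.random(54)
    v = rng.normal(size=54)
    v /= np.linalg.norm(v)
    c = rng.normal(scale=4.0, size=25)
    X = mu[:, None] + v[None, :].T * c[None, :]
    return FieldDataset(X, [f"e{i}" for i in range(25)], grid=grid24), mu, v, c


@pytest.fixture(scope="session")
def toy6():
    """Six-location toy instance for exhaustive greedy-oracle checks."""
    locations = ((3, 3), (9, 3), (3, 9), (-3, 3), (3, -3), (-3, -3))
    grid = GridSpec(locations=locations)
    rng = np.random.default_rng(7)
    # correlated low-rank-plus-noise data
    F = rng.normal(size=(6, 2))
    Z = rng.normal(size=(2, 40))
    X = 25 + F @ Z + 0.5 * rng.normal(size=(6, 40))
    return FieldDataset(X, [f"e{i}" for i in range(40)], grid=grid)
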