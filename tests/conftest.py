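import numpy as np
import pytest

from odmodels import (
    DistanceMatrix,
    FlowMatrix,
    SiteTable,
    generate_system,
)
from odmodels.synthetic import SyntheticConfig


@pytest.fixture
def tri_sites() -> SiteTable:
    """Three sites with coordinates and distinct count columns."""
    return SiteTable(
        site_id=np.array(["a", "b", "c"], dtype=object),
        population=np.array([100, 200, 50]),
        out_flow=np.array([40, 60, 10]),
        in_flow=np.array([30, 70, 10]),
        lat=np.array([0.0, 0.0, 1.0]),
        lon=np.array([0.0, 1.0, 0.0]),
    )


@pytest.fixture
def tri_distances() -> DistanceMatrix:
    """Distinct, tie-free pairwise distances for three sites."""
    return DistanceMatrix(
        np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.5], [2.0, 1.5, 0.0]])
    )


@pytest.fixture(scope="session")
def synth_system():
    """A small seeded gravity-truth system shared across tests."""
    return generate_system(SyntheticConfig(n_sites=80, seed=11))


def random_system(rng: np.random.Generator, n_sites: int):
    """Random tie-free system for oracle cross-checks.

    Continuous uniform coordinates make exact distance ties a
    measure-zero event, so the radiation row-sum identities apply.
    """
    xy = rng.uniform(0.0, 500.0, size=(n_sites, 2))
    diff = xy[:, None, :] - xy[None, :, :]
    D = DistanceMatrix(np.sqrt((diff**2).sum(axis=-1)))
    t = rng.uniform(10.0, 1000.0, size=n_sites)
    n = rng.uniform(1.0, 500.0, size=n_sites)
    F = FlowMatrix(rng.poisson(3.0, size=(n_sites, n_sites)))
    return D, t, n, F
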