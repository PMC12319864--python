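import numpy as np
import pytest

from thalagrad import connectome, decomposition, synthetic
from thalagrad.core import ConnectivityMatrix
from thalagrad.surfaces import SurfaceMesh, make_sphere_mesh


@pytest.fixture(scope="session")
def mesh1() -> SurfaceMesh:
    return make_sphere_mesh(1)


@pytest.fixture(scope="session")
def mesh2() -> SurfaceMesh:
    return make_sphere_mesh(2)


@pytest.fixture(scope="session")
def mesh3() -> SurfaceMesh:
    return make_sphere_mesh(3)


@pytest.fixture(scope="session")
def grid_small():
    """Coarse seed lattice (~100 seeds) for fast unit tests."""
    return synthetic.make_seed_grid(spacing=3.5)


@pytest.fixture(scope="session")
def grid_default():
    return synthetic.make_seed_grid()


@pytest.fixture(scope="session")
def planted_small(grid_small, mesh2):
    return synthetic.plant_structure(grid_small, mesh2, k=3)


@pytest.fixture(scope="session")
def cohort_small(planted_small):
    return synthetic.simulate_cohort(planted_small, n_subjects=12, rng_seed=5,
                                     template_size=4)


def normalize_cohort(cohort) -> list[ConnectivityMatrix]:
    """Run each cohort matrix through the sigmoid normalization stage."""
    out = []
    for m in cohort.matrices:
        filtered = m.with_values(m.values, "filtered")
        out.append(connectome.normalize_sigmoid(filtered)[0])
    return out


@pytest.fixture(scope="session")
def normalized_small(cohort_small):
    return normalize_cohort(cohort_small)


def random_decomposition(rng, n=30, m=40, k=4) -> decomposition.Decomposition:
    mat = ConnectivityMatrix(rng.normal(size=(n, m)), np.arange(n), np.arange(m),
                             state="normalized")
    return decomposition.decompose_normalized(mat, k)
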