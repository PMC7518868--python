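import numpy as np
import pytest

import covgrad as cg


@pytest.fixture(scope="session")
def geom50():
    return cg.make_sphere_parcellation(50, 4, seed=1)


@pytest.fixture(scope="session")
def truth50(geom50):
    return cg.make_ground_truth(geom50, cg.GroundTruthParams(h2_mean=0.5))


@pytest.fixture(scope="session")
def cohort50(truth50):
    return cg.simulate_cohort(truth50, n_mz=60, n_dz=60, n_singleton=20, seed=11)


@pytest.fixture(scope="session")
def geom_small():
    # coarse mesh keeps geodesic / spin machinery fast
    return cg.make_sphere_parcellation(16, 3, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
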