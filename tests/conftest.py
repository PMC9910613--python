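import logging

import numpy as np
import pytest

from qgdiv.gmatrix import DMatrix, GMatrix
from qgdiv.simulate import SimConfig, simulate_database

logging.getLogger("qgdiv").setLevel(logging.ERROR)


@pytest.fixture
def toy_G() -> GMatrix:
    """2x2 G with eigenvalues 0.03 (along [1,1]/sqrt2) and 0.01."""
    return GMatrix(
        trait_labels=("t1", "t2"),
        values=np.array([[0.02, 0.01], [0.01, 0.02]]),
        n_families=50,
        species="toy_sp",
        study_id="toy_G",
    )


@pytest.fixture
def toy_G3() -> GMatrix:
    """Anisotropic, well-conditioned 3x3 G for brute-force oracles."""
    return GMatrix(
        trait_labels=("t1", "t2", "t3"),
        values=np.array(
            [
                [0.030, 0.010, 0.005],
                [0.010, 0.020, 0.008],
                [0.005, 0.008, 0.015],
            ]
        ),
        n_families=40,
        species="toy_sp3",
    )


@pytest.fixture
def toy_D3(toy_G3) -> DMatrix:
    return DMatrix(trait_labels=toy_G3.trait_labels, values=3.0 * toy_G3.values,
                   n_pops=12)


@pytest.fixture(scope="session")
def small_db():
    """Small deterministic neutral world shared across pipeline tests."""
    return simulate_database(
        SimConfig(n_species=6, studies_per_species=2, k_traits=4, n_pops=8,
                  n_families=40, seed=123)
    )


@pytest.fixture(scope="session")
def uniform_db():
    """Neutral world without trait-category divergence offsets (D prop. G)."""
    return simulate_database(
        SimConfig(n_species=8, studies_per_species=2, k_traits=5, n_pops=8,
                  n_families=40, seed=321,
                  category_effects={"floral": 1.0, "vegetative": 1.0})
    )
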