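"""Shared fixtures: a small fast phantom for unit tests.

The full study phantom and its BEM systems live in a session-scoped bundle
inside test_acceptance.py, shared by all end-to-end checks.
"""

import numpy as np
import pytest

from ecgi.mesh_geometry import make_torso_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse nested phantom: fast to assemble, same topology as the default."""
    return make_torso_phantom(
        {
            "torso": {"refinement": 2},
            "lung_left": {"refinement": 1},
            "lung_right": {"refinement": 1},
            "blood": {"refinement": 1},
            "heart": {"target_vertices": 160},
            "n_electrodes": 40,
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_forward(small_phantom):
    """Forward (refined-mesh) and inverse transfer matrices on the small phantom."""
    from ecgi.gold_standard import fine_transfer_matrix
    from ecgi.volume_conductor import transfer_matrix

    tm_fine, heart_fine = fine_transfer_matrix(small_phantom)
    tm_inv = transfer_matrix(small_phantom, "A")
    return small_phantom, tm_fine, heart_fine, tm_inv
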