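import numpy as np
import pytest

from dynafit.synthetic_data import build_topology
from dynafit.trajectory_io import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_protein():
    """5-residue protein topology with base coordinates (no waters/ligand)."""
    return build_topology(5, seed=0)


@pytest.fixture
def random_trajectory(rng):
    """5-residue, 50-frame trajectory with i.i.d. coordinate noise."""
    top, base = build_topology(5, seed=0)
    coords = base[None] + 0.5 * rng.normal(size=(50, top.n_atoms, 3))
    return Trajectory(top, coords, frame_spacing=10.0)


def random_rotation_matrix(rng):
    """Uniform random rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
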