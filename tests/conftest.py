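import numpy as np
import pytest

from dendromd import synthetic
from dendromd.system import build_toy_dendrimer


@pytest.fixture(scope="session")
def g2_arg():
    return build_toy_dendrimer(2, "2Arg")


@pytest.fixture(scope="session")
def g2_lys():
    return build_toy_dendrimer(2, "2Lys")


@pytest.fixture(scope="session")
def toy_run():
    """Small equilibrated toy-dendrimer Brownian trajectory (G1, 2Arg)."""
    system, traj = synthetic.gen_toy_dendrimer_trajectory(
        generation=1, spacer_kind="2Arg", n_steps=3000, save_every=10,
        burn_in=500, seed=11)
    return system, traj


def random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
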