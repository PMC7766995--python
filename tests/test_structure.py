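"""Structural descriptors: Rg, asphericity, Rh, Re, radial profiles, k45."""

import numpy as np
import pytest

from conftest import random_rotation
from dendromd.io import Trajectory
from dendromd.structure import (ComputationError, asphericity,
                                congregation_coefficient,
                                kirkwood_hydrodynamic_radius,
                                radial_density_profile, radius_of_gyration,
                                terminal_group_radius)
from dendromd.system import AtomRecord, MolecularSystem


def point_system(coords, masses=None, selections=None, charges=None):
    coords = np.asarray(coords, float)
    n = len(coords)
    masses = np.ones(n) if masses is None else masses
    charges = np.zeros(n) if charges is None else charges
    atoms = [AtomRecord(i, "CA", float(masses[i]), float(charges[i]),
                        "backbone", "x") for i in range(n)]
    sel = {"dendrimer": list(range(n)), "dendrimer_heavy": list(range(n))}
    sel.update(selections or {})
    s = MolecularSystem(atoms, sel)
    return Trajectory(np.array([0.0]), coords[None]), s


@pytest.mark.parametrize("coords,expected", [
    ([[0.3, -0.2, 0.7]], 0.0),                       # single atom
    ([[1, 0, 0], [-1, 0, 0]], 1.0),                  # two unit masses
    ([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
     np.sqrt(3.0)),                                  # cube corners
])
def test_rg_closed_forms(coords, expected):
    traj, s = point_system(coords)
    gyr = radius_of_gyration(traj, s)
    assert gyr.rg_mean == pytest.approx(expected, abs=1e-12)
    # eigenvalue trace closure
    assert gyr.eigenvalues.sum() == pytest.approx(expected ** 2, abs=1e-10)


def test_cube_is_spherical():
    coords = [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
              for sz in (-1, 1)]
    traj, s = point_system(coords)
    assert asphericity(radius_of_gyration(traj, s)) == pytest.approx(0.0,
                                                                     abs=1e-12)


def test_asphericity_limits():
    rod, s1 = point_system([[x, 0, 0] for x in np.linspace(-1, 1, 9)])
    assert asphericity(radius_of_gyration(rod, s1)) == pytest.approx(1.0)
    point, s0 = point_system([[0.0, 0.0, 0.0]])
    with pytest.raises(ComputationError):
        asphericity(radius_of_gyration(point, s0))


def test_asphericity_matches_direct_eigen_oracle():
    """Ellipsoid cloud: alpha equals the formula evaluated on an
    independently assembled and diagonalised gyration tensor."""
    rng = np.random.default_rng(3)
    x = rng.standard_normal((500, 3)) * np.array([2.0, 1.0, 1.0])
    traj, s = point_system(x)
    got = asphericity(radius_of_gyration(traj, s))
    xc = x - x.mean(axis=0)
    tensor = xc.T @ xc / len(xc)
    ev = np.sort(np.linalg.eig(tensor)[0].real)
    oracle = 1 - 3 * (ev[0] * ev[1] + ev[0] * ev[2] + ev[1] * ev[2]) \
        / ev.sum() ** 2
    assert got == pytest.approx(oracle, rel=1e-10)


def test_kirkwood_rh_closed_forms():
    traj, s = point_system([[0, 0, 0], [0.8, 0, 0]])
    assert kirkwood_hydrodynamic_radius(traj, s) == pytest.approx(0.8)
    # regular tetrahedron, edge d
    d = 1.2
    verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                     float)
    verts *= d / np.linalg.norm(verts[0] - verts[1])
    traj, s = point_system(verts)
    assert kirkwood_hydrodynamic_radius(traj, s) == pytest.approx(d)


def test_kirkwood_rh_uniform_sphere_limit():
    """Mean inverse chord distance on a spherical surface is 1/R."""
    rng = np.random.default_rng(7)
    u = rng.standard_normal((2000, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    traj, s = point_system(1.5 * u)
    rh = kirkwood_hydrodynamic_radius(traj, s)
    assert rh == pytest.approx(1.5, rel=0.05)


def test_rh_input_validation(toy_run):
    system, traj = toy_run
    with pytest.raises(ComputationError):
        kirkwood_hydrodynamic_radius(traj, system, "no_such_mode")
    tiny, s = point_system([[0, 0, 0]])
    with pytest.raises(ComputationError):
        kirkwood_hydrodynamic_radius(tiny, s)


def test_terminal_radius_closed_forms():
    u = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, 0, 0],
                  [0, -1, 0], [0, 0, -1]], float)
    traj, s = point_system(2.2 * u, selections={"terminal_N": list(range(6))})
    assert terminal_group_radius(traj, s) == pytest.approx(2.2)
    # half at radius 1, half at radius 3 (COM-symmetric) -> sqrt(5)
    coords = np.array([[1, 0, 0], [-1, 0, 0], [0, 3, 0], [0, -3, 0]], float)
    traj, s = point_system(coords, selections={"terminal_N": list(range(4))})
    assert terminal_group_radius(traj, s) == pytest.approx(np.sqrt(5.0))


def test_radial_profile_mass_closure():
    rng = np.random.default_rng(1)
    masses = rng.uniform(1, 20, 300)
    x = rng.standard_normal((300, 3))
    traj, s = point_system(x, masses=masses)
    prof = radial_density_profile(traj, s, dr=0.05)
    total = np.sum(prof.values * prof.shell_volumes())
    assert total == pytest.approx(masses.sum(), rel=1e-2)


def test_radial_profile_uniform_ball_is_flat():
    rng = np.random.default_rng(2)
    r = 2.0 * rng.random(20000) ** (1 / 3)
    u = rng.standard_normal((20000, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    traj, s = point_system(r[:, None] * u)
    prof = radial_density_profile(traj, s, dr=0.1, com_selection="dendrimer")
    expect = 20000 / (4 / 3 * np.pi * 2.0 ** 3)
    inner = prof.values[(prof.r > 0.5) & (prof.r < 1.8)]
    assert np.abs(inner / expect - 1).max() < 0.15


def test_terminal_count_profile_peaks_at_shell():
    u = np.random.default_rng(4).standard_normal((200, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    traj, s = point_system(1.5 * u,
                           selections={"terminal_N": list(range(200))})
    prof = radial_density_profile(traj, s, selection="terminal_N", dr=0.05,
                                  mode="count")
    assert prof.r[np.argmax(prof.values)] == pytest.approx(1.5, abs=0.05)


def test_radial_profile_rejects_bad_dr(toy_run):
    system, traj = toy_run
    with pytest.raises(ComputationError):
        radial_density_profile(traj, system, dr=-0.1)
    with pytest.raises(ComputationError):
        radial_density_profile(traj, system, dr=1e9)


def test_k45_collapsed_limit():
    base = np.array([1.0, 0.3, -0.2])
    coords = np.outer(np.linspace(0.5, 2.0, 16), base / np.linalg.norm(base))
    coords = np.concatenate([coords, [[0, 0, 0]]])   # heavy anchor at COM
    masses = np.ones(17)
    masses[-1] = 1e9
    traj, s = point_system(coords, masses=masses,
                           selections={"terminal_N": list(range(16))})
    k = congregation_coefficient(traj, s)
    assert k == pytest.approx(1.0, abs=1e-9)


def test_k45_uniform_null():
    rng = np.random.default_rng(5)
    frames = []
    for _ in range(650):     # ~10^4 member resamples of 16 directions
        u = rng.standard_normal((16, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        frames.append(np.concatenate([1.8 * u, [[0, 0, 0]]]))
    masses = np.ones(17)
    masses[-1] = 1e9
    coords = np.stack(frames)
    atoms = [AtomRecord(i, "CA", float(masses[i]), 0.0, "backbone", "x")
             for i in range(17)]
    s = MolecularSystem(atoms, {"dendrimer": list(range(17)),
                                "terminal_N": list(range(16))})
    traj = Trajectory(np.arange(650.0), coords)
    assert abs(congregation_coefficient(traj, s)) < 0.05


def test_descriptors_rotation_translation_invariant(toy_run):
    system, traj = toy_run
    sub = Trajectory(traj.times[:20], traj.coords[:20].copy())
    rng = np.random.default_rng(8)
    rot = random_rotation(rng)
    shift = rng.uniform(-5, 5, 3)
    moved = Trajectory(sub.times, sub.coords @ rot.T + shift)
    for fn in (lambda t: radius_of_gyration(t, system).rg_mean,
               lambda t: asphericity(radius_of_gyration(t, system)),
               lambda t: kirkwood_hydrodynamic_radius(t, system),
               lambda t: terminal_group_radius(t, system),
               lambda t: congregation_coefficient(t, system)):
        assert fn(moved) == pytest.approx(fn(sub), rel=1e-8)
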