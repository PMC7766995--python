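"""Hydrogen-bond detection, per-class statistics and continuous lifetimes."""

import numpy as np
import pytest

from conftest import random_rotation
from dendromd import hbonds as hb
from dendromd.io import Trajectory
from dendromd.synthetic import gen_telegraph_bonds
from dendromd.system import AtomRecord, ConfigurationError, MolecularSystem


def dha_system(n_donors=1, n_acceptors=1):
    atoms = []
    for i in range(n_donors):
        atoms.append(AtomRecord(2 * i, "ND", 14.0, 0.0, "other", "x",
                                [2 * i + 1]))
        atoms.append(AtomRecord(2 * i + 1, "HD", 1.0, 0.0, "other", "x",
                                [2 * i]))
    for j in range(n_acceptors):
        atoms.append(AtomRecord(2 * n_donors + j, "OA", 16.0, 0.0, "other",
                                "x"))
    return MolecularSystem(atoms)


def test_detection_trivial_geometries():
    s = dha_system()
    # H on the D->A axis at 0.30 nm: bond
    coords = np.array([[0, 0, 0], [0.1, 0, 0], [0.30, 0, 0.0]])
    assert hb.detect_hbonds(coords, s) == [(0, 1, 2)]
    # same geometry at 0.40 nm: no bond
    coords = np.array([[0, 0, 0], [0.1, 0, 0], [0.40, 0, 0.0]])
    assert hb.detect_hbonds(coords, s) == []
    # angle beyond 30 degrees: no bond
    ang = np.deg2rad(40.0)
    coords = np.array([[0, 0, 0],
                       [0.1 * np.cos(ang), 0.1 * np.sin(ang), 0],
                       [0.30, 0, 0.0]])
    assert hb.detect_hbonds(coords, s) == []


def test_detection_matches_brute_force_oracle():
    """10^4 random triples: identical accept/reject set as direct
    evaluation of both criteria."""
    rng = np.random.default_rng(21)
    s = dha_system(n_donors=40, n_acceptors=50)
    acc = list(range(80, 130))
    n_checked = 0
    for _ in range(5):
        coords = rng.uniform(0, 1.2, (130, 3))
        found = set(hb.detect_hbonds(coords, s, acceptor_ids=acc))
        oracle = set()
        for i in range(40):
            dp, hp = coords[2 * i], coords[2 * i + 1]
            for j in acc:
                ap = coords[j]
                dda = np.linalg.norm(ap - dp)
                v1 = (hp - dp) / np.linalg.norm(hp - dp)
                v2 = (ap - dp) / dda
                ang = np.degrees(np.arccos(np.clip(v1 @ v2, -1, 1)))
                if dda < 0.35 and ang < 30.0:
                    oracle.add((2 * i, 2 * i + 1, j))
                n_checked += 1
        assert found == oracle
    assert n_checked == 10000


def test_detection_rotation_translation_invariant():
    rng = np.random.default_rng(22)
    s = dha_system(n_donors=10, n_acceptors=15)
    coords = rng.uniform(0, 0.8, (35, 3))
    rot = random_rotation(rng)
    moved = coords @ rot.T + rng.uniform(-3, 3, 3)
    assert set(hb.detect_hbonds(coords, s)) == \
        set(hb.detect_hbonds(moved, s))


def test_donor_without_hydrogen_rejected():
    atoms = [AtomRecord(0, "ND", 14.0, 0.0, "other", "x")]
    s = MolecularSystem(atoms)
    with pytest.raises(ConfigurationError, match="without bonded hydrogens"):
        hb.donors_and_acceptors(s, donor_ids=[0])


def test_statistics_partner_classes(toy_run):
    system, traj = toy_run
    sub = Trajectory(traj.times[:10], traj.coords[:10])
    s_id = hb.hbond_statistics(sub, system, "intra-dendrimer")
    s_side = hb.hbond_statistics(sub, system, "side-side")
    assert s_id.counts.shape == (10,)
    assert np.all(s_id.counts >= 0)
    assert s_side.mean <= s_id.mean + 1e-12   # side-side is a sub-class
    vals, freqs = s_id.histogram
    assert freqs.sum() == pytest.approx(1.0)
    with pytest.raises(Exception):
        hb.hbond_statistics(sub, system, "bogus-class")


def test_per_spacer_normalisation():
    assert round(hb.per_spacer_count(165.9, 28), 1) == 5.9
    assert round(hb.per_spacer_count(123.9, 28), 1) == 4.4


def test_event_extraction_conventions():
    # satisfied on frames 10..29, crossings at frame boundaries, dt=0.1
    m = -np.ones(50)
    m[10:30] = 1.0
    ev = hb.events_from_margin(m, 0.1, refine=False)
    assert len(ev) == 1
    assert ev[0].duration == pytest.approx(2.0)
    # single-frame event without refinement has duration dt
    m = -np.ones(20)
    m[5] = 1.0
    ev = hb.events_from_margin(m, 0.1, refine=False)
    assert ev[0].duration == pytest.approx(0.1)
    # event touching the boundary is censored
    m = np.ones(20)
    ev = hb.events_from_margin(m, 0.1)
    assert ev[0].censored
    res = hb.continuous_lifetimes(ev)
    assert res["n_censored"] == 1 and res["n_events"] == 0


def test_spline_refinement_recovers_exact_crossings():
    """Linear margin crossing between samples: refined duration is exact."""
    dt = 0.1
    t = np.arange(100) * dt
    # on from t=2.03 to t=7.61; margin = tent around the interval
    t0, t1 = 2.03, 7.61
    m = np.minimum(t - t0, t1 - t)
    ev = hb.events_from_margin(m, dt)
    assert len(ev) == 1
    assert ev[0].duration == pytest.approx(t1 - t0, abs=1e-6)


def test_telegraph_lifetime_recovery():
    s = gen_telegraph_bonds(10000, mean_on=110.0, mean_off=30.0, dt=0.1,
                            seed=23)
    res = hb.continuous_lifetimes(hb.events_from_margin(s.margins, s.dt))
    assert res["mean_lifetime"] == pytest.approx(
        s.true_on_durations.mean(), rel=0.05)


def test_heavy_discretisation_bias_is_reported():
    """mean on-time == dt: the estimator is strongly biased upward because
    sub-dt events vanish and surviving events are length-biased."""
    s = gen_telegraph_bonds(4000, mean_on=0.1, mean_off=1.0, dt=0.1, seed=24)
    res = hb.continuous_lifetimes(hb.events_from_margin(s.margins, s.dt))
    truth = s.true_on_durations.mean()
    assert res["mean_lifetime"] > truth        # documented bias direction
    assert res["n_events"] < len(s.true_on_durations)


def test_bond_margin_series_tracks_geometry():
    s = dha_system()
    coords = np.zeros((3, 3, 3))
    coords[:, 1, 0] = 0.1
    coords[0, 2, 0] = 0.30   # bonded
    coords[1, 2, 0] = 0.34   # bonded, smaller margin
    coords[2, 2, 0] = 0.45   # broken
    traj = Trajectory(np.arange(3.0), coords)
    m = hb.bond_margin_series(traj, s, (0, 1, 2))
    assert m[0] > m[1] > 0 > m[2]
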