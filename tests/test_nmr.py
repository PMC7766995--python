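"""Orientational ACFs, characteristic times, J(w) and relaxation rates."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import bisect

from dendromd import nmr
from dendromd.synthetic import gen_rotational_diffusion


def make_cf(lags, values, order="P2"):
    return nmr.CorrelationFunction(np.asarray(lags, float),
                                   np.asarray(values, float), order)


def test_frozen_vector_acfs_are_unity():
    vs = nmr.VectorSeries(np.arange(100.0),
                          np.tile([0.0, 0.0, 1.0], (100, 1, 1)))
    p1 = nmr.acf_p1(vs, max_lag=20)
    p2 = nmr.acf_p2(vs, max_lag=20)
    assert np.allclose(p1.values, 1.0, atol=1e-12)
    assert np.allclose(p2.values, 1.0, atol=1e-12)


def test_planar_rotator_legendre_values():
    """90 degrees per frame: at lag 1, P1 = 0 and P2 = -1/2."""
    v = np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]] * 25, float)
    vs = nmr.VectorSeries(np.arange(100.0), v[:, None, :])
    p1 = nmr.acf_p1(vs, max_lag=2)
    p2 = nmr.acf_p2(vs, max_lag=2)
    assert p1.values[0] == pytest.approx(1.0)
    assert p2.values[0] == pytest.approx(1.0)
    assert p1.values[1] == pytest.approx(0.0, abs=1e-12)
    assert p2.values[1] == pytest.approx(-0.5)
    # and the P2 = P1^3 identity must fail badly for this motion
    rep = nmr.p1_cubed_check(p1, p2, p1_floor=-2.0, tolerance=1e-3)
    assert rep.max_abs_deviation > 0.4
    assert not rep.passed


def test_rotational_diffusion_parameter_recovery():
    """tau_1 = 1/(2 Dr), tau_2 = 1/(6 Dr) within 3%; ratio 3 within 5%."""
    d_rot = 0.02
    vs = gen_rotational_diffusion(100000, 0.1, d_rot, n_vectors=40, seed=31,
                                  dtype=np.float32)
    p1 = nmr.acf_p1(vs, max_lag=1200)
    p2 = nmr.acf_p2(vs, max_lag=1200)
    t1 = nmr.characteristic_time(p1)
    t2 = nmr.characteristic_time(p2)
    assert not t1.censored and not t2.censored
    assert t2.tau == pytest.approx(1 / (6 * d_rot), rel=0.03)
    assert t1.tau == pytest.approx(1 / (2 * d_rot), rel=0.03)
    assert t1.tau / t2.tau == pytest.approx(3.0, rel=0.05)


def test_scalar_acf_normalisation_and_errors():
    rng = np.random.default_rng(32)
    x = rng.standard_normal(5000)
    cf = nmr.acf_scalar(np.arange(5000.0), x)
    assert cf.values[0] == pytest.approx(1.0)
    with pytest.raises(nmr.AnalysisError):
        nmr.acf_scalar(np.arange(100.0), np.full(100, 3.14))


def test_characteristic_time_exponential_and_censoring():
    t = np.arange(0, 50, 0.1)
    ct = nmr.characteristic_time(make_cf(t, np.exp(-t / 5.0)))
    assert ct.tau == pytest.approx(5.0, rel=1e-4)
    # estimator identity on exponentials holds at any scale (ns regime)
    t_ns = np.arange(0, 60000.0, 10.0)
    ct2 = nmr.characteristic_time(make_cf(t_ns, np.exp(-t_ns / 11900.0)))
    assert ct2.tau == pytest.approx(11900.0, rel=1e-4)
    slow = nmr.characteristic_time(make_cf(t, np.exp(-t / 1e6)))
    assert slow.censored


def test_characteristic_time_biexponential_matches_root_oracle():
    w1, tau1, w2, tau2 = 0.6, 2.0, 0.4, 20.0
    t = np.arange(0, 200, 0.05)
    f = lambda x: w1 * np.exp(-x / tau1) + w2 * np.exp(-x / tau2)  # noqa
    ct = nmr.characteristic_time(make_cf(t, f(t)))
    oracle = bisect(lambda x: f(x) - 1 / np.e, 0.01, 100.0, xtol=1e-10)
    assert ct.tau == pytest.approx(oracle, rel=1e-3)


def test_spectral_density_lorentzian():
    tau = 5.0
    t = np.arange(0, 200, 0.05)
    cf = make_cf(t, np.exp(-t / tau))
    om = np.geomspace(0.01 / tau, 100 / tau, 60)
    j = nmr.spectral_density(cf, om)
    assert np.abs(j / nmr.lorentzian_j(om, tau) - 1).max() < 0.01


def test_spectral_density_white_limit():
    tau = 0.02
    t = np.arange(0, 20, 0.005)
    cf = make_cf(t, np.exp(-t / tau))
    om = np.array([0.0, 0.5, 1.0])
    j = nmr.spectral_density(cf, om)
    assert np.allclose(j, 2 * tau, rtol=0.01)


def test_spectral_density_biexponential_matches_quadrature_oracle():
    w1, tau1, w2, tau2 = 0.7, 1.0, 0.3, 30.0
    t = np.arange(0, 400, 0.02)
    cf = make_cf(t, w1 * np.exp(-t / tau1) + w2 * np.exp(-t / tau2))
    om = np.geomspace(0.005, 20.0, 12)
    j = nmr.spectral_density(cf, om)
    for k, w in enumerate(om):
        oracle = 2 * quad(
            lambda x: (w1 * np.exp(-x / tau1) + w2 * np.exp(-x / tau2))
            * np.cos(w * x), 0, np.inf, limit=2000)[0]
        assert j[k] == pytest.approx(oracle, rel=0.01)


def test_truncate_mode_warns_on_undecayed_acf():
    t = np.arange(0, 10, 0.1)
    cf = make_cf(t, np.exp(-t / 100.0))
    with pytest.warns(UserWarning, match="not decayed"):
        nmr.spectral_density(cf, np.array([0.1]), tail_mode="truncate")


def test_reduced_rate_closed_form_and_limits():
    tau = 5.0
    t = np.arange(0, 300, 0.05)
    cf = make_cf(t, np.exp(-t / tau))
    om = np.geomspace(1e-4, 20 / tau, 40)
    red = nmr.reduced_rate(cf, om)
    closed = om * (nmr.lorentzian_j(om, tau)
                   + 4 * nmr.lorentzian_j(2 * om, tau))
    assert np.abs(red / closed - 1).max() < 0.01
    # w -> 0 limit: rate vanishes linearly (extreme narrowing)
    assert nmr.reduced_rate(cf, np.array([1e-7]))[0] < 1e-4
    # peak location matches a brute-force scan of the closed form
    scan = np.geomspace(1e-3, 10, 20000) / tau
    peak_oracle = scan[np.argmax(scan * (nmr.lorentzian_j(scan, tau)
                                         + 4 * nmr.lorentzian_j(2 * scan,
                                                                tau)))]
    fine = np.geomspace(1e-3, 10, 2000) / tau
    peak = fine[np.argmax(nmr.reduced_rate(cf, fine))]
    assert peak == pytest.approx(peak_oracle, rel=0.01)


def test_susceptibility_conversion_arithmetic():
    rate = nmr.t1_susceptibility(1.0, a0=0.56e10, omega_h=2 * np.pi * 4e8)
    assert rate == pytest.approx(0.56e10 / (2 * np.pi * 4e8), rel=1e-12)
    assert rate == pytest.approx(2.228, abs=0.001)
    assert nmr.t1_susceptibility(2.0) == pytest.approx(
        2 * nmr.t1_susceptibility(1.0))
    assert nmr.t1_susceptibility(0.0) == 0.0
    with pytest.raises(nmr.AnalysisError):
        nmr.t1_susceptibility(1.0, a0=-1.0)


def test_transform_consistency_inverse_recovers_p2():
    """Numerically inverting J(w) recovers P2(t) within 2% on the window."""
    tau = 5.0
    t = np.arange(0, 250, 0.05)
    cf = make_cf(t, np.exp(-t / tau))
    om = np.linspace(1e-4, 40 / tau, 20000)
    j = nmr.spectral_density(cf, om)
    ts = np.arange(0.5, 12.0, 0.5)
    rec = np.array([np.trapezoid(j * np.cos(om * x), om) for x in ts]) / np.pi
    assert np.abs(rec - np.exp(-ts / tau)).max() < 0.02


def test_group_mobility_recovers_per_class_times():
    """Vector classes with assigned Dr per topological distance are
    recovered within 5% and ordered by class."""
    from dendromd.io import Trajectory
    from dendromd.system import build_toy_dendrimer, hh_pairs_by_distance

    system = build_toy_dendrimer(1, "2Arg")
    n, dt = 30000, 0.1
    dr_by_class = {3: 0.08, 4: 0.04, 5: 0.02}
    coords = np.zeros((n, system.n_atoms, 3), dtype=np.float32)
    pairs = hh_pairs_by_distance(system)
    for dist, plist in pairs.items():
        vs = gen_rotational_diffusion(n, dt, dr_by_class[dist],
                                      n_vectors=len(plist), seed=33 + dist,
                                      dtype=np.float32)
        for k, (h1, h2) in enumerate(plist):
            coords[:, h2] = 0.05 * vs.vectors[:, k]
            coords[:, h1] = -0.05 * vs.vectors[:, k]
    traj = Trajectory(np.arange(n) * dt, coords)
    mob = nmr.group_mobility_by_topology(traj, system, max_lag=2000)
    for dist, rec in mob.items():
        assert rec["tau"].tau == pytest.approx(
            1 / (6 * dr_by_class[dist]), rel=0.05)
    taus = [mob[d]["tau"].tau for d in (3, 4, 5)]
    assert taus == sorted(taus)
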