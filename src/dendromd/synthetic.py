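"""Synthetic inputs with analytically known statistical structure.

Every generator here stands in for a class of trajectory data the analysis
modules consume, and ships its ground truth alongside:

* isotropic rotational diffusion of unit vectors -> P1 = exp(-2 Dr t),
  P2 = exp(-6 Dr t) exactly;
* an Ornstein-Uhlenbeck scalar (size-pulsation stand-in) -> ACF exp(-t/theta);
* a radially structured charge cloud with a counterion double layer ->
  closed-form cumulative charge Q(r);
* a two-state telegraph bond process -> exponential on-times with the exact
  continuous durations retained;
* a coarse-grained dendrimer trajectory from an overdamped (Brownian)
  harmonic-bond + soft-repulsion integrator, for end-to-end pipeline runs.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import norm as _norm

from .io import Trajectory
from .nmr import VectorSeries
from .system import (AtomRecord, ConfigurationError, MolecularSystem,
                     add_water, build_toy_dendrimer)


@dataclass
class GeneratorSpec:
    """Reproducibility manifest for one synthetic dataset."""

    kind: str
    parameters: dict = field(default_factory=dict)
    n_steps: int = 0
    dt: float = 0.1
    seed: int = 0


class StepSizeError(ValueError):
    """Integrator step outside its validity regime."""


# ---------------------------------------------------------------------------
# rotational diffusion
# ---------------------------------------------------------------------------

def gen_rotational_diffusion(n_steps: int, dt: float, d_rot: float,
                             n_vectors: int = 1, seed: int = 0,
                             dtype=np.float64) -> VectorSeries:
    """Unit vectors under isotropic rotational diffusion.

    Each step applies a small random rotation with angular variance
    4*Dr*dt about a random transverse axis; the exact orientational ACFs
    are P1(t) = exp(-2 Dr t) and P2(t) = exp(-6 Dr t).  The small-angle
    update requires Dr*dt <= 0.01.
    """
    if d_rot < 0:
        raise ConfigurationError("d_rot must be >= 0")
    if d_rot * dt > 0.01:
        raise StepSizeError(
            f"Dr*dt = {d_rot * dt:.3g} violates the small-angle regime "
            "(need <= 0.01)")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_vectors, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    out = np.empty((n_steps, n_vectors, 3), dtype=dtype)
    sigma = np.sqrt(2.0 * d_rot * dt)
    if sigma == 0.0:
        out[:] = u[None]
    else:
        # chunk the Gaussian increments to bound memory; the sequential
        # rotation update itself runs in a compiled kernel when available
        chunk = 4096
        start = 0
        while start < n_steps:
            stop = min(start + chunk, n_steps)
            g = rng.standard_normal((stop - start, n_vectors, 2)) * sigma
            _rotation_walk(u, g, out[start:stop])
            start = stop
    return VectorSeries(np.arange(n_steps) * dt, out,
                        label=f"rotdiff Dr={d_rot}")


def _rotation_walk_py(u: np.ndarray, g: np.ndarray,
                      out: np.ndarray) -> None:
    """Sequential small-rotation update; ``u`` is advanced in place."""
    helper = np.array([1.0, 0.0, 0.0])
    other = np.array([0.0, 1.0, 0.0])
    for k in range(len(g)):
        out[k] = u
        a = np.where(np.abs(u[:, :1]) < 0.9, helper, other)
        e1 = np.cross(u, a)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(u, e1)
        w = g[k, :, :1] * e1 + g[k, :, 1:] * e2
        theta = np.linalg.norm(w, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            what = np.where(theta > 0, w / theta, 0.0)
        u[:] = u * np.cos(theta) + what * np.sin(theta)
        u /= np.linalg.norm(u, axis=1, keepdims=True)


try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _rotation_walk_nb(u, g, out):   # pragma: no cover - compiled
        n_steps, m = g.shape[0], g.shape[1]
        for k in range(n_steps):
            for i in range(m):
                ux, uy, uz = u[i, 0], u[i, 1], u[i, 2]
                out[k, i, 0] = ux
                out[k, i, 1] = uy
                out[k, i, 2] = uz
                if abs(ux) < 0.9:
                    ax, ay, az = 1.0, 0.0, 0.0
                else:
                    ax, ay, az = 0.0, 1.0, 0.0
                e1x = uy * az - uz * ay
                e1y = uz * ax - ux * az
                e1z = ux * ay - uy * ax
                inv = 1.0 / np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
                e1x *= inv
                e1y *= inv
                e1z *= inv
                e2x = uy * e1z - uz * e1y
                e2y = uz * e1x - ux * e1z
                e2z = ux * e1y - uy * e1x
                g1, g2 = g[k, i, 0], g[k, i, 1]
                wx = g1 * e1x + g2 * e2x
                wy = g1 * e1y + g2 * e2y
                wz = g1 * e1z + g2 * e2z
                th = np.sqrt(wx * wx + wy * wy + wz * wz)
                if th > 0.0:
                    c, s = np.cos(th), np.sin(th)
                    ux = ux * c + wx / th * s
                    uy = uy * c + wy / th * s
                    uz = uz * c + wz / th * s
                    inv = 1.0 / np.sqrt(ux * ux + uy * uy + uz * uz)
                    u[i, 0] = ux * inv
                    u[i, 1] = uy * inv
                    u[i, 2] = uz * inv

    def _rotation_walk(u, g, out):
        if out.dtype == np.float64:
            _rotation_walk_nb(u, g, out)
        else:
            buf = np.empty(out.shape, np.float64)
            _rotation_walk_nb(u, g, buf)
            out[:] = buf

except ImportError:   # pragma: no cover - numba is an optional speed-up
    _rotation_walk = _rotation_walk_py


def rotational_diffusion_acf(t: np.ndarray, d_rot: float,
                             order: int = 2) -> np.ndarray:
    """Ground-truth ACF exp(-l(l+1) Dr t) for isotropic diffusion."""
    ll = order * (order + 1)
    return np.exp(-ll * d_rot * np.asarray(t, float))


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck scalar
# ---------------------------------------------------------------------------

def gen_ou_scalar(n_steps: int, dt: float, corr_time: float,
                  mean: float = 4.0, sd: float = 0.3,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mean-reverting Gaussian series with exact ACF exp(-t/corr_time).

    Uses the exact AR(1) discretisation of the Ornstein-Uhlenbeck process,
    so the stationary mean/sd and the ACF hold at any dt.  Defaults emulate
    an Rg^2 series pulsating in the band an equilibrated dendrimer shows
    (Rg between roughly 1.7 and 2.3 nm around a 2.0 nm mean).
    """
    if corr_time <= 0:
        raise ConfigurationError("corr_time must be > 0")
    rng = np.random.default_rng(seed)
    phi = np.exp(-dt / corr_time)
    x = np.empty(n_steps)
    x[0] = mean + sd * rng.standard_normal()
    noise = sd * np.sqrt(1 - phi ** 2) * rng.standard_normal(n_steps - 1)
    for k in range(1, n_steps):
        x[k] = mean + phi * (x[k - 1] - mean) + noise[k - 1]
    return np.arange(n_steps) * dt, x


# ---------------------------------------------------------------------------
# double-layer charge cloud
# ---------------------------------------------------------------------------

@dataclass
class DoubleLayerTruth:
    """Closed-form description of the generated double layer."""

    n_plus: int
    n_minus: int
    shell_mu: float
    shell_sigma: float
    decay_length: float

    def cumulative_charge(self, r: np.ndarray) -> np.ndarray:
        """Analytic expectation of Q(r) in e."""
        r = np.asarray(r, float)
        plus = self.n_plus * _norm.cdf((r - self.shell_mu) / self.shell_sigma)
        minus = np.where(
            r > self.shell_mu,
            self.n_minus * (1 - np.exp(-(r - self.shell_mu)
                                       / self.decay_length)),
            0.0)
        return plus - minus

    def r_max(self, grid_dr: float = 1e-3) -> float:
        r = np.arange(grid_dr, self.shell_mu + 12 * self.decay_length,
                      grid_dr)
        q = self.cumulative_charge(r)
        return float(r[np.argmax(q)])

    def q_star(self) -> float:
        return float(self.cumulative_charge(np.array([self.r_max()]))[0])


def gen_double_layer_cloud(n_plus: int = 44, n_minus: int = 44,
                           shell_mu: float = 2.6, shell_sigma: float = 0.3,
                           decay_length: float = 1.0, n_frames: int = 200,
                           seed: int = 0
                           ) -> tuple[MolecularSystem, Trajectory,
                                      DoubleLayerTruth]:
    """Radially structured charge cloud with a counterion double layer.

    Positive unit charges sit at Gaussian-distributed radii about
    ``shell_mu``; counterions at exponentially distributed excess radii
    beyond the shell.  Positions are redrawn independently every frame, so
    frame averaging converges to the closed-form Q(r) of the returned
    :class:`DoubleLayerTruth`.  A heavy neutral bead pins the centre of
    mass at the origin.
    """
    if n_plus != n_minus:
        import warnings
        warnings.warn("non-neutral double-layer spec", stacklevel=2)
    rng = np.random.default_rng(seed)
    atoms = [AtomRecord(0, "CC", 1e9, 0.0, "core", "anchor")]
    for k in range(n_plus):
        atoms.append(AtomRecord(1 + k, "CQ", 12.0, +1.0, "side_segment",
                                "charged-site"))
    for k in range(n_minus):
        atoms.append(AtomRecord(1 + n_plus + k, "CL", 35.45, -1.0,
                                "counterion", "ion-Cl"))
    sel = {
        "dendrimer": list(range(1 + n_plus)),
        "dendrimer_heavy": list(range(1 + n_plus)),
        "charged_side_groups": list(range(1, 1 + n_plus)),
        "ions": list(range(1 + n_plus, 1 + n_plus + n_minus)),
    }
    system = MolecularSystem(atoms, sel)

    n_atoms = system.n_atoms
    coords = np.zeros((n_frames, n_atoms, 3))
    for f in range(n_frames):
        r_plus = np.abs(rng.normal(shell_mu, shell_sigma, n_plus))
        r_minus = shell_mu + rng.exponential(decay_length, n_minus)
        radii = np.concatenate([r_plus, r_minus])
        dirs = rng.standard_normal((n_plus + n_minus, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        coords[f, 1:] = radii[:, None] * dirs
    traj = Trajectory(np.arange(n_frames, dtype=float), coords)
    truth = DoubleLayerTruth(n_plus, n_minus, shell_mu, shell_sigma,
                             decay_length)
    return system, traj, truth


# ---------------------------------------------------------------------------
# telegraph bond process
# ---------------------------------------------------------------------------

@dataclass
class TelegraphSample:
    """Sampled bond-criterion margin plus its continuous ground truth."""

    margins: np.ndarray          # sampled signed margin
    dt: float
    transitions: np.ndarray      # continuous transition times (ps)
    starts_on: bool
    true_on_durations: np.ndarray  # complete on-intervals inside the window


def gen_telegraph_bonds(n_events: int, mean_on: float, mean_off: float,
                        dt: float, seed: int = 0) -> TelegraphSample:
    """Two-state bond process with exponential on/off durations.

    The sampled margin is the signed distance to the nearest state
    transition (positive while bonded), which crosses zero linearly at the
    exact transition instants — the signal shape the spline refinement of
    the lifetime estimator expects.
    """
    if mean_on <= 0 or mean_off <= 0:
        raise ConfigurationError("mean_on and mean_off must be > 0")
    rng = np.random.default_rng(seed)
    on = rng.exponential(mean_on, n_events)
    off = rng.exponential(mean_off, n_events + 1)
    # off, on, off, on, ... off
    durations = np.empty(2 * n_events + 1)
    durations[0::2] = off
    durations[1::2] = on
    transitions = np.cumsum(durations)[:-1]
    total = durations.sum()
    t = np.arange(0.0, total, dt)
    # state after k-th transition alternates starting from off
    idx = np.searchsorted(transitions, t, side="right")
    state = idx % 2 == 1
    nearest = np.minimum(
        np.abs(t - transitions[np.minimum(idx, len(transitions) - 1)]),
        np.abs(t - transitions[np.maximum(idx - 1, 0)]))
    margins = np.where(state, nearest, -nearest)
    return TelegraphSample(margins=margins, dt=dt, transitions=transitions,
                           starts_on=False, true_on_durations=on)


# ---------------------------------------------------------------------------
# toy dendrimer Brownian trajectory
# ---------------------------------------------------------------------------

def _initial_coords(system: MolecularSystem, seed: int,
                    bond_length: float = 0.15) -> np.ndarray:
    """Deterministic tree embedding: children placed outward from parents."""
    rng = np.random.default_rng(seed)
    n = system.n_atoms
    x = np.full((n, 3), np.nan)
    placed = np.zeros(n, bool)
    from .io import _bond_walk_order
    dend = system.dendrimer_ids()
    order = _bond_walk_order(system, dend)
    for i, parent in order:
        if parent is None:
            x[i] = 0.0
        else:
            outward = x[parent]
            nrm = np.linalg.norm(outward)
            bias = outward / nrm if nrm > 1e-9 else np.zeros(3)
            d = 0.8 * bias + rng.standard_normal(3)
            d /= np.linalg.norm(d)
            length = bond_length * (0.7 if system.atoms[i].element == "H"
                                    else 1.0)
            x[i] = x[parent] + length * d
        placed[i] = True
    # counterions in a shell, waters in a ball
    for i in range(n):
        if placed[i]:
            continue
        a = system.atoms[i]
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        if a.role == "counterion":
            x[i] = (1.5 + 2.0 * rng.random()) * d
        elif a.role == "water_oxygen":
            x[i] = 4.0 * rng.random() ** (1 / 3) * d
        else:  # water hydrogens: near their oxygen
            o = a.bonded_ids[0]
            if np.isnan(x[o]).any():
                x[o] = 4.0 * rng.random() ** (1 / 3) * d
            x[i] = x[o] + 0.1 * d
        placed[i] = True
    return x


def gen_toy_dendrimer_trajectory(generation: int = 1,
                                 spacer_kind: str = "2Arg",
                                 n_steps: int = 5000, dt: float = 2e-4,
                                 save_every: int = 10, kt: float = 1.0,
                                 n_water: int = 0, seed: int = 0,
                                 burn_in: int = 0
                                 ) -> tuple[MolecularSystem, Trajectory]:
    """Overdamped Brownian trajectory of a toy dendrimer.

    Harmonic bonds (k = 200 kT/nm^2, r0 = 0.15 nm), a soft pairwise
    repulsion between non-bonded sites within 0.25 nm, and a weak radial
    tether on counterions standing in for their electrostatic confinement.
    Friction is unity, so the update is x += F dt + sqrt(2 kT dt) xi.
    Frames are saved every ``save_every`` steps with the dendrimer COM
    drift removed; times are in ps with one step = dt ps.
    """
    system = build_toy_dendrimer(generation, spacer_kind)
    if n_water:
        system = add_water(system, n_water, box=8.0, seed=seed)
    rng = np.random.default_rng(seed)
    x = _initial_coords(system, seed)
    n = system.n_atoms

    k_bond, r0_heavy, r0_h = 200.0 * kt, 0.15, 0.105
    rc, a_rep = 0.25, 50.0 * kt
    k_tether = 2.0 * kt
    bonds = np.array(system.bonds())
    bi, bj = bonds[:, 0], bonds[:, 1]
    is_h = np.array([(system.atoms[i].element == "H"
                      or system.atoms[j].element == "H")
                     for i, j in bonds])
    r0 = np.where(is_h, r0_h, r0_heavy)
    bonded_mask = np.zeros((n, n), bool)
    bonded_mask[bi, bj] = bonded_mask[bj, bi] = True
    np.fill_diagonal(bonded_mask, True)
    ions = np.array(system.ids_with_role("counterion"), int)
    dend = system.dendrimer_ids()
    m_dend = system.masses[dend]

    noise_sd = np.sqrt(2.0 * kt * dt)
    frames, times = [], []
    for step in range(n_steps):
        f = np.zeros_like(x)
        # bonds
        dvec = x[bj] - x[bi]
        dist = np.linalg.norm(dvec, axis=1)
        fb = (k_bond * (dist - r0) / np.maximum(dist, 1e-12))[:, None] * dvec
        np.add.at(f, bi, fb)
        np.add.at(f, bj, -fb)
        # soft repulsion
        d = cdist(x, x)
        np.fill_diagonal(d, np.inf)
        close = (d < rc) & ~bonded_mask
        ii, jj = np.where(close)
        if len(ii):
            dv = x[ii] - x[jj]
            dn = d[ii, jj]
            f[ii] += (a_rep * (1 - dn / rc) / dn)[:, None] * dv
        # counterion tether
        if len(ions):
            f[ions] -= k_tether * x[ions]
        disp = f * dt + noise_sd * rng.standard_normal((n, 3))
        step_len = np.linalg.norm(disp, axis=1).max()
        if step_len > 1.0:
            raise StepSizeError(
                f"integrator blow-up at step {step}: max displacement "
                f"{step_len:.2f} nm")
        x = x + disp
        if step >= burn_in and (step - burn_in) % save_every == 0:
            com = m_dend @ x[dend] / m_dend.sum()
            frames.append(x - com)
            times.append(step * dt)
    return system, Trajectory(np.asarray(times), np.asarray(frames))
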