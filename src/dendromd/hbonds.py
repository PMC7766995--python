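"""Geometric hydrogen-bond detection, statistics and continuous lifetimes.

A hydrogen bond is declared for a donor-hydrogen-acceptor triple when the
D-A distance is below 0.35 nm and the deviation-from-linearity angle
between the D->H and D->A directions is below 30 degrees (the standard
geometric criterion of MD packages).  Bond presence along a trajectory is
tracked as a signed criterion margin whose zero crossings are refined by
cubic-spline interpolation across the bracketing frames, giving continuous
lifetimes with sub-frame resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from .io import Trajectory
from .system import ConfigurationError, MolecularSystem, SelectionError

D_CUT_DEFAULT = 0.35      # nm
ANGLE_CUT_DEFAULT = 30.0  # degrees

#: angle margins are folded into the same scale as distance margins so a
#: single signed criterion can be interpolated; 1 degree ~ 0.01 nm here.
_ANGLE_SCALE = 0.01


def donors_and_acceptors(system: MolecularSystem,
                         donor_ids=None, acceptor_ids=None):
    """Identify (donor, hydrogen) pairs and acceptors from names and bonds.

    Donors are N/O atoms with at least one bonded H; acceptors are all N/O
    atoms.  Raises if a requested donor carries no hydrogen.
    """
    if donor_ids is None:
        donor_ids = [a.atom_id for a in system.atoms
                     if a.element in "NO"
                     and any(system.atoms[j].element == "H"
                             for j in a.bonded_ids)]
    if acceptor_ids is None:
        acceptor_ids = [a.atom_id for a in system.atoms if a.element in "NO"]
    dh_pairs = []
    missing = []
    for d in donor_ids:
        hs = [j for j in system.atoms[d].bonded_ids
              if system.atoms[j].element == "H"]
        if not hs:
            missing.append(d)
        dh_pairs.extend((d, h) for h in hs)
    if missing:
        raise ConfigurationError(
            f"donors without bonded hydrogens: {missing}")
    return dh_pairs, list(acceptor_ids)


def hbond_margin(coords: np.ndarray, dh_pairs, acceptors,
                 d_cut: float = D_CUT_DEFAULT,
                 angle_cut: float = ANGLE_CUT_DEFAULT) -> np.ndarray:
    """Signed criterion margin for every (D,H) x acceptor combination.

    margin = min(d_cut - d_DA, (angle_cut - theta) * scale) with theta the
    H-D-A deviation angle in degrees; positive iff the bond criteria hold.
    Shape (n_dh, n_acceptors); self-pairs (A == D) get -inf.
    """
    d_idx = np.array([d for d, _ in dh_pairs])
    h_idx = np.array([h for _, h in dh_pairs])
    a_idx = np.array(acceptors)
    d_pos, h_pos, a_pos = coords[d_idx], coords[h_idx], coords[a_idx]

    dist = cdist(d_pos, a_pos)
    dh = h_pos - d_pos
    dh /= np.linalg.norm(dh, axis=1, keepdims=True)
    da = a_pos[None, :, :] - d_pos[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        da_u = da / np.linalg.norm(da, axis=2, keepdims=True)
        cosang = np.clip(np.einsum("ic,iac->ia", dh, da_u), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    margin = np.minimum(d_cut - dist, (angle_cut - theta) * _ANGLE_SCALE)
    margin[d_idx[:, None] == a_idx[None, :]] = -np.inf
    return margin


def detect_hbonds(coords: np.ndarray, system: MolecularSystem,
                  d_cut: float = D_CUT_DEFAULT,
                  angle_cut: float = ANGLE_CUT_DEFAULT,
                  donor_ids=None, acceptor_ids=None
                  ) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples bonded in one frame."""
    dh_pairs, acceptors = donors_and_acceptors(system, donor_ids,
                                               acceptor_ids)
    if not dh_pairs or not acceptors:
        return []
    m = hbond_margin(coords, dh_pairs, acceptors, d_cut, angle_cut)
    out = []
    for i, j in zip(*np.where(m > 0)):
        d, h = dh_pairs[i]
        out.append((d, h, acceptors[j]))
    return out


# ---------------------------------------------------------------------------
# per-class statistics
# ---------------------------------------------------------------------------

_PARTNER_CLASSES = ("dendrimer-water", "intra-dendrimer",
                    "side-water", "side-side")


def _class_filter(system: MolecularSystem, partner_class: str):
    dend = set(system.dendrimer_ids())
    water = set(system.ids_with_role("water_oxygen"))
    water |= {j for o in water for j in system.atoms[o].bonded_ids}
    side = set(a.atom_id for a in system.atoms
               if a.residue_kind.startswith("side"))
    if partner_class == "dendrimer-water":
        return lambda d, a: ((d in dend) != (a in dend)) and \
            (d in water or a in water)
    if partner_class == "intra-dendrimer":
        return lambda d, a: d in dend and a in dend
    if partner_class == "side-water":
        return lambda d, a: ((d in side and a in water)
                             or (a in side and d in water))
    if partner_class == "side-side":
        return lambda d, a: d in side and a in side
    raise SelectionError(
        f"partner_class must be one of {_PARTNER_CLASSES}")


@dataclass
class HBondSummary:
    """Per-frame hydrogen-bond counts and their summaries for one class."""

    partner_class: str
    counts: np.ndarray            # per frame
    mean: float
    histogram: tuple[np.ndarray, np.ndarray]   # (bin values, frequencies)
    per_spacer: float | None = None


def hbond_statistics(traj: Trajectory, system: MolecularSystem,
                     partner_class: str = "dendrimer-water",
                     d_cut: float = D_CUT_DEFAULT,
                     angle_cut: float = ANGLE_CUT_DEFAULT) -> HBondSummary:
    """Per-frame bond counts, count histogram and time mean for one class.

    For side-segment-water bonds the mean is additionally normalised per
    spacer residue by Nins.
    """
    keep = _class_filter(system, partner_class)
    dh_pairs, acceptors = donors_and_acceptors(system)
    counts = []
    for k in range(traj.n_frames):
        m = hbond_margin(traj.coords[k], dh_pairs, acceptors, d_cut,
                         angle_cut)
        n = sum(1 for i, j in zip(*np.where(m > 0))
                if keep(dh_pairs[i][0], acceptors[j]))
        counts.append(n)
    counts = np.asarray(counts)
    vals, freqs = np.unique(counts, return_counts=True)
    per_spacer = (float(counts.mean()) / system.nins
                  if partner_class in ("side-water",) and system.nins
                  else None)
    return HBondSummary(partner_class=partner_class, counts=counts,
                        mean=float(counts.mean()),
                        histogram=(vals, freqs / len(counts)),
                        per_spacer=per_spacer)


def per_spacer_count(mean_side_count: float, nins: int) -> float:
    """Side-segment-water bond count normalised per inserted residue."""
    return mean_side_count / nins


# ---------------------------------------------------------------------------
# continuous lifetimes
# ---------------------------------------------------------------------------

@dataclass
class HBondEvent:
    """One continuous presence interval of a bond, with refined duration."""

    start_frame: int
    end_frame: int            # inclusive
    duration: float           # ps, spline-refined
    censored: bool = False


def events_from_margin(margin: np.ndarray, dt: float,
                       refine: bool = True) -> list[HBondEvent]:
    """Continuous bond events from a sampled criterion-margin series.

    A bond exists while margin > 0.  Formation/breaking instants are
    refined by interpolating the margin with a cubic spline through the 4
    frames around each sign change and taking its zero crossing; without
    refinement, crossings sit halfway between frames and a single-frame
    event has duration dt.  Events touching the series boundary are marked
    censored.
    """
    on = margin > 0
    if not on.any():
        return []
    n = len(margin)
    idx = np.flatnonzero(np.diff(on.astype(int)))
    starts = [0] if on[0] else []
    ends = []
    for i in idx:
        if on[i + 1]:
            starts.append(i + 1)
        else:
            ends.append(i)
    if on[-1]:
        ends.append(n - 1)

    def crossing(i: int) -> float:
        """Refined crossing time (ps) inside (i, i+1)."""
        if not refine:
            return (i + 0.5) * dt
        lo, hi = max(0, i - 1), min(n - 1, i + 2)
        t = np.arange(lo, hi + 1, dtype=float)
        finite = np.isfinite(margin[lo:hi + 1])
        if finite.sum() < 2:
            return (i + 0.5) * dt
        spl = CubicSpline(t[finite], margin[lo:hi + 1][finite])
        try:
            root = brentq(spl, i, i + 1)
        except ValueError:
            root = i + 0.5
        return root * dt

    events = []
    for s, e in zip(starts, ends):
        left_censored = s == 0 and on[0]
        right_censored = e == n - 1 and on[-1]
        t0 = s * dt if left_censored else crossing(s - 1)
        t1 = e * dt if right_censored else crossing(e)
        if s == e and not refine:
            dur = dt
        else:
            dur = max(t1 - t0, 0.0)
            if s == e and dur == 0.0:
                dur = dt
        events.append(HBondEvent(s, e, dur,
                                 censored=left_censored or right_censored))
    return events


def continuous_lifetimes(events: list[HBondEvent] | list[list[HBondEvent]],
                         ) -> dict:
    """Mean continuous lifetime over uncensored events.

    Accepts one event list or a list of per-bond lists; censored events
    (touching a trajectory boundary) are excluded from the mean and counted
    separately.
    """
    if events and isinstance(events[0], list):
        events = [e for sub in events for e in sub]
    complete = [e.duration for e in events if not e.censored]
    return {
        "mean_lifetime": float(np.mean(complete)) if complete else np.nan,
        "n_events": len(complete),
        "n_censored": sum(1 for e in events if e.censored),
    }


def bond_margin_series(traj: Trajectory, system: MolecularSystem,
                       triple: tuple[int, int, int],
                       d_cut: float = D_CUT_DEFAULT,
                       angle_cut: float = ANGLE_CUT_DEFAULT) -> np.ndarray:
    """Criterion-margin time series for one (D,H,A) triple."""
    d, h, a = triple
    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        out[k] = hbond_margin(traj.coords[k], [(d, h)], [a], d_cut,
                              angle_cut)[0, 0]
    return out
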