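"""Trajectory container and standard-format input/output.

Reading and writing of PDB/GRO structures and XTC/TRR/DCD trajectories is
delegated to MDAnalysis; this module fixes the internal unit convention
(nm, ps) regardless of the source format, attaches role/charge/mass
metadata from a YAML selection config, and provides periodic-image
unwrapping plus centre-of-mass centring, which every radial observable
downstream assumes.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .system import (AtomRecord, ConfigurationError, MolecularSystem,
                     resolve_selection)


class FormatError(ValueError):
    """Inconsistent trajectory/structure input."""


@dataclass
class Trajectory:
    """Time-ordered coordinate frames.

    times in ps (strictly increasing, uniformly spaced within 1e-6 relative
    tolerance), coords in nm with shape (n_frames, n_atoms, 3), box either
    None or per-frame orthorhombic box lengths (n_frames, 3) in nm.
    """

    times: np.ndarray
    coords: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.coords):
            raise FormatError("times and coords disagree on frame count")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise FormatError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Uniform frame spacing in ps; raises if spacing is not uniform."""
        if self.n_frames < 2:
            raise FormatError("need >= 2 frames for a timestep")
        steps = np.diff(self.times)
        if np.max(steps) - np.min(steps) > 1e-6 * np.max(steps):
            raise FormatError("non-uniform frame spacing")
        return float(steps[0])

    def is_uniform(self) -> bool:
        if self.n_frames < 2:
            return True
        steps = np.diff(self.times)
        return bool(np.max(steps) - np.min(steps) <= 1e-6 * np.max(steps))


@dataclass
class ResultTable:
    """Tabular analysis output with units and re-run provenance."""

    table: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.table.to_csv(path, index=False)
        meta = {"units": self.units, "provenance": self.provenance}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1, default=str))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def load_selection_config(path: str | Path) -> dict:
    """Load the YAML config mapping atoms to roles/charges and selections."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def _system_from_universe(u, config: dict | None) -> MolecularSystem:
    """Build a MolecularSystem from an MDAnalysis universe plus config.

    Structure formats do not carry roles or charges; the config supplies
    them keyed by atom name (``atoms: {name: {role, charge, mass}}``) and
    may register ``selections: {name: [atom names or role:<role>]}``.
    """
    cfg_atoms = (config or {}).get("atoms", {})
    atoms = []
    for i, a in enumerate(u.atoms):
        over = cfg_atoms.get(a.name, {})
        mass = float(over.get("mass", getattr(a, "mass", 0.0) or 12.0))
        if mass <= 0:
            mass = 12.0
        atoms.append(AtomRecord(
            atom_id=i,
            name=str(a.name),
            mass=mass,
            charge=float(over.get("charge", 0.0)),
            role=str(over.get("role", "other")),
            residue_kind=str(a.resname) if hasattr(a, "resname") else "",
        ))
    if hasattr(u, "bonds"):
        for b in u.bonds:
            i, j = int(b.atoms[0].index), int(b.atoms[1].index)
            atoms[i].bonded_ids.append(j)
            atoms[j].bonded_ids.append(i)
    sel = {}
    for name, spec in (config or {}).get("selections", {}).items():
        ids: list[int] = []
        for item in spec:
            if isinstance(item, str) and item.startswith("role:"):
                role = item.split(":", 1)[1]
                ids.extend(a.atom_id for a in atoms if a.role == role)
            else:
                ids.extend(a.atom_id for a in atoms if a.name == item)
        sel[name] = ids
    return MolecularSystem(atoms, sel)


def read_trajectory(structure_path: str | Path,
                    trajectory_path: str | Path | None = None,
                    config: dict | str | Path | None = None,
                    ) -> tuple[Trajectory, MolecularSystem]:
    """Read a structure (+ optional trajectory) into internal units.

    Positions are converted to nm and times to ps whatever the source
    format's native units (MDAnalysis reports Angstrom/ps).  Raises
    :class:`FormatError` on atom-count mismatch between the files.
    """
    import MDAnalysis as mda

    if isinstance(config, (str, Path)):
        config = load_selection_config(config)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory_path is None:
                u = mda.Universe(str(structure_path))
            else:
                u = mda.Universe(str(structure_path), str(trajectory_path))
    except ValueError as exc:
        raise FormatError(f"inconsistent structure/trajectory: {exc}") from exc

    times, coords, boxes = [], [], []
    has_box = True
    for ts in u.trajectory:
        times.append(float(ts.time))
        coords.append(ts.positions.astype(float) / 10.0)  # A -> nm
        if ts.dimensions is None or not np.any(ts.dimensions[:3]):
            has_box = False
        else:
            boxes.append(np.asarray(ts.dimensions[:3], float) / 10.0)
    traj = Trajectory(np.asarray(times), np.asarray(coords),
                      np.asarray(boxes) if has_box and boxes else None)
    if not traj.is_uniform():
        warnings.warn("non-uniform frame spacing: ACF analyses will refuse "
                      "this trajectory", stacklevel=2)
    return traj, _system_from_universe(u, config)


def write_trajectory(system: MolecularSystem, traj: Trajectory,
                     structure_path: str | Path,
                     trajectory_path: str | Path | None = None) -> None:
    """Write a GRO structure and optional XTC/TRR trajectory (nm -> A)."""
    import MDAnalysis as mda

    n = system.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", [a.name for a in system.atoms])
    u.add_TopologyAttr("masses", [a.mass for a in system.atoms])
    u.add_TopologyAttr("resids", [1])
    u.add_TopologyAttr("resnames", ["SYS"])
    box = traj.box[0] if traj.box is not None else np.full(3, 100.0)
    u.dimensions = [*(box * 10.0), 90.0, 90.0, 90.0]
    u.atoms.positions = traj.coords[0] * 10.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(structure_path))
        if trajectory_path is not None:
            with mda.Writer(str(trajectory_path), n) as w:
                for k in range(traj.n_frames):
                    u.atoms.positions = traj.coords[k] * 10.0
                    if traj.box is not None:
                        u.dimensions = [*(traj.box[k] * 10.0),
                                        90.0, 90.0, 90.0]
                    u.trajectory.ts.time = traj.times[k]
                    w.write(u.atoms)


# ---------------------------------------------------------------------------
# unwrapping and centring
# ---------------------------------------------------------------------------

def _minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def unwrap_or_center(traj: Trajectory, system: MolecularSystem,
                     mode: str = "center") -> Trajectory:
    """Make the dendrimer whole across periodic boundaries and centre it.

    mode="center": translate every frame so the dendrimer centre of mass
    (mass-weighted, not geometric) sits at the origin.  mode="unwrap_center"
    additionally walks the bond graph with minimum-image displacements to
    rejoin a molecule split by the box, and wraps counterions and waters to
    the image nearest the dendrimer COM.
    """
    if mode not in ("center", "unwrap_center"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    dend = system.dendrimer_ids()
    masses = system.masses
    coords = traj.coords.copy()

    if mode == "unwrap_center":
        if traj.box is None:
            raise ConfigurationError("unwrap requires box vectors")
        order = _bond_walk_order(system, dend)
        other = [i for i in range(system.n_atoms) if i not in set(dend)]
        for k in range(traj.n_frames):
            box = traj.box[k]
            x = coords[k]
            for i, parent in order:
                if parent is not None:
                    x[i] = x[parent] + _minimum_image(x[i] - x[parent], box)
            com = np.average(x[dend], axis=0, weights=masses[dend])
            for i in other:
                x[i] = com + _minimum_image(x[i] - com, box)

    w = masses[dend] / masses[dend].sum()
    for k in range(traj.n_frames):
        com = w @ coords[k][dend]
        coords[k] -= com
    return Trajectory(traj.times.copy(), coords,
                      traj.box.copy() if traj.box is not None else None)


def _bond_walk_order(system: MolecularSystem,
                     ids: list[int]) -> list[tuple[int, int | None]]:
    """BFS visit order over the bond graph of ``ids`` with parents."""
    idset = set(ids)
    seen: set[int] = set()
    order: list[tuple[int, int | None]] = []
    for root in ids:
        if root in seen:
            continue
        seen.add(root)
        order.append((root, None))
        q = deque([root])
        while q:
            node = q.popleft()
            for j in system.atoms[node].bonded_ids:
                if j in idset and j not in seen:
                    seen.add(j)
                    order.append((j, node))
                    q.append(j)
    return order


def center_of_mass(traj: Trajectory, system: MolecularSystem,
                   selection: str | list[int] = "dendrimer") -> np.ndarray:
    """Per-frame mass-weighted COM of a selection, shape (n_frames, 3)."""
    ids = (resolve_selection(system, selection)
           if isinstance(selection, str) else list(selection))
    m = system.masses[ids]
    return np.einsum("fij,i->fj", traj.coords[:, ids], m) / m.sum()
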