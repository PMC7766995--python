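"""Static molecular description of a peptide dendrimer.

A :class:`MolecularSystem` is the atom table every analysis stage consumes:
per-atom mass, formal/partial charge, a role label (core, backbone,
side_segment, terminal_group, counterion, water_oxygen, other) and the bond
list.  The module also builds coarse-grained toy dendrimer topologies with
the branch-tree of a lysine dendrimer carrying charged dipeptide spacers
(2Arg or 2Lys), and resolves the named atom selections used downstream.

The toy builder is coarse-grained — one interaction site per heavy-atom
group — because every analysis in this package consumes only positions,
masses, charges and labels.  Charges are formal (+1 per protonated
amine/guanidinium), which is the level of detail the electrostatic and
counting observables need.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

ROLES = (
    "core",
    "backbone",
    "side_segment",
    "terminal_group",
    "counterion",
    "water_oxygen",
    "other",
)


class SelectionError(KeyError):
    """Unknown or empty named selection."""


class ConfigurationError(ValueError):
    """Inconsistent or unsupported system configuration."""


class TopologyError(ValueError):
    """Bond graph does not support the requested operation."""


@dataclass
class AtomRecord:
    """One interaction site.

    ``name`` follows PDB-like conventions (CA, CB, NZ, HB1 ...); the leading
    letter is the element, which is how donors/acceptors are identified.
    """

    atom_id: int
    name: str
    mass: float
    charge: float
    role: str
    residue_kind: str
    bonded_ids: list[int] = field(default_factory=list)

    @property
    def element(self) -> str:
        return self.name[0]


@dataclass
class TopologicalDistanceLabel:
    """Bond-count from a CH2 carbon to the terminal N of its side segment."""

    group_id: int
    n_bonds_to_segment_end: int


class MolecularSystem:
    """Atom table plus named selections and headline counts.

    Parameters
    ----------
    atoms:
        Atom records with symmetric bond lists.
    named_selections:
        Mapping selection name -> ordered list of atom ids.
    nend, nins:
        Number of terminal NH3+ groups and of inserted (spacer) residues.
    """

    def __init__(
        self,
        atoms: list[AtomRecord],
        named_selections: dict[str, list[int]] | None = None,
        nend: int = 0,
        nins: int = 0,
    ):
        self.atoms = atoms
        self.named_selections = dict(named_selections or {})
        self.nend = nend
        self.nins = nins
        self._validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def roles(self) -> np.ndarray:
        return np.array([a.role for a in self.atoms])

    @property
    def bare_charge(self) -> int:
        """Net formal charge of the dendrimer (counterions excluded)."""
        q = sum(a.charge for a in self.atoms if a.role != "counterion"
                and a.role != "water_oxygen" and not a.residue_kind.startswith("water"))
        return int(round(q))

    def ids_with_role(self, *roles: str) -> list[int]:
        return [a.atom_id for a in self.atoms if a.role in roles]

    def dendrimer_ids(self) -> list[int]:
        return [a.atom_id for a in self.atoms
                if a.role not in ("counterion", "water_oxygen")
                and not a.residue_kind.startswith("water")]

    def bonds(self) -> list[tuple[int, int]]:
        out = []
        for a in self.atoms:
            for j in a.bonded_ids:
                if j > a.atom_id:
                    out.append((a.atom_id, j))
        return out

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        n = self.n_atoms
        for a in self.atoms:
            if a.role not in ROLES:
                raise ConfigurationError(f"unknown role {a.role!r}")
            if a.mass <= 0:
                raise ConfigurationError(f"atom {a.atom_id}: mass must be > 0")
            for j in a.bonded_ids:
                if not 0 <= j < n:
                    raise ConfigurationError(f"bond {a.atom_id}-{j} out of range")
                if a.atom_id not in self.atoms[j].bonded_ids:
                    raise ConfigurationError(
                        f"bond {a.atom_id}-{j} not symmetric")
        for name, ids in self.named_selections.items():
            for i in ids:
                if not 0 <= i < n:
                    raise SelectionError(f"selection {name!r}: id {i} unknown")


def resolve_selection(system: MolecularSystem, name: str) -> list[int]:
    """Return the ordered atom-id list registered under ``name``."""
    try:
        return list(system.named_selections[name])
    except KeyError:
        raise SelectionError(
            f"unknown selection {name!r}; available: "
            f"{sorted(system.named_selections)}") from None


# ---------------------------------------------------------------------------
# toy dendrimer builder
# ---------------------------------------------------------------------------

# heavy-bead masses (g/mol) for the coarse sites
_M_BB = 56.0      # backbone unit (N-CA-C=O)
_M_CH2 = 14.0
_M_N = 16.0       # NH/NH2/NH3 site
_M_CZ = 12.0
_M_H = 1.0
_M_ION = 35.45    # Cl-
_BOND = 0.15      # nm, coarse bond length


class _Builder:
    def __init__(self) -> None:
        self.atoms: list[AtomRecord] = []
        self.sel: dict[str, list[int]] = {}

    def add(self, name, mass, charge, role, kind, bonds=()) -> int:
        i = len(self.atoms)
        rec = AtomRecord(i, name, mass, charge, role, kind, [])
        self.atoms.append(rec)
        for j in bonds:
            rec.bonded_ids.append(j)
            self.atoms[j].bonded_ids.append(i)
        return i

    def tag(self, selection: str, i: int) -> None:
        self.sel.setdefault(selection, []).append(i)


def _add_side_segment(b: _Builder, backbone_id: int, spacer_kind: str) -> None:
    """Charged side segment of one spacer residue, with CH2 hydrogens.

    2Arg: CB-CG-CD-NE-CZ(+1)-NH2(end); CH2 carbons sit 5, 4, 3 bonds from
    the end N.  2Lys: CB-CG-CD-CE-NZ(+1, end); CH2 carbons sit 4, 3, 2, 1
    bonds from the end N.
    """
    if spacer_kind == "2Arg":
        ch2_names = ("CB", "CG", "CD")
        kind = "side-Arg"
    else:
        ch2_names = ("CB", "CG", "CD", "CE")
        kind = "side-Lys"
    prev = backbone_id
    ch2_ids = []
    for nm in ch2_names:
        c = b.add(nm, _M_CH2, 0.0, "side_segment", kind, [prev])
        for k in (1, 2):
            h = b.add(f"H{nm[1]}{k}", _M_H, 0.0, "other", kind, [c])
            b.tag("side_H", h)
        ch2_ids.append(c)
        b.tag("side_CH2", c)
        prev = c
    if spacer_kind == "2Arg":
        ne = b.add("NE", _M_N, 0.0, "side_segment", kind, [prev])
        cz = b.add("CZ", _M_CZ, +1.0, "side_segment", kind, [ne])
        nh = b.add("NH1", _M_N, 0.0, "side_segment", kind, [cz])
        hh = b.add("HH1", _M_H, 0.0, "other", kind, [nh])
        b.tag("charged_side_groups", cz)
        b.tag("side_segment_end_N", nh)
    else:
        nz = b.add("NZ", _M_N, +1.0, "side_segment", kind, [prev])
        hz = b.add("HZ1", _M_H, 0.0, "other", kind, [nz])
        b.tag("charged_side_groups", nz)
        b.tag("side_segment_end_N", nz)


def build_toy_dendrimer(generation: int, spacer_kind: str) -> MolecularSystem:
    """Build the coarse-grained branch tree of a Lys-2Arg / Lys-2Lys dendrimer.

    The tree grows from an alanine-lysine core; every edge between branching
    points (and to each terminal lysine) carries a dipeptide spacer whose two
    residues each bear one +1 side charge; every terminal lysine carries two
    +1 amine sites.  Chloride counterions neutralise the system.

    For generation g: 2**(g+1) terminal lysines, Nend = 2**(g+2) terminal
    NH3+ sites, Nins = 2*(2**(g+2) - 2) spacer residues, and
    Qbare = Nend + Nins (g=2 gives 16, 28, +44).
    """
    if spacer_kind not in ("2Arg", "2Lys"):
        raise ConfigurationError(f"unsupported spacer_kind {spacer_kind!r}")
    if generation < 0:
        raise ConfigurationError("generation must be >= 0")

    b = _Builder()
    # alanine-lysine core; the core lysine CA is the first branching point
    ala = b.add("CA", _M_BB + 15.0, 0.0, "core", "core-Ala")
    core = b.add("CA", _M_BB, 0.0, "core", "core-Lys", [ala])
    b.tag("core_branch_point", core)

    def grow(parent: int, level: int) -> None:
        """Attach one spacer edge and, below it, a branch or a terminal."""
        # dipeptide spacer: two residues, each backbone bead + charged side
        prev = parent
        for _ in range(2):
            bb = b.add("CA", _M_BB, 0.0, "backbone", f"spacer-{spacer_kind[1:]}",
                       [prev])
            _add_side_segment(b, bb, spacer_kind)
            prev = bb
        if level == 0:
            # terminal lysine: backbone bead + two protonated amine sites
            bb = b.add("CA", _M_BB + 56.0, 0.0, "backbone", "terminal-Lys",
                       [prev])
            b.tag("terminal_C", bb)
            for nm in ("NZ", "NA"):
                nt = b.add(nm, _M_N, +1.0, "terminal_group", "terminal-Lys",
                           [bb])
                ht = b.add("H" + nm[1], _M_H, 0.0, "other", "terminal-Lys",
                           [nt])
                b.tag("terminal_N", nt)
        else:
            bb = b.add("CA", _M_BB, 0.0, "backbone", "inner-Lys", [prev])
            b.tag("branch_points", bb)
            grow(bb, level - 1)
            grow(bb, level - 1)

    grow(core, generation)
    grow(core, generation)

    n_terminal_lys = 2 ** (generation + 1)
    nend = 2 * n_terminal_lys
    nins = 2 * (2 ** (generation + 2) - 2)
    qbare = nend + nins

    for _ in range(qbare):
        i = b.add("CL", _M_ION, -1.0, "counterion", "ion-Cl")
        b.tag("ions", i)

    b.sel["dendrimer"] = [a.atom_id for a in b.atoms
                          if a.role not in ("counterion",)]
    b.sel["dendrimer_heavy"] = [a.atom_id for a in b.atoms
                                if a.role not in ("counterion",)
                                and a.element != "H"]
    b.sel["backbone_CA"] = [a.atom_id for a in b.atoms
                            if a.name == "CA" and a.role in
                            ("core", "backbone")]
    sys_ = MolecularSystem(b.atoms, b.sel, nend=nend, nins=nins)
    assert sys_.bare_charge == qbare
    return sys_


def add_water(system: MolecularSystem, n_water: int, box: float,
              seed: int = 0) -> MolecularSystem:
    """Append ``n_water`` coarse waters (O + 2 bonded H) to a toy system.

    Only the topology is appended here; coordinates come from the trajectory
    generator.  Water oxygens get the ``water_oxygen`` role so hydrogen-bond
    partner classes can address them.
    """
    atoms = [AtomRecord(a.atom_id, a.name, a.mass, a.charge, a.role,
                        a.residue_kind, list(a.bonded_ids))
             for a in system.atoms]
    sel = {k: list(v) for k, v in system.named_selections.items()}
    for _ in range(n_water):
        o = len(atoms)
        atoms.append(AtomRecord(o, "OW", 16.0, 0.0, "water_oxygen", "water"))
        sel.setdefault("water_O", []).append(o)
        for k in (1, 2):
            h = len(atoms)
            atoms.append(AtomRecord(h, f"HW{k}", 1.0, 0.0, "other", "water",
                                    [o]))
            atoms[o].bonded_ids.append(h)
    return MolecularSystem(atoms, sel, nend=system.nend, nins=system.nins)


# ---------------------------------------------------------------------------
# topological distance labelling
# ---------------------------------------------------------------------------

def _bfs_distance(system: MolecularSystem, start: int, targets: set[int]) -> int:
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        node, d = frontier.popleft()
        if node in targets:
            return d
        for j in system.atoms[node].bonded_ids:
            if j not in seen:
                seen.add(j)
                frontier.append((j, d + 1))
    raise TopologyError(
        f"atom {start}: no bond path to any side-segment end nitrogen")


def label_topological_distance(system: MolecularSystem) -> list[TopologicalDistanceLabel]:
    """Bond-path length from every side CH2 carbon to its segment-end N.

    Breadth-first search on the bond graph; on a tree the shortest path is
    unique.  For 2Arg side segments the attainable distances are {3,4,5},
    for 2Lys {1,2,3,4}.
    """
    ch2 = resolve_selection(system, "side_CH2")
    ends = set(resolve_selection(system, "side_segment_end_N"))
    return [TopologicalDistanceLabel(c, _bfs_distance(system, c, ends))
            for c in ch2]


def hh_pairs_by_distance(system: MolecularSystem) -> dict[int, list[tuple[int, int]]]:
    """Map topological distance -> list of (H, H) atom-id pairs per CH2 group."""
    labels = {lab.group_id: lab.n_bonds_to_segment_end
              for lab in label_topological_distance(system)}
    out: dict[int, list[tuple[int, int]]] = {}
    for c, d in labels.items():
        hs = [j for j in system.atoms[c].bonded_ids
              if system.atoms[j].element == "H"]
        if len(hs) == 2:
            out.setdefault(d, []).append((hs[0], hs[1]))
    return out
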