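"""Clamp topologies, structures and domain centre-of-mass geometry.

A sliding clamp is decomposed into named *clamp domains* (three per protomer
for bacterial beta clamps, two per protomer for PCNA/gp45-like clamps).  The
decomposition is configuration data — chain identifiers plus inclusive
author-numbered residue ranges — carried by :class:`ClampTopology` and
typically loaded from a YAML file.  Structures are read from fixed-column PDB
files; multi-model files become a :class:`Trajectory`.

The residue ranges shipped under ``clampdyn/data/topologies`` are a
reconstruction from the visible domain decomposition of the crystal
structures; they are not part of any published coordinate file and should be
edited when better boundaries are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ClampTopology",
    "Structure",
    "Trajectory",
    "DomainAssignment",
    "TopologyError",
    "StructureParseError",
    "parse_structure",
    "write_structure",
    "assign_domains",
    "domain_com",
    "system_com",
    "load_topology",
    "save_topology",
    "bundled_topology",
]


class TopologyError(ValueError):
    """Raised when a topology is inconsistent or does not match a structure."""


class StructureParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClampTopology:
    """Domain decomposition of a sliding clamp.

    Parameters
    ----------
    clamp_name
        Free-text label, e.g. ``"pol3_beta"``.
    domains
        Ordered ``(label, chain_id, res_start, res_end)`` tuples; residue
        ranges are 1-based inclusive in PDB author numbering.
    ring_order
        Cyclic order of the domain labels around the ring.
    open_interface
        Ordered pair of adjacent labels designating the interface that is
        broken during ring opening.
    torsion_quadruples
        Exactly three ordered 4-tuples of labels: the three consecutive
        4-domain windows around the ring that avoid the open interface.
        Their signed COM dihedrals sum to the handedness statistic.
    """

    clamp_name: str
    domains: tuple[tuple[str, str, int, int], ...]
    ring_order: tuple[str, ...]
    open_interface: tuple[str, str]
    torsion_quadruples: tuple[tuple[str, str, str, str], ...]

    def __post_init__(self) -> None:
        labels = [d[0] for d in self.domains]
        if sorted(labels) != sorted(self.ring_order):
            raise TopologyError(
                f"ring_order {self.ring_order} does not match domain labels {labels}"
            )
        if len(set(labels)) != len(labels):
            raise TopologyError("duplicate domain labels")
        n = len(self.ring_order)
        i = self.ring_order.index(self.open_interface[0])
        j = self.ring_order.index(self.open_interface[1])
        if (i + 1) % n != j and (j + 1) % n != i:
            raise TopologyError(
                f"open_interface {self.open_interface} not adjacent in ring_order"
            )
        # non-ring fragments (e.g. an isolated protomer) may omit quadruples
        if len(self.torsion_quadruples) not in (0, 3):
            raise TopologyError("exactly three torsion quadruples are required")
        for quad in self.torsion_quadruples:
            if len(set(quad)) != 4 or any(q not in self.ring_order for q in quad):
                raise TopologyError(f"invalid torsion quadruple {quad}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(d[0] for d in self.domains)

    def interface_path(self) -> tuple[str, ...]:
        """Domain labels walked around the ring starting just after the open
        interface and ending just before it (the path the torsion windows
        slide along)."""
        n = len(self.ring_order)
        # open interface ordered (X, Y): path starts at Y and ends at X
        start = self.ring_order.index(self.open_interface[1])
        return tuple(self.ring_order[(start + k) % n] for k in range(n))


def default_torsion_quadruples(
    ring_order: Sequence[str], open_interface: Sequence[str]
) -> tuple[tuple[str, str, str, str], ...]:
    """The three consecutive 4-windows along the ring path that avoids the
    open interface (for a six-domain ring)."""
    n = len(ring_order)
    start = list(ring_order).index(open_interface[1])
    path = [ring_order[(start + k) % n] for k in range(n)]
    return tuple(tuple(path[k : k + 4]) for k in range(n - 3))[:3]


@dataclass
class Structure:
    """Atom records of one model: parallel arrays plus an (n, 3) coordinate
    block in Å.  Insertion codes are part of the residue identity."""

    chain_id: np.ndarray
    res_id: np.ndarray
    ins_code: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    mass: np.ndarray
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise StructureParseError("non-finite coordinates")
        if np.any(self.mass <= 0):
            raise StructureParseError("non-positive atomic mass")

    @property
    def n_atoms(self) -> int:
        return len(self.res_id)

    def copy(self) -> "Structure":
        return Structure(
            self.chain_id.copy(), self.res_id.copy(), self.ins_code.copy(),
            self.res_name.copy(), self.atom_name.copy(), self.element.copy(),
            self.mass.copy(), self.coord.copy(),
        )

    def with_coord(self, coord: np.ndarray) -> "Structure":
        out = self.copy()
        out.coord = np.asarray(coord, dtype=float)
        return out


@dataclass
class Trajectory:
    """Ordered frames congruent with a template :class:`Structure`."""

    template: Structure
    coords: np.ndarray               # (n_frames, n_atoms, 3)
    time_ps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.template.n_atoms:
            raise ValueError("frame shape does not match template atom count")
        if self.time_ps is not None:
            self.time_ps = np.asarray(self.time_ps, dtype=float)
            if len(self.time_ps) != len(self.coords):
                raise ValueError("time_ps length does not match frame count")
            if np.any(np.diff(self.time_ps) <= 0):
                raise ValueError("time_ps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def frame(self, i: int) -> Structure:
        return self.template.with_coord(self.coords[i])


@dataclass
class DomainAssignment:
    """Mapping domain label -> atom index array (disjoint, non-empty)."""

    indices: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for label, idx in self.indices.items():
            idx = np.asarray(idx, dtype=int)
            self.indices[label] = idx
            if idx.size == 0:
                raise TopologyError(f"domain {label!r} has no atoms")
            s = set(idx.tolist())
            if seen & s:
                raise TopologyError(f"domain {label!r} overlaps another domain")
            seen |= s

    def __getitem__(self, label: str) -> np.ndarray:
        return self.indices[label]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.indices)


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------

_MASS_CACHE: dict[str, float] = {}


def _element_mass(element: str) -> float:
    el = element.strip().capitalize()
    if el not in _MASS_CACHE:
        m = struc_info.mass(el)
        if m is None or m <= 0:
            m = 12.011  # unknown elements: carbon-like placeholder
        _MASS_CACHE[el] = float(m)
    return _MASS_CACHE[el]


def _from_atom_array(arr: struc.AtomArray) -> Structure:
    masses = np.array([_element_mass(e) for e in arr.element])
    return Structure(
        chain_id=arr.chain_id.astype("U4"),
        res_id=arr.res_id.astype(int),
        ins_code=arr.ins_code.astype("U1"),
        res_name=arr.res_name.astype("U5"),
        atom_name=arr.atom_name.astype("U6"),
        element=arr.element.astype("U2"),
        mass=masses,
        coord=np.array(arr.coord, dtype=float),
    )


def parse_structure(
    path: str | Path,
    include_hetero: bool = False,
) -> Structure | tuple[Structure, Trajectory]:
    """Read a fixed-column PDB file.

    Single-model files return a :class:`Structure`; multi-model files return
    ``(template, Trajectory)``.  Alternate locations are resolved to the
    highest-occupancy conformer; waters and (by default) other heteroatoms
    are excluded.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite raises various error types
        raise StructureParseError(f"cannot parse PDB file {path}: {exc}") from exc
    mask = stack.res_name != "HOH"
    if not include_hetero:
        mask &= ~stack.hetero
    stack = stack[..., mask]
    if stack.array_length() == 0:
        raise StructureParseError(f"no ATOM records retained from {path}")
    template = _from_atom_array(stack[0])
    if stack.stack_depth() == 1:
        return template
    traj = Trajectory(template=template, coords=np.array(stack.coord, dtype=float))
    return template, traj


def _to_atom_array(s: Structure, coord: np.ndarray) -> struc.AtomArray:
    arr = struc.AtomArray(s.n_atoms)
    arr.coord = np.asarray(coord, dtype=np.float32)
    arr.chain_id = s.chain_id
    arr.res_id = s.res_id
    arr.ins_code = s.ins_code
    arr.res_name = s.res_name
    arr.atom_name = s.atom_name
    arr.element = np.char.upper(s.element)
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    return arr


def write_structure(obj: Structure | Trajectory, path: str | Path) -> None:
    """Write a Structure (single model) or Trajectory (multi-model) PDB."""
    if isinstance(obj, Trajectory):
        arrays = [_to_atom_array(obj.template, c) for c in obj.coords]
        item: struc.AtomArray | struc.AtomArrayStack = struc.stack(arrays)
    else:
        item = _to_atom_array(obj, obj.coord)
    pdb = PDBFile()
    pdb.set_structure(item)
    pdb.write(str(path))


# --------------------------------------------------------------------------
# domain assignment and centres of mass
# --------------------------------------------------------------------------

def assign_domains(s: Structure, t: ClampTopology) -> DomainAssignment:
    """Map each topology domain to the atom indices inside its residue range.

    Atoms outside every range stay unassigned.  An empty match for any domain
    raises :class:`TopologyError` naming that domain.
    """
    indices: dict[str, np.ndarray] = {}
    for label, chain, start, end in t.domains:
        m = (s.chain_id == chain) & (s.res_id >= start) & (s.res_id <= end)
        idx = np.nonzero(m)[0]
        if idx.size == 0:
            raise TopologyError(
                f"domain {label!r}: no atoms in chain {chain!r} residues {start}-{end}"
            )
        indices[label] = idx
    return DomainAssignment(indices)


def _com(coord: np.ndarray, mass: np.ndarray) -> np.ndarray:
    total = float(mass.sum())
    if total <= 0:
        raise ValueError("zero total mass")
    return (coord * mass[:, None]).sum(axis=0) / total


def domain_com(
    s: Structure | np.ndarray,
    assignment: DomainAssignment,
    label: str,
    mode: str = "mass",
    mass: np.ndarray | None = None,
    element: np.ndarray | None = None,
    atom_name: np.ndarray | None = None,
) -> np.ndarray:
    """Centre of mass of one clamp domain.

    ``mode="mass"`` (default): mass-weighted mean over the domain's
    non-hydrogen atoms.  ``mode="ca"``: unweighted mean over CA atoms only.
    ``s`` may be a Structure or a bare (n, 3) coordinate frame, in which case
    ``mass``/``element``/``atom_name`` supply the per-atom metadata.
    """
    if isinstance(s, Structure):
        coord, mass, element, atom_name = s.coord, s.mass, s.element, s.atom_name
    else:
        coord = np.asarray(s, dtype=float)
        if mass is None:
            raise ValueError("bare coordinate frames require mass metadata")
    idx = assignment[label]
    if mode == "ca":
        if atom_name is None:
            raise ValueError("mode='ca' requires atom_name metadata")
        sel = idx[np.char.strip(atom_name[idx].astype(str)) == "CA"]
        if sel.size == 0:
            raise TopologyError(f"domain {label!r} has no CA atoms")
        return coord[sel].mean(axis=0)
    if element is not None:
        sel = idx[np.char.strip(element[idx].astype(str)) != "H"]
        if sel.size == 0:
            sel = idx
    else:
        sel = idx
    return _com(coord[sel], mass[sel])


def system_com(
    s: Structure | np.ndarray,
    assignment: DomainAssignment,
    mode: str = "mass",
    **meta,
) -> np.ndarray:
    """Mass-weighted COM over all assigned atoms (or CA mean for mode='ca')."""
    coms = []
    weights = []
    if isinstance(s, Structure):
        mass = s.mass
    else:
        mass = meta.get("mass")
    for label in assignment.labels:
        coms.append(domain_com(s, assignment, label, mode=mode, **meta))
        if mode == "mass" and mass is not None:
            weights.append(float(mass[assignment[label]].sum()))
        else:
            weights.append(1.0)
    coms_arr = np.array(coms)
    w = np.array(weights)
    return (coms_arr * w[:, None]).sum(axis=0) / w.sum()


# --------------------------------------------------------------------------
# YAML topology files
# --------------------------------------------------------------------------

def load_topology(path: str | Path) -> ClampTopology:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        domains = tuple(
            (d["label"], str(d["chain"]), int(d["start"]), int(d["end"]))
            for d in raw["domains"]
        )
        return ClampTopology(
            clamp_name=raw["clamp_name"],
            domains=domains,
            ring_order=tuple(raw["ring_order"]),
            open_interface=tuple(raw["open_interface"]),
            torsion_quadruples=tuple(tuple(q) for q in raw["torsion_quadruples"]),
        )
    except (KeyError, TypeError) as exc:
        raise TopologyError(f"malformed topology file {path}: {exc}") from exc


def save_topology(t: ClampTopology, path: str | Path) -> None:
    raw = {
        "clamp_name": t.clamp_name,
        "domains": [
            {"label": l, "chain": c, "start": a, "end": b}
            for l, c, a, b in t.domains
        ],
        "ring_order": list(t.ring_order),
        "open_interface": list(t.open_interface),
        "torsion_quadruples": [list(q) for q in t.torsion_quadruples],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def bundled_topology(name: str) -> ClampTopology:
    """Load one of the shipped topology files by stem name
    (``pol3_beta_1ok7``, ``pcna_1plq``, ``gp45_1b77``, ``beta_monomer_1jql``)."""
    path = Path(__file__).parent / "data" / "topologies" / f"{name}.yaml"
    if not path.exists():
        available = sorted(p.stem for p in path.parent.glob("*.yaml"))
        raise FileNotFoundError(f"no bundled topology {name!r}; available: {available}")
    return load_topology(path)
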