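"""One-bead-per-domain Langevin dynamics with steered ring opening.

Each clamp domain is reduced to a single bead at its centre of mass carrying
the domain's aggregate mass.  Beads along the ring (excluding the designated
opening interface) are connected by harmonic bonds, angles and torsions whose
equilibrium values are read off the conformation the system is built from,
so the built state has zero potential energy and zero force.

Ring opening follows three steering protocols applied as moving harmonic
restraints U = (k/2)(xi - xi0(t))^2 with linearly moving targets:

* type 1 — the COM distance across the opening interface is pulled apart at
  constant velocity 2.0 Å/ns with k = 500 kcal mol^-1 Å^-2 (net +20 Å over
  10 ns);
* type 2 — the three interface COM torsions are each driven -20° over 10 ns
  with k = 50 kcal mol^-1 deg^-2, producing a left-handed spiral;
* type 3 — the same torsions driven +20°, producing a right-handed spiral.

After steering, restraints are dropped and the system relaxes freely.
Integration is BAOAB-splitting Langevin dynamics (temperature 310 K, damping
5 ps^-1 by default) in an AKMA-like unit system (Å, ps, amu, kcal/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from clampdyn.constants import DEG, KB_KCAL, KCAL_TO_AKMA, PER_DEG2_TO_PER_RAD2
from clampdyn.topology import (
    ClampTopology,
    DomainAssignment,
    Structure,
    Trajectory,
    domain_com,
)

__all__ = [
    "StiffnessProfile",
    "CGSystem",
    "LangevinParams",
    "Restraint",
    "SteeringProtocol",
    "CGTrajectory",
    "IntegrationError",
    "build_cg",
    "build_cg_beads",
    "energy_forces",
    "run_langevin",
    "make_protocol",
    "run_steered",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator diverges (timestep too large)."""


@dataclass(frozen=True)
class StiffnessProfile:
    """Force constants for the bonded ring terms.

    Defaults give thermal COM-geometry fluctuations of a few degrees / a
    fraction of an Å at 310 K, comparable to the spread seen in equilibrium
    clamp simulations.
    """

    bond_k: float = 10.0      # kcal mol^-1 Å^-2
    angle_k: float = 30.0     # kcal mol^-1 rad^-2
    torsion_k: float = 30.0   # kcal mol^-1 rad^-2


@dataclass
class CGSystem:
    """Beads plus harmonic bonded terms spanning the (broken) ring."""

    labels: tuple[str, ...]
    mass: np.ndarray              # (n,), amu
    x0: np.ndarray                # (n, 3), Å — reference (zero-energy) state
    bond_idx: np.ndarray          # (nb, 2)
    bond_k: np.ndarray            # kcal/mol/Å^2
    bond_r0: np.ndarray           # Å
    angle_idx: np.ndarray         # (na, 3)
    angle_k: np.ndarray           # kcal/mol/rad^2
    angle_t0: np.ndarray          # rad
    tors_idx: np.ndarray          # (nt, 4)
    tors_k: np.ndarray            # kcal/mol/rad^2
    tors_p0: np.ndarray           # rad
    broken_interface: tuple[str, str]

    @property
    def n_beads(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def bead_structure(self) -> Structure:
        """Pseudo-atom Structure (one CA-like record per bead) for PDB output."""
        n = self.n_beads
        return Structure(
            chain_id=np.full(n, "A", dtype="U4"),
            res_id=np.arange(1, n + 1),
            ins_code=np.full(n, "", dtype="U1"),
            res_name=np.full(n, "GLY", dtype="U5"),
            atom_name=np.full(n, "CA", dtype="U6"),
            element=np.full(n, "C", dtype="U2"),
            mass=self.mass.copy(),
            coord=self.x0.copy(),
        )


@dataclass(frozen=True)
class LangevinParams:
    """Thermostat and integrator settings."""

    temperature: float = 310.0   # K
    damping: float = 5.0         # ps^-1
    timestep: float = 0.01       # ps (10 fs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature < 0 or self.damping < 0 or self.timestep <= 0:
            raise ValueError("invalid Langevin parameters")


@dataclass(frozen=True)
class Restraint:
    """Moving harmonic restraint on a collective variable.

    Internal units: distances in Å with k in kcal/mol/Å^2; torsions in rad
    with k in kcal/mol/rad^2.  Target xi0(t) = target0 + velocity*min(t, duration).
    """

    kind: str                    # "com_distance" | "torsion"
    idx: tuple[int, ...]
    k: float
    target0: float
    velocity: float              # per ps
    duration_ps: float
    label: str = ""

    def target(self, t: float) -> float:
        return self.target0 + self.velocity * min(max(t, 0.0), self.duration_ps)


@dataclass(frozen=True)
class SteeringProtocol:
    """Typed steering schedule (restraints at domain-label level).

    ``restraints`` entries: (kind, labels, k, net_change, duration_ps) with k
    and net_change in natural units — Å for distances, degrees for torsions.
    """

    model_type: int
    restraints: tuple[tuple[str, tuple[str, ...], float, float, float], ...]
    post_steering_ps: float = 10_000.0


# --------------------------------------------------------------------------
# system construction
# --------------------------------------------------------------------------

def _chain_terms(n: int):
    bonds = np.array([[i, i + 1] for i in range(n - 1)], dtype=int)
    angles = np.array([[i, i + 1, i + 2] for i in range(n - 2)], dtype=int)
    tors = np.array([[i, i + 1, i + 2, i + 3] for i in range(n - 3)], dtype=int)
    return bonds, angles, tors


def build_cg_beads(
    positions: np.ndarray,
    masses: np.ndarray,
    labels: tuple[str, ...],
    broken_interface: tuple[str, str],
    stiffness: StiffnessProfile | None = None,
) -> CGSystem:
    """Build a CG system from bead positions ordered along the ring *path*
    (the walk that starts just after the broken interface and ends just
    before it).  Equilibrium values are taken from the given positions."""
    if stiffness is None:
        stiffness = StiffnessProfile()
    x = np.asarray(positions, float)
    n = len(labels)
    if x.shape != (n, 3):
        raise ValueError("positions must be (n_labels, 3)")
    bonds, angles, tors = _chain_terms(n)
    bond_r0 = np.array([_distance(x[i], x[j]) for i, j in bonds])
    angle_t0 = np.array([_angle(x[i], x[j], x[k]) for i, j, k in angles])
    tors_p0 = np.array([_dihedral(x[a], x[b], x[c], x[d]) for a, b, c, d in tors])
    return CGSystem(
        labels=tuple(labels),
        mass=np.asarray(masses, float).copy(),
        x0=x.copy(),
        bond_idx=bonds,
        bond_k=np.full(len(bonds), stiffness.bond_k),
        bond_r0=bond_r0,
        angle_idx=angles,
        angle_k=np.full(len(angles), stiffness.angle_k),
        angle_t0=angle_t0,
        tors_idx=tors,
        tors_k=np.full(len(tors), stiffness.torsion_k),
        tors_p0=tors_p0,
        broken_interface=tuple(broken_interface),
    )


def build_cg(
    frame: Structure,
    assignment: DomainAssignment,
    topology: ClampTopology,
    stiffness: StiffnessProfile | None = None,
) -> CGSystem:
    """One bead per clamp domain at its COM, with the domain aggregate mass.

    The harmonic bond/angle/torsion terms span the ring along the path that
    avoids the topology's open interface (that interface's terms are the
    excluded *broken* set), and their equilibrium values equal the built
    conformation's COM geometry, so the built state has zero energy.
    """
    path = topology.interface_path()
    coms = []
    masses = []
    for lab in path:
        coms.append(domain_com(frame, assignment, lab))
        masses.append(float(frame.mass[assignment[lab]].sum()))
    return build_cg_beads(
        np.array(coms), np.array(masses), tuple(path),
        topology.open_interface, stiffness,
    )


# --------------------------------------------------------------------------
# scalar geometry helpers (radians; minimal, used in hot paths)
# --------------------------------------------------------------------------

def _distance(p, q) -> float:
    return float(np.linalg.norm(p - q))


def _angle(p1, p2, p3) -> float:
    u = p1 - p2
    v = p3 - p2
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.acos(min(1.0, max(-1.0, c)))


def _dihedral(p1, p2, p3, p4) -> float:
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    return math.atan2(y, x)


def _wrap_pi(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + math.pi) % (2.0 * math.pi) - math.pi
    if a == -math.pi:
        a = math.pi
    return a


#: floor on sin^2 factors in angle/torsion gradients (near-collinearity cap)
_SIN2_FLOOR = 1e-8


@njit(fastmath=False)
def _ef_kernel(x, bond_idx, bond_k, bond_r0,
               angle_idx, angle_k, angle_t0,
               tors_idx, tors_k, tors_p0,
               r_kind, r_idx, r_k, r_target):
    """Fused bonded + restraint energy/force kernel (hot path).

    r_kind: 0 = com_distance (r_idx columns 0,1), 1 = torsion (columns 0-3);
    r_target in Å or rad.  Identical functional forms to the public
    docstrings; compiled for the inner integration loop.
    """
    n = x.shape[0]
    F = np.zeros((n, 3))
    U = 0.0
    # bonds
    for b in range(bond_idx.shape[0]):
        i = bond_idx[b, 0]
        j = bond_idx[b, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        U += 0.5 * bond_k[b] * dr * dr
        c = bond_k[b] * dr / r
        F[i, 0] -= c * dx
        F[i, 1] -= c * dy
        F[i, 2] -= c * dz
        F[j, 0] += c * dx
        F[j, 1] += c * dy
        F[j, 2] += c * dz
    # angles
    for a in range(angle_idx.shape[0]):
        i = angle_idx[a, 0]
        j = angle_idx[a, 1]
        k = angle_idx[a, 2]
        ux = x[i, 0] - x[j, 0]
        uy = x[i, 1] - x[j, 1]
        uz = x[i, 2] - x[j, 2]
        vx = x[k, 0] - x[j, 0]
        vy = x[k, 1] - x[j, 1]
        vz = x[k, 2] - x[j, 2]
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = math.acos(c)
        s2 = 1.0 - c * c
        if s2 < _SIN2_FLOOR:
            s2 = _SIN2_FLOOR
        s = math.sqrt(s2)
        dt = theta - angle_t0[a]
        U += 0.5 * angle_k[a] * dt * dt
        coeff = angle_k[a] * dt
        # dtheta/dxi = (c*u_hat - v_hat)/(|u| s)
        uhx, uhy, uhz = ux / nu, uy / nu, uz / nu
        vhx, vhy, vhz = vx / nv, vy / nv, vz / nv
        g1x = (c * uhx - vhx) / (nu * s)
        g1y = (c * uhy - vhy) / (nu * s)
        g1z = (c * uhz - vhz) / (nu * s)
        g3x = (c * vhx - uhx) / (nv * s)
        g3y = (c * vhy - uhy) / (nv * s)
        g3z = (c * vhz - uhz) / (nv * s)
        F[i, 0] -= coeff * g1x
        F[i, 1] -= coeff * g1y
        F[i, 2] -= coeff * g1z
        F[k, 0] -= coeff * g3x
        F[k, 1] -= coeff * g3y
        F[k, 2] -= coeff * g3z
        F[j, 0] += coeff * (g1x + g3x)
        F[j, 1] += coeff * (g1y + g3y)
        F[j, 2] += coeff * (g1z + g3z)
    # torsions + restraints share the dihedral machinery
    n_t = tors_idx.shape[0]
    n_r = r_kind.shape[0]
    for item in range(n_t + n_r):
        if item < n_t:
            ia, ib, ic, id_ = (tors_idx[item, 0], tors_idx[item, 1],
                               tors_idx[item, 2], tors_idx[item, 3])
            kk = tors_k[item]
            p0 = tors_p0[item]
        else:
            r = item - n_t
            if r_kind[r] == 0:
                i = r_idx[r, 0]
                j = r_idx[r, 1]
                dx = x[i, 0] - x[j, 0]
                dy = x[i, 1] - x[j, 1]
                dz = x[i, 2] - x[j, 2]
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                dd = d - r_target[r]
                U += 0.5 * r_k[r] * dd * dd
                c = r_k[r] * dd / d
                F[i, 0] -= c * dx
                F[i, 1] -= c * dy
                F[i, 2] -= c * dz
                F[j, 0] += c * dx
                F[j, 1] += c * dy
                F[j, 2] += c * dz
                continue
            ia, ib, ic, id_ = (r_idx[r, 0], r_idx[r, 1],
                               r_idx[r, 2], r_idx[r, 3])
            kk = r_k[r]
            p0 = r_target[r]
        b1x = x[ib, 0] - x[ia, 0]
        b1y = x[ib, 1] - x[ia, 1]
        b1z = x[ib, 2] - x[ia, 2]
        b2x = x[ic, 0] - x[ib, 0]
        b2y = x[ic, 1] - x[ib, 1]
        b2z = x[ic, 2] - x[ib, 2]
        b3x = x[id_, 0] - x[ic, 0]
        b3y = x[id_, 1] - x[ic, 1]
        b3z = x[id_, 2] - x[ic, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        xc = n1x * n2x + n1y * n2y + n1z * n2z
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        yc = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        phi = math.atan2(yc, xc)
        dp = phi - p0
        # wrap to (-pi, pi]
        dp = (dp + math.pi) % (2.0 * math.pi) - math.pi
        if dp == -math.pi:
            dp = math.pi
        U += 0.5 * kk * dp * dp
        coeff = kk * dp
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < _SIN2_FLOOR:
            n1sq = _SIN2_FLOOR
        if n2sq < _SIN2_FLOOR:
            n2sq = _SIN2_FLOOR
        f1 = -nb2 / n1sq
        g1x_, g1y_, g1z_ = f1 * n1x, f1 * n1y, f1 * n1z
        f4 = nb2 / n2sq
        g4x, g4y, g4z = f4 * n2x, f4 * n2y, f4 * n2z
        nb2sq = nb2 * nb2
        c1 = (b1x * b2x + b1y * b2y + b1z * b2z) / nb2sq
        c3 = (b3x * b2x + b3y * b2y + b3z * b2z) / nb2sq
        g2x = -(1.0 + c1) * g1x_ + c3 * g4x
        g2y = -(1.0 + c1) * g1y_ + c3 * g4y
        g2z = -(1.0 + c1) * g1z_ + c3 * g4z
        g3x_ = c1 * g1x_ - (1.0 + c3) * g4x
        g3y_ = c1 * g1y_ - (1.0 + c3) * g4y
        g3z_ = c1 * g1z_ - (1.0 + c3) * g4z
        F[ia, 0] -= coeff * g1x_
        F[ia, 1] -= coeff * g1y_
        F[ia, 2] -= coeff * g1z_
        F[ib, 0] -= coeff * g2x
        F[ib, 1] -= coeff * g2y
        F[ib, 2] -= coeff * g2z
        F[ic, 0] -= coeff * g3x_
        F[ic, 1] -= coeff * g3y_
        F[ic, 2] -= coeff * g3z_
        F[id_, 0] -= coeff * g4x
        F[id_, 1] -= coeff * g4y
        F[id_, 2] -= coeff * g4z
    return U, F


def restraint_value(x: np.ndarray, r: Restraint) -> float:
    """Current collective-variable value (Å, or rad for torsions)."""
    if r.kind == "com_distance":
        return _distance(x[r.idx[0]], x[r.idx[1]])
    if r.kind == "torsion":
        return _dihedral(*(x[i] for i in r.idx))
    raise ValueError(f"unknown restraint kind {r.kind!r}")


def _restraint_arrays(restraints, t: float):
    m = len(restraints)
    r_kind = np.zeros(m, np.int64)
    r_idx = np.zeros((m, 4), np.int64)
    r_k = np.zeros(m)
    r_target = np.zeros(m)
    for ri, r in enumerate(restraints):
        if r.kind == "com_distance":
            r_kind[ri] = 0
            r_idx[ri, :2] = r.idx
        elif r.kind == "torsion":
            r_kind[ri] = 1
            r_idx[ri, :4] = r.idx
        else:
            raise ValueError(f"unknown restraint kind {r.kind!r}")
        r_k[ri] = r.k
        r_target[ri] = r.target(t)
    return r_kind, r_idx, r_k, r_target


def energy_forces(
    sys: CGSystem,
    x: np.ndarray | None = None,
    restraints: tuple[Restraint, ...] = (),
    t: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Total potential energy (kcal/mol) and per-bead forces (kcal/mol/Å).

    Includes the bonded ring terms and any time-dependent restraints with
    moving targets xi0(t); restraint energies are U = (k/2)(xi - xi0(t))^2
    with angular differences wrapped to (-180°, 180°].  Near-collinear
    torsion geometry is regularised (the 1/sin^2 factor is capped) so forces
    are always finite.
    """
    if x is None:
        x = sys.x0
    x = np.ascontiguousarray(x, dtype=float)
    r_kind, r_idx, r_k, r_target = _restraint_arrays(restraints, t)
    U, F = _ef_kernel(
        x, sys.bond_idx, sys.bond_k, sys.bond_r0,
        sys.angle_idx, sys.angle_k, sys.angle_t0,
        sys.tors_idx, sys.tors_k, sys.tors_p0,
        r_kind, r_idx, r_k, r_target,
    )
    return float(U), F


def kinetic_energy(sys: CGSystem, v: np.ndarray) -> float:
    """Kinetic energy in kcal/mol (v in Å/ps)."""
    return 0.5 * float((sys.mass[:, None] * v**2).sum()) / KCAL_TO_AKMA


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

@dataclass
class CGTrajectory:
    """Saved bead positions plus per-restraint collective-variable traces."""

    labels: tuple[str, ...]
    positions: np.ndarray            # (n_saved, n_beads, 3)
    time_ps: np.ndarray              # (n_saved,)
    colvars: pd.DataFrame            # time_ps, restraint_id, kind, value, target, energy
    final_x: np.ndarray
    final_v: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def to_trajectory(self, sys: CGSystem) -> Trajectory:
        tmpl = sys.bead_structure()
        return Trajectory(template=tmpl, coords=self.positions.copy(),
                          time_ps=self.time_ps.copy())


def _maxwell_velocities(rng, mass, temperature):
    if temperature == 0.0:
        return np.zeros((len(mass), 3))
    sd = np.sqrt(KB_KCAL * temperature * KCAL_TO_AKMA / mass)
    return rng.normal(size=(len(mass), 3)) * sd[:, None]


def run_langevin(
    sys: CGSystem,
    p: LangevinParams,
    n_steps: int,
    restraints: tuple[Restraint, ...] = (),
    x0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    t0: float = 0.0,
    save_every: int = 100,
    rng: np.random.Generator | None = None,
) -> CGTrajectory:
    """BAOAB-splitting Langevin integration; bitwise reproducible per seed.

    At zero damping the O-step is the identity and the scheme reduces to
    velocity Verlet.  Positions and restraint traces are recorded every
    ``save_every`` steps (and at the final step).
    """
    dt = p.timestep
    m = sys.mass[:, None]
    inv_m = KCAL_TO_AKMA / m                      # F (kcal/mol/Å) -> Å/ps^2
    if rng is None:
        rng = np.random.default_rng(p.seed)
    x = np.array(sys.x0 if x0 is None else x0, float)
    v = (
        _maxwell_velocities(rng, sys.mass, p.temperature)
        if v0 is None else np.array(v0, float)
    )
    c1 = math.exp(-p.damping * dt)
    if p.damping > 0.0 and p.temperature > 0.0:
        sigma = np.sqrt(KB_KCAL * p.temperature * KCAL_TO_AKMA / sys.mass
                        * (1.0 - c1 * c1))[:, None]
    else:
        sigma = None

    e_scale = max(abs(energy_forces(sys, x, restraints, t0)[0]), 1.0)
    U, F = energy_forces(sys, x, restraints, t0)
    n_saved_est = n_steps // save_every + 2
    saved_x = np.empty((n_saved_est, sys.n_beads, 3))
    saved_t = np.empty(n_saved_est)
    colvar_rows: list[tuple] = []
    n_saved = 0

    def _record(t):
        nonlocal n_saved
        saved_x[n_saved] = x
        saved_t[n_saved] = t
        for ri, r in enumerate(restraints):
            val = restraint_value(x, r)
            tgt = r.target(t)
            if r.kind == "torsion":
                diff = _wrap_pi(val - tgt)
                en = 0.5 * r.k * diff * diff
                val_out, tgt_out = math.degrees(val), math.degrees(tgt)
            else:
                en = 0.5 * r.k * (val - tgt) ** 2
                val_out, tgt_out = val, tgt
            colvar_rows.append(
                (t, r.label or f"r{ri}", r.kind, val_out, tgt_out, en)
            )
        n_saved += 1

    _record(t0)
    t = t0
    for step in range(1, n_steps + 1):
        v += (0.5 * dt) * F * inv_m
        x += (0.5 * dt) * v
        if sigma is not None:
            v = c1 * v + sigma * rng.normal(size=v.shape)
        elif p.damping > 0.0:
            v = c1 * v
        x += (0.5 * dt) * v
        t = t0 + step * dt
        U, F = energy_forces(sys, x, restraints, t)
        v += (0.5 * dt) * F * inv_m
        if step % save_every == 0 or step == n_steps:
            if not (np.isfinite(U) and np.all(np.isfinite(x))) or (
                p.temperature == 0.0 and U > 1e6 * e_scale
            ):
                raise IntegrationError(
                    f"integration diverged at t = {t:.3f} ps; "
                    "use a smaller timestep"
                )
            _record(t)

    colvars = pd.DataFrame(
        colvar_rows,
        columns=["time_ps", "restraint_id", "kind", "value", "target", "energy"],
    )
    return CGTrajectory(
        labels=sys.labels,
        positions=saved_x[:n_saved].copy(),
        time_ps=saved_t[:n_saved].copy(),
        colvars=colvars,
        final_x=x,
        final_v=v,
    )


# --------------------------------------------------------------------------
# steering protocols
# --------------------------------------------------------------------------

#: type-1 pulling: force constant (kcal/mol/Å^2), velocity (Å/ps), duration (ps)
TYPE1_K = 500.0
TYPE1_VELOCITY = 2.0e-3          # 2.0 Å/ns
TYPE1_NET = 20.0                 # Å
#: type-2/3 torsion steering: force constant (kcal/mol/deg^2), net change (deg)
TYPE23_K = 50.0
TYPE23_NET = 20.0
STEERING_DURATION_PS = 10_000.0  # 10 ns


def make_protocol(
    model_type: int,
    topology: ClampTopology,
    post_steering_ps: float = 10_000.0,
) -> SteeringProtocol:
    """The three ring-opening schedules.

    Type 1 pulls the open-interface COM distance +20 Å at 2.0 Å/ns
    (k = 500 kcal/mol/Å^2).  Types 2 and 3 drive each of the three interface
    torsions by -20° (left-handed) or +20° (right-handed) over 10 ns
    (k = 50 kcal/mol/deg^2).
    """
    if model_type not in (1, 2, 3):
        raise ValueError(f"model_type must be 1, 2 or 3, got {model_type!r}")
    if model_type == 1:
        restraints = (
            ("com_distance", tuple(topology.open_interface),
             TYPE1_K, TYPE1_NET, STEERING_DURATION_PS),
        )
    else:
        if not topology.torsion_quadruples:
            raise ValueError("topology defines no torsion quadruples")
        sign = -1.0 if model_type == 2 else 1.0
        restraints = tuple(
            ("torsion", tuple(quad), TYPE23_K, sign * TYPE23_NET,
             STEERING_DURATION_PS)
            for quad in topology.torsion_quadruples
        )
    return SteeringProtocol(
        model_type=model_type,
        restraints=restraints,
        post_steering_ps=post_steering_ps,
    )


def resolve_restraints(
    sys: CGSystem, proto: SteeringProtocol
) -> tuple[Restraint, ...]:
    """Bind a protocol's label-level restraints to bead indices and internal
    units, starting each target at the system's current colvar value."""
    out = []
    for ri, (kind, labels, k, net, duration) in enumerate(proto.restraints):
        idx = tuple(sys.index(lab) for lab in labels)
        if kind == "torsion":
            k_int = k * PER_DEG2_TO_PER_RAD2
            net_int = net * DEG
        else:
            k_int = k
            net_int = net
        start = restraint_value(sys.x0, Restraint(kind, idx, 0, 0, 0, 0))
        out.append(
            Restraint(
                kind=kind, idx=idx, k=k_int, target0=start,
                velocity=net_int / duration, duration_ps=duration,
                label=f"{kind}:{'-'.join(labels)}",
            )
        )
    return tuple(out)


def run_steered(
    sys: CGSystem,
    proto: SteeringProtocol,
    p: LangevinParams,
    save_every: int = 1000,
) -> CGTrajectory:
    """Steering phase followed by free relaxation, as one trajectory.

    The returned trajectory's colvar table covers the steering phase (value,
    moving target and restraint energy per saved frame); the free phase
    carries no restraints.
    """
    restraints = resolve_restraints(sys, proto)
    durations = {r.duration_ps for r in restraints} or {0.0}
    if len(durations) > 1:
        raise ValueError("restraints with unequal durations are not supported")
    duration = durations.pop()
    n_steer = int(round(duration / p.timestep))
    rng = np.random.default_rng(p.seed)
    if n_steer > 0:
        steer = run_langevin(
            sys, p, n_steer, restraints=restraints,
            save_every=save_every, rng=rng,
        )
    else:
        steer = None
    n_free = int(round(proto.post_steering_ps / p.timestep))
    if n_free > 0:
        free = run_langevin(
            sys, p, n_free,
            x0=steer.final_x if steer else None,
            v0=steer.final_v if steer else None,
            t0=duration,
            save_every=save_every, rng=rng,
        )
    else:
        free = None
    if steer is None and free is None:
        raise ValueError("protocol has zero steering and zero free duration")
    if free is None:
        return steer
    if steer is None:
        return free
    return CGTrajectory(
        labels=sys.labels,
        positions=np.concatenate([steer.positions, free.positions[1:]]),
        time_ps=np.concatenate([steer.time_ps, free.time_ps[1:]]),
        colvars=steer.colvars,
        final_x=free.final_x,
        final_v=free.final_v,
    )
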