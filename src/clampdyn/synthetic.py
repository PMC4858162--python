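"""Idealised clamp structures and trajectories with exact ground truth.

The generator emulates, at desk scale, the data an all-atom MD study of
sliding clamps produces: pseudo-six-fold toroidal rings of rigid
pseudo-domains, opened rings (planar, left- or right-handed spiral, in-plane
hinge), and trajectories whose inter-domain rotations fluctuate with a
prescribed Gaussian distribution plus coordinate noise.  Every deformation is
built from rigid per-domain transforms, so the injected geometry (interface
torsions, gaps, angles, rotations) is exact by construction and can be used
as ground truth for the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clampdyn.topology import (
    ClampTopology,
    DomainAssignment,
    Structure,
    Trajectory,
    assign_domains,
    default_torsion_quadruples,
    domain_com,
)

__all__ = [
    "RingSpec",
    "DeformationSpec",
    "build_ideal_ring",
    "apply_deformation",
    "generate_trajectory",
    "mirror_z",
]

_CARBON = 12.011


@dataclass(frozen=True)
class RingSpec:
    """Blueprint for an idealised pseudo-six-fold clamp ring."""

    n_domains: int = 6
    ring_radius: float = 35.0        # Å, COM circle radius
    atoms_per_domain: int = 20
    domain_spread: float = 6.0       # Å, size of the pseudo-atom cloud
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 4:
            raise ValueError("n_domains must be >= 4")
        if not (self.ring_radius > self.domain_spread > 0):
            raise ValueError("require ring_radius > domain_spread > 0")
        if self.atoms_per_domain < 4:
            raise ValueError("atoms_per_domain must be >= 4")


@dataclass(frozen=True)
class DeformationSpec:
    """Rigid-body deformation / trajectory recipe applied to an ideal ring.

    ``mode`` selects the conformational class: ``planar_open`` (in-plane gap
    at the open interface), ``lh_spiral`` / ``rh_spiral`` (per-interface
    twist of the designated torsion windows), ``in_plane_angle`` (change one
    COM angle by an increment).  Trajectory generation draws per-frame
    inter-domain rotations from Normal(rotation_mean, rotation_sd^2) degrees
    and adds isotropic Gaussian coordinate noise.
    """

    mode: str = "rh_spiral"
    twist_deg: float = 20.0          # per-interface torsion change (spirals)
    gap_A: float = 20.0              # open-interface COM gap (planar_open)
    angle_increment_deg: float = 7.0  # COM angle change (in_plane_angle)
    angle_triple: tuple[str, str, str] | None = None
    noise_sd: float = 0.0            # Å, per-coordinate Gaussian noise
    rotation_mean: float = 13.9      # deg, Gaussian inter-domain rotation
    rotation_sd: float = 4.4         # deg
    rotation_interfaces: tuple[tuple[str, str], ...] | None = None
    n_frames: int = 1000
    frame_dt_ps: float = 100.0
    seed: int = 0

    _MODES = ("planar_open", "lh_spiral", "rh_spiral", "in_plane_angle")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown mode {self.mode!r}; one of {self._MODES}")
        if self.noise_sd < 0 or self.rotation_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_dt_ps <= 0:
            raise ValueError("frame_dt_ps must be > 0")


# --------------------------------------------------------------------------
# ideal ring
# --------------------------------------------------------------------------

def _rand_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def build_ideal_ring(spec: RingSpec) -> tuple[Structure, ClampTopology]:
    """Planar closed ring of rigid pseudo-domains.

    Domain COMs sit exactly on a circle of the requested radius in the z = 0
    plane; each domain is an anisotropic (non-degenerate inertia) random
    cloud so Kabsch orientation fits are unique.  The emitted topology labels
    the domains A1…An around the ring, designates the (An, A1) interface as
    the opening interface and carries its three torsion windows.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_domains
    m = spec.atoms_per_domain
    coords = np.empty((n * m, 3))
    # anisotropic axis scales keep the inertia tensor non-degenerate
    scales = np.array([1.0, 0.6, 0.35]) * spec.domain_spread / 2.0
    for k in range(n):
        cloud = rng.normal(size=(m, 3)) * scales
        cloud = cloud @ _rand_rotation(rng).T
        cloud -= cloud.mean(axis=0)          # exact zero-COM (equal masses)
        phi = 2.0 * np.pi * k / n
        center = spec.ring_radius * np.array([np.cos(phi), np.sin(phi), 0.0])
        coords[k * m : (k + 1) * m] = cloud + center

    labels = tuple(f"A{k + 1}" for k in range(n))
    s = Structure(
        chain_id=np.full(n * m, "A", dtype="U4"),
        res_id=np.arange(1, n * m + 1),
        ins_code=np.full(n * m, "", dtype="U1"),
        res_name=np.full(n * m, "GLY", dtype="U5"),
        atom_name=np.full(n * m, "CA", dtype="U6"),
        element=np.full(n * m, "C", dtype="U2"),
        mass=np.full(n * m, _CARBON),
        coord=coords,
    )
    open_interface = (labels[-1], labels[0])
    topo = ClampTopology(
        clamp_name=f"ideal_ring_{n}",
        domains=tuple(
            (labels[k], "A", k * m + 1, (k + 1) * m) for k in range(n)
        ),
        ring_order=labels,
        open_interface=open_interface,
        torsion_quadruples=default_torsion_quadruples(labels, open_interface),
    )
    return s, topo


# --------------------------------------------------------------------------
# rigid deformations
# --------------------------------------------------------------------------

def _rodrigues(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    a = np.radians(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def _rotate_about(coord, idx, point, axis, angle_deg):
    R = _rodrigues(axis, angle_deg)
    coord[idx] = (coord[idx] - point) @ R.T + point
    return R


def apply_deformation(
    s: Structure,
    t: ClampTopology,
    d: DeformationSpec,
) -> tuple[Structure, list[dict]]:
    """Apply a rigid per-domain deformation; returns the deformed structure
    and the ground-truth record of applied transforms.

    Spiral modes change each of the topology's three interface torsions by
    exactly ±twist_deg (positive twist: right-handed, handedness sum
    +3·twist).  ``planar_open`` translates the two rigid half-rings apart so
    the open-interface COM distance grows by exactly ``gap_A`` in-plane.
    ``in_plane_angle`` rotates the third domain of ``angle_triple`` (and the
    domains beyond it along the ring path) so that the designated COM angle
    changes by exactly ``angle_increment_deg``.

    Applying the same mode with negated magnitude restores the input
    exactly (the windowed rotations invert in the same order).
    """
    assignment = assign_domains(s, t)
    out = s.copy()
    coord = out.coord
    path = t.interface_path()
    record: list[dict] = []

    def com(label):
        return domain_com(coord, assignment, label, mass=s.mass, element=s.element)

    if d.mode in ("rh_spiral", "lh_spiral"):
        delta = d.twist_deg if d.mode == "rh_spiral" else -d.twist_deg
        for q, quad in enumerate(t.torsion_quadruples):
            b, c = quad[1], quad[2]
            axis = com(c) - com(b)
            point = com(b)
            moved = [lab for lab in path[q + 3:]]
            idx = np.concatenate([assignment[lab] for lab in moved])
            R = _rotate_about(coord, idx, point, axis, delta)
            record.append({"op": "torsion", "quad": quad, "delta_deg": delta,
                           "domains": moved, "R": R, "point": point})
    elif d.mode == "planar_open":
        X, Y = t.open_interface
        dhat = com(Y) - com(X)
        dhat = dhat / np.linalg.norm(dhat)
        half = len(path) // 2
        first, second = path[:half], path[half:]
        for labs, sign in ((first, +0.5), (second, -0.5)):
            idx = np.concatenate([assignment[lab] for lab in labs])
            shift = sign * d.gap_A * dhat
            coord[idx] += shift
            record.append({"op": "translate", "domains": list(labs),
                           "shift": shift})
    elif d.mode == "in_plane_angle":
        triple = d.angle_triple
        if triple is None:
            triple = tuple(path[:3])
        a, b, c = triple
        u = com(a) - com(b)
        w = com(c) - com(b)
        axis = np.cross(u, w)
        if np.linalg.norm(axis) < 1e-12:
            raise ValueError("angle triple is collinear; axis undefined")
        point = com(b)
        c_pos = path.index(c)
        moved = [lab for lab in path[c_pos:]]
        idx = np.concatenate([assignment[lab] for lab in moved])
        R = _rotate_about(coord, idx, point, axis, d.angle_increment_deg)
        record.append({"op": "angle", "triple": triple,
                       "delta_deg": d.angle_increment_deg,
                       "domains": moved, "R": R, "point": point})
    else:  # pragma: no cover - guarded by DeformationSpec validation
        raise ValueError(d.mode)
    return out, record


def mirror_z(s: Structure) -> Structure:
    """z -> -z reflection (turns a right-handed spiral left-handed)."""
    out = s.copy()
    out.coord = out.coord * np.array([1.0, 1.0, -1.0])
    return out


# --------------------------------------------------------------------------
# stochastic trajectories
# --------------------------------------------------------------------------

def generate_trajectory(
    base: Structure,
    t: ClampTopology,
    d: DeformationSpec,
) -> tuple[Trajectory, pd.DataFrame]:
    """Trajectory with Gaussian inter-domain rotations plus coordinate noise.

    Each frame starts from ``base``; for every designated interface (i, j)
    an angle is drawn i.i.d. from Normal(rotation_mean, rotation_sd^2)
    degrees and domain j is rigidly rotated by that angle about the i→j COM
    axis through its own COM (so all COMs are preserved and the drawn angle
    is exactly the relative body rotation of j with respect to i).  Isotropic
    Gaussian noise of sd ``noise_sd`` Å is then added to every coordinate.

    Returns the trajectory (frame times k·frame_dt_ps) and the ground-truth
    draws as a tidy table (frame, interface, applied_rotation_deg).
    """
    assignment = assign_domains(base, t)
    interfaces = d.rotation_interfaces
    if interfaces is None:
        interfaces = ((t.ring_order[0], t.ring_order[1]),)
    for i, j in interfaces:
        if i not in t.labels or j not in t.labels:
            raise ValueError(f"unknown interface domain in ({i}, {j})")
    rng = np.random.default_rng(d.seed)
    coms = {
        lab: domain_com(base, assignment, lab) for lab in t.labels
    }
    n_atoms = base.n_atoms
    coords = np.empty((d.n_frames, n_atoms, 3))
    rows = []
    for f in range(d.n_frames):
        frame = base.coord.copy()
        for (i, j) in interfaces:
            ang = float(rng.normal(d.rotation_mean, d.rotation_sd))
            axis = coms[j] - coms[i]
            _rotate_about(frame, assignment[j], coms[j], axis, ang)
            rows.append((f, f"{i}-{j}", ang))
        if d.noise_sd > 0:
            frame += rng.normal(scale=d.noise_sd, size=frame.shape)
        coords[f] = frame
    traj = Trajectory(
        template=base,
        coords=coords,
        time_ps=np.arange(d.n_frames, dtype=float) * d.frame_dt_ps,
    )
    truth = pd.DataFrame(rows, columns=["frame", "interface", "applied_rotation_deg"])
    return traj, truth
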