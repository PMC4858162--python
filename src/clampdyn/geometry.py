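"""Geometric descriptors of clamp-domain arrangements.

All descriptors operate on centre-of-mass (COM) points or raw coordinate
sets: Euclidean distances, vertex angles, signed dihedrals (IUPAC
right-handed convention), the *handedness sum* — the sum of the three signed
COM torsions spanning an opened ring interface, positive for a right-handed
spiral — inter-domain rotation angles from relative Kabsch body frames, and
the size-normalised RMSD

    RMSD100 = RMSD / (1 + ln(N / 100)),

which makes fluctuation amplitudes comparable between assemblies of
different residue counts N.

Time series of these metrics are carried by :class:`GeometrySeries`; summary
statistics discard an initial pre-equilibration window (default 10 ns) and
unwrap angular series before averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from clampdyn.topology import (
    ClampTopology,
    DomainAssignment,
    Structure,
    Trajectory,
    domain_com,
)

__all__ = [
    "GeometrySeries",
    "DegenerateGeometryError",
    "com_distance",
    "com_angle",
    "com_dihedral",
    "handedness_sum",
    "kabsch_superpose",
    "rmsd100",
    "inter_domain_rotation",
    "series_summary",
    "unwrap_degrees",
    "trajectory_series",
]

#: Default pre-equilibration window discarded from summaries, ps (10 ns).
DEFAULT_DISCARD_PS = 10_000.0

_ANGULAR_UNITS = {"deg", "degree", "degrees"}


class DegenerateGeometryError(ValueError):
    """Raised for geometrically degenerate inputs (coincident or collinear
    points, rank-deficient point clouds)."""


# --------------------------------------------------------------------------
# point metrics
# --------------------------------------------------------------------------

def com_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance |p - q| in Å."""
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))


def com_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle at vertex ``p2`` in degrees, in [0, 180]."""
    u = np.asarray(p1, float) - np.asarray(p2, float)
    v = np.asarray(p3, float) - np.asarray(p2, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("angle vertex coincides with an endpoint")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def com_dihedral(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> float:
    """Signed dihedral of four points in degrees, in (-180, 180].

    IUPAC right-handed convention: rotating ``p4`` by +x° about the p2→p3
    axis (right-hand rule) adds +x° to the dihedral; the planar cis
    arrangement is 0° and trans is 180°.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0 or nb2 == 0.0:
        raise DegenerateGeometryError("three consecutive dihedral points collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def handedness_sum(
    frame: Structure | np.ndarray,
    topology: ClampTopology,
    assignment: DomainAssignment,
    mode: str = "mass",
    **meta,
) -> float:
    """Sum of the three signed COM torsions around the opening interface.

    Positive values indicate a right-handed spiral of the domain COMs,
    negative a left-handed one; a planar ring gives 0.
    """
    if not topology.torsion_quadruples:
        raise ValueError(
            f"topology {topology.clamp_name!r} defines no torsion quadruples"
        )
    coms = {
        label: domain_com(frame, assignment, label, mode=mode, **meta)
        for label in topology.labels
    }
    return sum(
        com_dihedral(*(coms[q] for q in quad))
        for quad in topology.torsion_quadruples
    )


# --------------------------------------------------------------------------
# superposition and RMSD
# --------------------------------------------------------------------------

def kabsch_superpose(
    X: np.ndarray,
    Y: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``X`` onto ``Y`` (least-squares).

    Returns ``(R, t, rmsd)`` such that ``R @ x + t`` best matches ``Y`` in
    the weighted least-squares sense, with ``R`` a proper rotation
    (det = +1).  Requires at least 3 points with non-degenerate spread.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = len(X)
    if n < 3:
        raise DegenerateGeometryError("superposition requires at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    xc = (X * w[:, None]).sum(axis=0)
    yc = (Y * w[:, None]).sum(axis=0)
    X0 = X - xc
    Y0 = Y - yc
    if np.linalg.matrix_rank(X0, tol=1e-10) < 2:
        raise DegenerateGeometryError("rank-deficient point spread")
    H = (X0 * w[:, None]).T @ Y0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = (X0 @ R.T) - Y0
    msd = float((w * (diff**2).sum(axis=1)).sum())
    return R, t, math.sqrt(max(msd, 0.0))


def rmsd100(rmsd: float, n_residues: int) -> float:
    """Size-normalised RMSD: RMSD / (1 + ln(N/100)).

    Equal to the raw RMSD at N = 100 residues and monotonically decreasing
    in N for fixed RMSD.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if rmsd < 0:
        raise ValueError("rmsd must be >= 0")
    return float(rmsd) / (1.0 + math.log(n_residues / 100.0))


def rotation_angle_axis(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (degrees, [0, 180]) and unit axis of a proper rotation matrix.

    For near-identity rotations the axis is taken from the skew-symmetric
    part; at 180° the axis comes from the dominant eigenvector.
    """
    R = np.asarray(R, float)
    cosang = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    ang = math.degrees(math.acos(cosang))
    skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    ns = np.linalg.norm(skew)
    if ns > 1e-12:
        axis = skew / ns
    else:
        # 0° (axis irrelevant) or 180° (eigenvector of R with eigenvalue +1)
        vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
        axis = vecs[:, -1]
        axis = axis / np.linalg.norm(axis)
    return ang, axis


def inter_domain_rotation(
    ref_i: np.ndarray,
    cur_i: np.ndarray,
    ref_j: np.ndarray,
    cur_j: np.ndarray,
) -> float:
    """Signed rotation (degrees) of domain *j* relative to domain *i*
    between a reference frame and the current frame.

    Each domain's body rotation ``R_i``, ``R_j`` is obtained by Kabsch
    superposition from its reference onto its current coordinates; the
    relative transform is ``R_rel = R_j @ R_i.T`` and its angle is
    ``arccos((tr R_rel - 1)/2)``.  The sign is the sign of the projection of
    the rotation axis onto the reference inter-domain COM axis (from the
    centroid of domain *i* to that of domain *j*): a rotation that advances
    domain *j* right-handedly about the i→j axis is positive.
    """
    R_i, _, _ = kabsch_superpose(ref_i, cur_i)
    R_j, _, _ = kabsch_superpose(ref_j, cur_j)
    R_rel = R_j @ R_i.T
    ang, axis = rotation_angle_axis(R_rel)
    if ang < 1e-10:
        return 0.0
    d = np.asarray(ref_j, float).mean(axis=0) - np.asarray(ref_i, float).mean(axis=0)
    nd = np.linalg.norm(d)
    if nd == 0.0:
        raise DegenerateGeometryError("coincident domain centroids")
    sign = 1.0 if float(np.dot(axis, d / nd)) >= 0.0 else -1.0
    return sign * ang


# --------------------------------------------------------------------------
# time series
# --------------------------------------------------------------------------

def unwrap_degrees(values: np.ndarray) -> np.ndarray:
    """Nearest-image continuation of an angular series: add/subtract 360° to
    minimise frame-to-frame jumps."""
    return np.degrees(np.unwrap(np.radians(np.asarray(values, float))))


@dataclass
class GeometrySeries:
    """Per-frame values of one metric, with units and timing metadata."""

    metric_name: str
    unit: str                      # "A" or "deg"
    values: np.ndarray
    time_ps: np.ndarray | None = None
    discard_ps: float = DEFAULT_DISCARD_PS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in series {self.metric_name!r}")
        if self.time_ps is not None:
            self.time_ps = np.asarray(self.time_ps, float)
            if len(self.time_ps) != len(self.values):
                raise ValueError("time_ps length mismatch")

    @property
    def is_angular(self) -> bool:
        return self.unit.lower() in _ANGULAR_UNITS

    def retained(self) -> np.ndarray:
        """Values surviving the pre-equilibration discard."""
        if self.time_ps is None:
            raise ValueError(
                f"series {self.metric_name!r} has no frame times; supply an "
                "explicit frame-count discard via values slicing"
            )
        return self.values[self.time_ps >= self.discard_ps]


def series_summary(s: GeometrySeries) -> tuple[float, float]:
    """Sample mean and sample SD (n-1 denominator) of the retained values.

    Angular series are unwrapped (nearest-image continuation) before
    averaging so that steering sweeps across ±180° do not bias the mean.
    """
    vals = s.retained()
    if len(vals) < 2:
        raise ValueError(
            f"series {s.metric_name!r}: fewer than 2 frames retained after "
            f"discarding t < {s.discard_ps} ps"
        )
    if s.is_angular:
        vals = unwrap_degrees(vals)
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


# --------------------------------------------------------------------------
# trajectory-level drivers
# --------------------------------------------------------------------------

def _frame_coms(
    coord: np.ndarray,
    template: Structure,
    assignment: DomainAssignment,
    labels,
    mode: str,
) -> dict[str, np.ndarray]:
    return {
        lab: domain_com(
            coord, assignment, lab, mode=mode,
            mass=template.mass, element=template.element,
            atom_name=template.atom_name,
        )
        for lab in labels
    }


def trajectory_series(
    traj: Trajectory,
    topology: ClampTopology,
    assignment: DomainAssignment,
    metrics: list[str],
    discard_ps: float = DEFAULT_DISCARD_PS,
    mode: str = "mass",
    reference: Structure | np.ndarray | None = None,
) -> list[GeometrySeries]:
    """Evaluate named metrics over every frame of a trajectory.

    ``metrics`` entries are strings of the form ``"distance:L1-L2"``,
    ``"angle:L1-L2-L3"``, ``"torsion:L1-L2-L3-L4"``, ``"handedness"`` or
    ``"rotation:L1-L2"`` with ``L*`` domain labels from the topology.

    ``rotation`` metrics are measured relative to ``reference`` (a starting
    structure, e.g. the crystal conformation); when omitted, frame 0 of the
    trajectory serves as the reference.
    """
    if not metrics:
        raise ValueError("empty metric list")
    parsed: list[tuple[str, list[str]]] = []
    for m in metrics:
        kind, _, rest = m.partition(":")
        labels = rest.split("-") if rest else []
        expected = {"distance": 2, "angle": 3, "torsion": 4,
                    "handedness": 0, "rotation": 2}
        if kind not in expected:
            raise ValueError(f"unknown metric {m!r}")
        if len(labels) != expected[kind]:
            raise ValueError(f"metric {m!r}: expected {expected[kind]} labels")
        for lab in labels:
            if lab not in topology.labels:
                raise ValueError(f"metric {m!r}: unknown domain label {lab!r}")
        parsed.append((kind, labels))

    tmpl = traj.template
    n = traj.n_frames
    out_vals: list[np.ndarray] = [np.empty(n) for _ in parsed]
    if reference is None:
        ref_coord = traj.coords[0]
    elif isinstance(reference, Structure):
        ref_coord = reference.coord
    else:
        ref_coord = np.asarray(reference, float)
    for f in range(n):
        coord = traj.coords[f]
        coms = _frame_coms(coord, tmpl, assignment, topology.labels, mode)
        for k, (kind, labels) in enumerate(parsed):
            if kind == "distance":
                v = com_distance(coms[labels[0]], coms[labels[1]])
            elif kind == "angle":
                v = com_angle(*(coms[lab] for lab in labels))
            elif kind == "torsion":
                v = com_dihedral(*(coms[lab] for lab in labels))
            elif kind == "handedness":
                v = handedness_sum(
                    coord, topology, assignment, mode=mode,
                    mass=tmpl.mass, element=tmpl.element,
                    atom_name=tmpl.atom_name,
                )
            else:  # rotation
                i_idx = assignment[labels[0]]
                j_idx = assignment[labels[1]]
                v = inter_domain_rotation(
                    ref_coord[i_idx], coord[i_idx],
                    ref_coord[j_idx], coord[j_idx],
                )
            out_vals[k][f] = v
    series = []
    for (kind, labels), vals in zip(parsed, out_vals):
        name = kind if not labels else f"{kind}:{'-'.join(labels)}"
        unit = "A" if kind == "distance" else "deg"
        series.append(
            GeometrySeries(name, unit, vals, time_ps=traj.time_ps,
                           discard_ps=discard_ps)
        )
    return series


def series_frame(series: list[GeometrySeries]) -> pd.DataFrame:
    """Tidy per-frame table: frame, time_ps, metric, value, unit."""
    rows = []
    for s in series:
        t = s.time_ps if s.time_ps is not None else np.full(len(s.values), np.nan)
        for f, (ti, v) in enumerate(zip(t, s.values)):
            rows.append((f, ti, s.metric_name, v, s.unit))
    return pd.DataFrame(rows, columns=["frame", "time_ps", "metric", "value", "unit"])


def summary_frame(series: list[GeometrySeries]) -> pd.DataFrame:
    """Summary table: metric, mean, sd, n_frames, discard_ps."""
    rows = []
    for s in series:
        mean, sd = series_summary(s)
        rows.append((s.metric_name, mean, sd, len(s.retained()), s.discard_ps))
    return pd.DataFrame(rows, columns=["metric", "mean", "sd", "n_frames", "discard_ps"])
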