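"""The "spheres and arrows" coarse-grained representation.

Each clamp domain is drawn as a sphere at its centre of mass plus a
body-fixed arrow.  At the reference frame the arrow is the vector from the
sphere to the system centre of mass; in later frames the arrow keeps its
length and its orientation *relative to the domain* — it is rotated by the
domain's fitted (Kabsch) body rotation — so changes in arrow direction
report changes in domain orientation.

For bead-only (CG simulator) trajectories there are no internal atoms to
fit, so domain orientation is propagated from a local ring frame built from
the neighbouring bead positions instead; see :func:`bead_orientation`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from clampdyn.geometry import DegenerateGeometryError, kabsch_superpose
from clampdyn.topology import (
    ClampTopology,
    DomainAssignment,
    Structure,
    Trajectory,
    domain_com,
    system_com,
)

__all__ = [
    "ArrowSet",
    "init_arrows",
    "update_arrows",
    "write_arrows",
    "read_arrows_csv",
    "arrow_series",
    "bead_orientation",
]


@dataclass
class ArrowSet:
    """Sphere centres and arrow vectors for one frame, plus the frozen
    reference data needed to update to later frames."""

    labels: tuple[str, ...]
    centers: np.ndarray           # (d, 3) current sphere centres (domain COMs)
    vectors: np.ndarray           # (d, 3) current arrow vectors
    ref_vectors: np.ndarray       # (d, 3) arrows at the reference frame
    ref_coord: np.ndarray         # (n_atoms, 3) reference frame coordinates

    def __post_init__(self) -> None:
        d = len(self.labels)
        for name in ("centers", "vectors", "ref_vectors"):
            arr = np.asarray(getattr(self, name), float)
            setattr(self, name, arr)
            if arr.shape != (d, 3):
                raise ValueError(f"{name} must be ({d}, 3)")


def _use_ca(s: Structure) -> bool:
    return bool(np.any(np.char.strip(s.atom_name.astype(str)) == "CA"))


def _fit_selection(s: Structure, idx: np.ndarray) -> np.ndarray:
    """Atoms used for the per-domain orientation fit: CA if present."""
    names = np.char.strip(s.atom_name[idx].astype(str))
    ca = idx[names == "CA"]
    return ca if len(ca) >= 3 else idx


def init_arrows(
    reference: Structure,
    assignment: DomainAssignment,
    topology: ClampTopology,
    mode: str = "mass",
) -> ArrowSet:
    """Arrows at the reference frame: system COM minus each domain COM."""
    labels = topology.labels
    if len(labels) < 2:
        raise DegenerateGeometryError(
            "a single-domain system has a degenerate system COM"
        )
    centers = np.array([
        domain_com(reference, assignment, lab, mode=mode) for lab in labels
    ])
    sys_com = system_com(reference, assignment, mode=mode)
    vectors = sys_com[None, :] - centers
    return ArrowSet(
        labels=labels,
        centers=centers,
        vectors=vectors.copy(),
        ref_vectors=vectors.copy(),
        ref_coord=reference.coord.copy(),
    )


def update_arrows(
    a: ArrowSet,
    frame: Structure | np.ndarray,
    assignment: DomainAssignment,
    template: Structure | None = None,
) -> ArrowSet:
    """Arrows for a new frame congruent with the reference.

    Per domain, the Kabsch rotation of the domain's fit atoms from the
    reference frame onto the current frame is applied to the reference
    vector, and the sphere is re-centred at the current COM.  Arrow lengths
    are conserved exactly (rotations are orthogonal).
    """
    if isinstance(frame, Structure):
        coord = frame.coord
        meta = frame
    else:
        coord = np.asarray(frame, float)
        if template is None:
            raise ValueError("bare coordinate frames require a template Structure")
        meta = template
    if coord.shape != a.ref_coord.shape:
        raise ValueError("frame not congruent with the reference frame")
    centers = np.empty_like(a.centers)
    vectors = np.empty_like(a.vectors)
    for d, lab in enumerate(a.labels):
        idx = assignment[lab]
        fit = _fit_selection(meta, idx)
        R, _, _ = kabsch_superpose(a.ref_coord[fit], coord[fit])
        vectors[d] = R @ a.ref_vectors[d]
        centers[d] = domain_com(
            coord, assignment, lab,
            mass=meta.mass, element=meta.element, atom_name=meta.atom_name,
        )
    return ArrowSet(
        labels=a.labels, centers=centers, vectors=vectors,
        ref_vectors=a.ref_vectors, ref_coord=a.ref_coord,
    )


def arrow_series(
    traj: Trajectory,
    assignment: DomainAssignment,
    topology: ClampTopology,
) -> list[ArrowSet]:
    """Arrows for every frame of a trajectory (frame 0 is the reference)."""
    ref = traj.frame(0)
    a0 = init_arrows(ref, assignment, topology)
    out = [a0]
    for f in range(1, traj.n_frames):
        out.append(update_arrows(a0, traj.coords[f], assignment,
                                 template=traj.template))
    return out


def bead_orientation(
    ref_positions: np.ndarray, cur_positions: np.ndarray, i: int
) -> np.ndarray:
    """Orientation change of bead ``i`` in a bead-only (CG) ring.

    With no internal atoms, a local frame is built from the vectors to the
    chain neighbours and to the ring centroid; the returned matrix rotates
    the bead's reference frame onto the current one.
    """
    def frame(x):
        n = len(x)
        prev = x[i - 1] if i > 0 else x[i]
        nxt = x[i + 1] if i < n - 1 else x[i]
        e1 = nxt - prev
        e1 = e1 / np.linalg.norm(e1)
        b = x.mean(axis=0) - x[i]
        e2 = b - np.dot(b, e1) * e1
        nrm = np.linalg.norm(e2)
        if nrm < 1e-10:
            raise DegenerateGeometryError("degenerate bead frame")
        e2 = e2 / nrm
        return np.column_stack([e1, e2, np.cross(e1, e2)])

    return frame(np.asarray(cur_positions, float)) @ frame(
        np.asarray(ref_positions, float)
    ).T


def write_arrows(
    series: list[ArrowSet],
    path: str | Path,
    fmt: str = "csv",
    sphere_radius: float = 4.0,
) -> None:
    """Write an arrow series as CSV or as a BILD graphics script.

    CSV columns: frame, domain, cx, cy, cz, vx, vy, vz.  The BILD dialect
    emits one ``.sphere`` and one ``.arrow`` primitive per domain per frame.
    """
    if not series:
        raise ValueError("empty arrow series")
    path = Path(path)
    if fmt == "csv":
        rows = []
        for f, a in enumerate(series):
            for d, lab in enumerate(a.labels):
                rows.append((f, lab, *a.centers[d], *a.vectors[d]))
        pd.DataFrame(
            rows, columns=["frame", "domain", "cx", "cy", "cz", "vx", "vy", "vz"]
        ).to_csv(path, index=False, float_format="%.6f")
    elif fmt == "bild":
        lines = []
        for f, a in enumerate(series):
            lines.append(f".comment frame {f}")
            for d, lab in enumerate(a.labels):
                c = a.centers[d]
                tip = c + a.vectors[d]
                lines.append(
                    f".sphere {c[0]:.3f} {c[1]:.3f} {c[2]:.3f} {sphere_radius:.3f}"
                )
                lines.append(
                    f".arrow {c[0]:.3f} {c[1]:.3f} {c[2]:.3f} "
                    f"{tip[0]:.3f} {tip[1]:.3f} {tip[2]:.3f}"
                )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown arrow format {fmt!r}")


def read_arrows_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
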