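"""Featurization of coordinate trajectories.

Pairwise distances (single-atom or minimum-over-heavy-atoms), signed
dihedral angles, circular sin/cos embedding, Kabsch superposition/RMSD,
and per-atom fluctuations (RMSF) after iterative superposition onto the
mean structure.  All outputs are invariant to global rigid-body motion —
distances and dihedrals directly, RMSD/RMSF after superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .traj import FeatureMatrix, Trajectory

__all__ = [
    "DistancePair",
    "FeatureSpec",
    "pairwise_distance",
    "dihedral",
    "embed_circular",
    "kabsch_superpose",
    "rmsf",
    "featurize",
]


@dataclass(frozen=True)
class DistancePair:
    """One distance feature: two atom selections and a mode.

    ``mode='single'`` requires one atom per selection and measures the plain
    Euclidean distance.  ``mode='min-heavy'`` takes the minimum distance over
    all heavy-atom cross pairs of the two groups (hydrogens excluded by
    atom-name convention).
    """

    selection_a: tuple[int, ...]
    selection_b: tuple[int, ...]
    mode: str = "single"
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.selection_a) == 0 or len(self.selection_b) == 0:
            raise ValueError("distance selections must be non-empty")
        if self.mode not in ("single", "min-heavy"):
            raise ValueError(f"unknown distance mode {self.mode!r}")
        if self.mode == "single" and (
            len(self.selection_a) != 1 or len(self.selection_b) != 1
        ):
            raise ValueError("mode='single' requires exactly one atom per side")


@dataclass
class FeatureSpec:
    """Editable template describing which distances and dihedrals to compute."""

    distance_pairs: list[DistancePair] = field(default_factory=list)
    dihedral_quads: list[tuple[tuple[int, int, int, int], str]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        for quad, _name in self.dihedral_quads:
            if len(set(quad)) != 4:
                raise ValueError(f"dihedral quadruplet {quad} has repeated atoms")


def pairwise_distance(traj: Trajectory, pair: DistancePair) -> np.ndarray:
    """Per-frame distance (Angstrom) for one :class:`DistancePair`."""
    sel_a = np.asarray(pair.selection_a, dtype=int)
    sel_b = np.asarray(pair.selection_b, dtype=int)
    if pair.mode == "min-heavy":
        sel_a = np.array([i for i in sel_a if traj.atom_meta[i].is_heavy], dtype=int)
        sel_b = np.array([i for i in sel_b if traj.atom_meta[i].is_heavy], dtype=int)
        if sel_a.size == 0 or sel_b.size == 0:
            raise ValueError("selection contains no heavy atoms")
        # (frames, |A|, |B|) cross-pair distances, reduced by min
        diff = traj.coordinates[:, sel_a, None, :] - traj.coordinates[:, None, sel_b, :]
        return np.sqrt((diff**2).sum(axis=-1)).min(axis=(1, 2))
    diff = traj.coordinates[:, sel_a[0], :] - traj.coordinates[:, sel_b[0], :]
    return np.sqrt((diff**2).sum(axis=-1))


def dihedral(traj: Trajectory, quad: Sequence[int]) -> np.ndarray:
    """Signed torsion angle over four atoms, per frame, in degrees.

    Uses the standard atan2 formulation; the IUPAC sign convention puts a
    planar *cis* arrangement at 0 deg and *trans* at 180 deg, with the
    result in (-180, 180].  Frames where one of the two planes is undefined
    (collinear atom triples) yield NaN.
    """
    i, j, k, l = (int(q) for q in quad)
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral requires four distinct atoms")
    x = traj.coordinates
    b1 = x[:, j] - x[:, i]
    b2 = x[:, k] - x[:, j]
    b3 = x[:, l] - x[:, k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    y = (np.cross(n1, n2) * (b2 / np.where(b2n[:, None] == 0, 1.0, b2n[:, None]))).sum(
        axis=1
    )
    xdot = (n1 * n2).sum(axis=1)
    ang = np.degrees(np.arctan2(y, xdot))
    degenerate = (np.linalg.norm(n1, axis=1) < 1e-10) | (
        np.linalg.norm(n2, axis=1) < 1e-10
    )
    ang[degenerate] = np.nan
    # map -180 -> 180 so the range is (-180, 180]
    ang[np.isclose(ang, -180.0)] = 180.0
    return ang


def embed_circular(angles_deg: np.ndarray, frame_interval: float = 0.1) -> FeatureMatrix:
    """Embed a degree-valued angle series on the unit circle as (sin, cos)."""
    angles_deg = np.asarray(angles_deg, dtype=float)
    if not np.all(np.isfinite(angles_deg)):
        raise ValueError("angles must be finite")
    rad = np.radians(angles_deg)
    values = np.column_stack([np.sin(rad), np.cos(rad)])
    return FeatureMatrix(
        values, ["sin(angle)", "cos(angle)"], frame_interval=frame_interval
    )


def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``Y`` onto ``X``.

    Returns ``(R, t, rmsd)`` with the proper rotation matrix ``R``
    (determinant +1, reflections excluded) and translation ``t`` such that
    ``Y @ R.T + t`` best matches ``X``; ``rmsd`` is the weighted
    root-mean-square deviation after superposition, in Angstrom.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must both have shape (n_atoms, 3)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    xc = (w[:, None] * X).sum(axis=0)
    yc = (w[:, None] * Y).sum(axis=0)
    X0, Y0 = X - xc, Y - yc
    if np.linalg.matrix_rank(Y0, tol=1e-10) < 2:
        raise ValueError("degenerate (rank-deficient) atom configuration")
    rot, _rssd = Rotation.align_vectors(X0, Y0, weights=w, return_sensitivity=False)
    R = rot.as_matrix()
    t = xc - yc @ R.T
    delta = Y @ R.T + t - X
    rmsd = float(np.sqrt((w * (delta**2).sum(axis=1)).sum()))
    return R, t, rmsd


def superpose_trajectory(
    traj: Trajectory, reference: np.ndarray, selection: np.ndarray | None = None
) -> np.ndarray:
    """Superpose every frame onto ``reference`` (fit on ``selection`` atoms)."""
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(reference[sel], traj.coordinates[f, sel])
        out[f] = traj.coordinates[f] @ R.T + t
    return out


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Angstrom).

    Frames are first superposed onto the mean structure, iterating the
    mean/superpose cycle until the mean structure shifts by less than
    ``tol`` Angstrom (at most ``max_iter`` rounds); the fluctuation is then
    ``sqrt(<|r_a - <r_a>|^2>)`` for each selected atom.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, int)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    coords = traj.coordinates.copy()
    mean = coords.mean(axis=0)
    for _ in range(max_iter):
        work = Trajectory(coords, traj.atom_meta, traj.frame_interval)
        coords = superpose_trajectory(work, mean)
        new_mean = coords.mean(axis=0)
        shift = np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean())
        mean = new_mean
        if shift < tol:
            break
    dev = coords[:, sel, :] - mean[sel]
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


def featurize(traj: Trajectory, spec: FeatureSpec) -> FeatureMatrix:
    """Apply a :class:`FeatureSpec` to a trajectory.

    Distances come out in Angstrom; each dihedral contributes its sin/cos
    embedding (two dimensionless columns) so downstream linear methods never
    see the branch cut at +-180 deg.
    """
    columns: list[np.ndarray] = []
    descriptors: list[str] = []
    for pair in spec.distance_pairs:
        columns.append(pairwise_distance(traj, pair))
        label = pair.name or f"dist[{pair.selection_a}-{pair.selection_b}]"
        descriptors.append(label)
    for quad, name in spec.dihedral_quads:
        ang = dihedral(traj, quad)
        if np.any(np.isnan(ang)):
            raise ValueError(f"dihedral {name or quad} undefined in some frames")
        rad = np.radians(ang)
        columns.extend([np.sin(rad), np.cos(rad)])
        tag = name or str(quad)
        descriptors.extend([f"sin({tag})", f"cos({tag})"])
    if not columns:
        raise ValueError("feature spec selects nothing")
    return FeatureMatrix(
        np.column_stack(columns), descriptors, frame_interval=traj.frame_interval
    )
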