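"""Presentation-layer quantities: free-energy surfaces, interaction
histograms, and voxel occupancy maps.

The free-energy surface reweights every frame by the MSM stationary
probability of its microstate, so the landscape reflects the estimated
equilibrium even when the raw trajectories are kinetically biased toward
their starting basins.  Interaction histograms summarize a distance time
series as a normalized distribution plus the contact fraction below a
cutoff.  Occupancy grids voxelize where selected atoms spend their time
(frames must be pre-superposed onto a common reference by the caller).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

from .msm import MarkovModel
from .traj import Trajectory

__all__ = [
    "FreeEnergySurface",
    "InteractionHistogram",
    "OccupancyGrid",
    "fes_from_msm",
    "interaction_histogram",
    "occupancy_grid",
]


@dataclass
class FreeEnergySurface:
    """2-D free energy in kT units, minimum normalized to zero.

    ``F`` is NaN on empty bins (undefined, never zero).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        occ = np.isfinite(self.F)
        if not occ.any():
            raise ValueError("free-energy surface has no occupied bins")
        if not np.isclose(np.nanmin(self.F), 0.0, atol=1e-12):
            raise ValueError("minimum over occupied bins must be 0")
        if np.nanmin(self.F) < -1e-12:
            raise ValueError("free energies must be non-negative")

    def write_csv(self, path: str | Path) -> None:
        """Bin centers and free energies as CSV; empty bins exported as ''."""
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        with open(path, "w") as fh:
            fh.write("tic1,tic2,free_energy_kT\n")
            for i, x in enumerate(xc):
                for j, y in enumerate(yc):
                    f = self.F[i, j]
                    fh.write(f"{x:.6g},{y:.6g},{'' if np.isnan(f) else f'{f:.6g}'}\n")


@dataclass
class InteractionHistogram:
    """Normalized distance histogram with a contact fraction below cutoff."""

    bin_edges: np.ndarray
    probability: np.ndarray
    contact_fraction: float
    cutoff: float

    def __post_init__(self) -> None:
        if not np.isclose(self.probability.sum(), 1.0, atol=1e-12):
            raise ValueError("probabilities must sum to 1 within 1e-12")
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ValueError("contact fraction must lie in [0, 1]")

    def write_csv(self, path: str | Path) -> None:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        with open(path, "w") as fh:
            fh.write(f"# cutoff_A={self.cutoff}, contact_fraction={self.contact_fraction:.6g}\n")
            fh.write("distance_A,probability\n")
            for c, p in zip(centers, self.probability):
                fh.write(f"{c:.6g},{p:.6g}\n")


@dataclass
class OccupancyGrid:
    """Voxelized visitation counts of selected atoms."""

    origin: np.ndarray
    spacing: float
    counts: np.ndarray
    n_frames: int
    n_selected: int

    @property
    def occupancy(self) -> np.ndarray:
        """Per-voxel occupancy fraction: counts / frames (in [0, n_selected])."""
        return self.counts / self.n_frames

    def write_dx(self, path: str | Path) -> None:
        """OpenDX-style regular-grid export for visualization tools."""
        nx, ny, nz = self.counts.shape
        occ = self.occupancy
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write(
                "origin {:.6f} {:.6f} {:.6f}\n".format(*self.origin)
            )
            fh.write(f"delta {self.spacing:.6f} 0 0\n")
            fh.write(f"delta 0 {self.spacing:.6f} 0\n")
            fh.write(f"delta 0 0 {self.spacing:.6f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(
                f"object 3 class array type double rank 0 items {occ.size} data follows\n"
            )
            flat = occ.ravel()
            for i in range(0, flat.size, 3):
                fh.write(" ".join(f"{v:.6g}" for v in flat[i : i + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n')

    def write_csv(self, path: str | Path) -> None:
        nz = np.argwhere(self.counts > 0)
        occ = self.occupancy
        with open(path, "w") as fh:
            fh.write("x_A,y_A,z_A,count,occupancy\n")
            for i, j, k in nz:
                c = self.origin + (np.array([i, j, k]) + 0.5) * self.spacing
                fh.write(
                    f"{c[0]:.4f},{c[1]:.4f},{c[2]:.4f},"
                    f"{int(self.counts[i, j, k])},{occ[i, j, k]:.6g}\n"
                )


def fes_from_msm(
    tic_coords,
    dtrajs,
    model: MarkovModel,
    bins: int | tuple[np.ndarray, np.ndarray] = 100,
    pad: float = 0.05,
) -> FreeEnergySurface:
    """MSM-weighted free-energy surface over the first two TIC coordinates.

    Each frame in microstate ``s`` carries weight ``pi_s / n_frames(s)``;
    the weighted 2-D histogram ``p`` becomes ``F = -ln(p / p_max)`` (kT
    units, occupied minimum exactly zero).  Frames in microstates outside
    the model's active set are ignored.
    """
    if isinstance(tic_coords, np.ndarray) and tic_coords.ndim == 2:
        tic_coords = [tic_coords]
    from .msm import _dtraj_list

    dlist = _dtraj_list(dtrajs)
    X = np.vstack([np.asarray(t)[:, :2] for t in tic_coords])
    S = np.concatenate(dlist)
    if X.shape[0] != S.shape[0]:
        raise ValueError("coordinates and assignments are not frame-aligned")
    # per-microstate frame counts on the active set
    pos = -np.ones(int(S.max()) + 1, dtype=int)
    pos[model.active_set] = np.arange(model.n_states)
    internal = pos[S]
    ok = internal >= 0
    counts = np.bincount(internal[ok], minlength=model.n_states)
    if np.any(counts == 0):
        raise ValueError(
            "active-set microstate without assigned frames: inputs inconsistent"
        )
    weights = np.zeros(S.shape[0])
    weights[ok] = model.pi[internal[ok]] / counts[internal[ok]]
    if isinstance(bins, int):
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        span = hi - lo
        lo, hi = lo - pad * span, hi + pad * span
        x_edges = np.linspace(lo[0], hi[0], bins + 1)
        y_edges = np.linspace(lo[1], hi[1], bins + 1)
    else:
        x_edges, y_edges = bins
    H, _, _ = np.histogram2d(X[:, 0], X[:, 1], bins=(x_edges, y_edges), weights=weights)
    F = np.full(H.shape, np.nan)
    occ = H > 0
    F[occ] = -np.log(H[occ] / H[occ].max())
    return FreeEnergySurface(x_edges, y_edges, F)


def interaction_histogram(
    distances: np.ndarray,
    bins: int | np.ndarray = 50,
    cutoff: float = 4.5,
) -> InteractionHistogram:
    """Distance-distribution summary of one interaction.

    The default 4.5 Angstrom cutoff suits hydrophobic contacts; use 4.0
    for salt bridges (N-O distances).  The contact fraction counts mass
    strictly below the cutoff.
    """
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty distance series")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    counts, edges = np.histogram(d, bins=bins)
    prob = counts / counts.sum()
    contact = float((d < cutoff).mean())
    return InteractionHistogram(
        bin_edges=edges, probability=prob, contact_fraction=contact, cutoff=cutoff
    )


def gaussian_contact_fraction(mean: float, sigma: float, cutoff: float) -> float:
    """Closed-form contact fraction for Gaussian-distributed distances."""
    return 0.5 * (1.0 + erf((cutoff - mean) / (sigma * np.sqrt(2.0))))


def occupancy_grid(
    traj: Trajectory,
    selection: np.ndarray,
    spacing: float = 1.0,
    frame_mask: np.ndarray | None = None,
) -> OccupancyGrid:
    """Voxel visitation counts for selected atoms.

    Assumes frames are already superposed onto a common reference.  Each
    selected atom increments exactly one voxel per frame (floor binning on
    half-open voxels).  ``frame_mask`` restricts the tally to a subset of
    frames (e.g., one metastable state).
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    coords = traj.coordinates[:, sel, :]
    if frame_mask is not None:
        coords = coords[np.asarray(frame_mask)]
    n_frames = coords.shape[0]
    pts = coords.reshape(-1, 3)
    origin = np.floor(pts.min(axis=0) / spacing) * spacing
    idx = np.floor((pts - origin) / spacing).astype(int)
    shape = idx.max(axis=0) + 1
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    assert counts.sum() == n_frames * sel.size
    return OccupancyGrid(
        origin=origin,
        spacing=spacing,
        counts=counts,
        n_frames=n_frames,
        n_selected=sel.size,
    )
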