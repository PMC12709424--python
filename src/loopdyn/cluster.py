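"""Microstate definition in TIC space via k-means.

The continuous collective-variable space is divided into a large number of
small clusters ("microstates") whose centers tile the sampled density;
kinetics between them is then described by a Markov state model.  Fitting
is delegated to scikit-learn's k-means (k-means++ initialization, single
seeded run); assignment of arbitrary data to fitted centers is the plain
nearest-center rule with ties broken toward the lowest index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = ["Microstates", "DiscreteTrajectorySet", "kmeans_fit", "assign"]


@dataclass
class Microstates:
    """Fitted microstate centers in TIC space."""

    centers: np.ndarray
    k: int
    inertia: float
    seed: int

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("centers must be finite")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "centers": self.centers.tolist(),
                    "k": self.k,
                    "inertia": self.inertia,
                    "seed": self.seed,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Microstates":
        doc = json.loads(Path(path).read_text())
        return cls(np.array(doc["centers"]), doc["k"], doc["inertia"], doc["seed"])


@dataclass
class DiscreteTrajectorySet:
    """Per-trajectory integer microstate sequences."""

    dtrajs: list[np.ndarray]
    k: int
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        self.dtrajs = [np.asarray(d, dtype=np.int64) for d in self.dtrajs]
        for d in self.dtrajs:
            if d.size and (d.min() < 0 or d.max() >= self.k):
                raise ValueError("discrete states must lie in [0, k)")

    def __len__(self) -> int:
        return len(self.dtrajs)

    def write_text(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, d in enumerate(self.dtrajs):
            np.savetxt(directory / f"dtraj_{i:03d}.txt", d, fmt="%d")


def kmeans_fit(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> Microstates:
    """Fit ``k`` microstate centers with seeded k-means++ / Lloyd iteration."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if k > points.shape[0]:
        raise ValueError(f"k={k} exceeds the number of points ({points.shape[0]})")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(points)
    return Microstates(
        centers=km.cluster_centers_, k=k, inertia=float(km.inertia_), seed=seed
    )


def assign(
    micro: Microstates,
    trajs: Sequence[np.ndarray] | np.ndarray,
    frame_interval: float = 0.1,
) -> DiscreteTrajectorySet:
    """Map every frame to its nearest microstate center (Euclidean).

    Ties are broken toward the lowest center index (``argmin`` semantics).
    """
    if isinstance(trajs, np.ndarray) and trajs.ndim == 2:
        trajs = [trajs]
    dtrajs = []
    for t in trajs:
        t = np.atleast_2d(np.asarray(t, dtype=float))
        if t.shape[1] != micro.centers.shape[1]:
            raise ValueError(
                f"dimension mismatch: data has {t.shape[1]} columns, "
                f"centers have {micro.centers.shape[1]}"
            )
        d = cdist(t, micro.centers)
        dtrajs.append(np.argmin(d, axis=1).astype(np.int64))
    return DiscreteTrajectorySet(dtrajs, k=micro.k, frame_interval=frame_interval)
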