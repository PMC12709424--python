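"""Two-dimensional toy potentials with analytic gradients.

These are desk-scale stand-ins for molecular potential-energy surfaces:
harmonic wells, a quartic double well, and free-form multi-well landscapes
built from inverted Gaussian basins.  Each potential exposes ``energy`` and
``gradient`` (vectorized over leading axes) plus optional named energy
``terms`` so that accelerated-sampling boosts can act on one term ("dual
boost") rather than only on the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["Harmonic", "DoubleWell", "GaussianWells", "LandscapeSpec"]


class Potential:
    """Base class; subclasses define energy/gradient on 2-vectors."""

    dim = 2

    def energy(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def terms(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Named energy decomposition; default: a single 'total' term."""
        return {"total": self.energy(x)}


@dataclass
class Harmonic(Potential):
    """Isotropic harmonic well ``U = kappa/2 |x - center|^2``."""

    kappa: float = 1.0
    center: tuple[float, float] = (0.0, 0.0)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        d = x - np.asarray(self.center)
        return 0.5 * self.kappa * (d**2).sum(axis=-1)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        return self.kappa * (x - np.asarray(self.center))


@dataclass
class DoubleWell(Potential):
    """Quartic double well along x with harmonic confinement along y.

    ``U = barrier * (x^2 - 1)^2 + kappa_y/2 * y^2``; minima at x = +-1,
    saddle at x = 0 with height ``barrier`` (energy units).
    """

    barrier: float = 4.0
    kappa_y: float = 1.0

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self.barrier * (x[..., 0] ** 2 - 1.0) ** 2 + 0.5 * self.kappa_y * x[
            ..., 1
        ] ** 2

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.empty_like(x)
        g[..., 0] = 4.0 * self.barrier * x[..., 0] * (x[..., 0] ** 2 - 1.0)
        g[..., 1] = self.kappa_y * x[..., 1]
        return g

    def terms(self, x):
        x = np.asarray(x, dtype=float)
        return {
            "dihedral": self.barrier * (x[..., 0] ** 2 - 1.0) ** 2,
            "total": self.energy(x),
        }

    def term_gradients(self, x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        g[..., 0] = 4.0 * self.barrier * x[..., 0] * (x[..., 0] ** 2 - 1.0)
        return {"dihedral": g}


@dataclass
class LandscapeSpec:
    """Multi-well landscape specification for Langevin sampling.

    ``wells`` is a list of ``(center, depth, width)`` with center a
    2-vector, depth > 0 (energy units) and width > 0 (length units); the
    landscape is a sum of inverted Gaussian basins plus a weak harmonic
    confinement so the Boltzmann measure is normalizable.
    """

    wells: Sequence[tuple[Sequence[float], float, float]]
    kT: float = 1.0
    friction: float = 1.0
    dt: float = 0.01
    seed: int = 0
    confinement: float = 0.05

    def __post_init__(self) -> None:
        if len(self.wells) < 1:
            raise ValueError("at least one well required")
        if self.kT < 0:
            raise ValueError("kT must be non-negative")
        if self.dt <= 0 or self.friction <= 0:
            raise ValueError("dt and friction must be positive")

    def potential(self) -> "GaussianWells":
        return GaussianWells(
            centers=np.array([w[0] for w in self.wells], dtype=float),
            depths=np.array([w[1] for w in self.wells], dtype=float),
            widths=np.array([w[2] for w in self.wells], dtype=float),
            confinement=self.confinement,
        )


@dataclass
class GaussianWells(Potential):
    """Sum of inverted Gaussian basins plus harmonic confinement."""

    centers: np.ndarray
    depths: np.ndarray
    widths: np.ndarray
    confinement: float = 0.05

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        d2 = ((x[..., None, :] - self.centers) ** 2).sum(axis=-1)  # (..., n_wells)
        basins = -(self.depths * np.exp(-d2 / (2.0 * self.widths**2))).sum(axis=-1)
        return basins + 0.5 * self.confinement * (x**2).sum(axis=-1)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        diff = x[..., None, :] - self.centers  # (..., n_wells, 2)
        d2 = (diff**2).sum(axis=-1)
        gauss = self.depths * np.exp(-d2 / (2.0 * self.widths**2))
        g = (gauss[..., None] * diff / self.widths[:, None] ** 2).sum(axis=-2)
        return g + self.confinement * x


def boltzmann_quadrature(
    potential: Potential,
    kT: float,
    extent: float = 6.0,
    n_grid: int = 401,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid evaluation of the Boltzmann density exp(-U/kT)/Z on a square.

    Returns ``(xs, ys, density)`` with density normalized by the trapezoid
    rule; serves as the independent oracle for sampled stationary statistics.
    """
    xs = np.linspace(-extent, extent, n_grid)
    ys = np.linspace(-extent, extent, n_grid)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X, Y], axis=-1)
    U = potential.energy(pts)
    w = np.exp(-(U - U.min()) / kT)
    Z = np.trapezoid(np.trapezoid(w, ys, axis=1), xs)
    return xs, ys, w / Z
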