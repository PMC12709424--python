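"""Gaussian-accelerated dynamics at desk scale.

GaMD flattens a potential-energy surface by adding a harmonic boost
``DeltaV = k/2 (E - V)^2`` whenever the instantaneous potential ``V`` lies
below a threshold ``E``; with the threshold at the running maximum
(``E = Vmax``) and the force constant ``k = k0 / (Vmax - Vmin)``,
``k0 = min(1, (sigma0/sigmaV) (Vmax - Vmin)/(Vmax - Vavg))``, the boost
standard deviation stays near or below the cap ``sigma0``, keeping the
second-order cumulant reweighting accurate.  This module realizes that
logic on 2-D toy landscapes propagated by overdamped Langevin dynamics:
an unbiased statistics-collection stage, an equilibration stage with
periodically re-derived parameters, and a production stage with frozen
parameters, followed by cumulant reweighting of the sampled histogram back
to the unbiased free-energy profile.

Energies are in kcal/mol by convention (any consistent unit works as long
as ``kT`` and ``sigma0`` share it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .potentials import LandscapeSpec, Potential

__all__ = [
    "PotentialStatistics",
    "BoostParameters",
    "BoostedRun",
    "derive_boost_params",
    "boost_energy",
    "run_staged_gamd",
    "reweight_pmf",
    "count_well_transitions",
]


@dataclass
class PotentialStatistics:
    """Running min/max/mean/std of a potential-energy term."""

    Vmax: float
    Vmin: float
    Vavg: float
    sigmaV: float
    term: str = "total"

    def __post_init__(self) -> None:
        if not (self.Vmin <= self.Vavg <= self.Vmax):
            raise ValueError("require Vmin <= Vavg <= Vmax")
        if self.sigmaV < 0:
            raise ValueError("sigmaV must be non-negative")


class _Welford:
    """Streaming mean/variance plus expanding extrema."""

    def __init__(self) -> None:
        self.n = 0
        self.mean = 0.0
        self.m2 = 0.0
        self.vmin = np.inf
        self.vmax = -np.inf

    def update(self, v: float) -> None:
        self.n += 1
        d = v - self.mean
        self.mean += d / self.n
        self.m2 += d * (v - self.mean)
        self.vmin = min(self.vmin, v)
        self.vmax = max(self.vmax, v)

    def stats(self, term: str = "total") -> PotentialStatistics:
        std = np.sqrt(self.m2 / self.n) if self.n > 1 else 0.0
        return PotentialStatistics(
            Vmax=self.vmax, Vmin=self.vmin, Vavg=self.mean, sigmaV=std, term=term
        )


@dataclass
class BoostParameters:
    """Derived boost: threshold E, fraction k0, force constant k, cap sigma0."""

    E: float
    k0: float
    k: float
    sigma0: float
    term: str = "total"

    def __post_init__(self) -> None:
        if not 0.0 <= self.k0 <= 1.0:
            raise ValueError("k0 must lie in [0, 1]")


def derive_boost_params(
    stats: PotentialStatistics, sigma0: float
) -> BoostParameters:
    """Boost parameters in the lower-bound mode with threshold ``E = Vmax``.

    ``k0 = min(1, (sigma0 / sigmaV) * (Vmax - Vmin) / (Vmax - Vavg))`` and
    ``k = k0 / (Vmax - Vmin)``.  A flat potential (``Vmax == Vmin``) has no
    meaningful boost and is rejected.
    """
    span = stats.Vmax - stats.Vmin
    if span <= 0:
        raise ValueError("flat potential: Vmax must exceed Vmin")
    if stats.Vmax <= stats.Vavg:
        raise ValueError("require Vmax > Vavg")
    if sigma0 <= 0:
        k0 = 0.0
    elif stats.sigmaV == 0:
        k0 = 1.0
    else:
        k0 = min(1.0, (sigma0 / stats.sigmaV) * span / (stats.Vmax - stats.Vavg))
    return BoostParameters(
        E=stats.Vmax, k0=k0, k=k0 / span, sigma0=sigma0, term=stats.term
    )


def boost_energy(V, params: BoostParameters):
    """Harmonic boost ``DeltaV = k/2 (E - V)^2`` below threshold, else 0.

    Continuous with continuous first derivative at ``V = E``.  For dual
    boost, apply per term and sum the results.
    """
    V = np.asarray(V, dtype=float)
    dv = np.where(V < params.E, 0.5 * params.k * (params.E - V) ** 2, 0.0)
    return dv if dv.ndim else float(dv)


@dataclass
class BoostedRun:
    """Production-stage output of a staged GaMD run."""

    positions: np.ndarray
    deltaV: np.ndarray
    potential_energy: np.ndarray
    params: dict[str, BoostParameters]
    stage_log: list = field(default_factory=list)
    dt: float = 0.01
    kT: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.deltaV < -1e-12):
            raise ValueError("boost energies must be non-negative")

    def save_npz(self, path: str | Path) -> None:
        import json

        np.savez_compressed(
            path,
            positions=self.positions,
            deltaV=self.deltaV,
            potential_energy=self.potential_energy,
            manifest=json.dumps(
                {
                    "stages": self.stage_log,
                    "params": {
                        t: vars(p) for t, p in self.params.items()
                    },
                    "dt": self.dt,
                    "kT": self.kT,
                }
            ),
        )


def _boost_force_factor(V: float, params: BoostParameters) -> float:
    # d(V + DeltaV)/dx = (1 - k (E - V)) dV/dx for V < E
    return 1.0 - params.k * (params.E - V) if V < params.E else 1.0


def run_staged_gamd(
    spec: LandscapeSpec,
    stage_lengths: tuple[int, int, int],
    sigma0: float,
    potential: Potential | None = None,
    dual: bool = False,
    update_interval: int = 1000,
    x0: np.ndarray | None = None,
    bound: float = 1e3,
) -> BoostedRun:
    """Three-stage GaMD protocol on a toy landscape.

    Stage 1 runs unbiased dynamics while collecting potential statistics;
    stage 2 propagates with the boost, re-deriving parameters from the
    (still-updating) statistics every ``update_interval`` steps; stage 3
    runs production with frozen parameters, recording positions and boost
    energies.  ``dual=True`` boosts the potential's "dihedral" term and the
    total independently (the potential must expose named terms and term
    gradients).
    """
    n1, n2, n3 = stage_lengths
    if min(n1, n2, n3) <= 0:
        raise ValueError("all stage lengths must be positive")
    pot = spec.potential() if potential is None else potential
    if dual and not hasattr(pot, "term_gradients"):
        raise ValueError("dual boost requires a potential with term gradients")
    rng = np.random.default_rng(spec.seed)
    total = n1 + n2 + n3
    noise_amp = np.sqrt(2.0 * spec.kT * spec.dt / spec.friction)
    xi = rng.standard_normal((total, 2)) if spec.kT > 0 else np.zeros((total, 2))
    x = np.array(spec.wells[0][0], dtype=float) if x0 is None else np.array(x0, float)
    inv_gamma_dt = spec.dt / spec.friction

    terms = ["dihedral", "total"] if dual else ["total"]
    acc = {t: _Welford() for t in terms}
    params: dict[str, BoostParameters] = {}
    stage_log: list[dict] = []

    def energies(xx) -> dict[str, float]:
        if dual:
            tv = pot.terms(xx)
            return {t: float(tv[t]) for t in terms}
        return {"total": float(pot.energy(xx))}

    def total_boost(ev: dict[str, float]) -> float:
        return sum(boost_energy(ev[t], params[t]) for t in terms if t in params)

    def step(xx, noise, boosted: bool):
        if not boosted or not params:
            g = pot.gradient(xx)
        elif dual:
            tg = pot.term_gradients(xx)
            ev = energies(xx)
            # total-term boost scales the full gradient; dihedral-term
            # boost adds its own scaled term gradient
            g = pot.gradient(xx) * _boost_force_factor(ev["total"], params["total"])
            fac_d = _boost_force_factor(ev["dihedral"], params["dihedral"]) - 1.0
            g = g + tg["dihedral"] * fac_d
        else:
            ev = energies(xx)
            g = pot.gradient(xx) * _boost_force_factor(ev["total"], params["total"])
        xn = xx - g * inv_gamma_dt + noise_amp * noise
        if np.abs(xn).max() > bound:
            raise RuntimeError("GaMD trajectory diverged; reduce dt")
        return xn

    t = 0
    # stage 1: conventional, statistics only
    for _ in range(n1):
        for term, v in energies(x).items():
            acc[term].update(v)
        x = step(x, xi[t], boosted=False)
        t += 1
    params = {term: derive_boost_params(acc[term].stats(term), sigma0) for term in terms}
    stage_log.append({"stage": "conventional", "steps": n1})
    # stage 2: equilibration with periodic parameter updates
    for i in range(n2):
        for term, v in energies(x).items():
            acc[term].update(v)
        if (i + 1) % update_interval == 0:
            params = {
                term: derive_boost_params(acc[term].stats(term), sigma0)
                for term in terms
            }
        x = step(x, xi[t], boosted=True)
        t += 1
    params = {term: derive_boost_params(acc[term].stats(term), sigma0) for term in terms}
    stage_log.append({"stage": "equilibration-updating", "steps": n2})
    # stage 3: production with frozen parameters
    positions = np.empty((n3, 2))
    dV = np.empty(n3)
    Vtot = np.empty(n3)
    for i in range(n3):
        ev = energies(x)
        positions[i] = x
        dV[i] = total_boost(ev)
        Vtot[i] = ev["total"] if not dual else float(pot.energy(x))
        x = step(x, xi[t], boosted=True)
        t += 1
    stage_log.append(
        {
            "stage": "production-fixed",
            "steps": n3,
            "params": {term: vars(p) for term, p in params.items()},
        }
    )
    return BoostedRun(
        positions=positions,
        deltaV=dV,
        potential_energy=Vtot,
        params=params,
        stage_log=stage_log,
        dt=spec.dt,
        kT=spec.kT,
    )


@dataclass
class ReweightedProfile:
    """1-D free-energy profile from cumulant reweighting (energy units)."""

    bin_edges: np.ndarray
    F: np.ndarray
    counts: np.ndarray


def reweight_pmf(
    run: BoostedRun,
    kT: float,
    bins: int | np.ndarray = 40,
    order: int = 2,
    coord: int = 0,
    min_samples: int = 20,
) -> ReweightedProfile:
    """Cumulant-expansion reweighting of a boosted run to an unbiased PMF.

    Per bin ``b``: ``ln p_b = ln p*_b + beta <DeltaV>_b +
    (beta^2 / 2) var(DeltaV)_b`` (to the requested order), then
    ``F = -kT ln p`` normalized to minimum zero.  Bins with fewer than
    ``min_samples`` frames are reported NaN.
    """
    if order not in (1, 2):
        raise ValueError("cumulant order must be 1 or 2")
    x = run.positions[:, coord]
    beta = 1.0 / kT
    counts, edges = np.histogram(x, bins=bins)
    which = np.digitize(x, edges[1:-1])
    lnp = np.full(counts.shape, np.nan)
    for b in range(counts.size):
        if counts[b] < max(min_samples, 1):
            continue
        dv = run.deltaV[which == b]
        corr = beta * dv.mean()
        if order >= 2:
            corr += 0.5 * beta**2 * dv.var()
        lnp[b] = np.log(counts[b] / counts.sum()) + corr
    F = -kT * lnp
    F -= np.nanmin(F)
    return ReweightedProfile(bin_edges=edges, F=F, counts=counts)


def count_well_transitions(x: np.ndarray, lo: float = -0.5, hi: float = 0.5) -> int:
    """Hysteresis-based count of crossings between two wells along x.

    A transition is registered each time the coordinate moves from below
    ``lo`` to above ``hi`` or vice versa, ignoring recrossings inside the
    barrier region.
    """
    state = 0  # -1 left, +1 right, 0 undetermined
    n = 0
    for v in np.asarray(x, dtype=float):
        if v <= lo:
            if state == 1:
                n += 1
            state = -1
        elif v >= hi:
            if state == -1:
                n += 1
            state = 1
    return n
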