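"""Markov state model estimation and validation.

The MSM pipeline step turns discretized trajectories into a kinetic model:
(1) count transitions between microstates at a chosen lag time, (2) trim
to the largest strongly connected set (reversible estimation needs
ergodicity), (3) estimate the maximum-likelihood transition matrix under a
detailed-balance constraint via the standard self-consistent fixed-point
iteration on symmetric auxiliary counts.  Validation utilities cover the
two canonical diagnostics: implied-timescale convergence in the lag time
and the Chapman-Kolmogorov test on metastable sets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cluster import DiscreteTrajectorySet

__all__ = [
    "CountMatrix",
    "MarkovModel",
    "count_transitions",
    "largest_connected_set",
    "estimate_reversible_mle",
    "stationary_distribution",
    "implied_timescales",
    "its_scan",
    "ck_test",
]


@dataclass
class CountMatrix:
    """Microstate transition counts at one lag time."""

    C: np.ndarray
    lag: int
    mode: str = "sliding"
    active_set: np.ndarray | None = None  # original microstate labels

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if np.any(self.C < 0):
            raise ValueError("counts must be non-negative")
        if self.active_set is None:
            self.active_set = np.arange(self.C.shape[0])
        self.active_set = np.asarray(self.active_set, dtype=int)


@dataclass
class MarkovModel:
    """Reversible transition matrix with stationary distribution and spectrum.

    ``T`` lives on ``active_set`` (original microstate labels kept for
    traceability).  Eigen-decomposition uses the symmetrization
    ``S = diag(pi)^1/2 T diag(pi)^-1/2``, so eigenvalues are real and
    sorted descending with ``lambda_1 = 1``.
    """

    T: np.ndarray
    pi: np.ndarray
    lag: int
    frame_interval: float
    active_set: np.ndarray = None
    eigenvalues: np.ndarray = field(init=False)
    right_eigenvectors: np.ndarray = field(init=False)
    left_eigenvectors: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        n = self.T.shape[0]
        if self.active_set is None:
            self.active_set = np.arange(n)
        self.active_set = np.asarray(self.active_set, dtype=int)
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("T rows must sum to 1 within 1e-10")
        if not np.allclose(self.pi @ self.T, self.pi, atol=1e-10):
            raise ValueError("pi T = pi violated beyond 1e-10")
        flux = self.pi[:, None] * self.T
        if not np.allclose(flux, flux.T, atol=1e-8):
            raise ValueError("detailed balance violated beyond 1e-8")
        sqrt_pi = np.sqrt(self.pi)
        S = sqrt_pi[:, None] * self.T / sqrt_pi[None, :]
        evals, evecs = np.linalg.eigh(0.5 * (S + S.T))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        evals[0] = 1.0
        self.eigenvalues = evals
        self.right_eigenvectors = evecs / sqrt_pi[:, None]
        self.left_eigenvectors = evecs * sqrt_pi[:, None]
        # normalize the stationary pair exactly
        self.right_eigenvectors[:, 0] = 1.0
        self.left_eigenvectors[:, 0] = self.pi

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def lag_time(self) -> float:
        """Lag time in ns."""
        return self.lag * self.frame_interval

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "T": self.T.tolist(),
                    "pi": self.pi.tolist(),
                    "lag": self.lag,
                    "frame_interval": self.frame_interval,
                    "active_set": self.active_set.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkovModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            T=np.array(doc["T"]),
            pi=np.array(doc["pi"]),
            lag=int(doc["lag"]),
            frame_interval=float(doc["frame_interval"]),
            active_set=np.array(doc["active_set"], dtype=int),
        )


def _dtraj_list(dtrajs) -> list[np.ndarray]:
    if isinstance(dtrajs, DiscreteTrajectorySet):
        return dtrajs.dtrajs
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        return [dtrajs]
    return [np.asarray(d, dtype=np.int64) for d in dtrajs]


def count_transitions(
    dtrajs, lag: int, mode: str = "sliding", n_states: int | None = None
) -> CountMatrix:
    """Count microstate transitions at ``lag`` frames.

    ``sliding`` counts every pair ``(t, t+lag)``; ``strided`` counts only
    non-overlapping pairs (t = 0, lag, 2 lag, ...).  Trajectories are
    counted independently: no pair crosses a boundary.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError(f"unknown counting mode {mode!r}")
    dlist = _dtraj_list(dtrajs)
    if n_states is None:
        if isinstance(dtrajs, DiscreteTrajectorySet):
            n_states = dtrajs.k
        else:
            n_states = int(max(d.max() for d in dlist if d.size)) + 1
    if all(len(d) <= lag for d in dlist):
        raise ValueError(f"lag {lag} is not shorter than any trajectory")
    C = np.zeros((n_states, n_states))
    for d in dlist:
        if len(d) <= lag:
            continue
        if mode == "sliding":
            a, b = d[:-lag], d[lag:]
        else:
            sub = d[::lag]
            a, b = sub[:-1], sub[1:]
        np.add.at(C, (a, b), 1.0)
    return CountMatrix(C, lag=lag, mode=mode)


def largest_connected_set(cm: CountMatrix) -> CountMatrix:
    """Restrict counts to the largest strongly connected component."""
    graph = csr_matrix(cm.C > 0)
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    sizes = np.bincount(labels, minlength=n_comp)
    # tie-break toward the component containing the lowest state index
    best = int(np.argmax(sizes))
    keep = np.where(labels == best)[0]
    if keep.size == 1:
        warnings.warn("largest connected set is a single state", stacklevel=2)
    return CountMatrix(
        cm.C[np.ix_(keep, keep)],
        lag=cm.lag,
        mode=cm.mode,
        active_set=cm.active_set[keep],
    )


def estimate_reversible_mle(
    cm: CountMatrix,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    frame_interval: float = 0.1,
) -> MarkovModel:
    """Maximum-likelihood reversible transition matrix from counts.

    Maximizes ``prod T_ij^C_ij`` subject to detailed balance using the
    self-consistent fixed-point iteration on symmetric auxiliary counts
    ``x_ij``: at each sweep ``x_ij <- (C_ij + C_ji) / (c_i/x_i + c_j/x_j)``
    with ``c_i`` and ``x_i`` the row sums.  The stationary distribution is
    the normalized auxiliary row sum.  Convergence is declared when the
    largest entry change of ``T`` drops below ``tol`` — an entrywise
    criterion, because the log-likelihood is quadratically flat near the
    optimum and stalls long before the matrix itself has converged.
    """
    C = cm.C
    n = C.shape[0]
    c = C.sum(axis=1)
    if np.any(c == 0):
        raise ValueError("count matrix has empty rows; trim connectivity first")
    Csym = C + C.T
    x = Csym.copy()

    def loglik(T: np.ndarray) -> float:
        mask = C > 0
        return float((C[mask] * np.log(T[mask])).sum())

    xi = x.sum(axis=1)
    T = x / xi[:, None]
    for it in range(max_iter):
        denom = c[:, None] / xi[:, None] + c[None, :] / xi[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_new = np.where(Csym > 0, Csym / denom, 0.0)
        x = x_new
        xi = x.sum(axis=1)
        T_new = x / xi[:, None]
        delta = np.max(np.abs(T_new - T))
        T = T_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"reversible MLE did not converge in {max_iter} iterations "
            f"(last entry change {delta:.3g}, log-likelihood {loglik(T):.6g})"
        )
    pi = xi / xi.sum()
    # polish to machine-precision stochasticity / stationarity
    T = T / T.sum(axis=1)[:, None]
    flux = 0.5 * (pi[:, None] * T + (pi[:, None] * T).T)
    pi = flux.sum(axis=1)
    T = flux / pi[:, None]
    return MarkovModel(
        T=T,
        pi=pi,
        lag=cm.lag,
        frame_interval=frame_interval,
        active_set=cm.active_set,
    )


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Unique stationary distribution of an irreducible stochastic matrix.

    Solved as the linear system ``pi (T - I) = 0`` with the normalization
    ``sum pi = 1`` appended, which gives machine-precision residuals.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    n_comp, _ = connected_components(
        csr_matrix(T > 0), directed=True, connection="strong"
    )
    if n_comp != 1:
        raise ValueError(
            "transition matrix is reducible; restrict to the largest "
            "connected set before computing the stationary distribution"
        )
    A = np.vstack([T.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    # one power-iteration polish
    for _ in range(5):
        pi = pi @ T
        pi /= pi.sum()
    return pi


def implied_timescales(model: MarkovModel, n: int = 5) -> np.ndarray:
    """Implied relaxation timescales ``-tau / ln lambda_{i+1}`` in ns."""
    lam = model.eigenvalues[1 : n + 1]
    out = np.full(lam.shape, np.nan)
    ok = (lam > 1e-12) & (lam < 1)
    out[ok] = -model.lag_time / np.log(lam[ok])
    return out


def its_scan(
    dtrajs,
    lags: Sequence[int],
    n_timescales: int = 3,
    frame_interval: float = 0.1,
    mode: str = "sliding",
) -> pd.DataFrame:
    """Implied timescales as a function of lag (model-validation table).

    For exactly Markovian data the rows are flat in the lag; systematic
    growth signals discretization that lumps kinetically distinct states.
    """
    rows = []
    for lag in lags:
        cm = largest_connected_set(count_transitions(dtrajs, lag, mode=mode))
        model = estimate_reversible_mle(cm, frame_interval=frame_interval)
        its = implied_timescales(model, n_timescales)
        rows.append(
            {"lag": lag, "lag_ns": lag * frame_interval}
            | {f"t{i + 2}": its[i] if i < its.size else np.nan for i in range(n_timescales)}
        )
    return pd.DataFrame(rows)


def _stay_fraction(dlist, in_set: np.ndarray, lag: int) -> float:
    num = den = 0
    for d in dlist:
        if len(d) <= lag:
            continue
        a = in_set[d[:-lag]]
        b = in_set[d[lag:]]
        den += a.sum()
        num += (a & b).sum()
    return num / den if den > 0 else np.nan


def ck_test(
    dtrajs,
    model: MarkovModel,
    sets: Sequence[np.ndarray],
    factors: Sequence[int] = (1, 2, 4, 8),
    n_bootstrap: int = 100,
    seed: int = 0,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Chapman-Kolmogorov test on metastable sets.

    For each set ``A`` and factor ``k``, compares the model prediction
    ``sum_{i in A} pi_i [T^k]_{i,A} / sum_{i in A} pi_i`` against the
    empirical probability of still being in ``A`` after ``k * lag`` frames,
    with a trajectory-bootstrap confidence band on the observation.
    Factors whose horizon exceeds the data are skipped with a warning.
    """
    dlist = _dtraj_list(dtrajs)
    n_total = int(max(d.max() for d in dlist)) + 1
    rng = np.random.default_rng(seed)
    rows = []
    pos = {s: i for i, s in enumerate(model.active_set)}
    for si, A in enumerate(sets):
        A = np.asarray(A, dtype=int)
        in_set = np.zeros(n_total, dtype=bool)
        in_set[A] = True
        idx = np.array([pos[a] for a in A if a in pos], dtype=int)
        w = model.pi[idx] / model.pi[idx].sum()
        Tk = np.eye(model.n_states)
        for k in sorted(factors):
            horizon = k * model.lag
            if all(len(d) <= horizon for d in dlist):
                warnings.warn(f"factor {k} exceeds data horizon; skipped", stacklevel=2)
                continue
            Tk = np.linalg.matrix_power(model.T, k)
            pred = float(w @ Tk[np.ix_(idx, idx)].sum(axis=1))
            obs = _stay_fraction(dlist, in_set, horizon)
            boot = []
            for _ in range(n_bootstrap):
                pick = rng.integers(0, len(dlist), size=len(dlist))
                boot.append(_stay_fraction([dlist[j] for j in pick], in_set, horizon))
            lo, hi = np.nanpercentile(boot, [50 * (1 - conf), 50 * (1 + conf)])
            rows.append(
                {
                    "set": si,
                    "factor": k,
                    "predicted": pred,
                    "observed": obs,
                    "lo": lo,
                    "hi": hi,
                }
            )
    return pd.DataFrame(rows)
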