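"""Time-lagged independent component analysis (tICA).

Extracts the slowest linear collective variables from feature time series
by solving the generalized eigenproblem ``C_tau v = lambda C_0 v`` built
from mean-free instantaneous and time-lagged covariances.  The symmetrized
(reversible) estimator is used throughout: ``C_tau`` is replaced by
``(C_tau + C_tau^T) / 2``, which guarantees real eigenvalues on data from a
reversible process and makes ``-tau / ln lambda`` interpretable as a
relaxation timescale.

Covariances are accumulated per trajectory so that no time-lagged pair
straddles a trajectory boundary.  Constant feature columns are dropped
(with a warning) before the eigenproblem; a small ridge on ``C_0``
regularizes near-singular feature sets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

from .traj import FeatureMatrix

__all__ = ["TicaModel", "fit_tica", "transform", "tica_timescales"]


@dataclass
class TicaModel:
    """Fitted tICA estimator.

    ``components`` has one generalized eigenvector per column, normalized so
    that ``V^T (C0 + ridge I) V = I`` and ordered by descending eigenvalue;
    each column is sign-fixed so its largest-magnitude loading is positive.
    ``retained`` maps component input dimensions to the original feature
    columns (constant columns are excluded).
    """

    mean: np.ndarray
    c0: np.ndarray
    ctau_sym: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray
    lag: int
    ridge: float
    retained: np.ndarray
    frame_interval: float

    @property
    def n_features(self) -> int:
        return self.retained.size

    def to_json(self, path: str | Path) -> None:
        doc = {
            "mean": self.mean.tolist(),
            "c0": self.c0.tolist(),
            "ctau_sym": self.ctau_sym.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "components": self.components.tolist(),
            "lag": self.lag,
            "ridge": self.ridge,
            "retained": self.retained.tolist(),
            "frame_interval": self.frame_interval,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "TicaModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            mean=np.array(doc["mean"]),
            c0=np.array(doc["c0"]),
            ctau_sym=np.array(doc["ctau_sym"]),
            eigenvalues=np.array(doc["eigenvalues"]),
            components=np.array(doc["components"]),
            lag=int(doc["lag"]),
            ridge=float(doc["ridge"]),
            retained=np.array(doc["retained"], dtype=int),
            frame_interval=float(doc["frame_interval"]),
        )


def _as_list(trajs) -> list[FeatureMatrix]:
    if isinstance(trajs, FeatureMatrix):
        return [trajs]
    return list(trajs)


def fit_tica(
    trajs: Sequence[FeatureMatrix] | FeatureMatrix,
    lag: int,
    n_components: int | None = None,
    ridge: float | None = None,
) -> TicaModel:
    """Estimate a :class:`TicaModel` from one or more feature trajectories.

    Parameters
    ----------
    trajs
        Feature time series; lagged pairs never cross trajectory boundaries.
    lag
        tICA lag time in frames; must be shorter than every trajectory.
    n_components
        Number of components to retain (default: all).
    ridge
        Regularization added to ``C0`` as ``ridge * I``.  Default
        ``1e-6 * trace(C0) / dim``.
    """
    tlist = _as_list(trajs)
    if not tlist:
        raise ValueError("no trajectories given")
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    shortest = min(t.n_frames for t in tlist)
    if lag >= shortest:
        raise ValueError(
            f"lag {lag} is not shorter than the shortest trajectory ({shortest})"
        )
    d_all = tlist[0].n_features
    frame_interval = tlist[0].frame_interval

    # drop constant columns (zero variance across all data)
    allvals = np.vstack([t.values for t in tlist])
    variances = allvals.var(axis=0)
    retained = np.where(variances > 1e-12)[0]
    if retained.size < d_all:
        warnings.warn(
            f"dropping {d_all - retained.size} constant feature column(s)",
            stacklevel=2,
        )
    if retained.size < 2:
        raise ValueError("need at least 2 non-constant features")

    # mean over instantaneous+lagged windows, accumulated per trajectory
    s = np.zeros(retained.size)
    n_pairs = 0
    for t in tlist:
        X = t.values[:, retained]
        s += X[:-lag].sum(axis=0) + X[lag:].sum(axis=0)
        n_pairs += X.shape[0] - lag
    mean = s / (2 * n_pairs)

    c0 = np.zeros((retained.size, retained.size))
    ctau = np.zeros_like(c0)
    for t in tlist:
        X = t.values[:, retained] - mean
        A, B = X[:-lag], X[lag:]
        c0 += A.T @ A + B.T @ B
        ctau += A.T @ B
    c0 /= 2 * n_pairs
    ctau /= n_pairs
    ctau_sym = 0.5 * (ctau + ctau.T)

    if ridge is None:
        ridge = 1e-6 * np.trace(c0) / retained.size
    c0r = c0 + ridge * np.eye(retained.size)
    if np.linalg.cond(c0r) > 1e12:
        raise ValueError(
            "instantaneous covariance is (near-)singular; increase ridge"
        )
    evals, evecs = scipy.linalg.eigh(ctau_sym, c0r)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # sign convention: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    if n_components is not None:
        evals = evals[:n_components]
        evecs = evecs[:, :n_components]
    return TicaModel(
        mean=mean,
        c0=c0,
        ctau_sym=ctau_sym,
        eigenvalues=evals,
        components=evecs,
        lag=lag,
        ridge=ridge,
        retained=retained,
        frame_interval=frame_interval,
    )


def transform(
    model: TicaModel,
    features: FeatureMatrix | np.ndarray,
    n_components: int | None = None,
) -> np.ndarray:
    """Project features onto the leading independent components.

    The map is affine: ``(x - mean) V`` restricted to the first
    ``n_components`` columns.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.atleast_2d(
        np.asarray(features, dtype=float)
    )
    if X.shape[1] == model.retained.size:
        Xr = X
    elif X.shape[1] > model.retained.max():
        Xr = X[:, model.retained]
    else:
        raise ValueError(
            f"feature dimension {X.shape[1]} incompatible with model "
            f"({model.retained.size} retained columns)"
        )
    V = model.components if n_components is None else model.components[:, :n_components]
    return (Xr - model.mean) @ V


def tica_timescales(model: TicaModel, frame_interval: float | None = None) -> np.ndarray:
    """Relaxation timescales ``-tau dt / ln(lambda)`` per component, in ns.

    Components with ``lambda >= 1`` map to ``+inf`` and those with
    ``lambda <= 0`` to ``nan`` (undefined, not an error).
    """
    dt = model.frame_interval if frame_interval is None else frame_interval
    lam = model.eigenvalues
    out = np.full(lam.shape, np.nan)
    pos = (lam > 0) & (lam < 1)
    out[pos] = -model.lag * dt / np.log(lam[pos])
    out[lam >= 1] = np.inf
    return out
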