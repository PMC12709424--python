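"""Synthetic datasets with the statistical structure of kinase-loop MD data.

Real activation-loop trajectories are tens of gigabytes; everything in this
package is exercised instead on generated data whose hidden kinetics are
known exactly, so that the full analysis chain (tICA -> clustering -> MSM ->
metastable decomposition) can be tested for *parameter recovery* rather than
eyeballed.  Each generator is a pure function of its parameters and a seed,
and returns the ground truth alongside the data.

The flagship generator, :func:`make_ck1_like_dataset`, emulates the two
study conditions: a wild-type-like system in which the activation loop
exchanges slowly between "up" and "down" through an intermediate with an
unfolded loop EF, with "down" dominant; and a tau-mutant-like system with
the preference inverted ("up" dominant), a direct up<->down pathway, and
exchange kinetics faster by at least :data:`DESIGNED_KINETICS_FACTOR`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .potentials import LandscapeSpec
from .traj import AtomRecord, FeatureMatrix, Trajectory

__all__ = [
    "GroundTruthModel",
    "DESIGNED_KINETICS_FACTOR",
    "sample_markov_chain",
    "emit_features",
    "simulate_langevin",
    "make_ck1_like_dataset",
    "make_dihedral_dataset",
    "make_toy_coordinates",
]

#: the tau-like scenario is designed to interconvert at least this factor
#: faster than the wt-like scenario (both directions of up<->down)
DESIGNED_KINETICS_FACTOR = 2.0


def _stationary(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class GroundTruthModel:
    """Hidden-state kinetics and emissions retained for recovery testing.

    ``macro_T`` is the per-frame hidden transition matrix; ``macro_pi`` its
    stationary distribution; ``emission_means`` / ``emission_covs`` define
    the per-state Gaussian observation model in feature space (Angstrom).
    """

    macro_T: np.ndarray
    emission_means: np.ndarray
    emission_covs: np.ndarray
    frame_interval: float = 0.1
    state_labels: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)
    macro_pi: np.ndarray = None  # computed in __post_init__ unless given

    def __post_init__(self) -> None:
        self.macro_T = np.asarray(self.macro_T, dtype=float)
        n = self.macro_T.shape[0]
        if self.macro_T.shape != (n, n):
            raise ValueError("macro_T must be square")
        if not np.allclose(self.macro_T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("macro_T rows must sum to 1 within 1e-12")
        if self.macro_pi is None:
            self.macro_pi = _stationary(self.macro_T)
        self.macro_pi = np.asarray(self.macro_pi, dtype=float)
        if not np.allclose(self.macro_pi @ self.macro_T, self.macro_pi, atol=1e-10):
            raise ValueError("macro_pi does not solve pi T = pi")
        self.emission_means = np.atleast_2d(np.asarray(self.emission_means, float))
        self.emission_covs = np.asarray(self.emission_covs, dtype=float)
        if self.emission_covs.ndim == 2:
            self.emission_covs = self.emission_covs[None].repeat(n, axis=0)
        for c in self.emission_covs:
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError("emission covariance not symmetric")
            if np.linalg.norm(c) > 0 and np.min(np.linalg.eigvalsh(c)) <= 0:
                raise ValueError("emission covariance not positive-definite")
        if not self.state_labels:
            self.state_labels = tuple(f"state{i}" for i in range(n))

    @property
    def n_states(self) -> int:
        return self.macro_T.shape[0]

    def mfpt_matrix(self) -> np.ndarray:
        """Analytic mean first passage times between hidden states (ns)."""
        n = self.n_states
        out = np.zeros((n, n))
        for b in range(n):
            keep = [i for i in range(n) if i != b]
            A = np.eye(n - 1) - self.macro_T[np.ix_(keep, keep)]
            m = np.linalg.solve(A, np.ones(n - 1)) * self.frame_interval
            for row, i in enumerate(keep):
                out[i, b] = m[row]
        return out

    def relaxation_times(self) -> np.ndarray:
        """Implied relaxation times (ns) of the hidden chain, descending."""
        vals = np.sort(np.real(np.linalg.eigvals(self.macro_T)))[::-1]
        vals = vals[1:]  # drop the stationary eigenvalue
        vals = vals[(vals > 0) & (vals < 1)]
        return -self.frame_interval / np.log(vals)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "macro_T": self.macro_T.tolist(),
            "macro_pi": self.macro_pi.tolist(),
            "emission_means": self.emission_means.tolist(),
            "emission_covs": self.emission_covs.tolist(),
            "frame_interval": self.frame_interval,
            "state_labels": list(self.state_labels),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            macro_T=np.array(doc["macro_T"]),
            emission_means=np.array(doc["emission_means"]),
            emission_covs=np.array(doc["emission_covs"]),
            frame_interval=doc["frame_interval"],
            state_labels=tuple(doc["state_labels"]),
            meta=doc.get("meta", {}),
            macro_pi=np.array(doc["macro_pi"]),
        )


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------


def sample_markov_chain(
    T: np.ndarray,
    n_steps: int,
    seed: int,
    initial: int | np.ndarray = 0,
) -> np.ndarray:
    """Sample a discrete-state chain from a row-stochastic matrix.

    ``initial`` may be a state index or a probability distribution over
    states.  Identical seed gives an identical sequence.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    if T.shape != (n, n):
        raise ValueError("T must be square")
    if np.any(T < -1e-12) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("T rows must be non-negative and sum to 1 within 1e-9")
    rng = np.random.default_rng(seed)
    if np.ndim(initial) == 0:
        s = int(initial)
        if not 0 <= s < n:
            raise ValueError(f"initial state {s} outside [0, {n})")
    else:
        p0 = np.asarray(initial, dtype=float)
        if p0.shape != (n,) or not np.isclose(p0.sum(), 1.0):
            raise ValueError("initial distribution must be length-n and sum to 1")
        s = int(rng.choice(n, p=p0))
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0  # guard rounding
    u = rng.random(n_steps)
    out = np.empty(n_steps, dtype=np.int64)
    for t in range(n_steps):
        out[t] = s
        s = int(np.searchsorted(cum[s], u[t], side="right"))
    return out


def emit_features(
    states: np.ndarray, model: GroundTruthModel, seed: int
) -> FeatureMatrix:
    """Draw per-frame feature vectors from the state-conditioned Gaussians."""
    states = np.asarray(states, dtype=int)
    if states.min() < 0 or states.max() >= model.n_states:
        raise ValueError("state sequence indexes an undefined emission")
    d = model.emission_means.shape[1]
    chols = []
    for c in model.emission_covs:
        if np.linalg.norm(c) == 0:
            chols.append(np.zeros((d, d)))
        else:
            chols.append(np.linalg.cholesky(c))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((states.size, d))
    values = model.emission_means[states].copy()
    for s in range(model.n_states):
        mask = states == s
        values[mask] += z[mask] @ chols[s].T
    descriptors = [f"distance_{i}" for i in range(d)]
    return FeatureMatrix(values, descriptors, frame_interval=model.frame_interval)


def simulate_langevin(
    spec: LandscapeSpec,
    n_steps: int,
    potential=None,
    x0: np.ndarray | None = None,
    bound: float = 1e3,
) -> np.ndarray:
    """Overdamped Euler-Maruyama trajectory on a 2-D landscape.

    Update rule ``x <- x - (grad U / gamma) dt + sqrt(2 kT dt / gamma) xi``
    with standard-normal ``xi``.  Returns positions of shape (n_steps, 2);
    the first row is the initial position.  Aborts with a diagnostic if
    ``|x|`` exceeds ``bound`` (numerical divergence).
    """
    pot = spec.potential() if potential is None else potential
    rng = np.random.default_rng(spec.seed)
    if x0 is None:
        x = np.array(spec.wells[0][0], dtype=float)
    else:
        x = np.array(x0, dtype=float)
    noise_amp = np.sqrt(2.0 * spec.kT * spec.dt / spec.friction)
    xi = rng.standard_normal((n_steps, 2)) if spec.kT > 0 else np.zeros((n_steps, 2))
    out = np.empty((n_steps, 2))
    inv_gamma_dt = spec.dt / spec.friction
    for t in range(n_steps):
        out[t] = x
        x = x - pot.gradient(x) * inv_gamma_dt + noise_amp * xi[t]
        if np.abs(x).max() > bound:
            raise RuntimeError(
                f"Langevin trajectory diverged at step {t}: |x| = "
                f"{np.abs(x).max():.3g} exceeds bound {bound:.3g}; "
                "reduce dt or check the potential gradient"
            )
    return out


# ---------------------------------------------------------------------------
# study-condition datasets
# ---------------------------------------------------------------------------

# Hidden kinetics for the two study conditions, per 0.1 ns frame.  The
# wild-type-like system is down-dominant (pi ~ [0.15, 0.10, 0.75]) and
# exchanges only through the intermediate (unfolded loop-EF) state; the
# tau-like system is up-dominant with a direct up<->down channel and
# overall faster exchange.  Both satisfy detailed balance by construction.
_WT_PI = np.array([0.15, 0.10, 0.75])
_WT_T = np.array(
    [
        [0.996, 0.004, 0.000],
        [0.006, 0.964, 0.030],
        [0.000, 0.004, 0.996],
    ]
)
_TAU_PI = np.array([0.70, 0.12, 0.18])
_TAU_T = np.array(
    [
        [1.0 - 0.004 - 0.006, 0.004, 0.006],
        [0.7 * 0.004 / 0.12, 1.0 - 0.7 * 0.004 / 0.12 - 0.025, 0.025],
        [0.7 * 0.006 / 0.18, 0.12 * 0.025 / 0.18, 0.0],
    ]
)
_TAU_T[2, 2] = 1.0 - _TAU_T[2, 0] - _TAU_T[2, 1]

# Per-state emission means in the 5-D pairwise-distance feature space
# (Angstrom).  The fifth distance is identical across states: a feature
# carrying no kinetic information, as real feature sets always include.
_EMISSION_MEANS = np.array(
    [
        [10.0, 4.0, 12.0, 6.0, 8.0],  # loop up
        [7.5, 6.5, 9.0, 8.5, 8.0],  # intermediate, loop EF unfolded
        [5.0, 9.0, 6.0, 11.0, 8.0],  # loop down
    ]
)
_EMISSION_STD = 0.7  # Angstrom, isotropic


def make_ck1_like_dataset(
    scenario: str,
    n_trajectories: int = 3,
    n_frames: int = 200_000,
    seed: int = 0,
) -> tuple[list[FeatureMatrix], GroundTruthModel]:
    """Multi-trajectory 5-distance feature data for one study condition.

    ``scenario`` is ``"wt"`` (down-dominant, slow exchange through the
    intermediate) or ``"tau"`` (up-dominant, direct up<->down exchange at
    least :data:`DESIGNED_KINETICS_FACTOR` times faster).  Each trajectory
    gets its own RNG stream seeded ``seed + trajectory index``, so
    individual trajectories can be regenerated independently.
    """
    if scenario == "wt":
        T, pi = _WT_T, _WT_PI
    elif scenario == "tau":
        T, pi = _TAU_T, _TAU_PI
    else:
        raise ValueError(f"unknown scenario {scenario!r}; expected 'wt' or 'tau'")
    covs = np.array([np.eye(5) * _EMISSION_STD**2] * 3)
    gt = GroundTruthModel(
        macro_T=T,
        emission_means=_EMISSION_MEANS,
        emission_covs=covs,
        frame_interval=0.1,
        state_labels=("up", "intermediate", "down"),
        meta={"scenario": scenario, "designed_factor": DESIGNED_KINETICS_FACTOR},
    )
    t_slow = gt.relaxation_times().max()
    if n_frames * gt.frame_interval < 20 * t_slow:
        warnings.warn(
            f"n_frames={n_frames} covers only "
            f"{n_frames * gt.frame_interval / t_slow:.1f} slowest relaxation "
            "times; kinetic estimates will be noisy",
            stacklevel=2,
        )
    trajs = []
    for i in range(n_trajectories):
        states = sample_markov_chain(T, n_frames, seed=seed + i, initial=pi)
        trajs.append(emit_features(states, gt, seed=seed + i + 7_000_000))
    return trajs, gt


def make_dihedral_dataset(
    n_frames: int,
    seed: int,
    centers_deg: tuple[float, float] = (-70.0, 70.0),
    kappa: float = 8.0,
) -> tuple[np.ndarray, GroundTruthModel]:
    """Two-state hidden chain emitting von Mises backbone-angle samples.

    Emulates a single backbone dihedral that switches sign with the hidden
    conformation (negative angle for "loop up", positive for "loop down").
    Angles are returned in degrees, wrapped to (-180, 180].  ``kappa`` is
    the von Mises concentration; ``kappa = inf`` gives zero angular spread.
    """
    T = np.array([[0.99, 0.01], [0.01, 0.99]])
    gt = GroundTruthModel(
        macro_T=T,
        emission_means=np.array([[centers_deg[0]], [centers_deg[1]]]),
        emission_covs=np.array([[[0.0]], [[0.0]]]),
        frame_interval=0.1,
        state_labels=("up", "down"),
        meta={"kappa": None if np.isinf(kappa) else kappa, "circular": True},
    )
    states = sample_markov_chain(T, n_frames, seed=seed, initial=gt.macro_pi)
    rng = np.random.default_rng(seed + 1)
    centers = np.radians(np.asarray(centers_deg))[states]
    if np.isinf(kappa):
        ang = np.degrees(centers)
    else:
        ang = np.degrees(rng.vonmises(centers, kappa))
    # wrap to (-180, 180]
    ang = np.mod(ang + 180.0, 360.0) - 180.0
    ang[ang == -180.0] = 180.0
    gt.meta["hidden_states"] = states.tolist() if n_frames <= 10_000 else None
    return ang, gt


def _reference_conformations() -> tuple[np.ndarray, np.ndarray]:
    """Two 10-atom pseudo-protein conformations differing in a 'loop' flip."""
    t = np.linspace(0, 3 * np.pi, 10)
    base = np.column_stack([3.8 * np.arange(10) / 3.0, 2.0 * np.sin(t), 2.0 * np.cos(t)])
    up = base.copy()
    down = base.copy()
    down[6:, 1] = -down[6:, 1] - 3.0  # flip the last four atoms downward
    down[6:, 2] += 1.5
    return up, down


def make_toy_coordinates(
    n_frames: int,
    seed: int,
    jitter: float = 0.1,
    rigid_motion: bool = True,
) -> tuple[Trajectory, GroundTruthModel]:
    """Toy 3-D coordinate trajectory hopping between two conformations.

    A 10-atom pseudo-protein interconverts between "loop up" and "loop
    down" reference conformations via a hidden two-state chain; every frame
    receives isotropic Gaussian jitter (``jitter`` Angstrom per coordinate)
    and, when ``rigid_motion`` is set, a random global rotation plus
    translation — exactly the nuisance motion featurization must ignore.
    """
    from scipy.spatial.transform import Rotation

    up, down = _reference_conformations()
    refs = np.stack([up, down])
    T = np.array([[0.98, 0.02], [0.03, 0.97]])
    gt = GroundTruthModel(
        macro_T=T,
        emission_means=refs.reshape(2, -1),
        emission_covs=np.array([np.eye(30) * jitter**2] * 2),
        frame_interval=0.1,
        state_labels=("up", "down"),
        meta={"jitter": jitter, "rigid_motion": rigid_motion},
    )
    states = sample_markov_chain(T, n_frames, seed=seed, initial=gt.macro_pi)
    rng = np.random.default_rng(seed + 1)
    coords = refs[states].copy()
    if jitter > 0:
        coords += rng.normal(scale=jitter, size=coords.shape)
    if rigid_motion:
        rots = Rotation.random(n_frames, rng=rng).as_matrix()
        trans = rng.normal(scale=5.0, size=(n_frames, 3))
        coords = np.einsum("fij,faj->fai", rots, coords) + trans[:, None, :]
    meta = [AtomRecord(i, "ALA", "CA") for i in range(10)]
    gt.meta["hidden_states"] = states.tolist() if n_frames <= 10_000 else None
    return Trajectory(coords, meta, frame_interval=0.1), gt
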