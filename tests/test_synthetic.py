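"""Generators: hidden-chain sampling, Gaussian emissions, Langevin dynamics,
and the study-condition datasets with retained ground truth."""

import numpy as np
import pytest

from loopdyn import gamd, synthetic
from loopdyn.potentials import (
    GaussianWells,
    Harmonic,
    LandscapeSpec,
    boltzmann_quadrature,
)
from loopdyn.synthetic import (
    GroundTruthModel,
    emit_features,
    make_ck1_like_dataset,
    make_dihedral_dataset,
    make_toy_coordinates,
    sample_markov_chain,
    simulate_langevin,
)


class TestSampleMarkovChain:
    def test_identity_is_absorbing(self):
        seq = sample_markov_chain(np.eye(3), 100, seed=0, initial=0)
        assert np.all(seq == 0)

    def test_deterministic_flip_alternates(self):
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        seq = sample_markov_chain(T, 50, seed=0, initial=0)
        assert np.array_equal(seq, np.arange(50) % 2)

    def test_empirical_frequencies_match_lln(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        seq = sample_markov_chain(T, 1_000_000, seed=42, initial=0)
        C = np.zeros((2, 2))
        np.add.at(C, (seq[:-1], seq[1:]), 1.0)
        T_emp = C / C.sum(axis=1)[:, None]
        assert np.max(np.abs(T_emp - T)) < 0.005

    def test_same_seed_same_sequence(self):
        T = np.array([[0.5, 0.5], [0.3, 0.7]])
        a = sample_markov_chain(T, 1000, seed=7)
        b = sample_markov_chain(T, 1000, seed=7)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "T,initial",
        [
            (np.array([[0.5, 0.4], [0.5, 0.5]]), 0),  # rows don't sum to 1
            (np.eye(2), 5),  # invalid initial state
            (np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), 0),  # not square
        ],
    )
    def test_invalid_inputs_rejected(self, T, initial):
        with pytest.raises(ValueError):
            sample_markov_chain(T, 10, seed=0, initial=initial)


class TestEmitFeatures:
    def _model(self, cov_scale):
        return GroundTruthModel(
            macro_T=np.array([[0.9, 0.1], [0.1, 0.9]]),
            emission_means=np.array([[0.0, 5.0], [3.0, -1.0]]),
            emission_covs=np.array([np.eye(2) * cov_scale] * 2),
        )

    def test_zero_covariance_gives_exact_means(self):
        model = self._model(0.0)
        states = np.array([0, 1, 1, 0])
        fm = emit_features(states, model, seed=0)
        assert np.array_equal(fm.values, model.emission_means[states])

    def test_sample_mean_obeys_clt_bound(self):
        model = GroundTruthModel(
            macro_T=np.array([[1.0]]),
            emission_means=np.array([[2.0]]),
            emission_covs=np.array([[[1.0]]]),
        )
        fm = emit_features(np.zeros(100_000, dtype=int), model, seed=3)
        # 3 sigma / sqrt(n) < 0.01; spec-level bound 0.02
        assert abs(fm.values.mean() - 2.0) < 0.02

    def test_determinism_bit_identical(self):
        model = self._model(1.0)
        states = np.tile([0, 1], 500)
        a = emit_features(states, model, seed=9)
        b = emit_features(states, model, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_non_positive_definite_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive-definite"):
            GroundTruthModel(
                macro_T=np.array([[1.0]]),
                emission_means=np.array([[0.0, 0.0]]),
                emission_covs=np.array([[[1.0, 2.0], [2.0, 1.0]]]),  # eig -1
            )

    def test_out_of_range_state_rejected(self):
        model = self._model(1.0)
        with pytest.raises(ValueError):
            emit_features(np.array([0, 2]), model, seed=0)


class TestSimulateLangevin:
    def test_zero_temperature_descends_monotonically(self):
        spec = LandscapeSpec(wells=[((0, 0), 1, 1)], kT=0.0, dt=0.01, seed=0)
        x = simulate_langevin(spec, 500, potential=Harmonic(kappa=1.0), x0=(3.0, -2.0))
        r = np.linalg.norm(x, axis=1)
        assert np.all(np.diff(r) <= 1e-12)

    def test_harmonic_equipartition_variance(self):
        # positional variance of an OU process is kT/kappa per coordinate;
        # relaxation time gamma/kappa = 100 steps -> ~2000 effective samples,
        # 3 SE ~ 0.1
        spec = LandscapeSpec(wells=[((0, 0), 1, 1)], kT=1.0, dt=0.01, seed=21)
        x = simulate_langevin(spec, 200_000, potential=Harmonic(kappa=1.0), x0=(0, 0))
        assert abs(x[:, 0].var() - 1.0) < 0.1
        assert abs(x[:, 1].var() - 1.0) < 0.1

    def test_double_well_occupancy_matches_boltzmann_quadrature(self):
        pot = GaussianWells(
            centers=np.array([[-1.5, 0.0], [1.5, 0.0]]),
            depths=np.array([3.0, 2.0]),
            widths=np.array([0.7, 0.7]),
        )
        spec = LandscapeSpec(wells=[((-1.5, 0), 3, 0.7)], kT=1.0, dt=0.01, seed=5)
        x = simulate_langevin(spec, 400_000, potential=pot, x0=(-1.5, 0.0))
        p_right = (x[:, 0] > 0).mean()
        xs, ys, dens = boltzmann_quadrature(pot, kT=1.0, extent=6.0, n_grid=301)
        mass = np.trapezoid(np.trapezoid(dens, ys, axis=1)[xs > 0], xs[xs > 0])
        n_trans = gamd.count_well_transitions(x[:, 0])
        se = np.sqrt(p_right * (1 - p_right) / max(n_trans, 1))
        assert n_trans > 20
        assert abs(p_right - mass) < 3 * se + 0.01

    def test_divergence_aborts_with_diagnostic(self):
        # negative-curvature "potential": gradient pushes outward
        class Unstable(Harmonic):
            def gradient(self, x):
                return -50.0 * np.asarray(x, dtype=float)

        spec = LandscapeSpec(wells=[((0, 0), 1, 1)], kT=1.0, dt=0.5, seed=0)
        with pytest.raises(RuntimeError, match="diverged"):
            simulate_langevin(spec, 10_000, potential=Unstable(), x0=(1.0, 1.0))


class TestCk1LikeDataset:
    @pytest.mark.parametrize("scenario", ["wt", "tau"])
    def test_populations_normalized_and_dominance(self, scenario):
        trajs, gt = make_ck1_like_dataset(scenario, 2, 5000, seed=0)
        assert abs(gt.macro_pi.sum() - 1.0) < 1e-12
        dominant = gt.state_labels[int(np.argmax(gt.macro_pi))]
        assert dominant == ("down" if scenario == "wt" else "up")
        assert len(trajs) == 2 and trajs[0].n_frames == 5000

    def test_tau_kinetics_designed_contrast(self):
        _, wt = make_ck1_like_dataset("wt", 1, 2000, seed=0)
        _, tau = make_ck1_like_dataset("tau", 1, 2000, seed=0)
        i_up, i_dn = 0, 2
        m_wt, m_tau = wt.mfpt_matrix(), tau.mfpt_matrix()
        factor = synthetic.DESIGNED_KINETICS_FACTOR
        assert m_wt[i_up, i_dn] >= factor * m_tau[i_up, i_dn]
        assert m_wt[i_dn, i_up] >= factor * m_tau[i_dn, i_up]

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            make_ck1_like_dataset("mutant-x", 1, 100, seed=0)

    def test_short_run_warns(self):
        with pytest.warns(UserWarning, match="relaxation"):
            make_ck1_like_dataset("wt", 1, 200, seed=0)

    def test_trajectory_streams_independent(self):
        trajs3, _ = make_ck1_like_dataset("wt", 3, 1000, seed=5)
        trajs2, _ = make_ck1_like_dataset("wt", 2, 1000, seed=5)
        assert np.array_equal(trajs3[0].values, trajs2[0].values)
        assert np.array_equal(trajs3[1].values, trajs2[1].values)


class TestDihedralDataset:
    def test_zero_spread_hits_centers(self):
        ang, gt = make_dihedral_dataset(500, seed=0, kappa=np.inf)
        assert set(np.unique(ang)) <= {-70.0, 70.0}

    def test_wrapped_range(self):
        ang, _ = make_dihedral_dataset(20_000, seed=1)
        assert ang.min() > -180.0 and ang.max() <= 180.0

    def test_sign_predicts_hidden_state(self):
        ang, gt = make_dihedral_dataset(10_000, seed=2)
        states = np.array(gt.meta["hidden_states"])
        predicted = (ang > 0).astype(int)  # state 1 centered at +70
        assert (predicted == states).mean() > 0.95


class TestToyCoordinates:
    def test_zero_jitter_no_motion_equals_references(self):
        traj, gt = make_toy_coordinates(200, seed=0, jitter=0.0, rigid_motion=False)
        refs = gt.emission_means.reshape(2, -1, 3)
        states = np.array(gt.meta["hidden_states"])
        assert np.allclose(traj.coordinates, refs[states])

    def test_pairwise_distances_invariant_under_rigid_motion(self):
        t_fix, _ = make_toy_coordinates(300, seed=3, jitter=0.05, rigid_motion=False)
        t_mov, _ = make_toy_coordinates(300, seed=3, jitter=0.05, rigid_motion=True)

        def dmat(c):
            return np.linalg.norm(c[:, :, None, :] - c[:, None, :, :], axis=-1)

        assert np.allclose(dmat(t_fix.coordinates), dmat(t_mov.coordinates), atol=1e-8)

    def test_frame_rmsd_tracks_jitter_level(self):
        from loopdyn.features import kabsch_superpose

        jitter = 0.2
        traj, gt = make_toy_coordinates(400, seed=4, jitter=jitter, rigid_motion=True)
        refs = gt.emission_means.reshape(2, -1, 3)
        states = np.array(gt.meta["hidden_states"])
        rmsds = [
            kabsch_superpose(refs[states[f]], traj.coordinates[f])[2]
            for f in range(traj.n_frames)
        ]
        # per-coordinate sigma -> RMSD ~ sigma * sqrt(3), reduced by the
        # 6 fitted rigid degrees of freedom out of 3N = 30
        expected = jitter * np.sqrt(3.0) * np.sqrt(1 - 6 / 30)
        assert abs(np.mean(rmsds) - expected) / expected < 0.1
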