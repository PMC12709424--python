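"""Transition counting, reversible MLE, spectra, and MSM validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from loopdyn.msm import (
    CountMatrix,
    MarkovModel,
    ck_test,
    count_transitions,
    estimate_reversible_mle,
    implied_timescales,
    its_scan,
    largest_connected_set,
    stationary_distribution,
)
from loopdyn.synthetic import sample_markov_chain


def _random_reversible(k, rng):
    """Random reversible transition matrix via symmetric fluxes."""
    w = rng.uniform(0.1, 1.0, size=(k, k))
    w = 0.5 * (w + w.T)
    pi = w.sum(axis=1) / w.sum()
    T = w / w.sum(axis=1)[:, None]
    return T, pi


class TestCounting:
    def test_hand_counted_example(self):
        cm = count_transitions([np.array([0, 0, 1, 1, 0])], lag=1)
        assert np.array_equal(cm.C, [[1, 1], [1, 1]])

    def test_maximal_lag_single_count(self):
        cm = count_transitions([np.array([0, 1, 1, 0])], lag=3)
        assert cm.C.sum() == 1 and cm.C[0, 0] == 1

    def test_strided_equals_sliding_of_downsampled(self, rng):
        d = rng.integers(0, 4, size=500)
        strided = count_transitions([d], lag=5, mode="strided")
        downsampled = count_transitions([d[::5]], lag=1, mode="sliding", n_states=4)
        assert np.array_equal(strided.C, downsampled.C)

    def test_no_cross_trajectory_pairs(self):
        cm = count_transitions([np.array([0, 0]), np.array([1, 1])], lag=1)
        assert cm.C[0, 1] == 0 and cm.C[1, 0] == 0

    def test_lag_too_long_rejected(self):
        with pytest.raises(ValueError):
            count_transitions([np.array([0, 1])], lag=5)


class TestConnectivity:
    def test_fully_connected_retained(self):
        cm = CountMatrix(np.ones((4, 4)), lag=1)
        assert largest_connected_set(cm).active_set.size == 4

    def test_block_diagonal_keeps_larger_block(self):
        C = np.zeros((5, 5))
        C[:3, :3] = 1.0
        C[3:, 3:] = 1.0
        keep = largest_connected_set(CountMatrix(C, lag=1)).active_set
        assert np.array_equal(keep, [0, 1, 2])

    def test_matches_brute_force_reachability(self, rng):
        def scc_brute(adj):
            n = adj.shape[0]
            reach = [set() for _ in range(n)]
            for s in range(n):
                stack, seen = [s], {s}
                while stack:
                    u = stack.pop()
                    for v in np.where(adj[u])[0]:
                        if v not in seen:
                            seen.add(int(v))
                            stack.append(int(v))
                reach[s] = seen
            best = []
            for s in range(n):
                comp = {t for t in reach[s] if s in reach[t]}
                if len(comp) > len(best):
                    best = sorted(comp)
            return best

        for _ in range(20):
            n = int(rng.integers(3, 10))
            C = (rng.random((n, n)) < 0.25).astype(float)
            got = sorted(largest_connected_set(CountMatrix(C, lag=1)).active_set)
            expected = scc_brute(C > 0)
            assert len(got) == len(expected)


class TestReversibleMle:
    def test_symmetric_counts_row_normalize(self):
        model = estimate_reversible_mle(
            CountMatrix(np.array([[8.0, 2.0], [2.0, 8.0]]), lag=1)
        )
        assert np.allclose(model.T, [[0.8, 0.2], [0.2, 0.8]], atol=1e-10)
        assert np.allclose(model.pi, [0.5, 0.5], atol=1e-10)

    def test_detailed_balance_contract(self, rng):
        C = rng.integers(1, 50, size=(5, 5)).astype(float)
        model = estimate_reversible_mle(CountMatrix(C, lag=1))
        flux = model.pi[:, None] * model.T
        assert np.allclose(flux, flux.T, atol=1e-8)

    def test_matches_constrained_likelihood_optimizer(self):
        C = np.array([[90.0, 10.0, 0.0], [5.0, 80.0, 15.0], [0.0, 10.0, 90.0]])
        model = estimate_reversible_mle(CountMatrix(C, lag=1))

        # oracle: direct numeric maximization over the reversible
        # parameterization x_ij = x_ji (log coordinates, analytic gradient)
        c = C.sum(axis=1)
        iu = np.triu_indices(3)
        live = (C + C.T)[iu] > 0

        def unpack(z):
            x = np.zeros((3, 3))
            x[iu] = np.where(live, np.exp(z), 0.0)
            return x + np.triu(x, 1).T

        def negll(z):
            x = unpack(z)
            T = x / x.sum(axis=1)[:, None]
            m = C > 0
            return -(C[m] * np.log(T[m])).sum()

        def grad(z):
            x = unpack(z)
            xi = x.sum(axis=1)
            g = np.zeros_like(z)
            for p, (i, j) in enumerate(zip(*iu)):
                if not live[p]:
                    continue
                if i == j:
                    d = -C[i, i] / x[i, i] + c[i] / xi[i]
                else:
                    d = -(C[i, j] + C[j, i]) / x[i, j] + c[i] / xi[i] + c[j] / xi[j]
                g[p] = d * x[i, j]
            return g

        z0 = np.where(live, np.log((C + C.T)[iu] + 1e-3), 0.0)
        res = minimize(
            negll, z0, jac=grad, method="L-BFGS-B",
            options={"gtol": 1e-13, "ftol": 1e-16},
        )
        x = unpack(res.x)
        T_opt = x / x.sum(axis=1)[:, None]
        assert np.max(np.abs(T_opt - model.T)) < 1e-6

    def test_empty_row_rejected(self):
        C = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="empty"):
            estimate_reversible_mle(CountMatrix(C, lag=1))


class TestStationary:
    def test_two_state_closed_form(self):
        pi = stationary_distribution(np.array([[0.8, 0.2], [0.4, 0.6]]))
        assert np.allclose(pi, [2 / 3, 1 / 3], atol=1e-12)

    def test_residual_contract(self, rng):
        T, _ = _random_reversible(6, rng)
        pi = stationary_distribution(T)
        assert np.max(np.abs(pi @ T - pi)) < 1e-12

    def test_matches_eigensolver_oracle(self, rng):
        for _ in range(10):
            T, _ = _random_reversible(5, rng)
            pi = stationary_distribution(T)
            vals, vecs = np.linalg.eig(T.T)
            v = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
            v = np.abs(v) / np.abs(v).sum()
            assert np.max(np.abs(pi - v)) < 1e-10

    def test_reducible_rejected(self):
        with pytest.raises(ValueError, match="reducible|connected"):
            stationary_distribution(np.eye(3))


class TestTimescales:
    def test_closed_form(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])  # lambda_2 = 0.8
        model = MarkovModel(T=T, pi=np.array([0.5, 0.5]), lag=1, frame_interval=1.0)
        ts = implied_timescales(model, 1)
        assert abs(ts[0] - 4.4814) < 1e-3

    def test_two_state_switching_probability(self):
        p = 0.05
        T = np.array([[1 - p, p], [p, 1 - p]])
        model = MarkovModel(T=T, pi=np.array([0.5, 0.5]), lag=1, frame_interval=1.0)
        assert abs(implied_timescales(model, 1)[0] - (-1 / np.log(0.9))) < 1e-10
        assert abs(implied_timescales(model, 1)[0] - 9.4912) < 1e-3


class TestItsScan:
    def test_flat_on_markovian_data(self):
        T = np.array([[0.95, 0.05, 0.0], [0.05, 0.9, 0.05], [0.0, 0.05, 0.95]])
        dtrajs = [sample_markov_chain(T, 100_000, seed=s) for s in range(3)]
        table = its_scan(dtrajs, [1, 2, 5, 10], frame_interval=0.1)
        t2 = table["t2"].to_numpy()
        assert np.all(np.abs(t2 - t2.mean()) / t2.mean() < 0.1)

    def test_single_lag_single_row(self):
        d = [np.array([0, 1, 0, 1, 0, 0, 1])]
        table = its_scan(d, [1])
        assert len(table) == 1

    def test_lumped_non_markovian_grows_with_lag(self):
        # 3-state chain with fast 0<->1 exchange and a slow, sticky state 2;
        # lumping {1, 2} into one label mixes the two timescales, so the
        # apparent slow timescale of the lumped process grows with the lag
        T = np.array(
            [[0.918, 0.08, 0.002], [0.08, 0.919, 0.001], [0.004, 0.002, 0.994]]
        )
        d = sample_markov_chain(T, 300_000, seed=7)
        lumped = np.where(d == 0, 0, 1)
        table = its_scan([lumped], [1, 5, 20, 50], frame_interval=0.1)
        t2 = table["t2"].to_numpy()
        assert t2[-1] > 1.5 * t2[0]


class TestCkTest:
    def _model_and_data(self, seed=0, n=200_000):
        T = np.array([[0.97, 0.03, 0.0], [0.03, 0.94, 0.03], [0.0, 0.03, 0.97]])
        dtrajs = [sample_markov_chain(T, n, seed=seed + s) for s in range(3)]
        cm = largest_connected_set(count_transitions(dtrajs, lag=2))
        model = estimate_reversible_mle(cm, frame_interval=0.1)
        return model, dtrajs

    def test_factor_one_observed_equals_predicted(self):
        model, dtrajs = self._model_and_data()
        table = ck_test(dtrajs, model, [np.array([0]), np.array([1, 2])], factors=[1])
        assert np.allclose(table["observed"], table["predicted"], atol=5e-3)

    def test_self_consistency_within_bands(self):
        model, dtrajs = self._model_and_data()
        sets = [np.array([0]), np.array([1]), np.array([2])]
        table = ck_test(dtrajs, model, sets, factors=[1, 2, 5, 10], seed=1)
        inside = (table["predicted"] >= table["lo"] - 5e-3) & (
            table["predicted"] <= table["hi"] + 5e-3
        )
        assert inside.mean() >= 0.9

    def test_constructed_violation_detected(self):
        # lump kinetically distinct states -> model at short lag cannot
        # predict long-horizon set survival
        T = np.array(
            [[0.918, 0.08, 0.002], [0.08, 0.919, 0.001], [0.004, 0.002, 0.994]]
        )
        d = [sample_markov_chain(T, 200_000, seed=s) for s in range(3)]
        lumped = [np.where(x == 0, 0, 1) for x in d]
        cm = largest_connected_set(count_transitions(lumped, lag=1))
        model = estimate_reversible_mle(cm, frame_interval=0.1)
        table = ck_test(
            lumped, model, [np.array([0]), np.array([1])], factors=[1, 10, 50],
            seed=2,
        )
        big = table[table["factor"] == 50]
        outside = (big["predicted"] < big["lo"]) | (big["predicted"] > big["hi"])
        assert outside.any()

    def test_excessive_factor_skipped_with_warning(self):
        model, dtrajs = self._model_and_data(n=5000)
        with pytest.warns(UserWarning, match="horizon"):
            table = ck_test(dtrajs, model, [np.array([0])], factors=[1, 10_000])
        assert set(table["factor"]) == {1}


def test_markov_model_invariants_enforced():
    with pytest.raises(ValueError):
        MarkovModel(
            T=np.array([[0.9, 0.2], [0.1, 0.9]]),  # rows don't sum to 1
            pi=np.array([0.5, 0.5]),
            lag=1,
            frame_interval=0.1,
        )
    with pytest.raises(ValueError, match="balance"):
        # stochastic, stationary pi, but not reversible
        T = np.array(
            [[0.8, 0.15, 0.05], [0.05, 0.8, 0.15], [0.15, 0.05, 0.8]]
        )
        pi = stationary_distribution(T)
        MarkovModel(T=T, pi=pi, lag=1, frame_interval=0.1)


def test_recovery_entrywise_from_sampled_chain(rng):
    T, _ = _random_reversible(4, rng)
    d = sample_markov_chain(T, 500_000, seed=3)
    model = estimate_reversible_mle(
        largest_connected_set(count_transitions([d], lag=1))
    )
    assert np.max(np.abs(model.T - T)) < 5e-3  # ~ n^(-1/2) scale
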