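"""Unit and property tests for the single-level active-inference engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twentyq.io import make_fixture
from twentyq.mdp import (
    LOG_FLOOR,
    BeliefState,
    bayesian_model_average,
    expected_free_energy,
    free_energy,
    occam_prune,
    outcome_surprise,
    policy_posterior,
    safe_log,
    select_outcome,
    softmax,
    update_precision,
    update_states,
)

from oracles import (
    brute_force_efe,
    brute_force_free_energy,
    brute_force_outcome_surprise,
    enumerate_posterior,
)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


class TestSoftmax:
    def test_symmetry(self):
        assert np.allclose(softmax(np.zeros(4)), 0.25)

    def test_closed_form(self):
        assert np.allclose(softmax(np.array([0.0, np.log(3)])), [0.25, 0.75])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([np.inf, 0.0]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-30, 30), min_size=5, max_size=5))
    def test_matches_direct_formula(self, xs):
        x = np.array(xs)
        direct = np.exp(x) / np.exp(x).sum()
        assert np.allclose(softmax(x), direct, atol=1e-12)
        assert np.isclose(softmax(x).sum(), 1.0, atol=1e-12)


class TestSafeLog:
    def test_floor_case(self):
        out = safe_log(np.array([1.0, 0.0]))
        assert out[0] == 0.0
        assert np.isclose(out[1], np.log(LOG_FLOOR))

    def test_closed_form(self):
        assert np.allclose(safe_log(np.array([0.5, 0.5])), np.log(0.5))

    def test_uniform(self):
        K = 7
        assert np.allclose(safe_log(np.full(K, 1 / K)), -np.log(K), atol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            safe_log(np.array([-0.1, 1.1]))


# ---------------------------------------------------------------------------
# state estimation
# ---------------------------------------------------------------------------


def _single_step_model(A, D, C=None):
    m = make_fixture(0, n_states=A.shape[1], n_outcomes=A.shape[0], T=1)
    C = [np.zeros(A.shape[0])] if C is None else C
    return type(m)(
        factors=m.factors, modalities=m.modalities, A=[A], B=m.B, C=C,
        D=[D], policies=m.policies, T=1,
    )


class TestUpdateStates:
    def test_uniform_fixed_point(self):
        """Uninformative likelihood, identity B, uniform D: beliefs stay uniform."""
        m0 = make_fixture(0, n_states=3, n_outcomes=2, T=3)
        m = type(m0)(
            factors=m0.factors, modalities=m0.modalities,
            A=[np.full((2, 3), 0.5)], B=[[np.eye(3)]], C=[np.zeros(2)],
            D=[np.full(3, 1 / 3)], policies=m0.policies, T=3,
        )
        b, tr = update_states(m, [[0], [1], None], iterations=16)
        for t in range(3):
            assert np.allclose(b.s[0][0, t], 1 / 3, atol=1e-9)

    def test_exact_posterior_single_factor_single_step(self):
        A = np.array([[0.9, 0.2], [0.1, 0.8]])
        D = np.array([0.5, 0.5])
        m = _single_step_model(A, D)
        b, _ = update_states(m, [[0]], iterations=200)
        expected = enumerate_posterior(D, A, 0)
        assert np.allclose(b.s[0][0, 0], expected, atol=1e-4)
        assert np.allclose(expected, [9 / 11, 2 / 11])

    @pytest.mark.parametrize("seed", range(8))
    def test_fixed_point_matches_enumeration(self, seed):
        m = make_fixture(seed, n_states=4, n_outcomes=3, T=1)
        o = seed % 3
        b, _ = update_states(m, [[o]], iterations=300)
        expected = enumerate_posterior(m.D[0], m.A[0], o)
        assert np.allclose(b.s[0][0, 0], expected, atol=1e-4)

    @pytest.mark.parametrize("seed", range(6))
    def test_free_energy_descends_single_step(self, seed):
        """F is non-increasing over update iterations on single-step models."""
        m = make_fixture(seed, n_states=(3, 2), n_outcomes=(2, 3), T=1)
        obs = [[0, 1]]
        b, _ = update_states(m, obs, iterations=1)
        prev = free_energy(m, b, obs)[1][0]
        for _ in range(5):
            b, _ = update_states(m, obs, b, iterations=16)
            cur = free_energy(m, b, obs)[1][0]
            assert cur <= prev + 1e-6
            prev = cur

    def test_fixed_point_not_above_initial_free_energy(self):
        m = make_fixture(3, n_states=3, n_outcomes=3, T=1)
        obs = [[2]]
        init = BeliefState.initialise(m)
        f0 = free_energy(m, init, obs)[1][0]
        b, _ = update_states(m, obs, iterations=64)
        f1 = free_energy(m, b, obs)[1][0]
        assert f1 <= f0 + 1e-9

    def test_simplex_invariant_at_every_iteration(self):
        m = make_fixture(5, n_states=(2, 3), n_outcomes=(2,), n_policies=2,
                         n_controls=2, T=3)
        b, tr = update_states(m, [[0], [1], None], iterations=16)
        for arr in b.s:
            assert np.all(arr >= 0)
            assert np.allclose(arr.sum(axis=-1), 1.0, atol=1e-8)
        # traced expectations are distributions too (per factor and time)
        assert np.all(tr.s >= -1e-12)

    def test_trace_has_one_bin_per_iteration(self):
        m = make_fixture(2, n_states=2, n_outcomes=2, T=1)
        _, tr = update_states(m, [[0]], iterations=16)
        assert tr.n_bins == 16
        assert tr.bin_ms == 16.0

    def test_bad_iterations_rejected(self):
        m = make_fixture(2, n_states=2, n_outcomes=2, T=1)
        with pytest.raises(ValueError):
            update_states(m, [[0]], iterations=0)


# ---------------------------------------------------------------------------
# free energies
# ---------------------------------------------------------------------------


class TestFreeEnergy:
    def test_zero_complexity_at_propagated_prior(self):
        """Belief equal to the deterministically propagated prior, with no
        observations, has zero complexity (KL of identical distributions)."""
        m0 = make_fixture(1, n_states=(3,), n_outcomes=(2,), T=3)
        perm = np.roll(np.eye(3), 1, axis=0)  # deterministic cyclic chain
        m = type(m0)(
            factors=m0.factors, modalities=m0.modalities, A=m0.A,
            B=[[perm]], C=m0.C, D=[np.array([1.0, 0.0, 0.0])],
            policies=m0.policies, T=3,
        )
        b = BeliefState.initialise(m)
        F_t, F = free_energy(m, b, None)
        assert np.allclose(F, 0.0, atol=1e-10)

    def test_deterministic_likelihood_accuracy_zero(self):
        """Deterministic A, belief on the generating state: F = complexity."""
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        D = np.array([0.7, 0.3])
        m = _single_step_model(A, D)
        b = BeliefState.initialise(m)
        for arr in b.s:
            arr[0, 0] = [1.0, 0.0]
        b.v = [safe_log(a) for a in b.s]
        F = free_energy(m, b, [[0]])[1][0]
        complexity = np.sum([1.0 * (np.log(1.0) - np.log(0.7))])
        assert np.isclose(F, complexity, atol=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        m = make_fixture(seed, n_states=(2, 3), n_outcomes=(3, 2),
                         n_policies=2, n_controls=2, T=3)
        obs = [[0, 1], [2, None], None]
        b, _ = update_states(m, obs, iterations=8)
        F = free_energy(m, b, obs)[1]
        for p in range(m.n_policies):
            oracle = brute_force_free_energy(m, b, obs, p)
            assert np.isclose(F[p], oracle, atol=1e-10)


class TestExpectedFreeEnergy:
    def test_identity_likelihood_closed_form(self):
        """Identity A over 2 states, uniform prior, flat preferences.

        Flat preferences as a proper distribution: cost C = -ln(1/2) on both
        outcomes, so extrinsic value is -ln 2 and G vanishes exactly.
        """
        A = np.eye(2)
        D = np.array([0.5, 0.5])
        m = _single_step_model(A, D, C=[np.full(2, np.log(2))])
        G, parts = expected_free_energy(m, BeliefState.initialise(m),
                                        return_parts=True)
        assert np.isclose(parts["intrinsic"][0, 0], np.log(2), atol=1e-12)
        assert np.isclose(parts["extrinsic"][0, 0], -np.log(2), atol=1e-12)
        assert np.isclose(G[0], 0.0, atol=1e-12)

    def test_uniform_likelihood_zero_information(self):
        A = np.full((3, 2), 1 / 3)
        D = np.array([0.3, 0.7])
        m = _single_step_model(A, D)
        _, parts = expected_free_energy(m, BeliefState.initialise(m),
                                        return_parts=True)
        assert np.isclose(parts["intrinsic"][0, 0], 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_two_forms_agree(self, seed):
        """Epistemic+pragmatic form equals risk+ambiguity within 1e-10."""
        m = make_fixture(seed, n_states=(2, 3), n_outcomes=(3, 2),
                         n_policies=3, n_controls=2, T=3)
        b = BeliefState.initialise(m)
        G, parts = expected_free_energy(m, b, return_parts=True)
        assert np.allclose(G, parts["G_risk_ambiguity"], atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        m = make_fixture(seed + 50, n_states=(2, 2), n_outcomes=(3,),
                         n_policies=2, n_controls=2, T=2)
        b = BeliefState.initialise(m)
        G, parts = expected_free_energy(m, b, future_times=[1],
                                        return_parts=True)
        for p in range(m.n_policies):
            assert np.isclose(G[p], brute_force_efe(m, b, p, 1), atol=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_intrinsic_value_nonnegative(self, seed):
        m = make_fixture(seed + 10, n_states=(3, 2), n_outcomes=(2, 2),
                         n_policies=2, n_controls=2, T=3)
        _, parts = expected_free_energy(m, BeliefState.initialise(m),
                                        return_parts=True)
        assert np.all(parts["intrinsic"] >= -1e-12)


# ---------------------------------------------------------------------------
# policies, precision, averaging, outcomes
# ---------------------------------------------------------------------------


class TestPolicyPosterior:
    def test_uniform_under_equal_inputs(self):
        pi = policy_posterior(np.zeros(5), np.zeros(5), 1.0)
        assert np.allclose(pi, 0.2)

    def test_strong_preference(self):
        pi = policy_posterior(np.zeros(2), np.array([0.0, 10.0]), 1.0)
        assert pi[0] > 0.9999

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            policy_posterior(np.zeros(2), np.zeros(2), 0.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        st.floats(0.1, 5.0),
        st.floats(-10, 10),
    )
    def test_formula_and_shift_invariance(self, F, G, gamma, c):
        F, G = np.array(F), np.array(G)
        pi = policy_posterior(F, G, gamma)
        direct = np.exp(-F - gamma * G) / np.exp(-F - gamma * G).sum()
        assert np.allclose(pi, direct, atol=1e-12)
        assert np.allclose(pi, policy_posterior(F + c, G, gamma), atol=1e-12)
        assert np.allclose(pi, policy_posterior(F, G + c / gamma, gamma), atol=1e-10)


class TestUpdatePrecision:
    def test_no_update_when_posterior_equals_prior(self):
        res = update_precision(np.zeros(3), np.array([0.1, 0.2, 0.3]),
                               beta_prior=2.0)
        assert np.allclose(res.gammas, 0.5)

    def test_gamma_rises_when_posterior_concentrates_on_low_G(self):
        res = update_precision(np.array([0.0, 10.0]), np.array([0.0, 1.0]),
                               beta_prior=1.0)
        assert res.gammas[-1] > 1.0

    def test_gamma_always_positive(self):
        res = update_precision(np.array([0.0, 50.0]), np.array([-30.0, 30.0]),
                               beta_prior=0.05)
        assert np.all(res.gammas > 0)


class TestBayesianModelAverage:
    def test_single_policy_identity(self):
        s = [np.random.default_rng(0).dirichlet(np.ones(3), size=(1, 2))]
        out = bayesian_model_average(s, np.array([1.0]))
        assert np.allclose(out[0], s[0][0])

    def test_equal_weights_symmetry(self):
        s = [np.array([[[1.0, 0.0]], [[0.0, 1.0]]])]  # [P=2, T=1, K=2]
        out = bayesian_model_average(s, np.array([0.5, 0.5]))
        assert np.allclose(out[0][0], [0.5, 0.5])

    def test_matches_direct_weighted_sum(self, rng):
        s = [rng.dirichlet(np.ones(4), size=(3, 2))]
        pi = rng.dirichlet(np.ones(3))
        out = bayesian_model_average(s, pi)
        direct = np.einsum("p,ptk->tk", pi, s[0])
        assert np.allclose(out[0], direct, atol=1e-12)
        assert np.allclose(out[0].sum(axis=-1), 1.0, atol=1e-12)


class TestSelectOutcome:
    def test_deterministic_likelihood(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        m = _single_step_model(A, np.array([0.5, 0.5]))
        assert select_outcome(m, [np.array([1.0, 0.0])]) == [1]

    def test_uniform_likelihood_tie_break(self):
        A = np.full((3, 2), 1 / 3)
        m = _single_step_model(A, np.array([0.5, 0.5]))
        assert select_outcome(m, [np.array([0.4, 0.6])]) == [0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_argmin(self, seed):
        m = make_fixture(seed, n_states=(2, 2), n_outcomes=3, T=1)
        rng = np.random.default_rng(seed)
        s_next = [rng.dirichlet(np.ones(2)) for _ in range(2)]
        g = outcome_surprise(m, s_next)[0]
        oracle = brute_force_outcome_surprise(m, s_next)
        assert np.allclose(g, oracle, atol=1e-10)
        assert select_outcome(m, s_next)[0] == int(np.argmin(oracle))


class TestOccamPrune:
    def test_keeps_best_and_renormalises(self):
        pi = np.array([0.6, 0.39, 0.01])
        out = occam_prune(pi, window=3.0)
        assert out[2] == 0.0
        assert np.isclose(out.sum(), 1.0)
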