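from __future__ import annotations

import math

import numpy as np
import pytest

from dxtraj.cthmm import (
    MISSING,
    CTHMMParams,
    ObsSequence,
    StateSpace,
    emission,
    estep,
    extract_graph,
    fit_em,
    graph_to_dot,
    interval_kernel_exact,
    interval_kernel_panel,
    loglik,
    mstep,
    observed_label_counts,
    posteriors,
    random_init,
    sequences_from_cohort,
)
from dxtraj.cohort_selection import build_cohort

from conftest import traj
from oracles import enumerate_posteriors, random_instance

SPACE2 = StateSpace(("s1", "s2"))


def two_state(q12=0.5, q21=0.0, b_diag=1.0, pi=(0.5, 0.5)):
    B = np.array([[b_diag, 1 - b_diag], [1 - b_diag, b_diag]])
    return CTHMMParams(SPACE2, pi=np.array(pi), Q=np.array([[0.0, q12], [q21, 0.0]]), B=B)


class TestIntervalKernelExact:
    def test_jump_factor_is_sojourn_density_times_selection(self):
        K = interval_kernel_exact(two_state(q12=0.5), dt=2.0)
        assert K[0, 1] == pytest.approx(0.5 * math.exp(-1.0), abs=1e-12)

    def test_diagonal_is_survival(self):
        K = interval_kernel_exact(two_state(q12=0.5), dt=2.0)
        assert K[0, 0] == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_zero_rate_gives_zero_factor(self):
        K = interval_kernel_exact(two_state(q12=0.5, q21=0.0), dt=3.7)
        assert K[1, 0] == 0.0

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            interval_kernel_exact(two_state(), dt=0.0)


class TestIntervalKernelPanel:
    def test_dt_zero_is_identity(self):
        assert np.array_equal(interval_kernel_panel(two_state(), 0.0), np.eye(2))

    def test_symmetric_two_state_closed_form(self):
        lam, t = 0.7, 1.3
        P = interval_kernel_panel(two_state(q12=lam, q21=lam), t)
        assert P[0, 0] == pytest.approx(0.5 * (1 + math.exp(-2 * lam * t)), abs=1e-12)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_matches_discretization_oracle(self, rng):
        params, _ = random_instance(rng, 3, 2)
        dt = 0.7
        P = interval_kernel_panel(params, dt)
        # (I + G dt/m)^m with m = 2^20 > 1e6, by repeated squaring
        M = np.eye(3) + params.generator() * dt / 2**20
        for _ in range(20):
            M = M @ M
        assert np.abs(P - M).max() < 1e-6


class TestEmission:
    def test_identity_emission_own_label(self):
        assert emission(two_state(), "s1", "s1") == 1.0

    def test_missing_is_uninformative_for_every_state(self):
        p = two_state(b_diag=0.7)
        assert emission(p, "s1", MISSING) == 1.0
        assert emission(p, "s2", MISSING) == 1.0

    def test_lookup(self):
        assert emission(two_state(b_diag=0.8), "s1", "s2") == pytest.approx(0.2)

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            emission(two_state(), "s1", "zz")


class TestLoglik:
    def test_single_visit_identity_emission(self):
        p = two_state(pi=(0.3, 0.7))
        seq = ObsSequence(np.array([0.0]), ("s1",))
        assert loglik(p, seq) == pytest.approx(math.log(0.3), abs=1e-12)

    @pytest.mark.parametrize("kernel", ["exact_times", "panel"])
    @pytest.mark.parametrize("n_states,n_visits", [(2, 3), (2, 5), (3, 4)])
    def test_matches_path_enumeration(self, rng, kernel, n_states, n_visits):
        for _ in range(5):
            params, seq = random_instance(rng, n_states, n_visits)
            expected = enumerate_posteriors(params, seq, kernel)[0]
            assert loglik(params, seq, kernel) == pytest.approx(expected, abs=1e-10)

    def test_all_missing_equals_total_path_mass(self, rng):
        params, seq = random_instance(rng, 2, 4, missing_rate=1.0)
        expected = enumerate_posteriors(params, seq)[0]
        assert loglik(params, seq) == pytest.approx(expected, abs=1e-10)
        # under panel semantics the kernel rows are probabilities, so the
        # total path mass of an uninformative sequence is exactly 1
        assert loglik(params, seq, kernel="panel") == pytest.approx(0.0, abs=1e-12)

    def test_zero_probability_sequence_warns_minus_inf(self):
        p = two_state(b_diag=1.0, pi=(1.0, 0.0), q12=0.0)
        seq = ObsSequence(np.array([0.0, 1.0]), ("s1", "s2"))  # unreachable
        with pytest.warns(UserWarning, match="zero probability"):
            assert loglik(p, seq) == -np.inf


class TestPosteriors:
    def test_identity_emission_fully_observed_is_one_hot(self):
        p = two_state(q12=0.4, q21=0.3, pi=(0.5, 0.5))
        seq = ObsSequence(np.array([0.0, 1.0, 2.5]), ("s1", "s2", "s1"))
        gamma, xi = posteriors(p, seq)
        assert np.allclose(gamma, [[1, 0], [0, 1], [1, 0]])
        assert xi.shape == (2, 2, 2)

    def test_symmetric_model_gives_symmetric_marginals(self):
        p = two_state(q12=0.5, q21=0.5, b_diag=0.8, pi=(0.5, 0.5))
        seq = ObsSequence(np.array([0.0, 1.0]), (MISSING, MISSING))
        gamma, _ = posteriors(p, seq)
        assert np.allclose(gamma, 0.5)

    def test_rows_sum_to_one_and_xi_marginalizes(self, rng):
        for _ in range(5):
            params, seq = random_instance(rng, 3, 5)
            ll = loglik(params, seq)
            if ll == -np.inf:
                continue
            gamma, xi = posteriors(params, seq)
            assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
            for v in range(len(seq) - 1):
                assert np.allclose(xi[v].sum(axis=1), gamma[v], atol=1e-10)
                assert np.allclose(xi[v].sum(axis=0), gamma[v + 1], atol=1e-10)

    def test_matches_path_enumeration(self, rng):
        params, seq = random_instance(rng, 3, 4)
        _, gamma_e, xi_e, _ = enumerate_posteriors(params, seq)
        gamma, xi = posteriors(params, seq)
        assert np.abs(gamma - gamma_e).max() < 1e-10
        assert np.abs(xi - xi_e).max() < 1e-10


class TestEstep:
    def test_fully_observed_degenerate_counts(self):
        p = two_state(q12=0.5, q21=0.3)
        seq = ObsSequence(np.array([0.0, 2.0, 3.0]), ("s1", "s2", "s2"))
        stats = estep(p, [seq])
        assert stats.n_ij[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert stats.n_ij[1, 0] == pytest.approx(0.0, abs=1e-12)
        assert stats.T_i == pytest.approx([2.0, 1.0], abs=1e-12)
        assert stats.m_ik[0, 0] == pytest.approx(1.0) and stats.m_ik[1, 1] == pytest.approx(2.0)

    def test_sojourn_conservation(self, rng):
        seqs = [random_instance(rng, 3, k)[1] for k in (2, 3, 5)]
        params = random_instance(rng, 3, 2)[0]
        stats = estep(params, seqs)
        total = sum(s.times[-1] for s in seqs)
        assert stats.total_time == pytest.approx(total, abs=1e-8)

    def test_matches_enumeration_with_uncertain_emissions(self, rng):
        for _ in range(5):
            params, seq = random_instance(rng, 2, 4, missing_rate=0.5)
            _, _, _, expected = enumerate_posteriors(params, seq)
            stats = estep(params, [seq])
            assert np.abs(stats.n_ij - expected["n_ij"]).max() < 1e-10
            assert np.abs(stats.T_i - expected["T_i"]).max() < 1e-10
            assert np.abs(stats.m_ik - expected["m_ik"]).max() < 1e-10
            assert np.abs(stats.g_i - expected["g_i"]).max() < 1e-10

    def test_panel_kernel_not_implemented(self):
        seq = ObsSequence(np.array([0.0, 1.0]), ("s1", "s2"))
        with pytest.raises(NotImplementedError):
            estep(two_state(), [seq], kernel="panel")


class TestMstep:
    def test_rate_is_jumps_over_sojourn(self):
        p = two_state()
        stats = estep(p, [ObsSequence(np.array([0.0, 2.0, 3.0]), ("s1", "s2", "s2"))])
        new = mstep(stats, SPACE2, prev=p)
        assert new.Q[0, 1] == 0.5  # 1 jump / 2 years, exactly
        assert new.Q[1, 0] == 0.0

    def test_emission_rows_normalised_with_floor(self):
        p = two_state(b_diag=0.9)
        seq = ObsSequence(np.array([0.0, 1.0, 2.0]), ("s1", "s1", "s2"))
        stats = estep(p, [seq])
        new = mstep(stats, SPACE2, prev=p)
        assert np.allclose(new.B.sum(axis=1), 1.0)
        assert (new.B > 0).all()

    def test_empty_state_keeps_previous_emission_row(self):
        p = two_state(q12=0.0, q21=0.0, b_diag=0.9, pi=(1.0, 0.0))
        seq = ObsSequence(np.array([0.0, 1.0]), ("s1", "s1"))
        stats = estep(p, [seq])
        new = mstep(stats, SPACE2, prev=p)
        assert np.allclose(new.B[1], p.B[1])


class TestFitEM:
    def _sim_sequences(self, rng, n=30):
        from dxtraj.synthetic_data import GeneratorConfig, generate_trajectories

        cfg = GeneratorConfig.default(n_patients=n, seed=int(rng.integers(2**31)), horizon=5.0)
        trajectories, _ = generate_trajectories(cfg)
        space = cfg.truth.state_space
        return sequences_from_cohort([(t, 0) for t in trajectories], space), space

    def test_loglik_trace_non_decreasing(self, rng):
        seqs, space = self._sim_sequences(rng)
        fit = fit_em(seqs, space, seed=1, n_restarts=1, max_iter=40)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-9).all()

    def test_same_seed_bit_identical_traces(self, rng):
        seqs, space = self._sim_sequences(rng)
        a = fit_em(seqs, space, seed=3, n_restarts=2, max_iter=15)
        b = fit_em(seqs, space, seed=3, n_restarts=2, max_iter=15)
        assert a.loglik_trace == b.loglik_trace
        assert np.array_equal(a.params.Q, b.params.Q)

    def test_start_at_truth_stays_within_tolerance(self, rng):
        from dxtraj.synthetic_data import GeneratorConfig, generate_trajectories

        cfg = GeneratorConfig.default(n_patients=200, seed=9)
        trajectories, _ = generate_trajectories(cfg)
        space = cfg.truth.state_space
        seqs = sequences_from_cohort([(t, 0) for t in trajectories], space)
        fit = fit_em(seqs, space, init=cfg.truth, max_iter=2)
        assert fit.loglik_trace[1] >= fit.loglik_trace[0] - 1e-9

    def test_all_zero_probability_raises_with_smoothing_hint(self):
        p = two_state(b_diag=1.0, pi=(1.0, 0.0), q12=0.0)
        seq = ObsSequence(np.array([0.0, 1.0]), ("s2", "s2"))
        with pytest.raises(ValueError, match="smoothing"):
            with pytest.warns(UserWarning):
                fit_em([seq], SPACE2, init=p, max_iter=3)


class TestExtractGraph:
    def _params(self, qAB, qBT, qAT=0.0):
        space = StateSpace(("A", "B", "F20"))
        Q = np.zeros((3, 3))
        Q[0, 1], Q[1, 2], Q[0, 2] = qAB, qBT, qAT
        B = np.eye(3) * 0.9 + 0.05
        B /= B.sum(axis=1, keepdims=True)
        return CTHMMParams(space, pi=np.ones(3) / 3, Q=Q, B=B)

    def test_all_edges_below_threshold_leaves_target_only(self):
        G = extract_graph(self._params(0.01, 0.02), {"A": 5, "B": 5, "F20": 9}, q_threshold=0.05)
        assert set(G.nodes) == {"F20"}

    def test_chain_to_target_is_retained(self):
        G = extract_graph(self._params(0.3, 0.4), {"A": 5, "B": 5, "F20": 9}, q_threshold=0.05)
        assert set(G.nodes) == {"A", "B", "F20"}
        assert G.edges["A", "B"]["rate"] == pytest.approx(0.3)
        assert G.edges["A", "B"]["embedded_prob"] == pytest.approx(1.0)

    def test_node_unreachable_after_edge_pruning_is_dropped(self):
        # A reaches F20 only through the sub-threshold A->B edge
        G = extract_graph(self._params(0.01, 0.4), {"A": 5, "B": 5, "F20": 9}, q_threshold=0.05)
        assert set(G.nodes) == {"B", "F20"}

    def test_zero_frequency_node_dropped(self):
        G = extract_graph(self._params(0.3, 0.4), {"A": 0, "B": 5, "F20": 9}, q_threshold=0.05)
        assert set(G.nodes) == {"B", "F20"}

    def test_unknown_target_raises(self):
        with pytest.raises(KeyError):
            extract_graph(self._params(0.3, 0.4), {}, target="F99")

    def test_dot_export_lists_nodes_and_edges(self):
        G = extract_graph(self._params(0.3, 0.4), {"A": 5, "B": 5, "F20": 9}, q_threshold=0.05)
        dot = graph_to_dot(G)
        assert '"A" -> "B"' in dot and dot.startswith("digraph")


class TestSequencesFromCohort:
    def test_first_code_only_and_missing(self):
        cohort = build_cohort(
            [traj("p", [(0, "F3", "F6"), (10,), (20, "F20"), (30, "F22")])]
        )
        space = StateSpace(("F3", "F20", "F22", "other"))
        (seq,) = sequences_from_cohort(cohort, space, other_label="other")
        assert seq.observations == ("F3", MISSING, "F20", "F22")
        assert seq.times[0] == 0.0 and np.all(np.diff(seq.times) > 0)

    def test_same_day_visits_get_half_day_gap(self):
        cohort = build_cohort(
            [traj("p", [(0, "F20"), (0, "F20"), (5, "F20")])]
        )
        space = StateSpace(("F20", "other"))
        (seq,) = sequences_from_cohort(cohort, space, other_label="other")
        assert seq.times[1] == pytest.approx(0.5 / 365.25)

    def test_out_of_space_label_without_other_raises(self):
        cohort = build_cohort([traj("p", [(0, "F9"), (10, "F20"), (20, "F20")])])
        with pytest.raises(KeyError, match="F9"):
            sequences_from_cohort(cohort, StateSpace(("F20", "F22")))

    def test_observed_label_counts(self):
        space = StateSpace(("F20", "F22"))
        seqs = [ObsSequence(np.array([0.0, 1.0]), ("F20", MISSING))]
        assert observed_label_counts(seqs, space) == {"F20": 1, "F22": 0}
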