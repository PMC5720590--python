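"""Transition counting, transpose symmetrization, stationary distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from allomsm.msm import (
    build_msm,
    count_transitions,
    raw_occupancy,
    stationary_distribution,
    symmetrize_transpose,
    top_occupied,
    transition_matrix,
)
from allomsm.synthetic import analytic_stationary, metastable_chain, sample_state_path
from oracles import brute_top_fraction


class TestCounting:
    def test_sliding_window_lag_one(self):
        C = count_transitions([np.array([0, 0, 1, 1])], 2, lag=1).counts
        assert np.array_equal(C, [[1, 1], [0, 1]])

    def test_sliding_window_lag_three(self):
        C = count_transitions([np.array([0, 0, 1, 1])], 2, lag=3).counts
        assert np.array_equal(C, [[0, 1], [0, 0]])

    def test_no_counts_across_replicate_boundaries(self):
        C = count_transitions([np.array([0, 1]), np.array([1, 0])], 2, lag=1).counts
        assert np.array_equal(C, [[0, 1], [1, 0]])

    def test_short_replicate_is_named_in_the_error(self):
        with pytest.raises(ValueError, match="replicate 1"):
            count_transitions([np.array([0, 1, 0]), np.array([0])], 2, lag=1)

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        seqs = [rng.integers(0, 5, size=n) for n in (50, 80, 20)]
        lag = 3
        cm = count_transitions(seqs, 5, lag=lag)
        assert cm.total == sum(len(s) - lag for s in seqs)
        assert symmetrize_transpose(cm).sum() == pytest.approx(cm.total)


class TestEstimator:
    def test_transpose_symmetrization_arithmetic(self):
        C = np.array([[1, 1], [0, 1]])
        assert np.array_equal(symmetrize_transpose(C), [[1.0, 0.5], [0.5, 1.0]])
        sym = np.array([[3.0, 2.0], [2.0, 5.0]])
        assert np.array_equal(symmetrize_transpose(sym), sym)
        assert np.array_equal(symmetrize_transpose(np.zeros((3, 3))),
                              np.zeros((3, 3)))

    def test_row_normalization(self):
        T, zero = transition_matrix(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert np.allclose(T, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]])
        assert not zero.any()
        T, _ = transition_matrix(np.array([[8.0, 2.0], [2.0, 8.0]]))
        assert np.allclose(T, [[0.8, 0.2], [0.2, 0.8]])

    def test_zero_row_becomes_identity_and_is_flagged(self):
        Cs = np.array([[2.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 4.0]])
        T, zero = transition_matrix(Cs)
        assert T[1, 1] == 1.0 and T[1, 0] == 0.0
        assert list(zero) == [False, True, False]
        pi = stationary_distribution(Cs)
        assert pi[1] == 0.0

    def test_stationary_closed_form(self):
        assert np.allclose(
            stationary_distribution(np.array([[1.0, 0.5], [0.5, 1.0]])), [0.5, 0.5])
        assert np.allclose(
            stationary_distribution(np.array([[6.0, 2.0], [2.0, 0.0]])), [0.8, 0.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hnp.arrays(np.int64, (5, 5), elements=st.integers(0, 30)))
    def test_detailed_balance_and_stationarity_exact(self, C):
        """pi_i T_ij == pi_j T_ji and pi T == pi, to 1e-12, for any counts."""
        if C.sum() == 0:
            C[0, 1] = 1
        Cs = symmetrize_transpose(C)
        T, _ = transition_matrix(Cs)
        pi = stationary_distribution(Cs)
        flux = pi[:, None] * T
        assert np.max(np.abs(flux - flux.T)) <= 1e-12
        assert np.max(np.abs(pi @ T - pi)) <= 1e-12
        assert np.max(np.abs(T.sum(axis=1) - 1.0)) <= 1e-12
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_stationary_matches_leading_left_eigenvector(self):
        rng = np.random.default_rng(1)
        C = rng.integers(1, 50, size=(6, 6))
        Cs = symmetrize_transpose(C)
        T, _ = transition_matrix(Cs)
        pi = stationary_distribution(Cs)
        w, v = np.linalg.eig(T.T)
        lead = np.real(v[:, np.argmax(np.real(w))])
        lead = lead / lead.sum()
        assert np.allclose(pi, lead, atol=1e-10)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.zeros((3, 3)))


class TestRecovery:
    def test_reversible_chain_parameters_recovered(self):
        """200k steps of a planted reversible 4-state chain: pi within 3
        asymptotic SEs (Markov-chain CLT), T within 3 conditional SEs."""
        pi = np.array([0.35, 0.30, 0.20, 0.15])
        T = metastable_chain(pi, 0.5)
        n = 200_000
        path = sample_state_path(T, n, 0, seed=12345)
        msm = build_msm(count_transitions([path], 4, lag=1))
        Z = np.linalg.inv(np.eye(4) - T + np.outer(np.ones(4), pi))
        se_pi = np.sqrt(pi * (2 * np.diag(Z) - 1 - pi) / n)
        assert np.all(np.abs(msm.stationary - pi) <= 3 * se_pi)
        visits = np.bincount(path[:-1], minlength=4)
        se_T = np.sqrt(T * (1 - T) / visits[:, None])
        assert np.all(np.abs(msm.transition - T) <= 3 * se_T)

    def test_irreversible_chain_converges_to_symmetrized_flux(self):
        """The transpose estimator's documented bias: it converges to the
        row-normalized additive symmetrization of the stationary flux,
        whose stationary distribution still equals the true one."""
        T = np.array([[0.1, 0.7, 0.1, 0.1],
                      [0.1, 0.1, 0.7, 0.1],
                      [0.1, 0.1, 0.1, 0.7],
                      [0.7, 0.1, 0.1, 0.1]])
        p = analytic_stationary(T)
        flux = p[:, None] * T
        sym_flux = (flux + flux.T) / 2
        target = sym_flux / sym_flux.sum(axis=1, keepdims=True)
        path = sample_state_path(T, 200_000, 0, seed=999)
        msm = build_msm(count_transitions([path], 4, lag=1))
        assert np.max(np.abs(msm.transition - target)) < 0.01
        assert np.max(np.abs(msm.transition - T)) > 0.2  # bias is real
        assert np.max(np.abs(msm.stationary - p)) < 0.01


class TestSelection:
    def test_five_percent_of_hundred_is_five(self):
        rng = np.random.default_rng(2)
        pi = rng.dirichlet(np.ones(100))
        assert len(top_occupied(pi, 0.05)) == 5

    def test_ceil_guarantees_nonempty_selection(self):
        assert list(top_occupied(np.array([0.5, 0.3, 0.2]), 0.05)) == [0]

    def test_boundary_tie_goes_to_lower_index(self):
        pi = np.array([0.4, 0.2, 0.2, 0.2])
        sel = top_occupied(pi, 0.5)  # ceil(0.5*4) = 2
        assert list(sel) == [0, 1]

    def test_zero_occupancy_states_shrink_the_denominator(self):
        pi = np.array([0.5, 0.5] + [0.0] * 38)
        assert len(top_occupied(pi, 0.05)) == 1  # ceil(0.05 * 2)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            top_occupied(np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            top_occupied(np.array([1.0]), 1.5)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 1.0))
    def test_matches_brute_force_sort(self, seed, fraction):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        pi = rng.dirichlet(np.ones(n))
        if rng.random() < 0.5:  # inject zeros and exact ties
            pi[rng.integers(0, n)] = 0.0
            if n >= 2:
                pi[0] = pi[-1]
            s = pi.sum()
            if s == 0:
                pi[0] = 1.0
                s = 1.0
            pi = pi / s
        assert np.array_equal(top_occupied(pi, fraction),
                              brute_top_fraction(pi, fraction))


def test_raw_occupancy_counts_frames():
    occ = raw_occupancy([np.array([0, 0, 1]), np.array([2, 2, 2, 1])], 4)
    assert np.allclose(occ, [2 / 7, 2 / 7, 3 / 7, 0.0])
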