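"""Markov-state-model estimation, validation, and PCCA+ coarse-graining."""

import itertools

import numpy as np
import pytest

import loopflex as lf
from loopflex.errors import ValidationError
from loopflex.msm import mfpt_to_set


def three_state_chain():
    """A reversible 3-state chain with known T and pi (edge-weight build)."""
    x = np.array([[8.0, 1.0, 0.5], [1.0, 6.0, 0.8], [0.5, 0.8, 4.0]])
    T = x / x.sum(axis=1, keepdims=True)
    pi = x.sum(axis=1) / x.sum()
    return T, pi


def block_chain():
    """4 states, two metastable blocks {0,1} and {2,3}."""
    T = np.array([[0.49, 0.49, 0.01, 0.01],
                  [0.49, 0.49, 0.01, 0.01],
                  [0.01, 0.01, 0.49, 0.49],
                  [0.01, 0.01, 0.49, 0.49]])
    return T, np.full(4, 0.25)


def brute_force_best_2partition(T):
    """Maximize the metastability sum_M T(M, M) over all 2-partitions."""
    n = T.shape[0]
    best, best_parts = -np.inf, None
    for size in range(1, n // 2 + 1):
        for members in itertools.combinations(range(n), size):
            A = set(members)
            B = set(range(n)) - A
            score = sum(T[i, j] for i in A for j in A) / len(A) \
                + sum(T[i, j] for i in B for j in B) / len(B)
            if score > best:
                best, best_parts = score, (A, B)
    return best_parts


class TestCountMatrix:
    def test_hand_enumerated(self):
        C = lf.count_matrix([np.array([0, 0, 1, 1, 0])], lag=1)
        assert np.array_equal(C, [[1, 1], [1, 1]])

    def test_constant_trajectory(self):
        C = lf.count_matrix([np.zeros(7, dtype=int)], lag=1)
        assert C[0, 0] == 6

    def test_boundary_lag(self):
        C = lf.count_matrix([np.array([0, 1, 0, 1])], lag=3)
        assert C.sum() == 1

    def test_no_cross_trajectory_pairs(self):
        a = np.zeros(5, dtype=int)
        b = np.ones(5, dtype=int)
        C = lf.count_matrix([a, b], lag=1)
        assert C[0, 1] == 0 and C[1, 0] == 0

    def test_short_trajectories_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            C = lf.count_matrix([np.array([0, 1, 0, 1]), np.array([1])],
                                lag=2)
        assert C.sum() == 2
        with pytest.raises(ValidationError):
            lf.count_matrix([np.array([1])], lag=2)


class TestConnectivity:
    def test_block_example(self):
        C = np.array([[5.0, 0, 0], [0, 3, 1], [0, 1, 2]])
        members, frac = lf.largest_connected_set(C)
        assert set(members) == {1, 2}
        assert frac == pytest.approx(2 / 3)

    def test_dense_all_connected(self):
        members, frac = lf.largest_connected_set(np.ones((4, 4)))
        assert members.size == 4 and frac == 1.0

    def test_one_way_edge_not_connected(self):
        C = np.array([[1.0, 2.0], [0.0, 1.0]])
        members, frac = lf.largest_connected_set(C)
        assert members.size == 1


class TestReversibleMLE:
    def test_symmetric_counts_row_normalized(self):
        C = np.array([[90.0, 10.0], [10.0, 90.0]])
        T, pi = lf.reversible_mle(C)
        assert np.allclose(T, [[0.9, 0.1], [0.1, 0.9]], atol=1e-10)
        assert np.allclose(pi, [0.5, 0.5], atol=1e-10)

    def test_detailed_balance_holds(self):
        rng = np.random.default_rng(3)
        C = rng.integers(1, 60, (6, 6)).astype(float)
        T, pi = lf.reversible_mle(C)
        flux = pi[:, None] * T
        assert np.max(np.abs(flux - flux.T)) < 1e-10
        assert np.max(np.abs(T.sum(axis=1) - 1.0)) < 1e-12
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(4)
        T0, _ = three_state_chain()
        d = lf.sample_markov_chain(T0, 20_000, 0, seed=9)
        fwd = lf.estimate_msm([d.states], lag=1)
        rev = lf.estimate_msm([d.states[::-1]], lag=1)
        assert np.max(np.abs(fwd.T - rev.T)) < 1e-12

    def test_recovery_from_long_trajectory(self):
        T0, pi0 = three_state_chain()
        d = lf.sample_markov_chain(T0, 200_000, 0, seed=10)
        model = lf.estimate_msm([d.states], lag=1)
        assert np.max(np.abs(model.T - T0)) < 0.02
        assert np.max(np.abs(model.pi - pi0)) < 0.02


class TestImpliedTimescales:
    def test_closed_form_two_state(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        ts = lf.implied_timescales(T, lag=1)
        assert ts[0] == pytest.approx(-1 / np.log(0.8), abs=1e-10)

    def test_identity_infinite(self):
        ts = lf.implied_timescales(np.eye(3), lag=1)
        assert np.isinf(ts).all()

    def test_lag_doubling_consistency(self):
        T, _ = three_state_chain()
        t1 = lf.implied_timescales(T, lag=1)
        t2 = lf.implied_timescales(np.linalg.matrix_power(T, 2), lag=2)
        assert np.allclose(t1, t2, atol=1e-10)


class TestITSScan:
    def test_markovian_data_flat(self):
        T, _ = three_state_chain()
        d = lf.sample_markov_chain(T, 500_000, 0, seed=11)
        table = lf.its_scan([d.states], lags=[1, 2, 4, 8], n_timescales=1)
        t2 = table["t2"].to_numpy()
        assert np.max(np.abs(t2 - t2[0]) / t2[0]) < 0.10

    def test_single_lag_single_row(self):
        T, _ = three_state_chain()
        d = lf.sample_markov_chain(T, 5_000, 0, seed=12)
        table = lf.its_scan([d.states], lags=[1])
        assert len(table) == 1

    def test_lumped_observable_timescale_grows(self):
        """Hiding a 3-state chain behind 2 symbols induces memory: the
        apparent slow timescale increases with lag before plateauing."""
        T = np.array([[0.97, 0.03, 0.00],
                      [0.03, 0.94, 0.03],
                      [0.00, 0.03, 0.97]])
        d = lf.sample_markov_chain(T, 500_000, 0, seed=13)
        lumped = np.where(d.states == 2, 1, 0)
        table = lf.its_scan([lumped], lags=[1, 5, 20], n_timescales=1)
        t2 = table["t2"].to_numpy()
        assert t2[0] < t2[1] < t2[2] * 1.05


class TestCKTest:
    def test_exact_chain_small_deviation(self):
        T, _ = three_state_chain()
        d = lf.sample_markov_chain(T, 200_000, 0, seed=14)
        table = lf.ck_test([d.states], lag=1, factors=(2, 3, 4, 5))
        assert np.all(table["max_deviation"].to_numpy() <= 0.02)

    def test_factor_one_identity(self):
        T, _ = three_state_chain()
        d = lf.sample_markov_chain(T, 5_000, 0, seed=15)
        table = lf.ck_test([d.states], lag=1, factors=(1,))
        assert table["max_deviation"].iloc[0] == 0.0

    def test_deterministic_flip_flop_exact(self):
        d = np.tile([0, 1], 500)
        table = lf.ck_test([d], lag=1, factors=(2, 3))
        assert np.all(table["max_deviation"].to_numpy() < 1e-12)


class TestPCCAPlus:
    def test_block_recovery_matches_brute_force(self):
        T, pi = block_chain()
        macro = lf.pcca_plus(T, pi, 2)
        A, B = brute_force_best_2partition(T)
        got_A = set(np.flatnonzero(macro.assignment
                                   == macro.assignment[min(A)]))
        assert got_A in (A, B)
        assert np.allclose(sorted(macro.probabilities), [0.5, 0.5],
                           atol=1e-10)

    def test_full_resolution_is_permutation(self):
        T, pi = three_state_chain()
        macro = lf.pcca_plus(T, pi, 3)
        # memberships are (a permutation of) the identity: one-hot rows
        chi = macro.memberships
        assert np.allclose(np.sort(chi, axis=1)[:, :-1], 0.0, atol=1e-8)
        assert np.allclose(chi.max(axis=1), 1.0, atol=1e-8)
        assert sorted(macro.assignment.tolist()) == [0, 1, 2]
        assert np.allclose(np.sort(macro.probabilities), np.sort(pi),
                           atol=1e-10)

    def test_membership_rows_sum_to_one(self):
        T, pi = block_chain()
        macro = lf.pcca_plus(T, pi, 2)
        assert np.allclose(macro.memberships.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(macro.memberships >= 0)

    def test_invalid_macrostate_count(self):
        T, pi = block_chain()
        with pytest.raises(ValidationError):
            lf.pcca_plus(T, pi, 1)
        with pytest.raises(ValidationError):
            lf.pcca_plus(T, pi, 5)


class TestMFPT:
    def test_two_state_geometric(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        m = mfpt_to_set(T, np.array([1]))
        assert m[0] == pytest.approx(10.0, abs=1e-10)

    def test_macrostate_diagonal_zero_and_symmetry(self):
        T, pi = block_chain()
        macro = lf.pcca_plus(T, pi, 2)
        M = lf.macrostate_mfpt(T, pi, macro.assignment, frame_interval=2.0)
        assert M[0, 0] == 0.0 and M[1, 1] == 0.0
        assert M[0, 1] == pytest.approx(M[1, 0], abs=1e-9)
        assert M[0, 1] > 0

    def test_unreachable_target_infinite(self):
        T = np.array([[1.0, 0.0], [0.5, 0.5]])
        m = mfpt_to_set(T, np.array([1]))
        assert np.isinf(m[0])


class TestRepresentatives:
    def test_single_macrostate_nearest_global_centroid(self):
        T, pi = block_chain()
        macro = lf.pcca_plus(T, pi, 2)
        centers = np.array([[0.0], [1.0], [10.0], [11.0]])
        frames = np.array([[0.2], [0.7], [10.4], [10.9]])
        reps = lf.macrostate_representatives(macro, centers, frames, pi=pi)
        assert len(set(reps.tolist())) == 2
        for k in range(2):
            members = set(np.flatnonzero(macro.assignment == k))
            # representative frame lies in the same block as the macrostate
            assert reps[k] in (members if members == {0, 1} else {2, 3})

    def test_tie_breaks_to_lowest_frame(self):
        T, pi = block_chain()
        macro = lf.pcca_plus(T, pi, 2)
        centers = np.array([[0.0], [0.0], [5.0], [5.0]])
        frames = np.array([[0.0], [0.0], [5.0], [5.0]])
        reps = lf.macrostate_representatives(macro, centers, frames, pi=pi)
        a = macro.assignment
        first_block = set(np.flatnonzero(a == a[0]))
        assert set(reps.tolist()) == {0, 2}


class TestEstimateMSM:
    def test_invariants_on_random_chain(self):
        T0, _ = three_state_chain()
        d = lf.sample_markov_chain(T0, 50_000, 0, seed=16)
        model = lf.estimate_msm([d.states], lag=2, frame_interval=0.5)
        assert model.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert np.all(model.T >= 0)
        flux = model.pi[:, None] * model.T
        assert np.max(np.abs(flux - flux.T)) < 1e-10
        assert model.lag_time == 1.0
        ts = model.timescales(2)
        assert np.all(np.diff(ts) <= 1e-12)
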