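import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dissimilarity
from vivoplan.dissimilarity import DissimilarityMatrix
from vivoplan.matching import (
    MatchingError,
    SubmatchPartition,
    brute_force,
    count_partitions,
    partition_cost,
    solve_exact,
    solve_ga,
)
from vivoplan.matching import _lower_bound


def _pair_instance():
    # units 0-1 and 2-3 are close, everything else is far
    M = np.full((4, 4), 10.0)
    np.fill_diagonal(M, 0.0)
    M[0, 1] = M[1, 0] = 1.0
    M[2, 3] = M[3, 2] = 1.0
    return DissimilarityMatrix(M)


class TestPartitionCost:
    def test_pairs_sum_their_edges(self):
        D = _pair_instance()
        p = SubmatchPartition([(0, 1), (2, 3)], 0.0, "brute_force", True)
        assert partition_cost(p, D) == 2.0

    def test_triple_has_three_edges(self, rng):
        D = random_dissimilarity(rng, 6)
        p = SubmatchPartition([(0, 1, 2), (3, 4, 5)], 0.0, "brute_force", True)
        expected = sum(D[i, j] for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)])
        assert partition_cost(p, D) == pytest.approx(expected)

    def test_zero_matrix_costs_zero(self):
        D = DissimilarityMatrix(np.zeros((6, 6)))
        p = SubmatchPartition([(0, 3), (1, 4), (2, 5)], 0.0, "exact", True)
        assert partition_cost(p, D) == 0.0

    def test_equals_half_hadamard_sum_with_matching_matrix(self, rng):
        D = random_dissimilarity(rng, 8)
        p = brute_force(D, 4)
        X = p.matching_matrix()
        assert p.total_cost == pytest.approx(0.5 * float((X * D.values).sum()))


class TestCountPartitions:
    @pytest.mark.parametrize("n,G,expected", [(6, 2, 15), (6, 3, 10), (2, 2, 1), (8, 4, 35)])
    def test_closed_form_counts(self, n, G, expected):
        assert count_partitions(n, G) == expected


class TestBruteForce:
    def test_recovers_obvious_pairing(self):
        p = brute_force(_pair_instance(), 2)
        assert p.submatches == [(0, 1), (2, 3)]
        assert p.total_cost == 2.0
        assert p.optimal

    def test_single_pair(self):
        D = DissimilarityMatrix(np.array([[0.0, 3.0], [3.0, 0.0]]))
        p = brute_force(D, 2)
        assert p.submatches == [(0, 1)] and p.total_cost == 3.0

    def test_guard_on_instance_size(self, rng):
        D = random_dissimilarity(rng, 30)
        with pytest.raises(MatchingError, match="partitions"):
            brute_force(D, 2, max_partitions=100)


class TestSolveExact:
    def test_small_pairing(self):
        p = solve_exact(_pair_instance(), 2)
        assert p.submatches == [(0, 1), (2, 3)] and p.total_cost == 2.0 and p.optimal

    def test_single_submatch_when_n_equals_g(self, rng):
        D = random_dissimilarity(rng, 4)
        p = solve_exact(D, 4)
        assert p.submatches == [(0, 1, 2, 3)]
        assert p.total_cost == pytest.approx(float(np.triu(D.values, 1).sum()))

    def test_indivisible_n_reports_remainder(self, rng):
        D = random_dissimilarity(rng, 7)
        with pytest.raises(MatchingError, match="remainder 1"):
            solve_exact(D, 3)

    def test_strict_infeasibility_detected(self):
        # three units mutually incompatible with the fourth's stratum
        M = np.full((4, 4), np.inf)
        np.fill_diagonal(M, 0.0)
        M[0, 1] = M[1, 0] = 1.0  # only one finite pair: no full pairing exists
        with pytest.raises(MatchingError, match="infeasib"):
            solve_exact(DissimilarityMatrix(M), 2)

    def test_strict_blocks_are_respected(self):
        # two strata of 2 under strict mode force within-stratum pairs
        M = np.array(
            [[0.0, 9.0, np.inf, np.inf],
             [9.0, 0.0, np.inf, np.inf],
             [np.inf, np.inf, 0.0, 9.0],
             [np.inf, np.inf, 9.0, 0.0]]
        )
        p = solve_exact(DissimilarityMatrix(M), 2)
        assert p.submatches == [(0, 1), (2, 3)]

    def test_many_submatches(self, rng):
        D = random_dissimilarity(rng, 15)
        p = solve_exact(D, 5)
        assert len(p.submatches) == 3 and p.optimal
        assert p.total_cost == pytest.approx(brute_force(D, 5).total_cost)

    def test_lower_bound_is_admissible(self, rng):
        # the bound on the full instance never exceeds the true optimum
        for _ in range(20):
            D = random_dissimilarity(rng, 8)
            for G in (2, 4):
                bound = _lower_bound(D.values.copy(), np.arange(8), G)
                assert bound <= brute_force(D, G).total_cost + 1e-9

    def test_deterministic_tie_break_lexicographic(self):
        D = DissimilarityMatrix(np.ones((4, 4)) - np.eye(4))
        p = solve_exact(D, 2)
        assert p.submatches == [(0, 1), (2, 3)]  # all pairings tie at cost 2


class TestSolveGa:
    def test_finds_known_optimum_on_small_instance(self):
        p = solve_ga(_pair_instance(), 2, seed=3)
        assert p.total_cost == 2.0
        assert not p.optimal

    def test_seeded_determinism(self, rng):
        D = random_dissimilarity(rng, 12)
        p1 = solve_ga(D, 3, seed=7)
        p2 = solve_ga(D, 3, seed=7)
        assert p1.submatches == p2.submatches and p1.total_cost == p2.total_cost

    def test_never_beats_exact(self, rng):
        for _ in range(5):
            D = random_dissimilarity(rng, 9)
            assert solve_ga(D, 3, seed=1).total_cost >= solve_exact(D, 3).total_cost - 1e-9

    def test_medium_instance_valid(self, rng):
        D = random_dissimilarity(rng, 60)
        p = solve_ga(D, 3, seed=5, generations=120, stall_generations=40)
        assert len(p.submatches) == 20
        _assert_matching_invariants(p)


def _assert_matching_invariants(p: SubmatchPartition):
    n, G = p.n_units, p.group_size
    flat = sorted(u for m in p.submatches for u in m)
    assert flat == list(range(n))  # disjoint cover
    assert all(len(m) == G for m in p.submatches)
    assert len(p.submatches) == n // G
    X = p.matching_matrix()
    assert (X == X.T).all() and (np.diagonal(X) == 0).all()
    assert (X.sum(axis=0) == G - 1).all() and (X.sum(axis=1) == G - 1).all()
    assert math.isfinite(p.total_cost)


@settings(deadline=None, max_examples=30)
@given(seed=st.integers(0, 10**6), ng=st.sampled_from([(6, 2), (6, 3), (8, 4), (9, 3)]))
def test_solver_outputs_satisfy_matching_matrix_constraints(seed, ng):
    n, G = ng
    D = random_dissimilarity(np.random.default_rng(seed), n)
    for p in (solve_exact(D, G), solve_ga(D, G, seed=seed % 1000, generations=60, stall_generations=20)):
        _assert_matching_invariants(p)


@settings(deadline=None, max_examples=20)
@given(seed=st.integers(0, 10**6))
def test_relabeling_units_preserves_optimal_cost(seed):
    r = np.random.default_rng(seed)
    D = random_dissimilarity(r, 8)
    perm = r.permutation(8)
    Dp = DissimilarityMatrix(D.values[np.ix_(perm, perm)])
    assert solve_exact(D, 2).total_cost == pytest.approx(solve_exact(Dp, 2).total_cost)


def test_relaxed_matchings_converge_to_strict_as_penalty_grows(rng):
    # small instance with one categorical covariate: a large relaxed penalty
    # must reproduce the strict partition
    import pandas as pd

    from vivoplan.data_model import CovariateTable
    from vivoplan.dissimilarity import compute_dissimilarity

    vals = rng.normal(size=8)
    df = pd.DataFrame({"x": vals, "sex": ["m", "m", "m", "m", "f", "f", "f", "f"]},
                      index=pd.Index([f"u{i}" for i in range(8)], name="unit_id"))
    t = CovariateTable(df, {"x": "numeric", "sex": "categorical"})
    strict = solve_exact(compute_dissimilarity(t, categorical_mode="strict"), 2)
    relaxed_big = solve_exact(compute_dissimilarity(t, relaxed_penalty=1e6), 2)
    assert relaxed_big.submatches == strict.submatches
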