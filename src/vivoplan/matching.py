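"""Generalized optimal non-bipartite matching into submatches of size G.

Given a symmetric dissimilarity matrix D over N units, partition the units
into N/G disjoint *submatches* of exactly G members each, minimizing the
sum over submatches of all within-submatch pairwise distances. Each
submatch later contributes one member to each of the G intervention arms,
so tight submatches translate directly into baseline-balanced arms. The
classical paired (G = 2) non-bipartite matching is the special case solved
by weighted perfect matching; for G > 2 the problem is a combinatorial
partition problem solved here by

* :func:`solve_exact` — a branch-and-bound search with an admissible
  lower bound, guaranteed to return a global optimum;
* :func:`solve_ga` — a seeded genetic algorithm on permutation
  chromosomes for instances too large for exact search;
* :func:`brute_force` — exhaustive enumeration, the testing oracle.

+inf entries in D (strict categorical mode) forbid co-membership and are
pruned early by every solver.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass, field

import numpy as np

from .dissimilarity import DissimilarityMatrix

__all__ = [
    "SubmatchPartition",
    "MatchingError",
    "solve_exact",
    "solve_ga",
    "brute_force",
    "partition_cost",
    "count_partitions",
]

_EPS = 1e-9


class MatchingError(ValueError):
    """Raised for infeasible or ill-posed matching instances."""


@dataclass
class SubmatchPartition:
    """A partition of N units into K = N/G submatches of size G.

    ``submatches`` holds integer unit indices into the dissimilarity
    matrix's unit order, in canonical form: each submatch sorted
    ascending, submatches ordered by their smallest member.
    """

    submatches: list[tuple[int, ...]]
    total_cost: float
    solver: str
    optimal: bool
    unit_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.submatches = canonical(self.submatches)
        if not self.unit_ids:
            n = sum(len(m) for m in self.submatches)
            self.unit_ids = [str(i) for i in range(n)]

    @property
    def n_units(self) -> int:
        return sum(len(m) for m in self.submatches)

    @property
    def group_size(self) -> int:
        return len(self.submatches[0]) if self.submatches else 0

    def submatch_of(self) -> dict[int, int]:
        """unit index -> submatch index."""
        return {u: k for k, mem in enumerate(self.submatches) for u in mem}

    def by_ids(self) -> list[tuple[str, ...]]:
        return [tuple(self.unit_ids[u] for u in mem) for mem in self.submatches]

    def matching_matrix(self) -> np.ndarray:
        """Binary N x N matrix X: X[i, j] = 1 iff i != j share a submatch.

        X is symmetric, zero-diagonal, and every row/column sums to G - 1.
        """
        n = self.n_units
        X = np.zeros((n, n), dtype=int)
        for mem in self.submatches:
            for i, j in itertools.combinations(mem, 2):
                X[i, j] = X[j, i] = 1
        return X


def canonical(submatches) -> list[tuple[int, ...]]:
    return sorted((tuple(sorted(m)) for m in submatches), key=lambda m: m[0])


def _check_instance(D: DissimilarityMatrix, G: int) -> tuple[np.ndarray, int]:
    if G < 2:
        raise MatchingError(f"group size G must be >= 2, got {G}")
    n = D.n
    if n % G != 0:
        raise MatchingError(f"N = {n} not divisible by G = {G} (remainder {n % G})")
    V = D.values
    if np.isfinite(V).all() and (np.abs(V - V.T) > 1e-8).any():
        raise MatchingError("dissimilarity matrix is not symmetric")
    return V, n


def _clique_cost(V: np.ndarray, members: tuple[int, ...]) -> float:
    idx = np.fromiter(members, dtype=int)
    sub = V[np.ix_(idx, idx)]
    return float(np.triu(sub, 1).sum()) if np.isfinite(sub).all() else math.inf


def partition_cost(partition: SubmatchPartition, D: DissimilarityMatrix) -> float:
    """Sum over submatches of all within-submatch pairwise distances.

    Equals (1/2) * sum(X * D) for the induced matching matrix X.
    """
    units = sorted(u for m in partition.submatches for u in m)
    if units != list(range(D.n)):
        raise MatchingError("partition does not cover exactly the units of D")
    return float(sum(_clique_cost(D.values, m) for m in partition.submatches))


def count_partitions(n: int, G: int) -> int:
    """Number of ways to split n labeled units into unordered groups of size G.

    n! / ((G!)^(n/G) * (n/G)!), computed multiplicatively as a product of
    binomial coefficients anchored at the smallest remaining unit.
    """
    if n % G:
        raise MatchingError(f"N = {n} not divisible by G = {G} (remainder {n % G})")
    total = 1
    remaining = n
    while remaining > 0:
        total *= math.comb(remaining - 1, G - 1)
        remaining -= G
    return total


# ---------------------------------------------------------------------------
# exhaustive oracle


def brute_force(D: DissimilarityMatrix, G: int, max_partitions: int = 10_000_000) -> SubmatchPartition:
    """Exhaustive-enumeration global optimum. Testing oracle for small N."""
    V, n = _check_instance(D, G)
    n_part = count_partitions(n, G)
    if n_part > max_partitions:
        raise MatchingError(f"instance has {n_part} partitions, exceeding the brute-force guard of {max_partitions}")

    best_cost = math.inf
    best: list[tuple[int, ...]] | None = None

    def rec(remaining: tuple[int, ...], acc: list[tuple[int, ...]], cost: float) -> None:
        nonlocal best_cost, best
        if not remaining:
            if cost < best_cost - _EPS or (abs(cost - best_cost) <= _EPS and (best is None or acc < best)):
                best_cost, best = cost, list(acc)
            return
        anchor, rest = remaining[0], remaining[1:]
        for combo in itertools.combinations(rest, G - 1):
            members = (anchor, *combo)
            c = _clique_cost(V, members)
            if not math.isfinite(c):
                continue
            acc.append(members)
            rec(tuple(u for u in rest if u not in combo), acc, cost + c)
            acc.pop()

    rec(tuple(range(n)), [], 0.0)
    if best is None:
        raise MatchingError("no finite-cost partition exists (strict-mode infeasibility)")
    return SubmatchPartition(best, best_cost, "brute_force", True, list(D.unit_ids))


# ---------------------------------------------------------------------------
# branch and bound


def _lower_bound(V: np.ndarray, remaining: np.ndarray, G: int) -> float:
    """Admissible completion bound for the unassigned units.

    Every unassigned unit still needs G - 1 incident within-submatch edges,
    all of which must go to other currently unassigned units (submatches are
    completed whole); each edge is shared by two units, hence the /2.
    """
    if remaining.size == 0:
        return 0.0
    sub = V[np.ix_(remaining, remaining)]
    np.fill_diagonal(sub, np.inf)
    smallest = np.sort(sub, axis=1)[:, : G - 1]
    if not np.isfinite(smallest).all():
        return math.inf  # some unit lacks G-1 finite partners: branch infeasible
    return float(smallest.sum()) / 2.0


def _greedy_partition(V: np.ndarray, n: int, G: int) -> list[tuple[int, ...]] | None:
    """Cheap feasible incumbent: grow each submatch from the lowest free unit."""
    unassigned = list(range(n))
    out: list[tuple[int, ...]] = []
    while unassigned:
        anchor = unassigned.pop(0)
        members = [anchor]
        for _ in range(G - 1):
            costs = [sum(V[m, c] for m in members) for c in unassigned]
            if not costs or not any(math.isfinite(c) for c in costs):
                return None
            k = int(np.argmin(costs))
            members.append(unassigned.pop(k))
        out.append(tuple(sorted(members)))
    return out


def solve_exact(D: DissimilarityMatrix, G: int, time_limit: float | None = None) -> SubmatchPartition:
    """Globally optimal partition via best-first branch and bound.

    Branching anchors each new submatch on the lowest-indexed unassigned
    unit (eliminating symmetric duplicates) and expands its (G-1)-subset
    completions in order of incremental cost. A branch is pruned when the
    accumulated cost plus an admissible lower bound on the completion
    exceeds the incumbent. Among equal-cost optima, the lexicographically
    smallest canonical representation is returned, so results are
    bit-for-bit reproducible.

    With ``time_limit`` (seconds), the best incumbent found so far is
    returned with ``optimal=False`` when the budget expires.
    """
    V, n = _check_instance(D, G)
    deadline = None if time_limit is None else time.monotonic() + float(time_limit)

    incumbent = _greedy_partition(V.copy(), n, G)
    best_cost = sum(_clique_cost(V, m) for m in incumbent) if incumbent else math.inf
    best = canonical(incumbent) if incumbent else None
    timed_out = False

    def rec(remaining: tuple[int, ...], acc: list[tuple[int, ...]], cost: float) -> None:
        nonlocal best_cost, best, timed_out
        if timed_out:
            return
        if deadline is not None and time.monotonic() > deadline:
            timed_out = True
            return
        if not remaining:
            cand = canonical(acc)
            if cost < best_cost - _EPS or (abs(cost - best_cost) <= _EPS and (best is None or cand < best)):
                best_cost, best = cost, cand
            return
        anchor, rest = remaining[0], remaining[1:]
        children = []
        for combo in itertools.combinations(rest, G - 1):
            c = _clique_cost(V, (anchor, *combo))
            if math.isfinite(c):
                children.append((c, combo))
        children.sort(key=lambda t: t[0])  # best-first; stable, so ties stay in lex order
        for c, combo in children:
            new_cost = cost + c
            if new_cost > best_cost + _EPS:
                break  # children are cost-ordered: all later ones prune too
            new_remaining = tuple(u for u in rest if u not in combo)
            bound = _lower_bound(V, np.fromiter(new_remaining, dtype=int), G) if new_remaining else 0.0
            if new_cost + bound > best_cost + _EPS:
                continue
            acc.append((anchor, *combo))
            rec(new_remaining, acc, new_cost)
            acc.pop()

    rec(tuple(range(n)), [], 0.0)
    if best is None:
        raise MatchingError(
            "no finite-cost partition exists: some stratum of mutually compatible units "
            "is smaller than G (strict-mode infeasibility)"
        )
    return SubmatchPartition(best, float(best_cost), "exact", not timed_out, list(D.unit_ids))


# ---------------------------------------------------------------------------
# genetic algorithm


def _decode_cost(V: np.ndarray, pop: np.ndarray, G: int) -> np.ndarray:
    """Vectorized partition cost of each permutation chromosome.

    A chromosome is decoded by chunking consecutive blocks of G indices
    into submatches, which makes every individual feasible by construction.
    """
    n_pop, n = pop.shape
    groups = pop.reshape(n_pop, n // G, G)
    cost = np.zeros(n_pop)
    for a, b in itertools.combinations(range(G), 2):
        cost += V[groups[:, :, a], groups[:, :, b]].sum(axis=1)
    return cost


def _order_crossover(p1: np.ndarray, p2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = p1.size
    i, j = sorted(rng.integers(0, n, size=2))
    child = np.full(n, -1, dtype=p1.dtype)
    child[i : j + 1] = p1[i : j + 1]
    fill = p2[~np.isin(p2, child[i : j + 1])]
    pos = np.concatenate([np.arange(j + 1, n), np.arange(0, i)])
    child[pos] = fill[: pos.size]
    return child


def solve_ga(
    D: DissimilarityMatrix,
    G: int,
    population_size: int = 100,
    generations: int = 500,
    crossover_rate: float = 0.9,
    mutation_rate: float = 0.05,
    seed: int = 0,
    stall_generations: int = 100,
) -> SubmatchPartition:
    """Heuristic optimum via a seeded genetic algorithm.

    Permutation encoding (chunked into blocks of G), tournament selection,
    order crossover, per-position pairwise swap mutation and elitism of 1.
    Deterministic for a fixed seed. ``optimal`` is always False: the result
    upper-bounds the exact optimum.
    """
    V, n = _check_instance(D, G)
    rng = np.random.default_rng(seed)
    pop = np.array([rng.permutation(n) for _ in range(population_size)])
    cost = _decode_cost(V, pop, G)
    best_i = int(np.argmin(cost))
    best_perm, best_cost = pop[best_i].copy(), float(cost[best_i])
    stall = 0

    for _ in range(generations):
        # tournament selection, size 2
        a = rng.integers(0, population_size, size=population_size)
        b = rng.integers(0, population_size, size=population_size)
        winners = np.where(cost[a] <= cost[b], a, b)
        parents = pop[winners]
        children = np.empty_like(pop)
        for k in range(population_size):
            mate = parents[rng.integers(0, population_size)]
            if rng.random() < crossover_rate:
                children[k] = _order_crossover(parents[k], mate, rng)
            else:
                children[k] = parents[k]
            swaps = np.nonzero(rng.random(n) < mutation_rate)[0]
            for s in swaps:
                t = rng.integers(0, n)
                children[k][[s, t]] = children[k][[t, s]]
        children[0] = best_perm  # elitism
        pop = children
        cost = _decode_cost(V, pop, G)
        i = int(np.argmin(cost))
        if cost[i] < best_cost - _EPS:
            best_perm, best_cost = pop[i].copy(), float(cost[i])
            stall = 0
        else:
            stall += 1
            if stall >= stall_generations:
                break

    if not math.isfinite(best_cost):
        raise MatchingError("genetic algorithm found no finite-cost partition (strict-mode infeasibility?)")
    submatches = [tuple(best_perm[k * G : (k + 1) * G]) for k in range(n // G)]
    return SubmatchPartition(submatches, best_cost, "ga", False, list(D.unit_ids))
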