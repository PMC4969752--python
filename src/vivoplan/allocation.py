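"""Blinded randomization within submatches and baseline-balance diagnostics.

Matching and randomization are deliberately separate phases: the optimizer
fixes *which* units are interchangeable (the submatches), and only then is
each submatch's membership randomly distributed over the G intervention
arms. Every arm therefore receives exactly one member of every submatch —
a randomized-block allocation with the blocks chosen optimally from the
baseline data — and the arm labels can be coded so the whole in-life phase
runs blinded.

:func:`simulate_balance` quantifies what this buys: it replays many
allocations either completely at random (unmatched) or by re-randomizing
arms within the fixed optimal submatches (matched), and records how often
at least one baseline covariate ends up significantly imbalanced across
arms (one-way ANOVA for numeric covariates, chi-square for categorical).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import CovariateTable, DataError
from .dissimilarity import compute_dissimilarity
from .matching import MatchingError, SubmatchPartition, canonical, count_partitions, solve_exact, solve_ga

__all__ = [
    "AllocationPlan",
    "BalanceReport",
    "randomize_within_submatches",
    "match_by_batch",
    "simulate_balance",
    "one_way_anova",
]

# exact search is practical while the raw partition count stays modest
_EXACT_PARTITION_LIMIT = 2_000_000


@dataclass
class AllocationPlan:
    """unit -> (submatch, arm, blinded code) produced by within-submatch randomization."""

    assignments: dict[str, tuple[int, str, str]]
    arms: list[str]
    seed: int
    code_to_arm: dict[str, str]
    unit_ids: list[str]

    def __post_init__(self) -> None:
        G = len(self.arms)
        per_sub: dict[int, list[str]] = {}
        for uid, (sub, arm, _code) in self.assignments.items():
            per_sub.setdefault(sub, []).append(arm)
        for sub, arms in per_sub.items():
            if sorted(arms) != sorted(self.arms):
                raise DataError(f"submatch {sub} does not contain each arm exactly once: {arms}")
        counts: dict[str, int] = {}
        for _, arm, _ in self.assignments.values():
            counts[arm] = counts.get(arm, 0) + 1
        if len(set(counts.values())) > 1:
            raise DataError(f"arms are not equally sized: {counts}")
        if sorted(self.code_to_arm.values()) != sorted(self.arms):
            raise DataError("blinded codes are not a bijection onto arms")

    def arm_of(self, unit_id: str) -> str:
        return self.assignments[unit_id][1]

    def units_in_arm(self, arm: str) -> list[str]:
        return [u for u in self.unit_ids if self.assignments[u][1] == arm]


def randomize_within_submatches(
    partition: SubmatchPartition, arms: list[str], seed: int
) -> AllocationPlan:
    """Distribute each submatch's members uniformly at random over the arms.

    Each submatch receives an independent uniform permutation of the arm
    labels, so no arm (including the control) is treated specially and the
    allocation is fully determined by ``seed``. Blinded codes ``T1..TG``
    are mapped to arms by a separate random permutation, independent of
    arm semantics.
    """
    G = partition.group_size
    if len(arms) != G:
        raise DataError(f"need exactly G = {G} arm labels, got {len(arms)}")
    if len(set(arms)) != len(arms):
        raise DataError(f"arm labels must be distinct: {arms}")
    rng = np.random.default_rng(seed)
    codes = [f"T{i + 1}" for i in range(G)]
    code_to_arm = dict(zip(codes, [arms[i] for i in rng.permutation(G)]))
    arm_to_code = {a: c for c, a in code_to_arm.items()}
    assignments: dict[str, tuple[int, str, str]] = {}
    for k, members in enumerate(partition.submatches):
        perm = rng.permutation(G)
        for slot, u in enumerate(members):
            arm = arms[perm[slot]]
            assignments[partition.unit_ids[u]] = (k, arm, arm_to_code[arm])
    return AllocationPlan(assignments, list(arms), seed, code_to_arm, list(partition.unit_ids))


def _solve_auto(D, G, solver: str, seed: int, time_limit: float | None):
    if solver == "auto":
        solver = "exact" if count_partitions(D.n, G) <= _EXACT_PARTITION_LIMIT else "ga"
    if solver == "exact":
        return solve_exact(D, G, time_limit=time_limit)
    if solver == "ga":
        return solve_ga(D, G, seed=seed)
    raise DataError(f"unknown solver {solver!r}")


def match_by_batch(
    table: CovariateTable,
    G: int,
    metric: str = "standardized-euclidean",
    categorical_mode: str = "relaxed",
    relaxed_penalty: float = 1.0,
    solver: str = "auto",
    seed: int = 0,
    time_limit: float | None = None,
) -> SubmatchPartition:
    """Batch-stratified matching: one independent matching problem per batch.

    No submatch ever spans two batches, so after within-submatch
    randomization every batch is spread uniformly over the arms — batch
    effects cannot be confounded with the interventions. Without a batch
    column this reduces to a single matching over the whole table.
    """
    blocks = table.batch_blocks()
    for name, ids in blocks.items():
        if len(ids) % G != 0:
            label = name or "<all>"
            raise MatchingError(f"batch {label!r}: {len(ids)} units not divisible by G = {G}")
    index_of = {u: i for i, u in enumerate(table.unit_ids)}
    submatches: list[tuple[int, ...]] = []
    total = 0.0
    all_optimal = True
    solver_used = set()
    for b, (name, ids) in enumerate(sorted(blocks.items())):
        sub_table = table.subset(ids)
        D = compute_dissimilarity(sub_table, metric, categorical_mode, relaxed_penalty)
        part = _solve_auto(D, G, solver, seed + b, time_limit)
        solver_used.add(part.solver)
        all_optimal &= part.optimal
        total += part.total_cost
        for members in part.submatches:
            submatches.append(tuple(index_of[part.unit_ids[u]] for u in members))
    return SubmatchPartition(
        canonical(submatches), total, "+".join(sorted(solver_used)), all_optimal, table.unit_ids
    )


@dataclass
class BalanceReport:
    """Monte-Carlo frequencies of significant baseline imbalance across arms."""

    mode: str
    n_sim: int
    alpha: float
    per_covariate: dict[str, float] = field(default_factory=dict)
    any_covariate: float = 0.0

    def __post_init__(self) -> None:
        freqs = list(self.per_covariate.values()) + [self.any_covariate]
        if any(f < 0 or f > 1 for f in freqs):
            raise DataError("imbalance frequencies must lie in [0, 1]")
        if self.per_covariate and self.any_covariate < max(self.per_covariate.values()) - 1e-12:
            raise DataError("any-covariate frequency cannot be below the per-covariate maximum")


def one_way_anova(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F test of equal group means.

    Returns ``(F, p)``. With zero within-group variance the test is
    degenerate: if the group means also coincide, ``(0.0, 1.0)`` is
    returned with a warning; otherwise the separation is perfect and the
    p-value is reported as 0.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise DataError("one-way ANOVA needs at least 2 groups")
    ns, means, ssw = [], [], 0.0
    for g in labels:
        v = values[groups == g]
        if v.size < 2:
            raise DataError(f"group {g!r} has fewer than 2 units")
        ns.append(v.size)
        means.append(v.mean())
        ssw += ((v - v.mean()) ** 2).sum()
    ns, means = np.array(ns), np.array(means)
    grand = values.mean()
    ssb = (ns * (means - grand) ** 2).sum()
    df1, df2 = labels.size - 1, values.size - labels.size
    if ssw <= 1e-300:
        warnings.warn("degenerate within-group variance in one-way ANOVA")
        return (0.0, 1.0) if ssb <= 1e-300 else (float("inf"), 0.0)
    F = (ssb / df1) / (ssw / df2)
    return float(F), float(stats.f.sf(F, df1, df2))


def _draw_assignments(
    rng: np.random.Generator, n_sim: int, n: int, G: int, mode: str, partition: SubmatchPartition | None
) -> np.ndarray:
    """(n_sim, n) integer arm indices; matched mode permutes arms within submatches."""
    if mode == "unmatched":
        base = np.repeat(np.arange(G), n // G)
        return rng.permuted(np.tile(base, (n_sim, 1)), axis=1)
    assert partition is not None
    out = np.empty((n_sim, n), dtype=int)
    for members in partition.submatches:
        perms = rng.permuted(np.tile(np.arange(G), (n_sim, 1)), axis=1)
        out[:, list(members)] = perms
    return out


def _anova_pvalues(X: np.ndarray, H: np.ndarray, G: int) -> np.ndarray:
    """Vectorized one-way ANOVA p-values, one per (replicate, covariate).

    X: (n, d) covariates; H: (n_sim, n, G) one-hot arm assignments with
    equal group sizes n/G.
    """
    n, d = X.shape
    K = n // G
    group_sums = np.einsum("nd,rng->rdg", X, H)
    grand = X.mean(axis=0)  # (d,)
    sst = ((X - grand) ** 2).sum(axis=0)  # (d,)
    ssb = (K * (group_sums / K - grand[None, :, None]) ** 2).sum(axis=2)  # (n_sim, d)
    ssw = np.maximum(sst[None, :] - ssb, 0.0)
    df1, df2 = G - 1, n - G
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(F, df1, df2)
    p = np.where(ssw <= 1e-12 * np.maximum(sst[None, :], 1.0), np.where(ssb <= 1e-12, 1.0, 0.0), p)
    return np.where(sst[None, :] <= 1e-300, 1.0, p)


def _chi2_pvalues(codes: np.ndarray, n_cat: int, H: np.ndarray, G: int) -> np.ndarray:
    """Vectorized chi-square test of arm x category counts per replicate."""
    C = np.eye(n_cat)[codes]  # (n, n_cat)
    counts = np.einsum("nc,rng->rgc", C, H)  # (n_sim, G, n_cat)
    n = codes.size
    row = counts.sum(axis=2, keepdims=True)
    col = counts.sum(axis=1, keepdims=True)
    expected = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chi2 = terms.sum(axis=(1, 2))
    df = (G - 1) * (n_cat - 1)
    if df == 0:
        return np.ones(chi2.size)
    return stats.chi2.sf(chi2, df)


def simulate_balance(
    table: CovariateTable,
    G: int,
    n_sim: int,
    mode: str = "unmatched",
    alpha: float = 0.05,
    seed: int = 0,
    partition: SubmatchPartition | None = None,
    metric: str = "standardized-euclidean",
    solver: str = "auto",
) -> BalanceReport:
    """Monte-Carlo frequency of significant baseline imbalance across arms.

    Each replicate draws one allocation — unmatched: a uniformly random
    partition of the units into G equal arms; matched: a fresh
    within-submatch randomization over one fixed optimal partition — and
    tests every baseline covariate across the arms (one-way ANOVA for
    numeric, chi-square for categorical) at level ``alpha``.
    """
    if mode not in ("matched", "unmatched"):
        raise DataError(f"mode must be 'matched' or 'unmatched', got {mode!r}")
    if n_sim < 1:
        raise DataError("n_sim must be >= 1")
    n = table.n_units
    if n % G != 0:
        raise MatchingError(f"N = {n} not divisible by G = {G} (remainder {n % G})")
    if mode == "matched" and partition is None:
        D = compute_dissimilarity(table, metric)
        partition = _solve_auto(D, G, solver, seed, None)

    rng = np.random.default_rng(seed)
    num_cols = table.numeric_columns
    cat_cols = table.categorical_columns
    X = table.data[num_cols].to_numpy(dtype=float) if num_cols else np.empty((n, 0))
    if X.size and np.isnan(X).any():
        raise DataError("missing values in numeric covariates; cannot simulate balance")

    per_cov_hits = {c: 0 for c in num_cols + cat_cols}
    any_hits = 0
    chunk = max(1, min(n_sim, int(4e7 // max(n * G, 1))))  # bound one-hot memory
    done = 0
    while done < n_sim:
        m = min(chunk, n_sim - done)
        assign = _draw_assignments(rng, m, n, G, mode, partition)
        H = (assign[:, :, None] == np.arange(G)[None, None, :]).astype(float)
        sig = np.zeros((m, 0), dtype=bool)
        if num_cols:
            p_num = _anova_pvalues(X, H, G)
            sig = np.concatenate([sig, p_num < alpha], axis=1)
        for ci, col in enumerate(cat_cols):
            codes, cats = pd_factorize(table.data[col])
            p_cat = _chi2_pvalues(codes, len(cats), H, G)
            sig = np.concatenate([sig, (p_cat < alpha)[:, None]], axis=1)
        for k, col in enumerate(num_cols + cat_cols):
            per_cov_hits[col] += int(sig[:, k].sum())
        any_hits += int(sig.any(axis=1).sum())
        done += m

    return BalanceReport(
        mode=mode,
        n_sim=n_sim,
        alpha=alpha,
        per_covariate={c: h / n_sim for c, h in per_cov_hits.items()},
        any_covariate=any_hits / n_sim,
    )


def pd_factorize(series):
    import pandas as pd

    codes, cats = pd.factorize(series.astype(str))
    return codes, list(cats)
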