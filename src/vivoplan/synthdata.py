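"""Synthetic baseline and longitudinal data with the structure the methods assume.

The generator emulates a VCaP-xenograft-like study: each unit carries a
latent random intercept and random growth slope; the longitudinal response
grows linearly in time around the population intercept/slope with an
arm-specific slope offset and Gaussian measurement noise; baseline
covariates are optionally *informative*, i.e. linearly correlated with the
latent slope, which is exactly the situation in which baseline matching
pays off in the paired analysis. Optional right-censoring truncates
trajectories with a hazard that can increase with the latent growth rate
(aggressive growers reach ethical endpoints earlier).

Default population parameters follow the magnitude of a castration-
resistant VCaP PSA study: intercept ~14 ug/l, weekly slope ~10, random
intercept/slope SDs ~8/5 and residual SD ~6.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import CovariateTable, DataError, LongitudinalTable

__all__ = ["SimulationScenario", "generate_baseline", "generate_longitudinal", "generate_study"]


@dataclass
class SimulationScenario:
    """Study-generating parameters (one arm offset per arm; offsets act on the slope)."""

    n_units: int = 45
    d: int = 3
    n_informative: int = 3
    rho: float = 0.8  # correlation of each informative covariate with the latent slope
    batch_sizes: tuple[int, ...] | None = None
    arms: tuple[str, ...] = ("Vehicle", "TreatA", "TreatB")
    arm_offsets: tuple[float, ...] = (0.0, -5.0, -8.0)
    beta0: float = 14.0
    beta1: float = 10.0
    sd_gamma0: float = 8.0
    sd_gamma1: float = 5.0
    sd_e: float = 6.0
    time_points: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8)
    censor_hazard: float = 0.0  # per-time-point dropout probability at average growth
    censor_growth_coef: float = 1.0  # log-hazard gain per SD of latent slope
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.d:
            raise DataError("n_informative cannot exceed d")
        if len(self.arm_offsets) != len(self.arms):
            raise DataError("need one slope offset per arm")
        if min(self.sd_gamma0, self.sd_gamma1, self.sd_e) < 0:
            raise DataError("standard deviations must be nonnegative")
        if not 0 <= self.censor_hazard <= 1:
            raise DataError("censor_hazard must be a probability")
        if not -1 <= self.rho <= 1:
            raise DataError("rho must lie in [-1, 1]")
        if self.batch_sizes is not None and sum(self.batch_sizes) != self.n_units:
            raise DataError("batch sizes must sum to n_units")

    def with_(self, **kw) -> "SimulationScenario":
        return replace(self, **kw)


# plausible measurement scales for the default three covariates
# (body weight in g, baseline PSA in ug/l, PSA fold change)
_DEFAULT_COLS = (("weight", 25.0, 2.0), ("psa", 14.0, 6.0), ("psa_fc", 1.3, 0.25))


def generate_baseline(
    scenario: SimulationScenario, seed: int | None = None
) -> tuple[CovariateTable, pd.DataFrame]:
    """Draw baseline covariates and the hidden per-unit random effects.

    Informative covariates are ``rho * z_slope + sqrt(1 - rho^2) * noise``
    on the standardized scale (z_slope is the unit's latent slope divided
    by its SD), then shifted/scaled to plausible measurement units.
    Returns ``(table, hidden)`` where ``hidden`` holds the latent
    ``gamma0``/``gamma1`` used later by :func:`generate_longitudinal` and
    by oracle evaluations in tests.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n, d = scenario.n_units, scenario.d
    ids = [f"m{i + 1:03d}" for i in range(n)]
    gamma0 = rng.normal(0.0, scenario.sd_gamma0, size=n)
    gamma1 = rng.normal(0.0, scenario.sd_gamma1, size=n)
    z_slope = gamma1 / scenario.sd_gamma1 if scenario.sd_gamma1 > 0 else np.zeros(n)

    cols = {}
    kinds = {}
    for k in range(d):
        name, loc, scale = _DEFAULT_COLS[k] if k < len(_DEFAULT_COLS) else (f"cov{k + 1}", 0.0, 1.0)
        noise = rng.normal(size=n)
        if k < scenario.n_informative:
            z = scenario.rho * z_slope + np.sqrt(1 - scenario.rho**2) * noise
        else:
            z = noise
        cols[name] = loc + scale * z
        kinds[name] = "numeric"
    data = pd.DataFrame(cols, index=pd.Index(ids, name="unit_id"))
    batch = None
    if scenario.batch_sizes is not None:
        labels = np.concatenate(
            [np.full(sz, f"B{i + 1}") for i, sz in enumerate(scenario.batch_sizes)]
        )
        batch = pd.Series(labels, index=data.index)
    hidden = pd.DataFrame({"gamma0": gamma0, "gamma1": gamma1}, index=data.index)
    return CovariateTable(data, kinds, batch), hidden


def generate_longitudinal(
    hidden: pd.DataFrame,
    plan,
    scenario: SimulationScenario,
    seed: int | None = None,
) -> LongitudinalTable:
    """Simulate linear-growth trajectories under an allocation plan.

    y_{i,t} = beta0 + (beta1 + offset_arm) * x_t + gamma0_i + gamma1_i * x_t + e_{i,t}

    With ``censor_hazard > 0`` each unit may drop out after any post-
    baseline time point with probability
    ``min(1, hazard * exp(coef * z_slope))`` — faster growers censor
    earlier — truncating the trajectory from the first dropout on.
    """
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    offset = dict(zip(scenario.arms, scenario.arm_offsets))
    times = np.asarray(scenario.time_points, dtype=float)
    rows = []
    for uid in plan.unit_ids:
        if uid not in hidden.index:
            raise DataError(f"unit {uid!r} missing from hidden effects")
        arm = plan.assignments[uid][1]
        if arm not in offset:
            raise DataError(f"arm {arm!r} has no slope offset in the scenario")
        g0, g1 = hidden.loc[uid, "gamma0"], hidden.loc[uid, "gamma1"]
        z = g1 / scenario.sd_gamma1 if scenario.sd_gamma1 > 0 else 0.0
        hazard = min(1.0, scenario.censor_hazard * float(np.exp(scenario.censor_growth_coef * z)))
        y = (
            scenario.beta0
            + (scenario.beta1 + offset[arm]) * times
            + g0
            + g1 * times
            + rng.normal(0.0, scenario.sd_e, size=times.size)
        )
        n_keep = times.size
        if hazard > 0:
            drops = rng.random(times.size - 1) < hazard  # dropout after each post-baseline point
            hit = np.nonzero(drops)[0]
            if hit.size:
                n_keep = int(hit[0]) + 1
        for t, v in zip(times[:n_keep], y[:n_keep]):
            rows.append((uid, t, v, arm))
    return LongitudinalTable(pd.DataFrame(rows, columns=["unit_id", "time", "response", "arm"]))


def generate_study(scenario: SimulationScenario, seed: int | None = None, solver: str = "auto"):
    """Full synthetic study: baseline -> dissimilarity -> matching -> blinded
    randomization -> longitudinal responses.

    Returns ``(table, hidden, partition, plan, long_table)``. Convenience
    wrapper used by tests and the worked examples; each stage is also
    available separately.
    """
    from .allocation import match_by_batch, randomize_within_submatches

    base_seed = scenario.seed if seed is None else seed
    table, hidden = generate_baseline(scenario, base_seed)
    partition = match_by_batch(table, len(scenario.arms), solver=solver, seed=base_seed + 1)
    plan = randomize_within_submatches(partition, list(scenario.arms), base_seed + 2)
    long_table = generate_longitudinal(hidden, plan, scenario, base_seed + 3)
    return table, hidden, partition, plan, long_table
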