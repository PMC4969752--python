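"""Bootstrap model-based power curves for longitudinal intervention effects.

Standard closed-form power formulas cannot honor the realities of a
preclinical study — longitudinal correlated measurements, right-censoring,
matched pairs — so power is estimated by resampling the *data*: whole
experimental units are drawn with replacement from a source dataset
(individual animals for the unmatched model, matched pairs for the paired
model, so censoring patterns and within-unit correlation ride along
intact), the specified model is refit on each resample at each candidate
per-arm sample size, and power at level alpha is the fraction of refits
whose intervention-term p-value falls below alpha. The smallest n whose
power reaches the conventional 0.8 threshold is the sample-size
recommendation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DataError, LongitudinalTable
from .models import (
    PairedDifferenceSeries,
    build_paired_differences,
    fit_matched,
    fit_unmatched,
)

__all__ = ["PowerCurve", "bootstrap_power", "required_n"]


@dataclass
class PowerCurve:
    """Estimated power per candidate per-arm sample size."""

    term: str
    n_grid: list[int]
    power: list[float]
    alpha: float
    n_boot: int
    mc_se: list[float] = field(default_factory=list)
    drop_rate: list[float] = field(default_factory=list)
    unreliable: list[bool] = field(default_factory=list)
    required_n: int | None = None
    target: float = 0.8
    seed: int = 0
    model: str = ""

    def __post_init__(self) -> None:
        if any(p < 0 or p > 1 for p in self.power):
            raise DataError("power values must lie in [0, 1]")
        if not self.mc_se:
            self.mc_se = [float(np.sqrt(p * (1 - p) / self.n_boot)) for p in self.power]

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "model": self.model,
            "n_grid": self.n_grid,
            "power": self.power,
            "mc_se": self.mc_se,
            "drop_rate": self.drop_rate,
            "unreliable": self.unreliable,
            "alpha": self.alpha,
            "n_boot": self.n_boot,
            "target": self.target,
            "required_n": self.required_n,
            "seed": self.seed,
        }


def required_n(curve: PowerCurve, target: float = 0.8) -> int | None:
    """Smallest grid sample size whose power reaches ``target`` (None if never)."""
    for n, p in sorted(zip(curve.n_grid, curve.power)):
        if p >= target:
            return int(n)
    return None


def _resample_unmatched(
    data: LongitudinalTable, arm_ref: str, arm_test: str, n: int, rng: np.random.Generator
) -> LongitudinalTable:
    df = data.data
    parts = []
    for arm in (arm_ref, arm_test):
        units = sorted(df[df["arm"].astype(str) == str(arm)]["unit_id"].unique())
        if not units:
            raise DataError(f"arm {arm!r} absent from source data")
        picks = rng.choice(len(units), size=n, replace=True)
        for k, idx in enumerate(picks):
            block = df[df["unit_id"] == units[idx]].copy()
            block["unit_id"] = f"{units[idx]}#{k}"  # each draw is its own unit
            parts.append(block)
    return LongitudinalTable(pd.concat(parts, ignore_index=True))


def _resample_pairs(diffs: PairedDifferenceSeries, n: int, rng: np.random.Generator) -> PairedDifferenceSeries:
    obs = diffs.observations
    keys = [f"{i}|{j}" for i, j in diffs.pairs]
    picks = rng.choice(len(keys), size=n, replace=True)
    parts, pairs = [], []
    for k, idx in enumerate(picks):
        block = obs[obs["pair"] == keys[idx]].copy()
        block["pair"] = f"{keys[idx]}#{k}"
        parts.append(block)
        i, j = diffs.pairs[idx]
        pairs.append((f"{i}#{k}", f"{j}#{k}"))
    return PairedDifferenceSeries(pairs, pd.concat(parts, ignore_index=True), diffs.arm_ref, diffs.arm_test)


def bootstrap_power(
    data: LongitudinalTable,
    model: str,
    contrast: tuple[str, str],
    n_grid=range(3, 41),
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    partition=None,
    plan=None,
    target: float = 0.8,
    reml: bool = True,
    max_drop_rate: float = 0.1,
) -> PowerCurve:
    """Bootstrap power curve for the intervention term.

    ``contrast = (arm_ref, arm_test)``. For ``model="matched"`` the source
    data are first reduced to within-submatch paired differences (needs
    ``partition`` and ``plan``) and the resampling unit is the pair; for
    ``model="unmatched"`` units are resampled within arm so both arms have
    exactly n units. Refits that fail to converge are dropped but stay in
    the denominator (conservative); a grid point with more than
    ``max_drop_rate`` dropped replicates is flagged unreliable.
    Deterministic for a fixed seed, with per-replicate derived substreams.
    """
    if model not in ("matched", "unmatched"):
        raise DataError(f"model must be 'matched' or 'unmatched', got {model!r}")
    if n_boot < 100:
        raise DataError("n_boot must be at least 100")
    arm_ref, arm_test = contrast
    n_grid = sorted(int(n) for n in n_grid)

    diffs = None
    if model == "matched":
        if partition is None or plan is None:
            raise DataError("matched power needs the partition and allocation plan")
        diffs = build_paired_differences(data, partition, plan, arm_ref, arm_test)
        # sanity-check that the source pairs support a fit at all
        fit_matched(diffs, reml=reml)
    else:
        fit_unmatched(data, arm_ref, arm_test, reml=reml)

    power, mc_se, drops, unreliable = [], [], [], []
    for ni, n in enumerate(n_grid):
        hits = dropped = 0
        for r in range(n_boot):
            rng = np.random.default_rng([seed, ni, r])  # order-independent substreams
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if model == "matched":
                        fit = fit_matched(_resample_pairs(diffs, n, rng), reml=reml)
                        ok, p = fit.converged, fit.beta_intervention.p
                    else:
                        fit = fit_unmatched(
                            _resample_unmatched(data, arm_ref, arm_test, n, rng),
                            arm_ref, arm_test, reml=reml,
                        )
                        ok, p = fit.converged, fit.beta2.p
            except (DataError, np.linalg.LinAlgError, ValueError):
                ok = False
            if not ok:
                dropped += 1
                continue
            if p < alpha:
                hits += 1
        pw = hits / n_boot  # attempted replicates in the denominator
        power.append(pw)
        mc_se.append(float(np.sqrt(pw * (1 - pw) / n_boot)))
        drops.append(dropped / n_boot)
        unreliable.append(dropped / n_boot > max_drop_rate)

    curve = PowerCurve(
        term="beta_intervention" if model == "matched" else "beta2",
        n_grid=n_grid,
        power=power,
        alpha=alpha,
        n_boot=n_boot,
        mc_se=mc_se,
        drop_rate=drops,
        unreliable=unreliable,
        target=target,
        seed=seed,
        model=model,
    )
    curve.required_n = required_n(curve, target)
    return curve
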