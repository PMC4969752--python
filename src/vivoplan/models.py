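"""Longitudinal mixed-effects inference of intervention effects.

Two models are provided for a linear-growth response such as serum PSA in
xenograft studies.

Unmatched (conventional) model, per unit i at time x_t::

    y_{i,t} = b0 + b1 * x_t + b2 * g2_i * x_t + g_{i,0} + g_{i,1} * x_t + e_{i,t}

with fixed intercept b0, common growth slope b1 and intervention effect b2
on the slope (g2_i indicates membership of the tested arm), unit-level
random intercept g_{i,0} and random slope g_{i,1}, and residual noise —
all Gaussian, random effects independent of the residual.

Matched (paired-difference) model: for each optimal submatch the two
members allocated to the compared arms form a pair {i, j}, and their
response difference D_{ij}(x_t) = y_i(x_t) - y_j(x_t) at *shared* time
points is itself modeled longitudinally::

    D_{ij}(x_t) = b_intervention * x_t + g_0 + g_1 * x_t + eps

with the fixed intercept and common slope set to zero by default: members
of a pair were chosen to be maximally similar at baseline, so those terms
are redundant in the differenced curves and b_intervention directly
captures the pairwise growth-rate separation between the arms.

Estimation goes through statsmodels' MixedLM (REML by default). P-values
for fixed effects use Satterthwaite's moment-matching approximation of the
t degrees of freedom, computed here by the delta method over the REML
variance parameters; a normal approximation is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError, LongitudinalTable

__all__ = [
    "FixedEffect",
    "UnmatchedModelFit",
    "MatchedModelFit",
    "PairedDifferenceSeries",
    "fit_unmatched",
    "build_paired_differences",
    "fit_matched",
    "satterthwaite_p",
    "paired_hotelling_t2",
]


@dataclass
class FixedEffect:
    name: str
    estimate: float
    se: float
    df: float
    p: float
    p_z: float  # normal-approximation p, reported for transparency


# ---------------------------------------------------------------------------
# REML machinery shared by both model variants


@dataclass
class _LMMContext:
    """Per-group data and variance parameters of a fitted linear mixed model.

    theta packs the variance parameters: the q random-effect variances
    (plus the intercept-slope covariance when ``correlated``) followed by
    the residual variance.
    """

    y: list[np.ndarray]
    X: list[np.ndarray]
    Z: list[np.ndarray]
    coef_names: list[str]
    theta: np.ndarray
    correlated: bool
    reml: bool
    theta_cov: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return sum(len(v) for v in self.y)

    @property
    def n_coef(self) -> int:
        return self.X[0].shape[1]

    @property
    def residual_df(self) -> float:
        return float(self.n_obs - self.n_coef)


def _psi(theta: np.ndarray, q: int, correlated: bool) -> tuple[np.ndarray, float]:
    if correlated:
        if q != 2:
            raise DataError("correlated random effects supported for intercept+slope only")
        v0, c01, v1, s2 = theta
        return np.array([[v0, c01], [c01, v1]]), float(s2)
    return np.diag(theta[:q]), float(theta[q])


def _group_V(Z: np.ndarray, theta: np.ndarray, correlated: bool) -> np.ndarray:
    psi, s2 = _psi(theta, Z.shape[1], correlated)
    return Z @ psi @ Z.T + s2 * np.eye(Z.shape[0])


def _gls_pieces(ctx: _LMMContext, theta: np.ndarray):
    """Accumulate GLS quantities: A = sum X'V^-1 X, b = sum X'V^-1 y, logdets."""
    p = ctx.n_coef
    A = np.zeros((p, p))
    b = np.zeros(p)
    logdet_V = 0.0
    yVy = 0.0
    for y, X, Z in zip(ctx.y, ctx.X, ctx.Z):
        V = _group_V(Z, theta, ctx.correlated)
        L = np.linalg.cholesky(V)  # raises LinAlgError if not PD
        Xs = np.linalg.solve(L, X)
        ys = np.linalg.solve(L, y)
        A += Xs.T @ Xs
        b += Xs.T @ ys
        yVy += ys @ ys
        logdet_V += 2.0 * np.log(np.diagonal(L)).sum()
    return A, b, logdet_V, yVy


def _profiled_loglike(ctx: _LMMContext, theta: np.ndarray) -> float:
    """(RE)ML log-likelihood with the fixed effects profiled out at GLS."""
    A, b, logdet_V, yVy = _gls_pieces(ctx, theta)
    beta = np.linalg.solve(A, b)
    rss = yVy - b @ beta  # (y - X beta)' V^-1 (y - X beta)
    ll = -0.5 * (logdet_V + rss)
    if ctx.reml:
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf
        ll -= 0.5 * logdet_A
    return float(ll)


def _coef_cov(ctx: _LMMContext, theta: np.ndarray) -> np.ndarray:
    A, _, _, _ = _gls_pieces(ctx, theta)
    return np.linalg.inv(A)


def _theta_cov(ctx: _LMMContext) -> np.ndarray | None:
    """Asymptotic covariance of the variance parameters from a finite-difference
    Hessian of the profiled (RE)ML criterion; None when the curvature is
    unavailable (boundary estimates, indefinite Hessian)."""
    theta = ctx.theta
    k = theta.size
    h = np.maximum(1e-5, 1e-3 * np.abs(theta))

    def f(t):
        try:
            return _profiled_loglike(ctx, t)
        except np.linalg.LinAlgError:
            return np.nan

    H = np.empty((k, k))
    for a in range(k):
        for b_ in range(a, k):
            ea, eb = np.zeros(k), np.zeros(k)
            ea[a], eb[b_] = h[a], h[b_]
            if a == b_:
                val = (f(theta + ea) - 2 * f(theta) + f(theta - ea)) / (h[a] ** 2)
            else:
                val = (
                    f(theta + ea + eb) - f(theta + ea - eb) - f(theta - ea + eb) + f(theta - ea - eb)
                ) / (4 * h[a] * h[b_])
            H[a, b_] = H[b_, a] = val
    if not np.all(np.isfinite(H)):
        return None
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diagonal(cov) <= 0):
        return None
    return cov


def _satterthwaite(ctx: _LMMContext, contrast: np.ndarray) -> tuple[float, bool]:
    """Satterthwaite df for c'beta: df = 2 g^2 / Var(g), g(theta) = Var(c'beta).

    Returns (df, fallback_used); falls back to the residual df when the
    variance-parameter curvature is unavailable.
    """
    theta = ctx.theta
    if ctx.theta_cov is None:
        ctx.theta_cov = _theta_cov(ctx)
    g0 = float(contrast @ _coef_cov(ctx, theta) @ contrast)
    if ctx.theta_cov is None:
        return ctx.residual_df, True
    k = theta.size
    h = np.maximum(1e-6, 1e-4 * np.abs(theta))
    grad = np.empty(k)
    try:
        for a in range(k):
            e = np.zeros(k)
            e[a] = h[a]
            gp = float(contrast @ _coef_cov(ctx, theta + e) @ contrast)
            gm = float(contrast @ _coef_cov(ctx, theta - e) @ contrast)
            grad[a] = (gp - gm) / (2 * h[a])
    except np.linalg.LinAlgError:
        return ctx.residual_df, True
    var_g = float(grad @ ctx.theta_cov @ grad)
    if var_g <= 0 or not np.isfinite(var_g):
        return ctx.residual_df, True
    df = 2.0 * g0**2 / var_g
    return float(np.clip(df, 1.0, ctx.residual_df)), False


def _fixed_effect(ctx: _LMMContext, name: str, estimate: float) -> FixedEffect:
    idx = ctx.coef_names.index(name)
    c = np.zeros(ctx.n_coef)
    c[idx] = 1.0
    se = float(np.sqrt(c @ _coef_cov(ctx, ctx.theta) @ c))
    df, fellback = _satterthwaite(ctx, c)
    if fellback:
        ctx.notes.append(f"satterthwaite curvature unavailable for {name}; residual df used")
    if se == 0:
        p = 1.0 if estimate == 0 else 0.0
        return FixedEffect(name, estimate, se, df, p, p)
    t = estimate / se
    p = float(2 * stats.t.sf(abs(t), df))
    p_z = float(2 * stats.norm.sf(abs(t)))
    return FixedEffect(name, estimate, se, df, max(p, 1e-300), max(p_z, 1e-300))


def satterthwaite_p(fit, coefficient: str) -> tuple[float, float]:
    """Satterthwaite degrees of freedom and two-sided t p-value for a
    fixed-effect coefficient of a fitted model (``fit_unmatched`` /
    ``fit_matched`` result)."""
    ctx: _LMMContext = fit._ctx
    if ctx is None:
        raise DataError("fit carries no mixed-model context (degenerate fit)")
    for fe in fit.fixed_effects():
        if fe.name == coefficient:
            refreshed = _fixed_effect(ctx, coefficient, fe.estimate)
            return refreshed.df, refreshed.p
    raise DataError(f"unknown coefficient {coefficient!r}")


# ---------------------------------------------------------------------------
# statsmodels-backed fitting


def _fit_mixedlm(df: pd.DataFrame, formula: str, groups: str, correlated: bool, reml: bool):
    import statsmodels.formula.api as smf

    kwargs = {"groups": df[groups]}
    if correlated:
        kwargs["re_formula"] = "~time"
    else:
        kwargs["re_formula"] = "1"
        kwargs["vc_formula"] = {"slope": "0 + time"}
    model = smf.mixedlm(formula, df, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method="lbfgs", maxiter=200)
            if not res.converged:
                res = model.fit(reml=reml, method="powell", maxiter=500)
        except Exception:
            res = model.fit(reml=reml, method="powell", maxiter=500)
    return res


def _theta_from_result(res, correlated: bool) -> np.ndarray:
    scale = float(res.scale)
    if correlated:
        cr = np.asarray(res.cov_re)
        return np.array([cr[0, 0], cr[0, 1], cr[1, 1], scale])
    v0 = float(np.asarray(res.cov_re)[0, 0])
    v1 = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    return np.array([v0, v1, scale])


def _make_ctx(df, ycol, xcols, names, group_col, theta, correlated, reml) -> _LMMContext:
    ys, Xs, Zs = [], [], []
    for _, g in df.groupby(group_col, sort=True):
        ys.append(g[ycol].to_numpy(float))
        Xs.append(np.column_stack([g[c].to_numpy(float) for c in xcols]))
        t = g["time"].to_numpy(float)
        Zs.append(np.column_stack([np.ones_like(t), t]))
    return _LMMContext(ys, Xs, Zs, list(names), np.asarray(theta, float), correlated, reml)


@dataclass
class UnmatchedModelFit:
    """Conventional two-arm longitudinal fit (intercept, slope, arm x time)."""

    beta0: FixedEffect
    beta1: FixedEffect
    beta2: FixedEffect
    sd_gamma0: float
    sd_gamma1: float
    sd_e: float
    reml: bool
    converged: bool
    arm_ref: str
    arm_test: str
    notes: list[str] = field(default_factory=list)
    _ctx: _LMMContext | None = None

    def fixed_effects(self) -> list[FixedEffect]:
        return [self.beta0, self.beta1, self.beta2]

    def summary_row(self) -> dict:
        return {
            "beta_intercept": self.beta0.estimate,
            "beta_slope": self.beta1.estimate,
            "beta_intervention": self.beta2.estimate,
            "p_intervention": self.beta2.p,
            "sd_gamma0": self.sd_gamma0,
            "sd_gamma1": self.sd_gamma1,
            "sd_e": self.sd_e,
        }


def fit_unmatched(
    data: LongitudinalTable,
    arm_ref: str,
    arm_test: str,
    reml: bool = True,
    correlated: bool = False,
) -> UnmatchedModelFit:
    """Fit the conventional unmatched growth model to two arms.

    The intervention effect is the arm-by-time interaction coefficient:
    the difference in growth slope of ``arm_test`` relative to
    ``arm_ref``. Random intercept and slope per unit are independent by
    default (``correlated=True`` estimates their covariance too).
    """
    df = data.data[data.data["arm"].astype(str).isin([str(arm_ref), str(arm_test)])].copy()
    for arm in (arm_ref, arm_test):
        units = df[df["arm"].astype(str) == str(arm)]["unit_id"].nunique()
        if units < 2:
            raise DataError(f"arm {arm!r} has {units} unit(s); need at least 2")
    if df.groupby("unit_id")["time"].nunique().min() < 2:
        raise DataError("every unit needs at least 2 time points")
    df["tx_time"] = (df["arm"].astype(str) == str(arm_test)).astype(float) * df["time"]

    names = ["Intercept", "time", "tx_time"]
    X = np.column_stack([np.ones(len(df)), df["time"], df["tx_time"]])
    y = df["response"].to_numpy(float)
    beta_ols, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    ssr = float(res_ss[0]) if len(res_ss) else float(((y - X @ beta_ols) ** 2).sum())
    if ssr <= 1e-10 * max(1.0, float((y**2).sum())):
        # deterministic limit: data lie exactly on the fixed-effect plane
        fes = [FixedEffect(n, float(b), 0.0, float(len(y) - 3), 0.0 if abs(b) > 1e-12 else 1.0, 0.0 if abs(b) > 1e-12 else 1.0) for n, b in zip(names, beta_ols)]
        return UnmatchedModelFit(*fes, 0.0, 0.0, 0.0, reml, True, str(arm_ref), str(arm_test), ["degenerate noise-free data; OLS solution is exact"], None)

    df["Intercept"] = 1.0
    res = _fit_mixedlm(df, "response ~ time + tx_time", "unit_id", correlated, reml)
    theta = _theta_from_result(res, correlated)
    ctx = _make_ctx(df, "response", ["Intercept", "time", "tx_time"], names, "unit_id", theta, correlated, reml)
    est = res.fe_params
    fes = [_fixed_effect(ctx, n, float(est.iloc[i])) for i, n in enumerate(names)]
    if correlated:
        sd0, sd1 = np.sqrt(theta[0]), np.sqrt(theta[2])
    else:
        sd0, sd1 = np.sqrt(theta[0]), np.sqrt(theta[1])
    fit = UnmatchedModelFit(
        fes[0], fes[1], fes[2], float(sd0), float(sd1), float(np.sqrt(theta[-1])),
        reml, bool(res.converged), str(arm_ref), str(arm_test), list(ctx.notes), ctx,
    )
    return fit


# ---------------------------------------------------------------------------
# paired differences and the matched model


@dataclass
class PairedDifferenceSeries:
    """Cross-arm response differences within submatches at shared time points."""

    pairs: list[tuple[str, str]]  # (test-arm unit i, reference-arm unit j)
    observations: pd.DataFrame  # columns: pair, time, delta
    arm_ref: str
    arm_test: str

    def __post_init__(self) -> None:
        need = {"pair", "time", "delta"}
        if not need.issubset(self.observations.columns):
            raise DataError(f"observations need columns {sorted(need)}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def swapped(self) -> "PairedDifferenceSeries":
        """Same series with the roles of the arms exchanged (all deltas negated)."""
        obs = self.observations.copy()
        obs["delta"] = -obs["delta"]
        return PairedDifferenceSeries(
            [(j, i) for i, j in self.pairs], obs, self.arm_test, self.arm_ref
        )


def build_paired_differences(
    data: LongitudinalTable,
    partition,
    plan,
    arm_ref: str,
    arm_test: str,
) -> PairedDifferenceSeries:
    """Pair each submatch's test-arm member with its reference-arm member.

    Differences delta = y(test) - y(ref) are formed only at time points
    where *both* members are observed: right-censoring of either member
    removes the later time points from the pair, so censored information
    never enters one-sidedly.
    """
    arm_of = {u: plan.assignments[u][1] for u in plan.unit_ids}
    resp: dict[str, pd.Series] = {
        str(u): g.set_index("time")["response"]
        for u, g in data.data.groupby("unit_id")
    }
    pairs: list[tuple[str, str]] = []
    rows = []
    for k, members in enumerate(partition.submatches):
        ids = [partition.unit_ids[u] for u in members]
        test = [u for u in ids if arm_of.get(u) == str(arm_test)]
        ref = [u for u in ids if arm_of.get(u) == str(arm_ref)]
        if len(test) != 1 or len(ref) != 1:
            raise DataError(
                f"submatch {k} does not contain exactly one unit of arm {arm_test!r} "
                f"and one of arm {arm_ref!r} (members: {ids})"
            )
        i, j = test[0], ref[0]
        if i not in resp or j not in resp:
            raise DataError(f"submatch {k}: no longitudinal observations for pair ({i}, {j})")
        shared = resp[i].index.intersection(resp[j].index)
        pairs.append((i, j))
        for t in sorted(shared):
            rows.append((f"{i}|{j}", float(t), float(resp[i].loc[t] - resp[j].loc[t])))
    obs = pd.DataFrame(rows, columns=["pair", "time", "delta"])
    return PairedDifferenceSeries(pairs, obs, str(arm_ref), str(arm_test))


@dataclass
class MatchedModelFit:
    """Paired-difference fit; the slope of delta vs time is the intervention effect."""

    beta_intervention: FixedEffect
    beta_intercept: float
    beta_slope: float
    sd_gamma0: float
    sd_gamma1: float
    sd_eps: float
    reml: bool
    converged: bool
    n_pairs: int
    notes: list[str] = field(default_factory=list)
    _ctx: _LMMContext | None = None

    def fixed_effects(self) -> list[FixedEffect]:
        return [self.beta_intervention]

    def summary_row(self) -> dict:
        return {
            "beta_intercept": self.beta_intercept,
            "beta_slope": self.beta_slope,
            "beta_intervention": self.beta_intervention.estimate,
            "p_intervention": self.beta_intervention.p,
            "sd_gamma0": self.sd_gamma0,
            "sd_gamma1": self.sd_gamma1,
            "sd_eps": self.sd_eps,
        }


def fit_matched(
    diffs: PairedDifferenceSeries,
    free_intercept_slope: bool = False,
    reml: bool = True,
    correlated: bool = False,
) -> MatchedModelFit:
    """Fit the paired-difference mixed model delta ~ b_intervention * time.

    Pair-level random intercept and random slope absorb between-pair
    heterogeneity. By default the fixed intercept and common slope are
    pinned to zero (redundant after pairing baseline-similar units);
    ``free_intercept_slope=True`` additionally frees the intercept — the
    freed common-slope term would be collinear with the intervention slope
    in a single contrast and stays at zero.
    """
    obs = diffs.observations
    if diffs.n_pairs < 2:
        raise DataError(f"need at least 2 pairs, got {diffs.n_pairs}")
    if obs.groupby("pair")["time"].nunique().min() < 2:
        raise DataError("every pair needs at least 2 shared time points")

    if np.allclose(obs["delta"], 0.0):
        fe = FixedEffect("time", 0.0, 0.0, float(len(obs) - 1), 1.0, 1.0)
        return MatchedModelFit(fe, 0.0, 0.0, 0.0, 0.0, 0.0, reml, True, diffs.n_pairs,
                               ["all paired differences are zero"], None)

    df = obs.rename(columns={"delta": "response"}).copy()
    formula = "response ~ time" if free_intercept_slope else "response ~ 0 + time"
    res = _fit_mixedlm(df, formula, "pair", correlated, reml)
    theta = _theta_from_result(res, correlated)
    if free_intercept_slope:
        names, xcols = ["Intercept", "time"], ["Intercept", "time"]
        df["Intercept"] = 1.0
    else:
        names, xcols = ["time"], ["time"]
    ctx = _make_ctx(df, "response", xcols, names, "pair", theta, correlated, reml)
    est = res.fe_params
    fe_time = _fixed_effect(ctx, "time", float(est["time"]))
    fe_time = FixedEffect("beta_intervention", fe_time.estimate, fe_time.se, fe_time.df, fe_time.p, fe_time.p_z)
    ctx.coef_names[ctx.coef_names.index("time")] = "beta_intervention"
    intercept = float(est["Intercept"]) if free_intercept_slope else 0.0
    if correlated:
        sd0, sd1 = np.sqrt(theta[0]), np.sqrt(theta[2])
    else:
        sd0, sd1 = np.sqrt(theta[0]), np.sqrt(theta[1])
    return MatchedModelFit(
        fe_time, intercept, 0.0, float(sd0), float(sd1), float(np.sqrt(theta[-1])),
        reml, bool(res.converged), diffs.n_pairs, list(ctx.notes), ctx,
    )


# ---------------------------------------------------------------------------
# paired multivariate endpoint test


def paired_hotelling_t2(endpoints: pd.DataFrame, pairs: list[tuple[str, str]]):
    """Paired Hotelling T^2 test of d endpoint measurements against zero.

    ``endpoints`` is indexed by unit id with one column per endpoint.
    For each pair (i, j) the difference vector x_i - x_j is formed and the
    one-sample T^2 statistic tests whether the mean difference vector is
    zero, with the exact F reference distribution. At d = 1 the statistic
    reduces to the squared paired t statistic.

    Returns ``(t2, f_stat, p)``.
    """
    endpoints = pd.DataFrame(endpoints)
    d = endpoints.shape[1]
    n = len(pairs)
    if n < d + 1:
        raise DataError(f"need at least d + 1 = {d + 1} pairs for d = {d} endpoints, got {n}")
    diffs = np.array(
        [endpoints.loc[i].to_numpy(float) - endpoints.loc[j].to_numpy(float) for i, j in pairs]
    )
    mean = diffs.mean(axis=0)
    if np.allclose(diffs, 0.0):
        return 0.0, 0.0, 1.0
    S = np.cov(diffs, rowvar=False, ddof=1).reshape(d, d)
    try:
        sol = np.linalg.solve(S, mean)
    except np.linalg.LinAlgError:
        raise DataError(
            "singular paired-difference covariance; consider dropping a redundant endpoint"
        ) from None
    if np.linalg.cond(S) > 1e12:
        raise DataError(
            "near-singular paired-difference covariance; consider dropping a redundant endpoint"
        )
    t2 = float(n * mean @ sol)
    f_stat = float(t2 * (n - d) / (d * (n - 1)))
    p = float(stats.f.sf(f_stat, d, n - d))
    return t2, f_stat, p
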