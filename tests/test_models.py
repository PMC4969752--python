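import subprocess
import textwrap
import warnings

import numpy as np
import pandas as pd
import pytest

import vivoplan as vp
from vivoplan.data_model import DataError, LongitudinalTable
from vivoplan.matching import SubmatchPartition
from vivoplan.allocation import randomize_within_submatches
from vivoplan.models import _LMMContext, _satterthwaite, PairedDifferenceSeries
from vivoplan.synthdata import SimulationScenario, generate_study


def _long(rows):
    return LongitudinalTable(pd.DataFrame(rows, columns=["unit_id", "time", "response", "arm"]))


def _noise_free_table(n_per_arm=2, times=range(5), b0=10.0, b1=2.0, b2=-1.0):
    rows = []
    for i in range(2 * n_per_arm):
        g2 = 1 if i >= n_per_arm else 0
        for t in times:
            rows.append((f"u{i}", t, b0 + b1 * t + b2 * g2 * t, "T" if g2 else "V"))
    return _long(rows)


def sim_paired_diffs(rng, n_pairs=15, sd_g0=7.0, sd_g1=7.4, sd_eps=11.2, slope=0.0,
                     times=np.arange(9.0)):
    """Simulate paired-difference trajectories directly from the matched model."""
    rows, pairs = [], []
    for k in range(n_pairs):
        g0, g1 = rng.normal(0, sd_g0), rng.normal(0, sd_g1)
        d = slope * times + g0 + g1 * times + rng.normal(0, sd_eps, times.size)
        pairs.append((f"i{k}", f"j{k}"))
        rows += [(f"p{k}", float(t), float(v)) for t, v in zip(times, d)]
    return PairedDifferenceSeries(pairs, pd.DataFrame(rows, columns=["pair", "time", "delta"]), "V", "T")


class TestFitUnmatched:
    def test_noise_free_data_recovers_exact_coefficients(self):
        fit = vp.fit_unmatched(_noise_free_table(), "V", "T")
        assert fit.beta0.estimate == pytest.approx(10.0)
        assert fit.beta1.estimate == pytest.approx(2.0)
        assert fit.beta2.estimate == pytest.approx(-1.0)
        assert fit.converged

    def test_swapping_arms_negates_effect_keeps_p(self):
        sc = SimulationScenario(n_units=16, arms=("V", "T"), arm_offsets=(0.0, -4.0), seed=21)
        *_, lt = generate_study(sc, seed=21)
        f1 = vp.fit_unmatched(lt, "V", "T")
        f2 = vp.fit_unmatched(lt, "T", "V")
        assert f1.beta2.estimate == pytest.approx(-f2.beta2.estimate, rel=1e-5)
        assert f1.beta2.p == pytest.approx(f2.beta2.p, rel=1e-4)

    def test_time_shift_leaves_intervention_effect(self):
        sc = SimulationScenario(n_units=12, arms=("V", "T"), arm_offsets=(0.0, -3.0), seed=8)
        *_, lt = generate_study(sc, seed=8)
        shifted = LongitudinalTable(lt.data.assign(time=lt.data["time"] * 1.0))
        shifted.data.loc[:, "response"] += 5.0  # constant shift absorbed by intercept
        f1 = vp.fit_unmatched(lt, "V", "T")
        f2 = vp.fit_unmatched(shifted, "V", "T")
        assert f1.beta2.estimate == pytest.approx(f2.beta2.estimate, rel=1e-6)

    def test_too_few_units_rejected(self):
        rows = [("u0", t, 1.0 + t, "V") for t in range(3)] + [("u1", t, 1.0 + t, "T") for t in range(3)]
        with pytest.raises(DataError, match="at least 2"):
            vp.fit_unmatched(_long(rows), "V", "T")


class TestBuildPairedDifferences:
    @pytest.fixture
    def study(self):
        sc = SimulationScenario(n_units=12, arms=("V", "T"), arm_offsets=(0.0, -3.0), seed=31)
        table, hidden, part, plan, lt = generate_study(sc, seed=31)
        return part, plan, lt

    def test_one_pair_per_submatch(self, study):
        part, plan, lt = study
        diffs = vp.build_paired_differences(lt, part, plan, "V", "T")
        assert diffs.n_pairs == len(part.submatches)
        for i, j in diffs.pairs:
            assert plan.assignments[i][1] == "T" and plan.assignments[j][1] == "V"
            assert plan.assignments[i][0] == plan.assignments[j][0]

    def test_identical_trajectories_give_zero_deltas(self):
        rows = [(u, t, 5.0 + t, a) for u, a in [("a", "V"), ("b", "T")] for t in range(4)]
        part = SubmatchPartition([(0, 1)], 0.0, "exact", True, ["a", "b"])
        plan = randomize_within_submatches(part, ["V", "T"], seed=1)
        lt = _long([(u, t, 5.0 + t, plan.assignments[u][1]) for u in ("a", "b") for t in range(4)])
        diffs = vp.build_paired_differences(lt, part, plan, "V", "T")
        assert np.allclose(diffs.observations["delta"], 0.0)

    def test_censoring_truncates_pair_to_shared_times(self, study):
        part, plan, lt = study
        i0, j0 = vp.build_paired_differences(lt, part, plan, "V", "T").pairs[0]
        censored = LongitudinalTable(
            lt.data[~((lt.data["unit_id"] == i0) & (lt.data["time"] > 3))].reset_index(drop=True)
        )
        diffs = vp.build_paired_differences(censored, part, plan, "V", "T")
        times = diffs.observations.loc[diffs.observations["pair"] == f"{i0}|{j0}", "time"]
        assert times.max() == 3  # the reference member's later points drop out too

    def test_swap_negates_all_deltas(self, study):
        part, plan, lt = study
        d1 = vp.build_paired_differences(lt, part, plan, "V", "T")
        d2 = vp.build_paired_differences(lt, part, plan, "T", "V")
        m = d1.observations.merge(d2.observations, on=["time"], suffixes=("_a", "_b"))
        s1 = d1.observations.sort_values(["time", "delta"])["delta"].to_numpy()
        s2 = -d2.observations.sort_values(["time", "delta"], ascending=[True, False])["delta"].to_numpy()
        assert np.allclose(s1, s2)
        assert d1.swapped().observations["delta"].equals(-d1.observations["delta"])

    def test_missing_arm_in_submatch_is_error(self, study):
        part, plan, lt = study
        with pytest.raises(DataError, match="submatch"):
            vp.build_paired_differences(lt, part, plan, "V", "NoSuchArm")


class TestFitMatched:
    def test_all_zero_deltas(self):
        rows = [(f"p{k}", float(t), 0.0) for k in range(3) for t in range(4)]
        diffs = PairedDifferenceSeries([("a", "b"), ("c", "d"), ("e", "f")],
                                       pd.DataFrame(rows, columns=["pair", "time", "delta"]), "V", "T")
        fit = vp.fit_matched(diffs)
        assert fit.beta_intervention.estimate == 0.0 and fit.beta_intervention.p == 1.0

    def test_fewer_than_two_pairs_rejected(self):
        rows = [("p0", float(t), 1.0 * t) for t in range(4)]
        diffs = PairedDifferenceSeries([("a", "b")], pd.DataFrame(rows, columns=["pair", "time", "delta"]), "V", "T")
        with pytest.raises(DataError, match="2 pairs"):
            vp.fit_matched(diffs)

    def test_parameter_recovery_over_seeds(self):
        # true slope -5 with VCaP-like pair variance components
        ests = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(60):
                fit = vp.fit_matched(sim_paired_diffs(np.random.default_rng(700 + s), slope=-5.0))
                ests.append(fit.beta_intervention.estimate)
        ests = np.array(ests)
        mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - (-5.0)) < 3 * mc_se

    def test_free_intercept_reported(self):
        rng = np.random.default_rng(5)
        diffs = sim_paired_diffs(rng, slope=-3.0)
        shifted = PairedDifferenceSeries(
            diffs.pairs, diffs.observations.assign(delta=diffs.observations["delta"] + 4.0),
            diffs.arm_ref, diffs.arm_test)
        fit = vp.fit_matched(shifted, free_intercept_slope=True)
        assert fit.beta_intercept == pytest.approx(4.0, abs=3.0)  # noisy but centred at 4
        assert fit.beta_slope == 0.0


class TestSatterthwaite:
    def test_balanced_random_intercept_df_is_clusters_minus_one(self):
        rng = np.random.default_rng(3)
        k, n = 8, 5
        Y = np.array([10 + rng.normal(0, 2.0) + rng.normal(0, 1.0, n) for _ in range(k)])
        msw = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum() / (k * (n - 1))
        msb = n * ((Y.mean(axis=1) - Y.mean()) ** 2).sum() / (k - 1)
        ctx = _LMMContext(
            y=[Y[i] for i in range(k)],
            X=[np.ones((n, 1))] * k,
            Z=[np.ones((n, 1))] * k,
            coef_names=["Intercept"],
            theta=np.array([max((msb - msw) / n, 0.0), msw]),
            correlated=False,
            reml=True,
        )
        df, fellback = _satterthwaite(ctx, np.array([1.0]))
        assert not fellback
        assert df == pytest.approx(k - 1, rel=1e-4)

    def test_df_bounded_by_residual_df(self):
        sc = SimulationScenario(n_units=12, arms=("V", "T"), arm_offsets=(0.0, -3.0), seed=13)
        *_, lt = generate_study(sc, seed=13)
        fit = vp.fit_unmatched(lt, "V", "T")
        for fe in fit.fixed_effects():
            assert 0 < fe.df <= len(lt.data) - 3

    def test_public_api_matches_fit_values(self):
        rng = np.random.default_rng(9)
        fit = vp.fit_matched(sim_paired_diffs(rng, slope=-4.0))
        df, p = vp.satterthwaite_p(fit, "beta_intervention")
        assert df == pytest.approx(fit.beta_intervention.df)
        assert p == pytest.approx(fit.beta_intervention.p)


class TestPairedHotelling:
    def test_univariate_reduces_to_squared_paired_t(self, rng):
        from scipy import stats

        x, y = rng.normal(size=8), rng.normal(size=8)
        ep = pd.DataFrame({"v": np.concatenate([x, y])},
                          index=[f"i{k}" for k in range(8)] + [f"j{k}" for k in range(8)])
        pairs = [(f"i{k}", f"j{k}") for k in range(8)]
        t2, f, p = vp.paired_hotelling_t2(ep, pairs)
        tt = stats.ttest_1samp(x - y, 0.0)
        assert t2 == pytest.approx(tt.statistic**2)
        assert p == pytest.approx(tt.pvalue)

    def test_zero_differences(self, rng):
        base = rng.normal(size=(5, 2))
        ep = pd.DataFrame(np.vstack([base, base]), columns=["a", "b"],
                          index=[f"i{k}" for k in range(5)] + [f"j{k}" for k in range(5)])
        t2, f, p = vp.paired_hotelling_t2(ep, [(f"i{k}", f"j{k}") for k in range(5)])
        assert t2 == 0.0 and p == 1.0

    def test_singular_covariance_rejected(self, rng):
        x = rng.normal(size=6)
        ep = pd.DataFrame({"a": np.concatenate([x, np.zeros(6)]),
                           "b": np.concatenate([2 * x, np.zeros(6)])},
                          index=[f"i{k}" for k in range(6)] + [f"j{k}" for k in range(6)])
        with pytest.raises(DataError, match="singular"):
            vp.paired_hotelling_t2(ep, [(f"i{k}", f"j{k}") for k in range(6)])

    def test_too_few_pairs_rejected(self, rng):
        ep = pd.DataFrame(rng.normal(size=(4, 2)), columns=["a", "b"], index=list("wxyz"))
        with pytest.raises(DataError, match="pairs"):
            vp.paired_hotelling_t2(ep, [("w", "x"), ("y", "z")])


class TestAgainstLme4:
    """Cross-check against lme4/lmerTest (independent reference) on one fixture."""

    def test_matched_fit_matches_lmer(self, tmp_path):
        sc = SimulationScenario(n_units=16, arms=("V", "T"), arm_offsets=(0.0, -4.0),
                                sd_gamma1=3.0, seed=11)
        table, hidden, part, plan, lt = generate_study(sc, seed=11)
        diffs = vp.build_paired_differences(lt, part, plan, "V", "T")
        fit = vp.fit_matched(diffs)
        csv = tmp_path / "diffs.csv"
        diffs.observations.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            m <- lmer(delta ~ 0 + time + (1|pair) + (0+time|pair), data=d, REML=TRUE)
            s <- summary(m)$coefficients
            cat(s[1,1], s[1,2], s[1,3], s[1,5], sep=",")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        est, se, df, p = (float(x) for x in out.stdout.strip().split(","))
        assert fit.beta_intervention.estimate == pytest.approx(est, rel=1e-4)
        assert fit.beta_intervention.se == pytest.approx(se, rel=1e-3)
        assert fit.beta_intervention.df == pytest.approx(df, rel=5e-3)
        assert fit.beta_intervention.p == pytest.approx(p, rel=2e-2)
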