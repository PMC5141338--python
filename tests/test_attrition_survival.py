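import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from surveyattrition.attrition_survival import (
    DropoutSurvivalData,
    RankDeficientError,
    _partial_loglik,
    build_survival_data,
    cox_fit,
    kaplan_meier,
    logrank_test,
    screen_then_adjust,
)
from surveyattrition.attrition_summary import ConfigError
from surveyattrition.simulate import (
    CovariateSpec,
    SimulationConfig,
    preset,
    simulate_survey,
)

from conftest import make_rm


def _sd(times, events, index=None, **cols):
    idx = index or [f"s{i}" for i in range(len(times))]
    df = pd.DataFrame({"time": times, "event": events, **cols}, index=idx)
    return DropoutSurvivalData(df, n_items=int(max(times)))


class TestBuildSurvivalData:
    def test_times_events_from_classification(self):
        rm = make_rm([[1] * 12, [1] * 4 + [0] * 8])
        sd = build_survival_data(rm)
        assert sd.table.loc["s0", "event"] == 0
        assert sd.table.loc["s0", "time"] == 12  # completer censored at end
        assert sd.table.loc["s1", "time"] == 5 and sd.table.loc["s1", "event"] == 1

    def test_event_count_conservation(self, paper_like_sim):
        _, rm, covs, _ = paper_like_sim
        from surveyattrition.survey_data import classify_cells

        sd = build_survival_data(rm, covs)
        n_completers = classify_cells(rm).is_completer.sum()
        assert sd.event.sum() == rm.n_subjects - n_completers


class TestLogRank:
    def test_identical_groups_are_null(self):
        t = [2, 3, 5, 5, 7, 2, 3, 5, 5, 7]
        e = [1, 1, 0, 1, 0] * 2
        lr = logrank_test(_sd(t, e, grp=list("aaaaabbbbb")), "grp")
        assert lr.statistic == pytest.approx(0.0, abs=1e-12)
        assert lr.p_value == pytest.approx(1.0)

    def test_hand_worked_toy_value(self):
        # A dropping at 2,3,4 vs B at 4,5,6 (all events):
        # O_A = 3, E_A = 0.5 + 0.4 + 0.5 = 1.4, V = 0.25 + 0.24 + 0.25
        lr = logrank_test(
            _sd([2, 3, 4, 4, 5, 6], [1] * 6, grp=list("AAABBB")), "grp")
        assert lr.statistic == pytest.approx((3 - 1.4) ** 2 / 0.74)
        assert dict(lr.expected)["A"] == pytest.approx(1.4)

    def test_observed_equals_expected_in_total(self, paper_like_sim):
        _, rm, covs, _ = paper_like_sim
        lr = logrank_test(build_survival_data(rm, covs), "group")
        assert lr.observed.sum() == pytest.approx(lr.expected.sum(), abs=1e-8)

    def test_group_label_swap_invariance(self):
        t = [2, 3, 4, 4, 5, 6]
        a = logrank_test(_sd(t, [1] * 6, grp=list("AAABBB")), "grp")
        b = logrank_test(_sd(t, [1] * 6, grp=list("BBBAAA")), "grp")
        assert a.statistic == pytest.approx(b.statistic)

    def test_matches_established_implementation(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(314)
        for _ in range(20):
            n = int(rng.integers(40, 200))
            t = rng.integers(2, 10, n)
            e = rng.integers(0, 2, n)
            g = rng.choice(list("abc"), n)
            if e.sum() == 0 or len(np.unique(g)) < 2:
                continue
            lr = logrank_test(_sd(t, e, grp=g), "grp")
            ref = multivariate_logrank_test(t, g, e)
            assert lr.statistic == pytest.approx(ref.test_statistic, abs=1e-6)
            assert lr.p_value == pytest.approx(ref.p_value, abs=1e-6)

    def test_power_and_size_two_group(self):
        hits_alt = hits_null = 0
        n_rep = 60
        for r in range(n_rep):
            alt = SimulationConfig(
                group_sizes={"a": 600, "b": 600}, n_items=8,
                hazard=np.full(7, 0.08), group_log_hr={"a": np.log(1.5)},
                seed=1000 + r)
            rm, covs, _ = simulate_survey(alt)
            lr = logrank_test(build_survival_data(rm, covs), "group")
            hits_alt += lr.p_value < 0.05
            null = SimulationConfig(
                group_sizes={"a": 600, "b": 600}, n_items=8,
                hazard=np.full(7, 0.08), seed=5000 + r)
            rm, covs, _ = simulate_survey(null)
            lr = logrank_test(build_survival_data(rm, covs), "group")
            hits_null += lr.p_value < 0.05
        assert hits_alt / n_rep >= 0.8
        assert hits_null / n_rep <= 0.15

    def test_single_group_rejected(self):
        with pytest.raises(ConfigError):
            logrank_test(_sd([2, 3], [1, 1], grp=["a", "a"]), "grp")


class TestKaplanMeier:
    def test_product_limit_against_established(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(7)
        t = rng.integers(2, 12, 150)
        e = rng.integers(0, 2, 150)
        km = kaplan_meier(t, e)
        ref = KaplanMeierFitter().fit(t, e)
        for _, row in km.iterrows():
            assert row["survival"] == pytest.approx(
                float(ref.predict(row["time"])), abs=1e-10)


class TestCoxFit:
    def test_hand_maximized_partial_likelihood_no_ties(self):
        # times 2,3,4,5 all events, x = (1,0,1,0); no ties so Efron and
        # Breslow coincide with the plain partial likelihood:
        # l(b) = [b - ln(2e^b + 2)] + [-ln(e^b + 2)] + [b - ln(e^b + 1)]
        def neg_l(b):
            return -((b - np.log(2 * np.exp(b) + 2))
                     + (0 - np.log(np.exp(b) + 2))
                     + (b - np.log(np.exp(b) + 1)))

        oracle = minimize_scalar(neg_l, bounds=(-5, 5), method="bounded",
                                 options={"xatol": 1e-12})
        sd = _sd([2, 3, 4, 5], [1] * 4, x=[1.0, 0.0, 1.0, 0.0])
        for ties in ("efron", "breslow"):
            fit = cox_fit(sd, ["x"], tie_method=ties, ph_check=False)
            assert fit.summary.loc["x", "coef"] == pytest.approx(
                oracle.x, abs=1e-6)

    def test_matches_established_implementation(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(99)
        for rep in range(20):
            n = int(rng.integers(80, 250))
            t = rng.integers(2, 10, n)
            e = rng.integers(0, 2, n)
            x1 = rng.normal(size=n)
            x2 = rng.integers(0, 2, n).astype(float)
            if e.sum() < 10:
                continue
            sd = _sd(t, e, x1=x1, x2=x2)
            fit = cox_fit(sd, ["x1", "x2"], ph_check=False)
            df = sd.table[["time", "event", "x1", "x2"]]
            ref = CoxPHFitter().fit(df, "time", "event")
            np.testing.assert_allclose(
                fit.summary["coef"].to_numpy(), ref.params_.to_numpy(),
                atol=1e-4)
            np.testing.assert_allclose(
                fit.summary["se"].to_numpy(),
                ref.standard_errors_.to_numpy(), atol=1e-4)

    def test_null_covariate_within_three_se(self):
        cfg = SimulationConfig(
            group_sizes={"g": 2000}, n_items=10, hazard=np.full(9, 0.08),
            covariates=(CovariateSpec(name="noise", kind="normal",
                                      mean=0, sd=1, effect=0.0),),
            seed=55)
        rm, covs, _ = simulate_survey(cfg)
        fit = cox_fit(build_survival_data(rm, covs), ["noise"], ph_check=False)
        row = fit.summary.loc["noise"]
        assert abs(row["coef"]) < 3 * row["se"]

    def test_hazard_ratio_recovery(self):
        # true hazard odds ratio 2 on a small per-item hazard, frailty 0
        cfg = SimulationConfig(
            group_sizes={"g": 2000}, n_items=12, hazard=np.full(11, 0.05),
            covariates=(CovariateSpec(name="exposed", kind="categorical",
                                      levels=(0, 1), probs=[0.5, 0.5],
                                      effect={1: np.log(2.0), 0: 0.0}),),
            seed=77)
        rm, covs, _ = simulate_survey(cfg)
        fit = cox_fit(build_survival_data(rm, covs), ["exposed"],
                      ph_check=False)
        row = fit.summary.loc["exposed"]  # numeric 0/1 stays a single column
        assert abs(row["coef"] - np.log(2.0)) < 3 * row["se"]

    def test_score_test_at_zero_equals_logrank_without_ties(self):
        rng = np.random.default_rng(13)
        n = 40
        t = rng.permutation(np.arange(2, 2 + n)).astype(float)  # no ties
        e = np.ones(n, dtype=int)
        x = rng.integers(0, 2, n).astype(float)
        if len(np.unique(x)) < 2:
            x[0] = 1 - x[0]
        sd = _sd(t, e, grp=np.where(x > 0, "a", "b"), x=x)
        lr = logrank_test(sd, "grp")
        _, g, H = _partial_loglik(np.zeros(1), sd.time, sd.event,
                                  x[:, None], None, "efron")
        score_stat = float(g @ np.linalg.solve(-H, g))
        assert score_stat == pytest.approx(lr.statistic, abs=1e-6)

    def test_affine_covariate_rescaling(self):
        rng = np.random.default_rng(3)
        t = rng.integers(2, 9, 300)
        e = rng.integers(0, 2, 300)
        age = rng.normal(60, 10, 300)
        f1 = cox_fit(_sd(t, e, age=age), ["age"], ph_check=False)
        f2 = cox_fit(_sd(t, e, age=age / 10), ["age"], ph_check=False)
        assert f2.summary.loc["age", "coef"] == pytest.approx(
            10 * f1.summary.loc["age", "coef"], rel=1e-5)

    def test_loglik_improves_over_null(self, paper_like_sim):
        _, rm, covs, _ = paper_like_sim
        fit = cox_fit(build_survival_data(rm, covs), ["group"], ph_check=False)
        assert fit.loglik >= fit.loglik_null

    def test_collinear_columns_named(self):
        t = [2, 3, 4, 5, 6, 7]
        e = [1] * 6
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        sd = _sd(t, e, x=x, x2=[2 * v for v in x])
        with pytest.raises(RankDeficientError, match="x"):
            cox_fit(sd, ["x", "x2"], ph_check=False)

    def test_too_few_events_rejected(self):
        sd = _sd([2, 3, 4], [1, 0, 0], x=[1.0, 0.0, 1.0])
        with pytest.raises(ConfigError):
            cox_fit(sd, ["x"], ph_check=False)

    def test_ph_check_runs_per_covariate(self, paper_like_sim):
        _, rm, covs, _ = paper_like_sim
        fit = cox_fit(build_survival_data(rm, covs), ["group", "age"])
        assert set(fit.ph_check) == {"group", "age"}
        assert all(0 <= p <= 1 for p in fit.ph_check.values())


class TestScreenThenAdjust:
    def test_screening_retains_strong_covariate_and_adjusts(self):
        cfg = SimulationConfig(
            group_sizes={"g": 3000}, n_items=10, hazard=np.full(9, 0.07),
            covariates=(
                CovariateSpec(name="gender", kind="categorical",
                              levels=("F", "M"), probs=[0.5, 0.5],
                              effect={"F": 0.25, "M": 0.0}),
                CovariateSpec(name="phase", kind="categorical",
                              levels=("p1", "p2"), probs=[0.5, 0.5],
                              effect={"p1": 0.0, "p2": 0.6}),
                CovariateSpec(name="noise", kind="normal", mean=0, sd=1,
                              effect=0.0),
            ),
            seed=404)
        rm, covs, _ = simulate_survey(cfg)
        sd = build_survival_data(rm, covs)
        res = screen_then_adjust(sd, "gender", ["phase", "noise"])
        assert "phase" in res.retained
        assert "noise" not in res.retained
        assert "gender_M" in res.final.summary.index
        assert any(t.startswith("phase_") for t in res.final.summary.index)
        assert set(res.labels) <= {"phase"}

    def test_no_retained_candidates_returns_unadjusted(self):
        rng = np.random.default_rng(8)
        t = rng.integers(2, 9, 400)
        e = rng.integers(0, 2, 400)
        sd = _sd(t, e, x=rng.normal(size=400), z=rng.normal(size=400))
        res = screen_then_adjust(sd, "x", ["z"])
        assert res.retained == []
        assert res.final is res.unadjusted
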