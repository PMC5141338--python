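import numpy as np
import pytest

from surveyattrition.simulate import (
    PAPER_LIKE_GROUP_SIZES,
    PAPER_LIKE_PROPORTIONS,
    CovariateSpec,
    SimConfigError,
    SimulationConfig,
    calibrate_hazard,
    expected_proportions,
    preset,
    simulate_survey,
    trailing_skip_misclassification_rate,
)


def _basic(n=2000, n_items=8, h=0.1, s=0.0, frailty=0.0, seed=0, **kw):
    return SimulationConfig(group_sizes={"g": n}, n_items=n_items,
                            hazard=np.full(n_items - 1, h), skip_prob=s,
                            frailty_sd=frailty, seed=seed, **kw)


class TestSimulateSurvey:
    def test_degenerate_config_all_complete(self):
        rm, _, truth = simulate_survey(_basic(n=200, h=0.0))
        assert rm.answered.all()
        assert (truth["latent_T"] == 9).all()

    def test_closed_form_discrete_survival(self):
        cfg = _basic(n=10000, h=0.1, seed=7)
        rm, _, _ = simulate_survey(cfg)
        q = np.arange(1, 9)
        expected = 0.9 ** (q - 1)
        se = np.sqrt(expected * (1 - expected) / 10000)
        obs = rm.answered.mean(axis=0)
        assert (np.abs(obs - expected) <= 3 * np.maximum(se, 1e-12)).all()

    def test_marginal_formula_with_skips(self):
        h = np.array([0.05, 0.2, 0.0, 0.1, 0.02, 0.0, 0.08])
        s = np.array([0.0, 0.03, 0.1, 0.0, 0.05, 0.0, 0.02, 0.04])
        cfg = SimulationConfig(group_sizes={"g": 20000}, n_items=8, hazard=h,
                               skip_prob=s, seed=5)
        rm, _, truth = simulate_survey(cfg)
        expected = (1 - s) * np.concatenate([[1.0], np.cumprod(1 - h)])
        np.testing.assert_allclose(expected, expected_proportions(cfg))
        # subjects answering zero items are excluded, so count answers over all
        n_total = len(truth)
        obs = np.zeros(8)
        obs[: rm.n_items] = rm.answered.sum(axis=0) / n_total
        se = np.sqrt(expected * (1 - expected) / n_total)
        assert (np.abs(obs - expected) <= 3 * np.maximum(se, 1e-9)).all()

    def test_bit_identical_under_fixed_seed(self):
        a, _, _ = simulate_survey(_basic(seed=3, s=0.05, frailty=0.5))
        b, _, _ = simulate_survey(_basic(seed=3, s=0.05, frailty=0.5))
        np.testing.assert_array_equal(a.answered, b.answered)
        c, _, _ = simulate_survey(_basic(seed=4, s=0.05, frailty=0.5))
        assert not np.array_equal(a.answered, c.answered)

    def test_adding_subjects_preserves_existing_streams(self):
        small, _, _ = simulate_survey(_basic(n=100, s=0.05, frailty=0.5, seed=9))
        large, _, _ = simulate_survey(_basic(n=150, s=0.05, frailty=0.5, seed=9))
        np.testing.assert_array_equal(small.answered, large.answered[:100])

    def test_frailty_expectation_matches_quadrature(self):
        cfg = _basic(n=20000, h=0.1, frailty=0.75, seed=13)
        rm, _, _ = simulate_survey(cfg)
        exp = expected_proportions(cfg)
        se = np.sqrt(exp * (1 - exp) / 20000)
        z = (rm.answered.mean(axis=0) - exp) / np.maximum(se, 1e-12)
        # 8 correlated per-item deviations; a bound of 4 SDs is conservative
        assert np.abs(z[1:]).max() < 4.0

    def test_group_effect_orders_attrition(self):
        cfg = SimulationConfig(
            group_sizes={"hi": 3000, "lo": 3000}, n_items=6,
            hazard=np.full(5, 0.15), group_log_hr={"hi": 0.5, "lo": -0.5},
            seed=21,
        )
        rm, covs, _ = simulate_survey(cfg)
        last = rm.answered[:, -1]
        grp = covs.aligned_to(rm)["group"].to_numpy()
        assert last[grp == "lo"].mean() > last[grp == "hi"].mean()

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_items=1, hazard=[]),
            dict(hazard=[1.2] + [0.1] * 6),
            dict(hazard=[0.1] * 3),
            dict(frailty_sd=-1.0),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        base = dict(group_sizes={"g": 10}, n_items=8,
                    hazard=np.full(7, 0.1))
        base.update(kw)
        with pytest.raises(SimConfigError):
            SimulationConfig(**base)


class TestPaperLikePreset:
    def test_starter_count(self, paper_like_sim):
        _, rm, _, _ = paper_like_sim
        assert rm.n_subjects + rm.n_excluded == sum(PAPER_LIKE_GROUP_SIZES.values())

    def test_calibrated_expectation_hits_target_curve(self):
        cfg = preset("paper_like")
        np.testing.assert_allclose(
            expected_proportions(cfg), PAPER_LIKE_PROPORTIONS, atol=1e-8
        )

    def test_outcome_linked_to_completion(self):
        cfg = preset("paper_like", seed=29)
        rm, covs, _ = simulate_survey(cfg)
        from surveyattrition.survey_data import classify_cells

        grid = classify_cells(rm)
        out = covs.aligned_to(rm)["screening_obtained"].to_numpy()
        comp = grid.is_completer
        p_c = out[comp].mean()
        se = np.sqrt(0.2237 * (1 - 0.2237) / comp.sum())
        assert abs(p_c - 0.2237) < 3 * se

    def test_attrition_curve_is_non_monotone(self):
        # the skip-induced rise at item 6 must survive in expectation
        exp = expected_proportions(preset("paper_like"))
        assert exp[5] > exp[4]


class TestCalibrateHazard:
    def test_base_skip_spreads_sporadic_skips(self):
        hz, skip = calibrate_hazard(PAPER_LIKE_PROPORTIONS,
                                    {"g": 1000}, base_skip=0.02)
        assert skip[0] == 0.0          # target proportion 1.0 forbids skipping
        assert (skip[1:] >= 0.02 - 1e-12).all()

    def test_calibration_with_frailty_and_groups(self):
        covs = (CovariateSpec(name="x", kind="categorical", levels=("a", "b"),
                              probs=[0.5, 0.5], effect={"a": 0.3, "b": 0.0}),)
        hz, skip = calibrate_hazard(
            [1.0, 0.8, 0.6, 0.55], {"g1": 500, "g2": 500}, frailty_sd=1.0,
            group_log_hr={"g1": 0.2, "g2": -0.2}, covariates=covs,
        )
        cfg = SimulationConfig(group_sizes={"g1": 500, "g2": 500}, n_items=4,
                               hazard=hz, skip_prob=skip, frailty_sd=1.0,
                               group_log_hr={"g1": 0.2, "g2": -0.2},
                               covariates=covs)
        np.testing.assert_allclose(expected_proportions(cfg),
                                   [1.0, 0.8, 0.6, 0.55], atol=1e-8)


class TestTrailingSkipMisclassification:
    def test_zero_without_skips(self):
        assert trailing_skip_misclassification_rate(
            _basic(n=500, h=0.1), replicates=2) == 0.0

    def test_bounded_by_skip_rate(self):
        rate = trailing_skip_misclassification_rate(
            _basic(n=2000, h=0.1, s=0.05), replicates=5)
        assert 0.0 < rate < 0.05

    def test_monotone_in_skip_probability(self):
        rates = [
            trailing_skip_misclassification_rate(
                _basic(n=4000, h=0.1, s=s, seed=31), replicates=5)
            for s in (0.01, 0.05, 0.1)
        ]
        assert rates[0] < rates[1] < rates[2]
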