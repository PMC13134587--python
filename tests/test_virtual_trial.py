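import numpy as np
import pandas as pd
import pytest

from poaf_twin.synth_cohort import GroundTruthConfig, generate_cohort
from poaf_twin.virtual_trial import (
    InterventionPolicy,
    TrialConfig,
    apply_policy,
    km_curve,
    logrank_test,
    randomize_arms,
    relative_risk_reduction,
    simulate_trial,
    two_proportion_test,
    window_sweep,
)


class TestRandomizeArms:
    def test_ten_thousand_split_evenly(self, cohort_10k):
        a, b = randomize_arms(cohort_10k, seed=0)
        assert len(a) == len(b) == 5000

    def test_same_seed_same_allocation(self, cohort_small):
        a1, _ = randomize_arms(cohort_small, seed=3)
        a2, _ = randomize_arms(cohort_small, seed=3)
        pd.testing.assert_frame_equal(a1, a2)

    def test_partition(self, cohort_small):
        a, b = randomize_arms(cohort_small, seed=1)
        assert set(a.id) | set(b.id) == set(cohort_small.id)
        assert set(a.id) & set(b.id) == set()

    def test_odd_n_rejected(self, cohort_small):
        with pytest.raises(ValueError, match="drop one record"):
            randomize_arms(cohort_small.head(7), seed=0)


class TestApplyPolicy:
    def test_below_threshold_untreated(self, cohort_small, gt_config):
        policy = InterventionPolicy(risk_threshold=0.9)
        prob = np.full(len(cohort_small), 0.1)
        mult, out = apply_policy(cohort_small, prob, policy, gt_config)
        assert np.all(mult == 1.0)
        pd.testing.assert_frame_equal(out, cohort_small)

    def test_potassium_raised_to_target(self, cohort_small, gt_config):
        df = cohort_small.head(1).copy()
        df["potassium_meq_l"] = 3.6
        policy = InterventionPolicy(risk_threshold=0.0)
        _, out = apply_policy(df, np.array([0.5]), policy, gt_config)
        assert out["potassium_meq_l"].iloc[0] == 4.0

    def test_electrolytes_above_target_untouched(self, cohort_small,
                                                 gt_config):
        df = cohort_small.head(1).copy()
        df["potassium_meq_l"] = 4.8
        policy = InterventionPolicy(risk_threshold=0.0)
        _, out = apply_policy(df, np.array([0.5]), policy, gt_config)
        assert out["potassium_meq_l"].iloc[0] == 4.8

    def test_lead_time_scales_multiplier(self, cohort_small, gt_config):
        prob = np.full(len(cohort_small), 0.9)
        m_opt, _ = apply_policy(cohort_small, prob,
                                InterventionPolicy(risk_threshold=0.0,
                                                   lead_time_h=60.0),
                                gt_config)
        m_zero, _ = apply_policy(cohort_small, prob,
                                 InterventionPolicy(risk_threshold=0.0,
                                                    lead_time_h=0.0),
                                 gt_config)
        assert m_opt.max() < m_zero.min()


class TestSimulateTrial:
    def test_null_intervention_identical_arms_distribution(self, cohort_10k,
                                                           panel_10k,
                                                           gt_config):
        """hazard multiplier 1 with electrolyte targets at 0: the RRR is
        within Monte-Carlo noise of zero."""
        policy = InterventionPolicy(hazard_multiplier=1.0, k_target=0.0,
                                    mg_target=0.0)
        rep = simulate_trial(cohort_10k, panel_10k["twin_prob"], gt_config,
                             TrialConfig(seed=5), policy)
        p = gt_config.target_7day_incidence
        se_rrr = 100 / p * np.sqrt(2 * p * (1 - p) / 5000)
        assert abs(rep.rrr_percent) < 3 * se_rrr

    def test_absorbing_multiplier_zero(self, cohort_small):
        """A fully effective, perfectly timed drug (multiplier ~ 0 with a
        benefit profile reaching 0) abolishes intervention-arm POAF."""
        cfg = GroundTruthConfig(
            benefit_profile={0.0: 1.0, 48.0: 0.0, 72.0: 0.0, 120.0: 1.0})
        df = cohort_small.head(200)
        policy = InterventionPolicy(risk_threshold=0.0,
                                    hazard_multiplier=1e-12,
                                    lead_time_h=60.0)
        rep = simulate_trial(df, np.full(200, 0.9), cfg,
                             TrialConfig(seed=2), policy)
        assert rep.intervention.poaf_events == 0

    def test_control_incidence_near_configured_target(self, cohort_10k,
                                                      panel_10k, gt_config):
        rep = simulate_trial(cohort_10k, panel_10k["twin_prob"], gt_config,
                             TrialConfig(seed=11))
        target = gt_config.target_7day_incidence
        se = np.sqrt(target * (1 - target) / 5000)
        assert abs(rep.control.poaf_incidence - target) < 3 * se

    def test_reproducible(self, cohort_small, gt_config):
        prob = np.linspace(0, 1, len(cohort_small))
        r1 = simulate_trial(cohort_small, prob, gt_config, TrialConfig(seed=9))
        r2 = simulate_trial(cohort_small, prob, gt_config, TrialConfig(seed=9))
        assert r1.to_dict() == r2.to_dict()

    def test_counts_and_positivity(self, cohort_small, gt_config):
        prob = np.linspace(0, 1, len(cohort_small))
        rep = simulate_trial(cohort_small, prob, gt_config,
                             TrialConfig(seed=3))
        for arm in (rep.intervention, rep.control):
            assert arm.poaf_events <= arm.n
            assert arm.mean_los_days > 0
            assert arm.mean_icu_days > 0

    def test_missing_twin_prob_rejected(self, cohort_small, gt_config):
        prob = np.full(len(cohort_small), np.nan)
        with pytest.raises(ValueError, match="missing twin probability"):
            simulate_trial(cohort_small, prob, gt_config)


class TestNullTrialCalibration:
    def test_rrr_centered_and_logrank_uniform(self, gt_config):
        """Null-effect trials over 200 seeds: RRR centered on zero and
        log-rank p approximately uniform (KS at alpha = 0.01)."""
        from scipy.stats import kstest

        df = generate_cohort(gt_config, n=200, seed=1)
        policy = InterventionPolicy(hazard_multiplier=1.0, k_target=0.0,
                                    mg_target=0.0)
        prob = np.linspace(0, 1, 200)
        rrrs, pvals = [], []
        for seed in range(200):
            rep = simulate_trial(df, prob, gt_config, TrialConfig(seed=seed),
                                 policy)
            rrrs.append(rep.rrr_percent)
            pvals.append(rep.logrank_p)
        se_mean = np.std(rrrs) / np.sqrt(len(rrrs))
        assert abs(np.mean(rrrs)) < 3 * se_mean
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestRelativeRiskReduction:
    def test_paper_arm_incidences(self):
        rrr = relative_risk_reduction(0.276, 0.182)
        assert rrr == pytest.approx(34.058, abs=0.01)
        assert round(rrr) == 34

    def test_identity(self):
        assert relative_risk_reduction(0.3, 0.3) == 0.0

    def test_halving(self):
        assert relative_risk_reduction(0.2, 0.1) == pytest.approx(50.0)

    def test_zero_control_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relative_risk_reduction(0.0, 0.1)


class TestTwoProportionTest:
    def test_equal_proportions_large_n(self):
        z, p = two_proportion_test(500, 1000, 500, 1000)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pooled_z(self):
        """910/5000 vs 1380/5000: z from the pooled formula by hand."""
        z, p = two_proportion_test(910, 5000, 1380, 5000)
        pool = 2290 / 10_000
        z_hand = (0.182 - 0.276) / np.sqrt(pool * (1 - pool) * (2 / 5000))
        assert z == pytest.approx(z_hand, rel=1e-12)
        assert abs(z) == pytest.approx(11.19, abs=0.01)
        assert p < 0.001

    def test_symmetry(self):
        z1, p1 = two_proportion_test(30, 100, 50, 100)
        z2, p2 = two_proportion_test(50, 100, 30, 100)
        assert z1 == -z2
        assert p1 == p2

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            two_proportion_test(11, 10, 1, 10)


class TestKmCurve:
    def test_no_events_survival_one(self):
        km = km_curve([7, 7, 7], [True, True, True], horizon=7)
        assert (km["survival"] == 1.0).all()

    def test_uncensored_equals_empirical(self):
        km = km_curve([1, 2, 7, 7], [False, False, True, True], horizon=7)
        assert km.loc[km.time == 2, "survival"].iloc[0] == pytest.approx(0.5)
        # uncensored survival equals the empirical fraction still event-free
        assert km.loc[km.time == 1, "survival"].iloc[0] == pytest.approx(0.75)

    def test_hand_worked_censored_example(self):
        """6 patients: events at days 1 and 3, censorings at 2 and 4,
        two survivors to day 7: S = (1-1/6)(1-1/4) after day 3."""
        days = [1, 2, 3, 4, 7, 7]
        cens = [False, True, False, True, True, True]
        km = km_curve(days, cens, horizon=7)
        s3 = (1 - 1 / 6) * (1 - 1 / 4)
        assert km.loc[km.time == 3, "survival"].iloc[0] == pytest.approx(s3)
        assert km.loc[km.time == 7, "survival"].iloc[0] == pytest.approx(s3)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        days = rng.integers(1, 8, 100)
        cens = rng.random(100) < 0.3
        km = km_curve(days, cens, horizon=7)
        kmf = KaplanMeierFitter().fit(days, event_observed=~cens)
        for t in range(1, 8):
            assert km.loc[km.time == t, "survival"].iloc[0] == pytest.approx(
                float(kmf.predict(t)), abs=1e-10)

    def test_survival_monotone_nonincreasing(self, rng):
        days = rng.integers(1, 8, 60)
        cens = rng.random(60) < 0.5
        km = km_curve(days, cens, horizon=7)
        assert (np.diff(km["survival"]) <= 1e-12).all()


class TestLogrankTest:
    def test_identical_arms_zero_statistic(self):
        days = [1, 2, 3, 7]
        cens = [False, False, False, True]
        stat, p = logrank_test(days, cens, days, cens)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_accumulation(self):
        """Statistic equals the per-event-time 2x2 hypergeometric
        accumulation done by hand on a 10-patient example."""
        d1 = [1, 2, 2, 5, 7]
        c1 = [False, False, True, False, True]
        d2 = [1, 3, 4, 7, 7]
        c2 = [False, False, False, True, True]
        stat, _ = logrank_test(d1, c1, d2, c2)
        o_minus_e, var = 0.0, 0.0
        for t in [1, 2, 3, 4, 5]:
            n1 = sum(1 for x in d1 if x >= t)
            n2 = sum(1 for x in d2 if x >= t)
            e1 = sum(1 for x, c in zip(d1, c1) if x == t and not c)
            e2 = sum(1 for x, c in zip(d2, c2) if x == t and not c)
            n, d = n1 + n2, e1 + e2
            if d == 0:
                continue
            o_minus_e += e1 - d * n1 / n
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        assert stat == pytest.approx(o_minus_e**2 / var, rel=1e-12)

    def test_label_symmetry(self):
        d1, c1 = [1, 2, 7], [False, False, True]
        d2, c2 = [3, 7, 7], [False, True, True]
        s12, p12 = logrank_test(d1, c1, d2, c2)
        s21, p21 = logrank_test(d2, c2, d1, c1)
        assert s12 == pytest.approx(s21)
        assert p12 == pytest.approx(p21)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        d1 = rng.integers(1, 8, 80)
        c1 = rng.random(80) < 0.3
        d2 = rng.integers(1, 8, 80)
        c2 = rng.random(80) < 0.3
        stat, p = logrank_test(d1, c1, d2, c2)
        ref = ll_logrank(d1, d2, event_observed_A=~c1, event_observed_B=~c2)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([7], [True], [7], [True])


class TestWindowSweep:
    def test_flat_profile_no_window(self, gt_config):
        flat = GroundTruthConfig(benefit_profile={0.0: 0.8, 120.0: 0.8})
        df = generate_cohort(flat, n=2000, seed=4)
        prob = np.linspace(0, 1, 2000)
        sweep = window_sweep(df, prob, flat, TrialConfig(seed=6),
                             lead_times_h=(12, 60, 120))
        inc = sweep["intervention_incidence"]
        assert inc.max() - inc.min() < 6 * np.sqrt(0.25 * 0.75 / 1000)

    def test_optimal_window_recovered(self, cohort_10k, panel_10k, gt_config):
        """Argmin of the simulated incidence falls in the 48-72 h window
        encoded in the benefit profile."""
        sweep = window_sweep(cohort_10k, panel_10k["twin_prob"], gt_config,
                             TrialConfig(seed=11))
        best = sweep.loc[sweep["argmin"], "lead_time_h"].iloc[0]
        assert best in (48.0, 60.0, 72.0)

    def test_deterministic(self, cohort_small, gt_config):
        prob = np.linspace(0, 1, len(cohort_small))
        s1 = window_sweep(cohort_small, prob, gt_config, TrialConfig(seed=2),
                          lead_times_h=(24, 60))
        s2 = window_sweep(cohort_small, prob, gt_config, TrialConfig(seed=2),
                          lead_times_h=(24, 60))
        pd.testing.assert_frame_equal(s1, s2)

    def test_empty_grid_rejected(self, cohort_small, gt_config):
        with pytest.raises(ValueError):
            window_sweep(cohort_small, np.zeros(len(cohort_small)),
                         gt_config, lead_times_h=())
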