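import numpy as np
import pandas as pd
import pytest

from poaf_twin.synth_cohort import (
    CONTINUOUS_COLUMNS,
    GroundTruthConfig,
    PatientRecord,
    UnimputableError,
    benefit_multiplier,
    generate_cohort,
    impute_chained,
    inject_and_impute,
    inject_missing,
    split_cohort,
    true_daily_hazard,
)
from dataclasses import replace


class TestGenerateCohort:
    def test_empty_cohort(self, gt_config):
        df = generate_cohort(gt_config, n=0, seed=1)
        assert len(df) == 0

    def test_negative_n_rejected(self, gt_config):
        with pytest.raises(ValueError):
            generate_cohort(gt_config, n=-1, seed=1)

    def test_determinism(self, gt_config):
        a = generate_cohort(gt_config, n=500, seed=7)
        b = generate_cohort(gt_config, n=500, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_untreated_incidence_calibrated(self, gt_config):
        """Observed 7-day incidence matches the 27.6% target within 3
        binomial standard errors at n = 10,000."""
        df = generate_cohort(gt_config, n=10_000, seed=3)
        target = gt_config.target_7day_incidence
        se = np.sqrt(target * (1 - target) / 10_000)
        assert abs(df["poaf_event"].mean() - target) < 3 * se

    def test_schema_and_invariants(self, cohort_small):
        df = cohort_small
        assert (df["age"] >= 18).all()
        assert (df["qt_ms"] < df["rr_s"] * 1000).all()
        assert df["poaf_day"].notna().equals(df["poaf_event"])
        for c in ["pr_ms", "qrs_ms", "qt_ms", "rr_s"]:
            assert (df[c] > 0).all()

    def test_event_days_within_horizon(self, cohort_small):
        days = cohort_small.loc[cohort_small.poaf_event, "poaf_day"]
        assert days.between(1, 7).all()


class TestPatientRecord:
    def _base(self, **over):
        kw = dict(
            id="P1", age=60, sex="male", hypertension=False, diabetes=False,
            chf=False, vascular_disease=False, prior_stroke_tia=False,
            renal_disease=False, liver_disease=False, bleeding_history=False,
            labile_inr=False, alcohol_use=False, antiplatelet_use=False,
            surgery_type="CABG", pr_ms=170, qrs_ms=95, qt_ms=400, rr_s=1.0,
            hrv_sdnn_ms=50, potassium_meq_l=4.1, magnesium_meq_l=2.0,
            crp_mg_l=5.0, bnp_pg_ml=150.0,
        )
        kw.update(over)
        return PatientRecord(**kw)

    def test_valid_record(self):
        assert self._base().poaf_event is False

    @pytest.mark.parametrize("over", [
        {"age": 17}, {"qt_ms": 1000, "rr_s": 0.9},
        {"poaf_event": True}, {"poaf_day": 3},
        {"sex": "other"}, {"surgery_type": "unknown"},
    ])
    def test_invariant_violations_rejected(self, over):
        with pytest.raises(ValueError):
            self._base(**over)


class TestTrueDailyHazard:
    def test_zero_coefficients_give_baseline(self, cohort_small):
        cfg = GroundTruthConfig(coef_vulnerability=0, coef_electrolyte=0,
                                coef_inflammation=0, coef_age=0,
                                day_shape=(1,) * 7)
        rec = cohort_small.iloc[0]
        for day in range(1, 8):
            h = true_daily_hazard(rec, day, cfg)
            assert h == pytest.approx(cfg.baseline_daily_hazard)

    def test_zero_multiplier_absorbs(self, gt_config, cohort_small):
        rec = cohort_small.iloc[0]
        assert true_daily_hazard(rec, 3, gt_config, 0.0) == 0.0

    def test_day_out_of_range(self, gt_config, cohort_small):
        with pytest.raises(ValueError):
            true_daily_hazard(cohort_small.iloc[0], 8, gt_config)

    def test_monotone_in_crp(self, gt_config, cohort_small):
        lo = cohort_small.iloc[0].copy()
        hi = lo.copy()
        lo["crp_mg_l"], hi["crp_mg_l"] = 2.0, 40.0
        assert (true_daily_hazard(hi, 1, gt_config)
                > true_daily_hazard(lo, 1, gt_config))

    def test_hazard_in_unit_interval(self, gt_config, cohort_small):
        for _, rec in cohort_small.head(20).iterrows():
            h = true_daily_hazard(rec, 2, gt_config, 5.0)
            assert 0 <= h < 1


class TestBenefitProfile:
    def test_minimum_on_optimal_window(self, gt_config):
        grid = np.arange(0, 121, 4.0)
        mult = np.array([benefit_multiplier(gt_config, t) for t in grid])
        argmins = grid[mult == mult.min()]
        assert argmins.min() >= 48 and argmins.max() <= 72

    def test_no_benefit_at_zero_lead(self, gt_config):
        assert benefit_multiplier(gt_config, 0.0) == 1.0


class TestImputation:
    def test_identity_when_complete(self, cohort_small):
        done, report = impute_chained(cohort_small)
        pd.testing.assert_frame_equal(done, cohort_small)
        assert report["iterations"] == 0

    def test_linear_relation_recovered(self, cohort_small):
        """A value masked in one of two perfectly linearly related columns
        is recovered by the chained regression."""
        df = cohort_small.head(100).copy()
        df["crp_mg_l"] = 2.0 * df["potassium_meq_l"] + 1.0
        true_val = df.loc[5, "crp_mg_l"]
        df.loc[5, "crp_mg_l"] = np.nan
        done, report = impute_chained(df, tol=1e-8)
        assert done.loc[5, "crp_mg_l"] == pytest.approx(true_val, abs=1e-4)
        assert report["converged"]

    def test_injection_fraction_and_removal(self, cohort_small, gt_config):
        done, report = inject_and_impute(cohort_small, gt_config, seed=3)
        assert done[CONTINUOUS_COLUMNS].notna().all().all()
        assert sum(report["n_missing"].values()) > 0

    def test_max_change_monotone_tail(self, cohort_small, gt_config):
        _, report = inject_and_impute(cohort_small, gt_config, seed=3)
        hist = report["max_change_history"]
        assert len(hist) >= 2 and hist[-1] < hist[0]

    def test_excess_missingness_warns(self):
        with pytest.warns(UserWarning, match="exceeds"):
            GroundTruthConfig(missing_fraction=0.10)

    def test_fully_missing_column_rejected(self, cohort_small):
        df = cohort_small.copy()
        df["bnp_pg_ml"] = np.nan
        with pytest.raises(UnimputableError, match="bnp_pg_ml"):
            impute_chained(df)

    def test_multiple_completions(self, cohort_small, gt_config):
        masked = inject_missing(cohort_small, gt_config, seed=3)
        _, report = impute_chained(masked, m=3, seed=1)
        comps = report["completions"]
        assert len(comps) == 3
        assert not comps[0].equals(comps[1])  # stochastic completions differ


class TestSplitCohort:
    def test_paper_fractions(self, gt_config):
        df = generate_cohort(gt_config, n=1000, seed=2)
        tr, va, te = split_cohort(df, seed=0)
        assert (len(tr), len(va), len(te)) == (700, 150, 150)

    def test_partition_property(self, cohort_small):
        tr, va, te = split_cohort(cohort_small, seed=4)
        ids = pd.concat([tr, va, te])["id"]
        assert sorted(ids) == sorted(cohort_small["id"])
        assert len(set(tr.id) & set(va.id)) == 0
        assert len(set(tr.id) & set(te.id)) == 0
        assert len(set(va.id) & set(te.id)) == 0

    def test_remainder_to_training(self, cohort_small):
        tr, va, te = split_cohort(cohort_small.head(10), seed=0)
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_bad_fractions_rejected(self, cohort_small):
        with pytest.raises(ValueError):
            split_cohort(cohort_small, fractions=(0.5, 0.3, 0.1))

    def test_reproducible(self, cohort_small):
        a = split_cohort(cohort_small, seed=9)[0]
        b = split_cohort(cohort_small, seed=9)[0]
        pd.testing.assert_frame_equal(a, b)
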