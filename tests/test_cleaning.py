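"""Exclusion cascade: per-stage rules, boundaries, accounting, idempotence."""

import numpy as np
import pandas as pd
import pytest

from abmiref.cleaning import (
    CleaningConfig,
    PipelineError,
    filter_eligibility,
    filter_missing,
    filter_sparse_ages,
    flag_height_decrease,
    flag_implausible,
    flag_individual_bmi_outliers,
    flag_population_weight_outliers,
    run_pipeline,
)

COLS = ["subject_id", "survey", "sweep", "sex", "age_months",
        "weight_kg", "height_cm", "ethnicity"]


def _frame(rows):
    return pd.DataFrame(rows, columns=COLS)


def _subject(sid, survey, n_sweeps, start=60.0, height0=110.0, **kw):
    rows = []
    for k in range(n_sweeps):
        rows.append([
            sid, survey, k + 1, kw.get("sex", "M"), start + 12 * k,
            kw.get("weight_kg", 20.0 + k), height0 + 5 * k,
            kw.get("ethnicity", "White"),
        ])
    return rows


class TestEligibility:
    def test_three_sweeps_default_survey_removed(self):
        df = _frame(_subject("a", "YL", 3) + _subject("b", "YL", 4))
        out = filter_eligibility(df, CleaningConfig())
        assert set(out["subject_id"]) == {"b"}

    def test_three_sweeps_elana_hs_kept(self):
        df = _frame(_subject("a", "ELANA_HS", 3))
        out = filter_eligibility(df, CleaningConfig())
        assert set(out["subject_id"]) == {"a"}

    def test_unknown_ethnicity_removed(self):
        df = _frame(
            _subject("a", "YL", 4, ethnicity="Martian") + _subject("b", "YL", 4)
        )
        out = filter_eligibility(df, CleaningConfig())
        assert set(out["subject_id"]) == {"b"}

    def test_empty_input_empty_output(self):
        out = filter_eligibility(_frame([]), CleaningConfig())
        assert out.empty


class TestMissing:
    def test_record_without_height_removed(self):
        rows = _subject("a", "YL", 5)
        df = _frame(rows)
        df.loc[0, "height_cm"] = np.nan
        out = filter_missing(df, CleaningConfig())
        assert len(out) == 4

    def test_subject_dropping_below_minimum_removed_entirely(self):
        rows = _subject("a", "YL", 4)
        df = _frame(rows)
        df.loc[[0, 1], "weight_kg"] = np.nan  # 2 valid sweeps < 4 required
        out = filter_missing(df, CleaningConfig())
        assert out.empty

    def test_complete_records_kept(self):
        df = _frame(_subject("a", "YL", 4))
        assert len(filter_missing(df, CleaningConfig())) == 4


class TestHeightDecrease:
    def _heights(self, hs):
        rows = []
        for k, h in enumerate(hs):
            rows.append(["a", "YL", k + 1, "M", 60.0 + 12 * k, 20.0, h, "White"])
        return _frame(rows)

    @pytest.mark.parametrize(
        "heights,flagged",
        [
            ((110.0, 109.4), True),   # drop 0.6 >= 0.5
            ((110.0, 109.6), False),  # drop 0.4 < 0.5
            ((110.0, 109.5), True),   # boundary inclusive
            ((110.0, 115.0, 114.4), True),   # vs running maximum
            ((110.0, 112.0, 118.0), False),
        ],
    )
    def test_rule_application(self, heights, flagged):
        assert (flag_height_decrease(self._heights(heights)) == {"a"}) == flagged

    def test_duplicate_ages_rejected(self):
        df = self._heights((110.0, 112.0))
        df.loc[1, "age_months"] = 60.0
        with pytest.raises(PipelineError, match="duplicate"):
            flag_height_decrease(df)


class TestImplausible:
    def test_haz_beyond_six_flags_subject(self, clean_cohort):
        df, _, screening = clean_cohort
        sub = df.head(8).copy()
        # 200 cm at the first sweep (~5 y): height-for-age z far above +6
        sub.loc[sub.index[0], "height_cm"] = 200.0
        flagged = flag_implausible(sub, screening)
        assert sub.loc[sub.index[0], "subject_id"] in flagged

    def test_all_within_limits_none_flagged(self, clean_cohort):
        df, _, screening = clean_cohort
        assert flag_implausible(df.head(40), screening) == set()

    def test_bmi_z_boundary_is_strict(self, clean_cohort):
        # the rule is strictly "below -5": a z just inside stays, just
        # outside goes
        from abmiref.lms import inverse_z
        from abmiref.reference import lms_at

        df, _, screening = clean_cohort
        for z, expect_flagged in [(-4.999999, False), (-5.000001, True)]:
            row = df.head(1).copy()
            age, sex = row["age_months"].iloc[0], row["sex"].iloc[0]
            h = lms_at(screening.height_ref, sex, age).M
            bmi = inverse_z(z, lms_at(screening.bmi_ref, sex, age))
            row["height_cm"] = h
            row["weight_kg"] = bmi * (h / 100.0) ** 2
            flagged = flag_implausible(row, screening)
            assert bool(flagged) == expect_flagged, z


class TestSparseAges:
    def test_boundary_at_ten_observations(self):
        rows = []
        for i in range(9):
            rows.append([f"s{i}", "YL", 1, "M", 100.0, 20.0, 120.0, "White"])
        for i in range(10):
            rows.append([f"t{i}", "YL", 1, "F", 101.0, 20.0, 120.0, "White"])
        out = filter_sparse_ages(_frame(rows), min_obs=10)
        assert set(out["age_months"]) == {101.0}
        assert len(out) == 10

    def test_empty_input(self):
        assert filter_sparse_ages(_frame([])).empty


class TestPopulationWeightOutliers:
    def _bin(self, weights, age=100.0):
        rows = []
        for i, w in enumerate(weights):
            rows.append([f"s{i}", "YL", 1, "M", age, w, 120.0, "White"])
        return _frame(rows)

    def test_constructed_bin_z_thresholds(self):
        # 50 weights at mean 30, SD ~5: appending 41 lands beyond z=2,
        # appending 39 stays inside
        base = [25.0, 35.0] * 25
        df = self._bin(base + [41.0])
        w = np.asarray(df["weight_kg"])
        assert (41.0 - w.mean()) / w.std(ddof=1) > 2
        flagged = flag_population_weight_outliers(df)
        assert list(df.loc[flagged, "weight_kg"]) == [41.0]
        df2 = self._bin(base + [39.0])
        assert len(flag_population_weight_outliers(df2)) == 0

    def test_identical_weights_warn_and_skip(self):
        df = self._bin([30.0] * 6)
        with pytest.warns(UserWarning, match="degenerate"):
            flagged = flag_population_weight_outliers(df)
        assert len(flagged) == 0


class TestIndividualBMIOutliers:
    def test_spiked_observation_flagged(self, clean_cohort):
        df, _, _ = clean_cohort
        d = df.copy().reset_index(drop=True)
        sid = d["subject_id"].iloc[0]
        idx = d.index[d["subject_id"] == sid][1]
        h = d.loc[idx, "height_cm"] / 100.0
        d.loc[idx, "weight_kg"] += 12.0 * h**2  # spike BMI by +12 units
        flagged = flag_individual_bmi_outliers(d)
        assert idx in flagged

    def test_null_flag_rate_near_expected(self, clean_cohort):
        df, _, _ = clean_cohort
        sp = filter_sparse_ages(df)
        flagged = flag_individual_bmi_outliers(sp)
        rate = len(flagged) / len(sp)
        p = 0.0455
        se = np.sqrt(p * (1 - p) / len(sp))
        assert abs(rate - p) < 3 * se

    def test_identical_bmi_warns_no_flags(self):
        rows = []
        for i in range(20):
            for k in range(4):
                rows.append([f"s{i}", "YL", k + 1, "M", 60.0 + 12 * k,
                             20.0 * (1.2 + 0.05 * k) ** 2, 120.0 + 5 * k, "White"])
        df = _frame(rows)
        df["weight_kg"] = 20.0 * (df["height_cm"] / 100.0) ** 2  # constant BMI
        with pytest.warns(UserWarning):
            flagged = flag_individual_bmi_outliers(df)
        assert len(flagged) == 0


class TestRunPipeline:
    def test_report_conservation(self, dirty_cohort):
        df, _, screening = dirty_cohort
        cleaned, report = run_pipeline(df, CleaningConfig(), screening)
        removed = sum(s.observations_removed for s in report.stages)
        assert report.input_observations == len(cleaned) + removed
        subj_removed = sum(s.subjects_removed for s in report.stages)
        assert report.input_subjects == cleaned["subject_id"].nunique() + subj_removed

    def test_remaining_counts_non_increasing(self, dirty_cohort):
        df, _, screening = dirty_cohort
        _, report = run_pipeline(df, CleaningConfig(), screening)
        obs = [s.observations_remaining for s in report.stages]
        assert all(a >= b for a, b in zip(obs[:-1], obs[1:]))

    def test_injected_error_recall(self, dirty_cohort):
        df, labels, screening = dirty_cohort
        cleaned, _ = run_pipeline(df, CleaningConfig(), screening)
        kept = set(cleaned["subject_id"])
        for cat in ("height_decrease", "implausible"):
            bad = set(df.loc[labels["category"] == cat, "subject_id"])
            assert bad.isdisjoint(kept), f"{cat} subjects survived cleaning"
        miss_idx = labels.index[labels["category"] == "missing"]
        assert not set(miss_idx) & set(cleaned.index)

    def test_deterministic_stages_idempotent(self, dirty_cohort):
        # each deterministic rule, re-applied to its own output, is a no-op
        df, _, screening = dirty_cohort
        cfg = CleaningConfig()
        cur = filter_eligibility(df, cfg)
        assert len(filter_eligibility(cur, cfg)) == len(cur)
        cur = filter_missing(cur, cfg)
        assert len(filter_missing(cur, cfg)) == len(cur)
        cur = cur[~cur["subject_id"].isin(flag_height_decrease(cur))]
        assert flag_height_decrease(cur) == set()
        cur = cur[~cur["subject_id"].isin(flag_implausible(cur, screening))]
        assert flag_implausible(cur, screening) == set()
        cur = filter_sparse_ages(cur)
        assert len(filter_sparse_ages(cur)) == len(cur)

    def test_empty_input_zero_report(self):
        df = _frame([])
        cleaned, report = run_pipeline(df, CleaningConfig(), None)
        assert cleaned.empty
        assert all(s.observations_removed == 0 for s in report.stages)
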