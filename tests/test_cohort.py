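"""Cohort assembly: case definitions, visit selection, exclusions, strata."""

import numpy as np
import pandas as pd
import pytest

from diabrisk.cohort import (
    FPG_CRITERION,
    HBA1C_CRITERION,
    VISIT_COLUMNS,
    assemble_analysis_dataset,
    check_min_events,
    classify_t2d,
    complete_case_filter,
    hypertension_composite,
    read_cohort_csv,
    stratify,
    write_cohort_csv,
)
from diabrisk.scores import bundled_spec


@pytest.mark.parametrize(
    "fpg,hba1c,criterion,expected",
    [
        (7.0, 5.6, FPG_CRITERION, "case"),          # threshold is inclusive
        (6.9, 5.6, FPG_CRITERION, "noncase"),
        (5.5, 6.4, HBA1C_CRITERION, "noncase"),
        (5.5, 6.5, HBA1C_CRITERION, "case"),
        (6.0, 6.5, FPG_CRITERION, "noncase"),       # criteria disagree by analyte
        (6.0, 6.5, HBA1C_CRITERION, "case"),
        (np.nan, 5.6, FPG_CRITERION, "indeterminate"),
        (np.nan, 7.0, HBA1C_CRITERION, "case"),
    ],
)
def test_classify_t2d(make_visit, fpg, hba1c, criterion, expected):
    assert classify_t2d(make_visit(fpg=fpg, hba1c=hba1c), criterion) == expected


class TestAssemble:
    def test_case_at_visit_two_uses_first_diagnosis_visit(self, make_visit, make_table):
        table = make_table(
            [
                make_visit(participant_id="A", visit_index=1, fpg=5.0),
                make_visit(participant_id="A", visit_index=2, fpg=7.4),
                make_visit(participant_id="A", visit_index=3, fpg=8.0),
            ]
        )
        cohort = assemble_analysis_dataset(table, FPG_CRITERION)
        rec = cohort.records.iloc[0]
        assert rec["case"] and rec["index_visit"] == 2 and rec["fpg"] == 7.4

    def test_noncase_uses_baseline(self, make_visit, make_table):
        table = make_table(
            [
                make_visit(participant_id="A", visit_index=v, fpg=5.0 + v / 10, age=50 + v)
                for v in (1, 2, 3)
            ]
        )
        cohort = assemble_analysis_dataset(table, FPG_CRITERION)
        rec = cohort.records.iloc[0]
        assert not rec["case"] and rec["index_visit"] == 1 and rec["age"] == 51

    def test_diabetes_medication_excludes_at_any_visit(self, make_visit, make_table):
        table = make_table(
            [
                make_visit(participant_id="A", visit_index=1, fpg=7.5),
                make_visit(participant_id="A", visit_index=3, diabetes_medication="yes"),
                make_visit(participant_id="B", visit_index=1, fpg=7.5),
            ]
        )
        cohort = assemble_analysis_dataset(table, FPG_CRITERION)
        assert list(cohort.records["participant_id"]) == ["B"]
        assert ("A", "diabetes_medication") in cohort.exclusions

    def test_indeterminate_at_all_visits_excluded_with_log(self, make_visit, make_table):
        table = make_table(
            [
                make_visit(participant_id="A", fpg=np.nan),
                make_visit(participant_id="B", fpg=5.0),
            ]
        )
        cohort = assemble_analysis_dataset(table, FPG_CRITERION)
        assert list(cohort.records["participant_id"]) == ["B"]
        assert ("A", "analyte_never_measured") in cohort.exclusions
        assert any("indeterminate" in w for w in cohort.warnings)

    def test_missing_analyte_at_some_visits_conservative_noncase(self, make_visit, make_table):
        # noncase only if below threshold at every visit where measured
        table = make_table(
            [
                make_visit(participant_id="A", visit_index=1, fpg=np.nan),
                make_visit(participant_id="A", visit_index=2, fpg=6.0),
            ]
        )
        cohort = assemble_analysis_dataset(table, FPG_CRITERION)
        rec = cohort.records.iloc[0]
        assert not rec["case"] and rec["index_visit"] == 1

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            assemble_analysis_dataset(pd.DataFrame(columns=VISIT_COLUMNS), FPG_CRITERION)

    def test_counts_are_consistent(self, default_sim):
        visits, _ = default_sim
        cohort = assemble_analysis_dataset(visits, FPG_CRITERION)
        assert cohort.n_cases + cohort.n_noncases == cohort.n_total
        assert cohort.n_cases == int(cohort.records["case"].sum())
        # exclusion reasons partition the complement of the analysis set
        included = set(cohort.records["participant_id"])
        excluded = {pid for pid, _ in cohort.exclusions}
        everyone = set(visits["participant_id"])
        assert included | excluded == everyone
        assert not included & excluded

    def test_idempotent_on_single_visit_input(self, default_sim):
        # with one visit per participant, re-assembling the assembled output
        # reproduces it exactly
        visits, _ = default_sim
        single = visits[visits["visit_index"].eq(1)]
        first = assemble_analysis_dataset(single, FPG_CRITERION)
        again = assemble_analysis_dataset(
            first.records.rename(columns={"index_visit": "visit_index"})[VISIT_COLUMNS],
            FPG_CRITERION,
        )
        cols = ["participant_id", "case", "index_visit"]
        pd.testing.assert_frame_equal(
            first.records[cols].reset_index(drop=True),
            again.records[cols].reset_index(drop=True),
        )


class TestHypertensionComposite:
    def test_any_component_yes(self, make_table, make_visit):
        df = make_table(
            [
                make_visit(hypertension="yes"),
                make_visit(bp_medication="yes"),
                make_visit(systolic_bp=140.0),
                make_visit(diastolic_bp=90.0),
            ]
        )
        assert hypertension_composite(df).eq("yes").all()

    def test_missing_component_without_yes_is_missing(self, make_table, make_visit):
        df = make_table([make_visit(hypertension=np.nan)])
        assert hypertension_composite(df).isna().all()

    def test_all_known_negative_is_no(self, make_table, make_visit):
        df = make_table([make_visit()])
        assert hypertension_composite(df).eq("no").all()


class TestCompleteCase:
    def test_family_history_not_required_by_adrs(self, make_visit, make_table):
        table = make_table(
            [
                make_visit(participant_id="A", family_history_dm=np.nan, fpg=7.5),
                make_visit(participant_id="B", fpg=5.0),
            ]
        )
        cohort = assemble_analysis_dataset(table, FPG_CRITERION)
        filtered = complete_case_filter(cohort, bundled_spec("adrs"))
        assert set(filtered.records["participant_id"]) == {"A", "B"}

    def test_missing_required_predictor_excluded(self, make_visit, make_table):
        table = make_table(
            [
                make_visit(participant_id="A", family_history_dm=np.nan, fpg=7.5),
                make_visit(participant_id="B", fpg=7.5),
                make_visit(participant_id="C", fpg=5.0),
            ]
        )
        cohort = assemble_analysis_dataset(table, FPG_CRITERION)
        filtered = complete_case_filter(cohort, bundled_spec("ada"))
        assert "A" not in set(filtered.records["participant_id"])
        assert ("A", "missing_predictor:ADA") in filtered.exclusions

    def test_no_missing_is_identity(self, default_sim):
        visits, model = default_sim
        cohort = assemble_analysis_dataset(visits, FPG_CRITERION)
        spec = model.to_score_spec()
        complete = cohort.records.dropna(subset=spec.required_predictors)
        sub = cohort.with_records(complete.reset_index(drop=True))
        filtered = complete_case_filter(sub, spec)
        assert filtered.n_total == sub.n_total

    def test_single_class_result_errors(self, make_visit, make_table):
        table = make_table([make_visit(participant_id="A", fpg=5.0)])
        cohort = assemble_analysis_dataset(table, FPG_CRITERION)
        with pytest.raises(ValueError, match="ADRS"):
            complete_case_filter(cohort, bundled_spec("adrs"))


class TestStratify:
    def test_age_median_tie_goes_to_upper_group(self, make_visit, make_table):
        ages = [40, 50, 51, 60, 70]
        table = make_table(
            [make_visit(participant_id=f"P{i}", age=a, fpg=7.5 if i < 2 else 5.0)
             for i, a in enumerate(ages)]
        )
        cohort = assemble_analysis_dataset(table, FPG_CRITERION)
        strata = stratify(cohort, "age_median")
        upper = strata[">=median"].records
        assert 51 in upper["age"].values
        assert set(strata["<median"].records["age"]) == {40, 50}

    def test_bmi_25_tie_goes_to_upper_group(self, make_visit, make_table):
        table = make_table(
            [
                make_visit(participant_id="A", bmi=25.0, fpg=7.5),
                make_visit(participant_id="B", bmi=24.9, fpg=5.0),
            ]
        )
        cohort = assemble_analysis_dataset(table, FPG_CRITERION)
        strata = stratify(cohort, "bmi_25")
        assert list(strata[">=25"].records["participant_id"]) == ["A"]

    def test_partition_is_exhaustive(self, default_sim):
        visits, _ = default_sim
        cohort = assemble_analysis_dataset(visits, FPG_CRITERION)
        for axis in ("sex", "age_median", "bmi_25", "residency"):
            strata = stratify(cohort, axis)
            (a, b) = strata.values()
            col = {"sex": "sex", "age_median": "age_group",
                   "bmi_25": "bmi_group", "residency": "residency"}[axis]
            dropped = int(cohort.records[col].isna().sum())
            assert a.n_total + b.n_total + dropped == cohort.n_total

    def test_small_stratum_carries_warning(self, make_visit, make_table):
        rows = [make_visit(participant_id=f"P{i}", sex="female",
                           fpg=7.5 if i < 3 else 5.0) for i in range(20)]
        cohort = assemble_analysis_dataset(make_table(rows), FPG_CRITERION)
        strata = stratify(cohort, "sex")
        assert any("cases" in w for w in strata["female"].warnings)
        assert strata["male"].n_total == 0


def test_check_min_events():
    class Stub:
        def __init__(self, c, n):
            self.n_cases, self.n_noncases = c, n

    assert check_min_events(Stub(100, 620)).status == "pass"
    warn = check_min_events(Stub(49, 371))
    assert warn.status == "warn" and "49" in warn.message
    assert check_min_events(Stub(0, 100)).status == "warn"


def test_cohort_csv_round_trip(tmp_path, default_sim):
    visits, _ = default_sim
    path = tmp_path / "cohort.csv"
    write_cohort_csv(visits, path)
    back = read_cohort_csv(path)
    pd.testing.assert_frame_equal(
        back.reset_index(drop=True), visits.reset_index(drop=True),
        check_exact=False, rtol=1e-12,
    )
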