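"""Eligibility screening, strategy assignment, and attrition bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from ttemu.cohort import CRITERIA, build_cohort, check_eligibility
from ttemu.errors import DataError, PatientLookupError
from ttemu.synthetic import VIOLATION_TO_CRITERION

from conftest import day, micro_dataset


def _base_patient(pid=1, birth="1945-06-15", dx="2015-06-15"):
    return (pid, birth, dx)


def _standard(pid=1, birth="1945-06-15", dx="2015-06-15", fills=(), events=(),
              deaths=(), coverage=None):
    """One patient with ADT at dx+10 and otherwise clean history."""
    import datetime as dt
    adt = (dt.date.fromisoformat(dx) + dt.timedelta(days=10)).isoformat()
    fills = [(pid, "adt_hormonal", adt, 90), *fills]
    return micro_dataset([(pid, birth, dx)], coverage_rows=coverage,
                         fills_rows=fills, events_rows=list(events),
                         deaths_rows=list(deaths))


class TestEligibilityCriteria:
    def test_age_65_fails_only_age(self):
        ds = _standard(birth="1950-01-01", dx="2015-06-15")  # age 65.45
        res = check_eligibility(1, ds)
        assert res.age_ge_66 is False and res.eligible is False
        assert all(res.criteria[c] for c in CRITERIA if c != "age_ge_66")

    def test_metformin_fill_30_days_before_diagnosis_fails_washout(self):
        ds = _standard(fills=[(1, "metformin", "2015-05-16", 30)])
        res = check_eligibility(1, ds)
        assert res.no_prior_metformin_6mo is False
        assert res.adt_within_6mo is True

    def test_fill_exactly_on_day_183_is_initiator(self):
        ds = _standard(fills=[(1, "metformin", "2015-12-15", 30)])  # dx + 183
        cohort, _ = build_cohort(ds)
        assert cohort.iloc[0]["strategy"] == "initiator"
        ds2 = _standard(fills=[(1, "metformin", "2015-12-16", 30)])  # dx + 184
        cohort2, _ = build_cohort(ds2)
        assert cohort2.iloc[0]["strategy"] == "non_initiator"

    def test_contraindication_in_prior_year_excludes(self):
        ds = _standard(events=[(1, "severe_renal", "2015-01-10")])
        assert check_eligibility(1, ds).no_contraindication is False

    def test_prevalent_chf_does_not_exclude(self):
        # CHF stays a baseline covariate in the eligible population
        ds = _standard(events=[(1, "chf", "2015-01-10")])
        res = check_eligibility(1, ds)
        assert res.no_contraindication is True and res.eligible is True
        cohort, _ = build_cohort(ds)
        assert cohort.iloc[0]["chf"] == 1

    def test_coverage_hole_over_31_days_fails_prior_info(self):
        cov = []
        for part in ("A", "B", "D"):
            cov.append((1, part, "2013-06-15", "2015-01-01"))
            cov.append((1, part, "2015-02-15", "2020-12-31"))  # 44-day hole
        ds = _standard(coverage=cov)
        assert check_eligibility(1, ds).one_year_prior_AB_no_HMO is False

    def test_coverage_hole_under_31_days_tolerated(self):
        cov = []
        for part in ("A", "B", "D"):
            cov.append((1, part, "2013-06-15", "2015-01-01"))
            cov.append((1, part, "2015-01-20", "2020-12-31"))  # 18-day hole
        ds = _standard(coverage=cov)
        assert check_eligibility(1, ds).one_year_prior_AB_no_HMO is True

    def test_death_before_6_months_fails_post_dx_criterion(self):
        ds = _standard(deaths=[(1, "2015-10-01", "pca")])  # dx + 108
        assert check_eligibility(1, ds).alive_enrolled_D_6mo_post is False

    def test_unknown_patient_raises_lookup_error(self):
        ds = _standard()
        with pytest.raises(PatientLookupError):
            check_eligibility(99, ds)


class TestStrategyAssignment:
    def test_time_zero_is_max_of_adt_and_fill(self):
        ds = _standard(fills=[(1, "metformin", "2015-07-05", 30)])  # 10 d after ADT
        cohort, _ = build_cohort(ds)
        assert cohort.iloc[0]["time_zero_day"] == day("2015-07-05")

    def test_non_initiator_time_zero_is_adt_date(self):
        ds = _standard()
        cohort, _ = build_cohort(ds)
        row = cohort.iloc[0]
        assert row["strategy"] == "non_initiator"
        assert row["time_zero_day"] == day("2015-06-25")

    def test_max_followup_is_3_years_capped_by_admin_end(self):
        ds = _standard(dx="2015-06-15")
        cohort, _ = build_cohort(ds)
        assert cohort.iloc[0]["max_followup_end_day"] == day("2015-06-15") + 1095
        ds2 = _standard(pid=1, dx="2019-06-15", birth="1949-06-15")
        cohort2, _ = build_cohort(ds2)
        assert cohort2.iloc[0]["max_followup_end_day"] == day("2020-12-31")


class TestAttrition:
    def test_all_eligible_means_zero_removals(self):
        ds = _standard()
        _, attrition = build_cohort(ds)
        assert attrition["removed"].sum() == 0

    def test_every_patient_contraindicated_gives_empty_cohort(self):
        ds = micro_dataset(
            [(1, "1945-06-15", "2015-06-15"), (2, "1940-01-01", "2016-01-01")],
            fills_rows=[(1, "adt_hormonal", "2015-06-25", 90),
                        (2, "adt_hormonal", "2016-01-05", 90)],
            events_rows=[(1, "hepatic_failure", "2015-01-01"),
                         (2, "metabolic_acidosis", "2015-08-01")])
        cohort, attrition = build_cohort(ds)
        assert len(cohort) == 0
        removed = dict(zip(attrition["criterion"], attrition["removed"]))
        assert removed["no_contraindication"] == 2

    def test_attrition_matches_generator_bookkeeping(self, default_dataset):
        cohort, attrition = build_cohort(default_dataset)
        truth = default_dataset.truth
        assert len(cohort) == int(truth["eligible"].sum())
        expected = truth.loc[~truth["eligible"], "violation"] \
            .map(VIOLATION_TO_CRITERION).value_counts()
        removed = dict(zip(attrition["criterion"], attrition["removed"]))
        for crit in CRITERIA:
            assert removed[crit] == int(expected.get(crit, 0)), crit

    def test_attrition_counts_conserve_population(self, default_dataset):
        cohort, attrition = build_cohort(default_dataset)
        n = len(default_dataset.patients)
        assert attrition["removed"].sum() + len(cohort) == n


class TestDeterminism:
    def test_rebuild_is_identical(self, default_dataset):
        a, fa = build_cohort(default_dataset)
        b, fb = build_cohort(default_dataset)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(fa, fb)

    def test_row_order_invariance(self, default_dataset):
        import dataclasses
        rng = np.random.default_rng(0)
        shuffled = dataclasses.replace(
            default_dataset,
            fills=default_dataset.fills.sample(frac=1, random_state=1).reset_index(drop=True),
            events=default_dataset.events.sample(frac=1, random_state=2).reset_index(drop=True),
            coverage=default_dataset.coverage.sample(frac=1, random_state=3).reset_index(drop=True))
        a, fa = build_cohort(default_dataset)
        b, fb = build_cohort(shuffled)
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))
        pd.testing.assert_frame_equal(fa, fb)

    def test_strategy_and_time_zero_match_truth(self, default_dataset):
        cohort, _ = build_cohort(default_dataset)
        t = default_dataset.truth.set_index("patient_id")
        m = cohort.set_index("patient_id")
        assert (m["initiator"] == t.loc[m.index, "initiator"]).all()
        assert (m["time_zero_day"] == t.loc[m.index, "tz_day"]).all()

    def test_baseline_confounders_match_truth(self, default_dataset):
        cohort, _ = build_cohort(default_dataset)
        t = default_dataset.truth.set_index("patient_id")
        m = cohort.set_index("patient_id")
        for cond in ("diabetes", "chf", "hypertension", "depression"):
            assert (m[cond].astype(bool) == t.loc[m.index, cond]).all(), cond
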