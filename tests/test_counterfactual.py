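"""Rollback interventions, benefit metrics and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from pdac_earlybench import (
    EXCLUDED,
    HealthState,
    benefit_summary,
    cohort_counterfactual,
    compare_groups,
    eligibility,
    run_counterfactual,
    select_pdac_deaths,
)
from pdac_earlybench.microsim import IndividualHistory
from pdac_earlybench.pipeline import subgroup_lookup


def _history(person_id=0, ut_entries=((1, 500),), diag=(4, 540), death=("cancer", 560)):
    """Hand-built compressed history (stage, month) helpers."""
    trans = [(216, HealthState.NORMAL)]
    for stage, month in ut_entries:
        trans.append((month, HealthState(HealthState.UT1 + stage - 1)))
    if diag:
        trans.append((diag[1], HealthState(HealthState.DT1 + diag[0] - 1)))
    return IndividualHistory(person_id, trans, diag, death)


def test_eligibility_returns_rollback_state():
    # DT4 diagnosis; 12 months earlier the patient sat in UT3
    h = _history(ut_entries=((1, 500), (2, 510), (3, 520), (4, 535)), diag=(4, 540))
    assert eligibility(h, 12) is HealthState.UT3
    assert eligibility(h, 4) is HealthState.UT4


def test_eligibility_excludes_normal_at_rollback():
    h = _history(ut_entries=((1, 500),), diag=(1, 540))
    assert eligibility(h, 41) is EXCLUDED
    assert eligibility(h, 40) is HealthState.UT1


def test_eligibility_excludes_rollback_before_age_18():
    h = _history(ut_entries=((1, 217),), diag=(1, 230))
    assert eligibility(h, 20) is EXCLUDED


def test_eligibility_rejects_bad_inputs():
    h = _history()
    with pytest.raises(ValueError):
        eligibility(h, 0)
    h_undiag = IndividualHistory(1, [(216, HealthState.NORMAL)], None, ("other", 700))
    with pytest.raises(ValueError):
        eligibility(h_undiag, 6)


def test_run_counterfactual_record_identities(truth_schedule):
    h = _history(ut_entries=((1, 500), (2, 510), (3, 520), (4, 535)), diag=(4, 540),
                 death=("cancer", 556))
    rec = run_counterfactual(h, 12, truth_schedule, seed=3)
    assert rec.rollback_state is HealthState.UT3
    assert rec.converted_state is HealthState.DT3
    assert rec.converted_state.stage == rec.rollback_state.stage
    assert rec.lyg_months >= 0
    assert rec.survival_months == rec.lyg_months + 12 + (556 - 540)
    assert rec.zero_gain == (rec.lyg_months == 0)


def test_run_counterfactual_rejects_ineligible(truth_schedule):
    h = _history(ut_entries=((1, 530),), diag=(1, 540))
    with pytest.raises(ValueError, match="NORMAL"):
        run_counterfactual(h, 30, truth_schedule, seed=0)


@pytest.fixture(scope="module")
def truth_records(truth_cohort):
    return cohort_counterfactual(truth_cohort, x_grid=(3, 6, 12, 24, 60),
                                 n_iterations=2, seed=9)


def test_record_identities_hold_for_every_simulated_record(truth_records):
    r = truth_records
    assert (r.lyg_months >= 0).all()
    assert (r.zero_gain == (r.lyg_months == 0)).all()
    lhs = r.survival_months
    rhs = r.lyg_months + r.x + (r.real_death_month - r.diag_month)
    assert (lhs == rhs).all()
    assert (r.cf_death_month >= r.real_death_month).all()


def test_eligible_cohort_monotone_non_increasing_in_x(truth_records):
    n_by_x = truth_records.groupby("x")["person_id"].nunique()
    assert (np.diff(n_by_x.loc[[3, 6, 12, 24, 60]]) <= 0).all()


def test_rollback_stage_never_exceeds_diagnosis_stage(truth_records):
    assert (truth_records.rollback_stage <= truth_records.diag_stage).all()
    assert truth_records.rollback_stage.between(1, 4).all()


def test_excluded_people_have_no_rows(truth_cohort, truth_records):
    sel = select_pdac_deaths(truth_cohort)
    at60 = truth_records[truth_records.x == 60]
    expected = sel.person_ids[sel.sojourn_months >= 60]
    assert set(at60.person_id) == set(expected)


def test_benefit_summary_hand_example():
    recs = pd.DataFrame({
        "person_id": range(5), "x": 6, "iteration": 0,
        "rollback_stage": 1, "diag_stage": 2, "diag_month": 700,
        "real_death_month": 710, "cf_death_month": 710,
        "cf_cause": 1, "lyg_months": [0, 6, 12, 24, 60],
        "survival_months": 16, "zero_gain": [True, False, False, False, False],
    })
    out = benefit_summary(recs).iloc[0]
    assert out["mean_lyg_years"] == pytest.approx(20.4 / 12)
    assert out["median_lyg_years"] == pytest.approx(1.0)
    assert out["prop_zero_gain"] == pytest.approx(0.2)
    assert out["ci_low_years"] <= out["mean_lyg_years"] <= out["ci_high_years"]


def test_benefit_summary_all_zero_gains():
    recs = pd.DataFrame({
        "person_id": range(4), "x": 12, "iteration": 0,
        "rollback_stage": 2, "diag_stage": 2, "diag_month": 700,
        "real_death_month": 710, "cf_death_month": 710,
        "cf_cause": 1, "lyg_months": 0, "survival_months": 22,
        "zero_gain": True,
    })
    out = benefit_summary(recs).iloc[0]
    assert out["mean_lyg_years"] == 0.0
    assert out["prop_zero_gain"] == 1.0


def test_benefit_groupings(truth_records):
    whole = benefit_summary(truth_records, "whole")
    assert set(whole["x"]) == {3, 6, 12, 24, 60}
    byage = benefit_summary(truth_records, "age_band")
    assert {"age_band", "x"} <= set(byage.columns)
    cell = benefit_summary(truth_records, "stage_age")
    assert {"diag_stage", "diag_age_years"} <= set(cell.columns)
    with pytest.raises(ValueError):
        benefit_summary(truth_records, "bogus")


def test_subgroup_lookup_window_boundaries():
    base = {
        "x": 6, "iteration": 0, "rollback_stage": 3, "diag_stage": 3,
        "real_death_month": 900, "cf_death_month": 912, "cf_cause": 1,
        "survival_months": 20, "zero_gain": False,
    }
    recs = pd.DataFrame([
        {**base, "person_id": 0, "diag_month": 53 * 12, "lyg_months": 12},
        {**base, "person_id": 1, "diag_month": 53 * 12 + 11, "lyg_months": 24},
        {**base, "person_id": 2, "diag_month": 54 * 12, "lyg_months": 120},
    ])
    out = subgroup_lookup(recs, stage=3, age_years=53).set_index("x")
    assert out.loc[6, "n"] == 2  # 53y0m and 53y11m in; 54y0m out
    assert out.loc[6, "mean_lyg_years"] == pytest.approx(18 / 12)
    empty = subgroup_lookup(recs, stage=1, age_years=53).set_index("x")
    assert empty.loc[6, "n"] == 0


def test_compare_groups_tests():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 100)
    t, p = compare_groups(a, a)
    assert p == pytest.approx(1.0)
    t, p = compare_groups(a, a + 5.0)
    assert p < 0.05
    f, p3 = compare_groups(a, a, a)
    assert f == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        compare_groups(a)
    with pytest.raises(ValueError):
        compare_groups(a, np.array([1.0]))
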