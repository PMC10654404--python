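"""Deterministic cohort projection and the microsimulation engine.

The two engines implement the same per-cycle multinomial convention,
so the projection is the exact expectation of the simulation; the
engine-equivalence checks here are the small-scale counterparts of the
acceptance tests.
"""

import numpy as np
import pytest

from pdac_earlybench import (
    HealthState,
    cohort_project,
    preclinical_stage_durations,
    select_pdac_deaths,
    simulate_population,
    sojourn_time_of,
)
from pdac_earlybench.microsim import CAUSE_CANCER, CAUSE_CENSORED, CAUSE_OTHER
from pdac_earlybench.schedule import TransitionSchedule


def test_occupancy_conserved_and_deaths_monotone(truth_schedule):
    proj = cohort_project(truth_schedule)
    assert np.allclose(proj.occupancy.sum(axis=1), 1.0, atol=1e-10)
    for d in (HealthState.CANCER_DEATH, HealthState.OTHER_DEATH):
        assert (np.diff(proj.occupancy[:, d]) >= -1e-15).all()


def test_projection_lifetime_risk_matches_configured_value(truth_schedule, synth_config):
    proj = cohort_project(truth_schedule)
    assert proj.lifetime_cancer_death_risk == pytest.approx(
        synth_config.lifetime_risk, abs=1e-9
    )


def test_late_stages_dominate_at_diagnosis(truth_schedule):
    mix = cohort_project(truth_schedule).stage_at_diagnosis_mix
    assert mix[3] == max(mix)
    assert mix[3] > 0.3


def test_closed_pathway_yields_no_cancer(truth_schedule):
    sched = truth_schedule.replace_free(
        np.zeros_like(truth_schedule.onset), truth_schedule.prog, truth_schedule.det
    )
    cohort = simulate_population(sched, 5_000, seed=2)
    assert (cohort.diag_month < 0).all()
    assert (cohort.cause != CAUSE_CANCER).all()


def test_forced_detection_diagnoses_stage_one_next_month():
    # certain detection: the whole UT1 exit budget goes to diagnosis
    sched = TransitionSchedule.age_invariant(
        onset=0.05, prog=[0, 0, 0], det=[1, 1, 1, 1], cdeath=[0.02] * 4, odeath=0.0
    )
    cohort = simulate_population(sched, 5_000, seed=2)
    diagnosed = cohort.diag_month >= 0
    assert diagnosed.any()
    assert (cohort.diag_stage[diagnosed] == 1).all()
    assert np.array_equal(
        cohort.diag_month[diagnosed], cohort.ut_entry[diagnosed, 0] + 1
    )


def test_simulation_is_reproducible(truth_schedule):
    a = simulate_population(truth_schedule, 2_000, seed=5)
    b = simulate_population(truth_schedule, 2_000, seed=5)
    c = simulate_population(truth_schedule, 2_000, seed=6)
    assert np.array_equal(a.end_month, b.end_month)
    assert np.array_equal(a.ut_entry, b.ut_entry)
    assert not np.array_equal(a.end_month, c.end_month)


def test_histories_are_prefix_stable_in_population_size(truth_schedule):
    """Counter-based per-person streams: person i's history does not
    depend on how many other people are simulated."""
    small = simulate_population(truth_schedule, 500, seed=5)
    large = simulate_population(truth_schedule, 2_000, seed=5)
    assert np.array_equal(small.end_month, large.end_month[:500])
    assert np.array_equal(small.diag_month, large.diag_month[:500])


def test_every_person_ends_in_exactly_one_terminal_state(truth_cohort):
    censored = truth_cohort.cause == CAUSE_CENSORED
    assert np.array_equal(truth_cohort.end_month[censored], np.full(censored.sum(), 1020))
    assert ((truth_cohort.cause == CAUSE_CANCER) | (truth_cohort.cause == CAUSE_OTHER)
            | censored).all()
    occ = truth_cohort.occupancy_counts()
    assert (occ.sum(axis=1) == truth_cohort.n).all()


def test_history_view_respects_allowed_paths(truth_cohort):
    sel = select_pdac_deaths(truth_cohort)
    h = truth_cohort.history(int(sel.person_ids[0]))
    months = [m for m, _ in h.transitions]
    assert months == sorted(months)
    assert h.diagnosis is not None
    assert h.death[0] == "cancer"
    # diagnosis stage equals the last undetected stage occupied
    ut_states = [s for _, s in h.transitions if s.is_undetected]
    assert ut_states[-1].stage == h.diagnosis[0]


def test_sojourn_and_stage_durations_partition(truth_cohort):
    sel = select_pdac_deaths(truth_cohort)
    assert np.array_equal(sel.stage_durations.sum(axis=1), sel.sojourn_months)
    assert (sel.sojourn_months > 0).all()
    for pid in sel.person_ids[:50]:
        h = truth_cohort.history(int(pid))
        assert sojourn_time_of(h) == sel.sojourn_months[sel.person_ids == pid][0]
        assert preclinical_stage_durations(h).sum() == sojourn_time_of(h)


def test_undiagnosed_history_raises(truth_cohort):
    undiag = int(np.where(truth_cohort.diag_month < 0)[0][0])
    with pytest.raises(ValueError):
        sojourn_time_of(truth_cohort.history(undiag))
    with pytest.raises(ValueError):
        preclinical_stage_durations(truth_cohort.history(undiag))


def test_pdac_death_selection_excludes_other_causes(truth_cohort):
    sel = select_pdac_deaths(truth_cohort)
    assert np.array_equal(
        np.sort(sel.person_ids), np.where(truth_cohort.cause == CAUSE_CANCER)[0]
    )
    # diagnosed people who died of something else are excluded
    other = (truth_cohort.diag_month >= 0) & (truth_cohort.cause == CAUSE_OTHER)
    assert other.any()
    assert not np.isin(np.where(other)[0], sel.person_ids).any()


def test_selection_rate_estimates_projected_lifetime_risk(truth_cohort, truth_schedule):
    proj = cohort_project(truth_schedule)
    p = proj.lifetime_cancer_death_risk
    k = len(select_pdac_deaths(truth_cohort))
    se = np.sqrt(p * (1 - p) * truth_cohort.n)
    assert abs(k - p * truth_cohort.n) < 4 * se


def test_empty_population_rejected(truth_schedule):
    with pytest.raises(ValueError):
        simulate_population(truth_schedule, 0, seed=1)
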