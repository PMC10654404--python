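"""Shared fixtures.

The expensive calibration fixtures are session-scoped: the parameter
recovery run and the three sojourn-variant fits are each computed once
and reused by the unit tests and the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from pdac_earlybench import (
    CalibrationConfig,
    SyntheticConfig,
    build_truth_schedule,
    generate_reference_targets,
    sequential_calibrate,
    simulate_population,
    targets_from_truth,
)
from pdac_earlybench.schedule import TransitionSchedule

SEED = 1


@pytest.fixture(scope="session")
def synth_config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def truth_schedule(synth_config):
    return build_truth_schedule(synth_config)


@pytest.fixture(scope="session")
def study_inputs(synth_config):
    """(targets, life_table, stage_survival) under the default conditions."""
    return generate_reference_targets(synth_config, seed=0)


@pytest.fixture(scope="session")
def truth_targets(truth_schedule):
    return targets_from_truth(truth_schedule)


@pytest.fixture(scope="session")
def hand_chain() -> TransitionSchedule:
    """Age-invariant chain with UT1->UT2 0.5, UT1->DT1 0.25, UT2->DT2 0.5.

    Solving the first-passage system by hand: m(UT2) = 1/0.5 = 2 and
    m(UT1) = (1 + 0.5 * 2) / 0.75 = 8/3 months.
    """
    return TransitionSchedule.age_invariant(
        onset=0.01,
        prog=[0.5, 0.0, 0.0],
        det=[0.25, 0.5, 0.0, 0.1],
        cdeath=[0.05, 0.05, 0.05, 0.1],
        odeath=0.001,
    )


@pytest.fixture(scope="session")
def recovery_fit(study_inputs):
    """Sequential calibration against targets from a known schedule,
    asking for that schedule's own mean sojourn time (default config)."""
    targets, life, surv = study_inputs
    cfg = CalibrationConfig(seed=3)
    fits = sequential_calibrate(
        targets, [targets.mean_sojourn_target_months], cfg, life, surv
    )
    return fits[targets.mean_sojourn_target_months]


@pytest.fixture(scope="session")
def variant_fits(study_inputs):
    """Three calibrated sojourn variants (120/60/36 months)."""
    targets, life, surv = study_inputs
    cfg = CalibrationConfig(seed=3)
    return sequential_calibrate(targets, [120.0, 60.0, 36.0], cfg, life, surv)


@pytest.fixture(scope="session")
def truth_cohort(truth_schedule):
    """100k-person microsimulation under the ground-truth schedule."""
    return simulate_population(truth_schedule, 100_000, seed=SEED)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
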