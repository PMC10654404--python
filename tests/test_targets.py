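"""Synthetic targets, smoothing and target preparation."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdac_earlybench import (
    CalibrationTargets,
    LifeTable,
    StageSurvival,
    SyntheticConfig,
    generate_reference_targets,
    redistribute_unknown_stage,
    smooth_incidence_trendlines,
    sojourn_profile,
)
from pdac_earlybench.calibration import objective


# ----------------------------------------------------------------------
# unknown-stage redistribution
# ----------------------------------------------------------------------
def test_redistribution_identity_when_unknown_zero():
    staged = np.array([1.0, 2.0, 3.0, 4.0])
    assert np.array_equal(redistribute_unknown_stage(staged, 0.0), staged)


def test_redistribution_proportional_allocation():
    out = redistribute_unknown_stage([1, 2, 3, 4], 10)
    assert np.allclose(out, [2, 4, 6, 8])


def test_redistribution_degenerate_input_errors():
    with pytest.raises(ValueError):
        redistribute_unknown_stage([0, 0, 0, 0], 5)


@settings(max_examples=50, deadline=None)
@given(
    staged=st.tuples(*[st.floats(0.01, 100)] * 4),
    unknown=st.floats(0, 50),
)
def test_redistribution_conserves_total_and_proportions(staged, unknown):
    staged = np.asarray(staged)
    out = redistribute_unknown_stage(staged, unknown)
    assert out.sum() == pytest.approx(staged.sum() + unknown, rel=1e-12)
    assert np.allclose(out / out.sum(), staged / staged.sum())


# ----------------------------------------------------------------------
# trendline smoothing
# ----------------------------------------------------------------------
def test_smoothing_idempotent_on_curve_in_family():
    ages = np.arange(18.0, 85.0)
    x = (ages - ages.mean()) / ages.std()
    truth = np.exp(0.5 + 1.2 * x + 0.3 * x**2 - 0.1 * x**3) - 1e-3
    smoothed = smooth_incidence_trendlines(ages, truth[:, None], degree=3)
    assert np.allclose(smoothed[:, 0], truth, atol=1e-6)


def test_smoothing_denoises_toward_truth(rng):
    ages = np.arange(18.0, 85.0)
    truth = 50 * np.exp(0.06 * (ages - 60))
    noisy = truth * rng.lognormal(0, 0.25, truth.size)
    smoothed = smooth_incidence_trendlines(ages, noisy[:, None])[:, 0]
    rmse_raw = np.sqrt(np.mean((noisy - truth) ** 2))
    rmse_smooth = np.sqrt(np.mean((smoothed - truth) ** 2))
    assert rmse_smooth < rmse_raw


def test_smoothing_clips_at_zero():
    ages = np.arange(18.0, 85.0)
    tiny = np.full(ages.size, 1e-9)
    out = smooth_incidence_trendlines(ages, tiny[:, None])
    assert (out >= 0).all()


def test_smoothing_requires_age_coverage():
    with pytest.raises(ValueError):
        smooth_incidence_trendlines(np.array([50.0, 60.0]), np.ones((2, 1)), degree=3)


# ----------------------------------------------------------------------
# synthetic generator
# ----------------------------------------------------------------------
def test_generator_is_pure_function_of_config_and_seed(synth_config):
    a = generate_reference_targets(synth_config, seed=4)
    b = generate_reference_targets(synth_config, seed=4)
    for x, y in zip(a, b):
        for f in x.__dataclass_fields__:
            xa, ya = getattr(x, f), getattr(y, f)
            if isinstance(xa, np.ndarray):
                assert np.array_equal(xa, ya)


def test_stage_survival_ordering(study_inputs):
    _, _, surv = study_inputs
    q = surv.q_month
    assert (np.diff(q, axis=1) > 0).all()  # IV strictly worst at all ages
    assert (q >= 0).all() and (q <= 1).all()


def test_incidence_rises_steeply_after_fifty(study_inputs):
    targets, _, _ = study_inputs
    total = targets.incidence_per_100k.sum(axis=1)
    ages = targets.ages_years
    assert total[ages == 75][0] > 10 * total[ages == 45][0]
    assert targets.incidence_per_100k[-10:, 3].mean() > targets.incidence_per_100k[-10:, 0].mean()


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(lifetime_risk=0.9).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(stage_mix=(0.5, 0.5, 0.2, 0.2)).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(median_survival_months=(10, 20, 5, 2)).validate()


def test_truth_attains_zero_objective(truth_schedule, truth_targets):
    total, comps = objective(truth_schedule, truth_targets)
    assert total == pytest.approx(0.0, abs=1e-8)
    assert sum(comps.values()) == pytest.approx(total)


def test_perturbing_free_hazards_increases_objective(truth_schedule, truth_targets):
    for attr in ("onset", "prog", "det"):
        kwargs = {
            "onset": truth_schedule.onset.copy(),
            "prog": truth_schedule.prog.copy(),
            "det": truth_schedule.det.copy(),
        }
        kwargs[attr] = kwargs[attr] * 1.5
        sched = truth_schedule.replace_free(**kwargs)
        total, _ = objective(sched, truth_targets)
        assert total > 1e-4, attr


def test_truth_sojourn_equals_recorded_target(truth_schedule, truth_targets):
    prof = sojourn_profile(truth_schedule)
    assert truth_targets.mean_sojourn_target_months == pytest.approx(prof.mean_18_60)


def test_noise_config_produces_smoothed_targets():
    cfg = SyntheticConfig(noise_sd=0.2)
    noisy_t, _, _ = generate_reference_targets(cfg, seed=5)
    clean_t, _, _ = generate_reference_targets(SyntheticConfig(), seed=5)
    assert not np.allclose(noisy_t.incidence_per_100k, clean_t.incidence_per_100k)
    # smoothing keeps the noisy curves close to the clean ones
    rel = np.abs(noisy_t.incidence_per_100k - clean_t.incidence_per_100k)
    scale = np.maximum(clean_t.incidence_per_100k, 0.05 * clean_t.incidence_per_100k.max())
    assert np.median(rel / scale) < 0.2


# ----------------------------------------------------------------------
# CSV round trips
# ----------------------------------------------------------------------
def test_targets_csv_round_trip(truth_targets):
    buf = io.StringIO()
    truth_targets.to_csv(buf)
    buf.seek(0)
    back = CalibrationTargets.from_csv(buf)
    assert np.array_equal(back.incidence_per_100k, truth_targets.incidence_per_100k)
    assert np.array_equal(back.mortality_per_100k, truth_targets.mortality_per_100k)
    assert back.mean_sojourn_target_months == truth_targets.mean_sojourn_target_months


def test_life_table_and_survival_round_trip(study_inputs):
    _, life, surv = study_inputs
    buf = io.StringIO()
    life.to_csv(buf)
    buf.seek(0)
    assert np.array_equal(LifeTable.from_csv(buf).q_month, life.q_month)
    buf = io.StringIO()
    surv.to_csv(buf)
    buf.seek(0)
    assert np.array_equal(StageSurvival.from_csv(buf).q_month, surv.q_month)


def test_negative_rates_rejected():
    with pytest.raises(ValueError):
        CalibrationTargets(np.arange(18, 85), -np.ones((67, 4)), np.ones(67))
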