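"""Model/Results facade, pipeline orchestration and CLI plumbing."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from pdac_earlybench import NaturalHistoryModel, run_pipeline
from pdac_earlybench.calibration import CalibrationConfig
from pdac_earlybench.cli import main
from pdac_earlybench.schedule import TransitionSchedule

FAST_CAL = dict(
    n_steps_invariant=600, n_steps_variant=600, n_steps_sojourn=600,
    n_steps_refine=300, max_alternations=2, polish_max_evals=2_000,
    powell_maxfev=2_000, sojourn_tol=0.5,
)


@pytest.fixture(scope="module")
def smoke_manifest(tmp_path_factory, study_inputs):
    out = tmp_path_factory.mktemp("pipeline")
    cfg = {
        "calibration": FAST_CAL,
        "sojourn_targets": [90.0],
        "population": 10_000,
        "x_grid": [6, 24],
        "iterations": 2,
    }
    manifest = run_pipeline(cfg, outdir=out, seed=1)
    return out, manifest, cfg


def test_pipeline_smoke_emits_declared_outputs(smoke_manifest):
    out, manifest, _ = smoke_manifest
    for name in ("targets.csv", "life_table.csv", "stage_survival.csv",
                 "schedule_sj90m.csv", "calibration_summary.json",
                 "records_sj90m.csv", "benefit_whole_sj90m.csv",
                 "benefit_ageband_sj90m.csv", "benefit_stageage_sj90m.csv",
                 "iteration_means_sj90m.csv", "manifest.json"):
        assert (out / name).exists(), name
    assert "sj90m" in manifest["achieved_sojourn_months"]


def test_pipeline_rerun_uses_cache_and_reproduces(smoke_manifest):
    out, manifest, cfg = smoke_manifest
    before = (out / "records_sj90m.csv").read_bytes()
    manifest2 = run_pipeline(cfg, outdir=out, seed=1)
    assert all(s["cached"] for s in manifest2["stages"].values())
    assert (out / "records_sj90m.csv").read_bytes() == before
    assert manifest2["achieved_sojourn_months"] == manifest["achieved_sojourn_months"]


def test_pipeline_benefit_tables_regenerable_from_records(smoke_manifest):
    from pdac_earlybench import benefit_summary

    out, _, _ = smoke_manifest
    records = pd.read_csv(out / "records_sj90m.csv")
    again = benefit_summary(records, "whole")
    stored = pd.read_csv(out / "benefit_whole_sj90m.csv")
    pd.testing.assert_frame_equal(
        again.reset_index(drop=True), stored, check_dtype=False, atol=1e-12
    )


def test_model_results_facade(study_inputs):
    targets, life, surv = study_inputs
    model = NaturalHistoryModel(
        targets, life, surv, CalibrationConfig(seed=2, **FAST_CAL)
    )
    res = model.fit(sojourn_targets=90.0)
    assert res.labels == ["sj90m"]
    summ = res.summary()
    assert summ.loc[0, "variant"] == "sj90m"
    assert summ.loc[0, "achieved_sojourn_months"] == pytest.approx(
        res["sj90m"].achieved_sojourn_months
    )
    cohort = res.simulate(5_000, seed=1)
    assert cohort.n == 5_000
    recs = res.counterfactual(5_000, x_grid=(6,), n_iterations=1, seed=1)
    tbl = res.benefit_table(recs)
    assert (tbl["n"] > 0).all()


def test_model_from_csv_round_trip(tmp_path, study_inputs):
    targets, life, surv = study_inputs
    targets.to_csv(tmp_path / "t.csv")
    life.to_csv(tmp_path / "l.csv")
    surv.to_csv(tmp_path / "s.csv")
    model = NaturalHistoryModel.from_csv(
        tmp_path / "t.csv", tmp_path / "l.csv", tmp_path / "s.csv"
    )
    assert np.array_equal(model.targets.incidence_per_100k, targets.incidence_per_100k)


def test_cli_synth_targets_and_simulate(tmp_path, truth_schedule):
    runner = CliRunner()
    res = runner.invoke(main, ["synth-targets", "--seed", "1", "--out", str(tmp_path)])
    assert res.exit_code == 0, res.output
    assert (tmp_path / "targets.csv").exists()

    sched_path = tmp_path / "sched.csv"
    truth_schedule.to_csv(sched_path)
    res = runner.invoke(main, [
        "simulate", "--schedule", str(sched_path), "--n", "2000",
        "--seed", "1", "--out", str(tmp_path / "hist.csv"),
    ])
    assert res.exit_code == 0, res.output
    hist = pd.read_csv(tmp_path / "hist.csv")
    assert len(hist) == 2000

    res = runner.invoke(main, [
        "counterfact", "--schedule", str(sched_path), "--n", "20000",
        "--x", "6,24", "--iterations", "1", "--seed", "1",
        "--out", str(tmp_path / "recs.csv"),
    ])
    assert res.exit_code == 0, res.output
    res = runner.invoke(main, [
        "report", "--records", str(tmp_path / "recs.csv"),
        "--out", str(tmp_path / "benefit.csv"),
    ])
    assert res.exit_code == 0, res.output
    ben = pd.read_csv(tmp_path / "benefit.csv")
    assert set(ben["x"]) == {6, 24}


def test_schedule_csv_is_loadable_by_cli_outputs(smoke_manifest):
    out, _, _ = smoke_manifest
    sched = TransitionSchedule.from_csv(out / "schedule_sj90m.csv")
    sched.validate()
    summary = json.loads((out / "calibration_summary.json").read_text())
    assert "sj90m" in summary
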