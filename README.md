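# pdac-earlybench

Natural-history microsimulation of pancreatic ductal adenocarcinoma
(PDAC) with a counterfactual early-detection benchmark: how many
life-years would a patient who died of PDAC have gained if their cancer
had been found *x* months before its clinical diagnosis?

The package is for modellers and cancer-screening researchers who want
a reproducible, desk-scale implementation of this analysis: an
11-state monthly-cycle multistate model calibrated to age-dependent
incidence-by-stage and mortality curves, with the cancer **sojourn
time** (months from onset of screen-detectable disease to clinical
diagnosis) controlled as an explicit calibration target.

## The model

Eleven health states: `NORMAL`, four preclinical screen-detectable
stages `UT1..UT4`, four clinically detected stages `DT1..DT4`, and two
absorbing deaths (cancer, other causes).  Allowed transitions are
onset (`NORMAL→UT1`), progression (`UTi→UTi+1`), detection
(`UTi→DTi`), cancer death from detected stages only, and other-cause
death from any alive state.  People enter at age 18 and are followed
in monthly cycles to age 85; all hazards are age-indexed.

The mean sojourn time is the Markov-chain mean first passage time from
`UT1` to the detected set,

    m_i = 1 + Σ_{k∉targets} p_ik · m_k ,

evaluated on the age-frozen transition matrix and summarised as the
unweighted mean over ages 18–60.  Detection and progression hazards
are calibrated by stepwise simulated annealing so that the model
reproduces stage-specific incidence and PDAC mortality curves *and*
attains a requested mean sojourn time (the fit alone does not identify
it: unconstrained fits drift to implausibly long sojourns).  Variants
calibrated to 120-, 60- and 36-month sojourns are labelled `sj120m`,
`sj60m`, `sj36m`.

The counterfactual rollback takes every simulated patient who died of
PDAC, looks up their state *x* months before diagnosis, converts
`UTi → DTi` there (perfect screening sensitivity), and resimulates
forward under that stage's mortality, never letting the counterfactual
death precede the real-world one.  **Life-years gained** (LYG,
counterfactual minus real death age) excludes lead time by
construction; **survival duration** (intervention to counterfactual
death) includes it, which is exactly the lead-time bias a naive
survival-from-diagnosis comparison suffers.

## Worked example

```python
from pdac_earlybench import NaturalHistoryModel

model = NaturalHistoryModel.from_synthetic(seed=0)   # SEER/CDC-like synthetic inputs
results = model.fit(sojourn_targets=(120, 60, 36), seed=2)
print(results.summary())

records = results.counterfactual(200_000, n_iterations=3, seed=2, label="sj36m")
print(results.benefit_table(records))
```

which prints (abridged):

```
variant  target_sojourn_months  achieved_sojourn_months  fit_objective  converged
 sj120m                    120               119.996199       0.000038       True
  sj60m                     60                59.999966       0.000002       True
  sj36m                     36                36.000842       0.000010       True

  x    n  mean_lyg_years  median_lyg_years  ci_low_years  ci_high_years  prop_zero_gain
  3 6063           0.937               0.0         0.887          0.987           0.531
  6 5874           1.125               0.0         1.067          1.182           0.523
 12 5259           1.443               0.0         1.368          1.518           0.516
 24 3603           1.615               0.0         1.518          1.713           0.537
 48 1236           1.345               0.0         1.176          1.513           0.666
 60  654           1.187               0.0         0.964          1.409           0.703
```

Reading: all three variants hit their sojourn targets to a fraction of
a month while fitting the same incidence/mortality curves.  For the
36-month variant, a rollback 24 months before diagnosis yields a mean
gain of 1.6 life-years over the 3,603 eligible person-records (people
still preclinical at that month); more than half of rollbacks gain
nothing (`prop_zero_gain`) — pure lead time.  Eligibility (`n`) shrinks
as the lead grows, and the mean gain peaks near 2 years of lead and
declines for earlier interventions, a pattern that is strongest for
the short-sojourn variant.

The CLI mirrors the pipeline:

```bash
pdac-earlybench run-all --seed 1 --out pipeline_out/
pdac-earlybench synth-targets | calibrate | simulate | counterfact | report  # stage by stage
```

## Layout

| module | contents |
| --- | --- |
| `states`, `schedule` | state space, age-indexed transition schedules, matrix builder |
| `cohort`, `sojourn` | deterministic cohort projection; MFPT and sojourn profiles |
| `targets` | synthetic SEER/CDC-like inputs, trendline smoothing, unknown-stage redistribution |
| `calibration` | stepwise simulated annealing + derivative-free refinement |
| `microsim`, `counterfactual` | individual-level engine; rollback analysis and benefit tables |
| `model` | `NaturalHistoryModel` / `NaturalHistoryResults` facade |
| `pipeline`, `cli` | stage orchestration, manifests, `pdac-earlybench` CLI |

See `docs/methods.md` for the modelling assumptions, parameter
defaults and numerical choices.
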