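# Methods

## Model structure and assumptions

The natural history of PDAC is a discrete-time multistate model on a
monthly cycle.  Eleven states: cancer-free (`NORMAL`), preclinical
screen-detectable tumor stages `UT1..UT4`, clinically detected stages
`DT1..DT4`, and absorbing cancer and other-cause deaths.  Permitted
transitions: `NORMAL→UT1` (onset), `UTi→UTi+1` (progression while
undetected), `UTi→DTi` (clinical detection), `DTi→cancer death`, and
other-cause death from every alive state.  There is no regression, no
detected-stage progression (treatment effects are folded into the
stage- and age-specific cancer mortality), and no cure state.

Everyone enters at exact age 18 and is censored at 85.  Months of age
are absolute integers (month 216 = age 18), giving 804 cycles.
Within a cycle the competing exits of a state are resolved by a
**single multinomial draw** from the transition-matrix row — exit
probabilities are additive, the residual is the stay probability.
This convention makes the deterministic cohort projection the exact
expectation of the microsimulation, which the engine-equivalence tests
exploit.

Hazards are stored at age knots (default 12 knots, denser above age
40 where incidence moves fastest) and interpolated piecewise-linearly
to months.  The two *fixed* hazard groups — stage-specific monthly
cancer-death probabilities (from cause-specific survival data) and the
all-cause life table — are never modified by calibration.

## Sojourn time

The sojourn time is the expected number of months from `UT1` entry to
first reaching any detected state, computed as a Markov-chain mean
first passage time: `m = 1 + Q m` over transient states with `m = 0`
on the targets, on the transition matrix frozen at the evaluation age
(one homogeneous chain per age, which yields the age trendline).  The
headline summary is the unweighted mean over whole-year ages 18–60.

Mortality handling in the MFPT is a genuine modelling choice.  The
default **excludes** both death hazards from the sub-chain without
renormalising (sojourn as a pure disease-progression quantity, the
first-passage system containing no mortality term); `renormalize`
conditions on surviving each cycle and is available as an alternative
(`death_handling=` argument).  On the stage chain the default has the
closed form `m4 = 1/det4`, `m_i = (1 + prog_i·m_{i+1})/(prog_i+det_i)`,
which the calibration fast path uses; the general linear solve is the
reference implementation and the two are cross-checked in tests.

## Synthetic study inputs

The real analysis calibrated to SEER incidence-by-stage and
cause-specific survival plus CDC 2017 life tables, none of which ship
with the package.  `targets.generate_reference_targets` emulates those
inputs; since its defaults define the study conditions for every test,
they are worth stating:

* **Lifetime PDAC death risk 1%** — the value the full-scale model
  produces (slightly under the real-world 1.7%).  The onset hazard is
  an exponential in age (growth 0.085/yr) whose scale is solved by 1-D
  root finding so the deterministic projection hits this risk exactly.
* **Stage mix at diagnosis (10/20/25/45%)** on the progression chain —
  late-stage dominant, as in SEER.  Progression/detection hazards are
  derived in closed form from the mix and the target sojourn (equal
  per-stage exit rates), then scaled in age.
* **Mean sojourn time 60 months** at ages 18–60, rising ~1.2%/yr of age
  (slower progression at older ages, consistent with the calibrated
  full-scale models).
* **Stage survival medians 48/22/13/6 months** (stages I–IV) — anchored
  to SEER 5-year cause-specific survival (localized ≈44%, regional
  ≈16%, distant ≈3%) under the model's geometric monthly survival,
  with hazards rising 2%/yr of age; the strong age gradient reflects
  the much longer survival of younger, earlier-detected patients.
* **Gompertz–Makeham life table** (annual hazard `7e-4 +
  5e-5·e^{0.0875·age}`), a standard approximation to U.S. all-cause
  mortality at adult ages.
* Optional multiplicative log-normal noise (`noise_sd`) for exercising
  the trendline smoother; the default targets are noise-free.

`targets_from_truth` projects a known schedule to target curves and
records its sojourn mean, giving parameter-recovery fixtures whose
global optimum is known exactly.

Target preparation implements the two published steps: unknown-stage
incidence is redistributed proportionally across stages I–IV *per age,
before smoothing*, and trendlines are cubic polynomials in age fitted
to `log(rate + ε)` and clipped at zero.  The functional form of the
trendlines is not documented in the source material; the log-cubic is
our choice (monotone-friendly, strictly positive, 4 df per curve).

## Calibration

Free parameters: onset, three progression and four detection hazards
at the age knots, searched on the logit scale (probabilities stay in
(0,1) without clipping; proposals violating total row exit mass ≤ 1
are rejected).  The fit objective is, per target curve, the mean over
ages of squared relative residuals with the denominator floored at 1%
of the curve's maximum — the floor keeps near-zero young-age rates
from dominating, and "relative error with a 1%-of-max floor" is also
exactly the recovery metric the tests use.

The staged procedure:

1. **Age-invariant annealing** (8 scalars, sojourn excluded) from a
   random valid start — a cheap approximation used to seed stage 2.
2. **Age-variant annealing** (knot values, sojourn excluded), followed
   by a compass-search polish.
3. **Sojourn-targeted annealing**: the squared deviation of the 18–60
   mean sojourn (in years) joins the objective, its weight auto-scaled
   so its initial magnitude matches the incidence component.  A
   one-sided regulariser additionally penalises the mean sojourn over
   ages 61–85 when it exceeds 1.6× the target: the 18–60 summary alone
   leaves old-age sojourn unconstrained, and without the guard it
   drifts to values that distort the cancer-death cohort's sojourn
   distribution.
4. **Alternation** of sojourn-targeted and fit-refinement annealing
   until the achieved sojourn is within ±5% of the target, then a
   **joint refinement**: compass (pattern) search and repeated Powell
   direction-set passes under a pinned-sojourn objective (penalty
   weight chosen so a deviation at tolerance costs the whole fit
   ceiling).  Both refiners are derivative-free and deterministic;
   no gradient-based optimisation is used anywhere.
5. Descending sojourn targets (e.g. 120 → 60 → 36 months) are processed
   sequentially, each warm-started from the previous fit.

Annealing mechanics: geometric cooling from `0.1×` the starting
objective down by `1e-4`, proposal SD decaying from 0.3 to 0.03
(logit scale), cycled proposal kinds — single-coordinate moves (the
workhorse), whole-hazard shifts, and a "speed" move shifting all
progression and detection logits together, which retunes the sojourn
while approximately preserving the stage mix.  Convergence is declared
numerically (sojourn tolerance + fit ceiling of 10× the post-fit
objective); results carry a `converged` flag, the objective breakdown
and the best-seen trace.  Without the sojourn target the model is
unidentifiable: fits to the synthetic curves alone sit at sojourns of
2,000+ months, reproducing the motivation for the sequential loop.

## Microsimulation and counterfactual analysis

The individual-level engine draws each person-month from the same
multinomial rows as the projection.  Randomness is a **counter-based
splitmix64 stream per (seed, stream-tag, person)**, so histories are
bit-reproducible and independent of population size or execution
order (person *i*'s path is identical in an *n*=500 and an *n*=2,000
run).  Histories are stored compressed — entry months per visited
state — which is sufficient for all downstream queries and keeps a
million-person cohort small.  Censoring at 85 is recorded as its own
outcome, distinct from death.

Rollback: for each PDAC death and lead *x* (default grid 3, 6, 12, 24,
48, 60, 72, 84, 96, 108, 120 months), the state at (diagnosis − *x*)
is looked up; `NORMAL` (or a month before age 18) excludes the person,
`UTi` converts to `DTi` with perfect sensitivity.  The forward
resimulation from that month draws that stage's cancer mortality plus
all-cause mortality at attained age; any counterfactual death before
the real-world cancer death is deferred to it (death floor), so
life-years gained are never negative and `zero_gain` flags the pure
lead-time cases.  The identity
`survival = lyg + x + (real death − diagnosis)` holds exactly for
every record and is audited in tests.  Iterations are independent
streams; the 95% CI of the mean is the normal-approximation interval
over person-records pooled across iterations (per-iteration means are
also available) — whether the published CIs pooled persons or
iteration means is not stated, and pooling was chosen as the
convention consistent with their narrowness.  Group comparisons use
the independent-samples t-test (two groups) and one-way ANOVA (three),
at α = 0.05, via scipy.

## Problem sizes and numerical tolerances

Desk-scale sizes, chosen as the package defaults: engine-equivalence
checks run 100,000 people against the exact projection (4 binomial
SEs, on cells with ≥5 expected events where the normal approximation
is meaningful); parameter recovery and the three-variant comparison
calibrate under the default config with fixed seeds; the directional
benefit checks simulate 300,000 people per variant with 5 iterations;
the acceptance script uses 200,000 people and 3 iterations per
variant.  MFPT solves agree with 100,000 simulated first passages
within 1%.  Schedule CSVs round-trip bit-exactly (shortest-repr floats
plus round-trip parsing).

## Limitations

* The synthetic generator produces smooth, internally consistent
  inputs from the very model family being fitted.  Passing recovery
  tests therefore demonstrates that the calibration machinery works,
  not that the model family fits real SEER extracts; real-data runs go
  through the documented CSV readers.
* Tumor biology is not modelled (no size, growth kinetics or cellular
  dynamics); stages are the only disease resolution, and detected
  stages do not progress.
* Screening is perfectly sensitive and specific at the rollback month;
  harms, costs and quality adjustments are out of scope.
* Exact levels of life-years gained depend strongly on the stage- and
  age-survival inputs; under the synthetic defaults they are smaller
  than published full-scale values, while the qualitative structure
  (benefit rising with lead to a peak near 2–5 years, stronger and
  earlier-peaking for shorter sojourn, mean ≫ median with a large
  zero-gain mass) is reproduced and is what the tests assert.
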