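"""Sequential simulated-annealing calibration.

The eight free hazards (onset, three progression, four detection) are
fitted to stage-specific incidence and overall PDAC mortality curves
in a staged procedure:

1. target preparation (see :mod:`pdac_earlybench.targets`),
2. age-invariant annealing — eight scalars, sojourn excluded,
3. age-variant annealing — knot values of the eight hazards, sojourn
   excluded,
4. age-variant annealing with the mean sojourn time added as a target,
5. alternation of (3) and (4) until the requested mean sojourn time is
   reached while the incidence/mortality fit stays under a ceiling.

Fitted without a sojourn target the model is unidentifiable: very low
progression and detection hazards can reproduce the incidence curves
with implausibly long sojourn times (order of a thousand months), which
is why the sojourn target and the sequential loop exist.

Proposals perturb logit-transformed knot values, which keeps every
probability inside (0,1) without clipping; the residual row constraint
(total exit mass <= 1) is enforced by rejecting violating proposals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .schedule import TransitionSchedule
from .sojourn import sojourn_profile
from .states import AgeGrid
from .targets import CalibrationTargets, LifeTable, StageSurvival, DEFAULT_KNOT_AGES

__all__ = [
    "CalibrationConfig",
    "CalibrationResult",
    "objective",
    "anneal_age_invariant",
    "anneal_age_variant",
    "sequential_calibrate",
]


@dataclass
class CalibrationConfig:
    """Tunables of the annealing procedure.

    Temperatures are relative: the initial temperature is
    ``t0_frac * objective(start)`` and decays geometrically to
    ``t_end_frac`` of itself over the stage.  The proposal standard
    deviation (on the logit scale) decays the same way down to a tenth
    of its initial value, so early steps explore and late steps refine.
    """

    knot_ages: tuple = DEFAULT_KNOT_AGES
    n_steps_invariant: int = 6000
    n_steps_variant: int = 8000
    n_steps_sojourn: int = 4000
    n_steps_refine: int = 3000
    max_alternations: int = 10
    proposal_sd: float = 0.3
    t0_frac: float = 0.1
    t_end_frac: float = 1e-4
    w_incidence: float = 1.0
    w_mortality: float = 1.0
    sojourn_tol: float = 0.05
    #: one-sided guard on the post-60 sojourn profile: the mean over
    #: ages 61-85 may not exceed sojourn_elder_ratio times the 18-60
    #: target without penalty (weight relative to the main sojourn
    #: term).  Without it the summary ages leave old-age sojourn
    #: unconstrained and it drifts to implausible values.
    sojourn_elder_ratio: float = 1.6
    sojourn_elder_weight: float = 0.5
    fit_ceiling_factor: float = 10.0
    plateau_steps: int = 0  # 0 disables plateau early stopping
    #: compass-search refinement (zero-temperature coordinate moves)
    #: appended to selected annealing stages; step halves from
    #: polish_delta0 down to polish_delta_min on the logit scale
    polish_delta0: float = 0.2
    polish_delta_min: float = 5e-4
    polish_max_evals: int = 400_000
    #: budget of each Powell direction-set pass inside the final joint
    #: refinement (derivative-free line searches), and the number of
    #: Powell+compass rounds
    powell_maxfev: int = 150_000
    refine_rounds: int = 6
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.t_end_frac < 1:
            raise ValueError("t_end_frac must lie in (0,1)")
        if min(self.w_incidence, self.w_mortality) < 0:
            raise ValueError("objective weights must be non-negative")


@dataclass
class CalibrationResult:
    """Best-seen schedule of one annealing stage and its diagnostics."""

    schedule: TransitionSchedule
    objective_total: float
    components: dict
    achieved_sojourn_months: float
    trace: np.ndarray  # best-seen objective per step
    n_accepted: int
    converged: bool
    seed: int
    label: str = ""

    def simulate(self, n: int, seed: int = 0):
        """Run the microsimulation engine under the fitted schedule."""
        from .microsim import simulate_population

        return simulate_population(self.schedule, n, seed)


# ----------------------------------------------------------------------
# fast evaluator
# ----------------------------------------------------------------------
from numba import njit  # noqa: E402


@njit(cache=True)
def _fit_kernel(free_p, mi0, mi1, mw, cdeath_m, odeath_m,
                t_inc, t_mort, inc_scale, mort_scale, w_inc, w_mort):
    """Interpolate free hazards to months, project the cohort and score
    the fit — the whole inner loop of one objective evaluation.

    Returns (valid, comps[5]) with comps = four incidence components
    then mortality; invalid means the row-mass constraint is violated.
    """
    n_t = mi0.shape[0]
    comps = np.zeros(5)
    # interpolate to months
    onset = np.empty(n_t)
    prog = np.empty((n_t, 3))
    det = np.empty((n_t, 4))
    for t in range(n_t):
        a, b, w = mi0[t], mi1[t], mw[t]
        onset[t] = free_p[a, 0] * (1 - w) + free_p[b, 0] * w
        for j in range(3):
            prog[t, j] = free_p[a, 1 + j] * (1 - w) + free_p[b, 1 + j] * w
        for j in range(4):
            det[t, j] = free_p[a, 4 + j] * (1 - w) + free_p[b, 4 + j] * w
        od = odeath_m[t]
        if onset[t] + od > 1.0:
            return False, comps
        for j in range(4):
            g = prog[t, j] if j < 3 else 0.0
            if g + det[t, j] + od > 1.0:
                return False, comps
    # cohort projection with annual flow aggregation
    occ = np.zeros(11)
    occ[0] = 1.0
    nxt = np.zeros(11)
    n_years = n_t // 12
    inc = np.zeros((n_years, 4))
    mort = np.zeros(n_years)
    py = np.zeros(n_years)
    for t in range(n_t):
        y = t // 12
        od = odeath_m[t]
        alive = 0.0
        for s in range(9):
            alive += occ[s]
        py[y] += alive / 12.0
        for s in range(11):
            nxt[s] = 0.0
        nxt[1] += occ[0] * onset[t]
        nxt[10] += occ[0] * od
        nxt[0] += occ[0] * (1.0 - onset[t] - od)
        for i in range(4):
            g = prog[t, i] if i < 3 else 0.0
            d = det[t, i]
            m0 = occ[1 + i]
            nxt[5 + i] += m0 * d
            inc[y, i] += m0 * d
            if i < 3:
                nxt[2 + i] += m0 * g
            nxt[10] += m0 * od
            nxt[1 + i] += m0 * (1.0 - g - d - od)
        for i in range(4):
            c = cdeath_m[t, i]
            m0 = occ[5 + i]
            nxt[9] += m0 * c
            mort[y] += m0 * c
            nxt[10] += m0 * od
            nxt[5 + i] += m0 * (1.0 - c - od)
        nxt[9] += occ[9]
        nxt[10] += occ[10]
        for s in range(11):
            occ[s] = nxt[s]
    for y in range(n_years):
        d = py[y] if py[y] > 1e-12 else 1e-12
        for i in range(4):
            r = (1e5 * inc[y, i] / d - t_inc[y, i]) / inc_scale[y, i]
            comps[i] += w_inc * r * r / n_years
        r = (1e5 * mort[y] / d - t_mort[y]) / mort_scale[y]
        comps[4] += w_mort * r * r / n_years
    return True, comps


@njit(cache=True)
def _sojourn_kernel(free_p, ai0, ai1, aw):
    """Mean (over the summary ages) UT1->detected MFPT via the chain
    closed form, on hazards interpolated at those ages."""
    n = ai0.shape[0]
    tot = 0.0
    for a in range(n):
        i, j, w = ai0[a], ai1[a], aw[a]
        d4 = free_p[i, 7] * (1 - w) + free_p[j, 7] * w
        if d4 <= 0.0:
            return np.inf
        m = 1.0 / d4
        for st in (2, 1, 0):
            g = free_p[i, 1 + st] * (1 - w) + free_p[j, 1 + st] * w
            d = free_p[i, 4 + st] * (1 - w) + free_p[j, 4 + st] * w
            if g + d <= 0.0:
                return np.inf
            m = (1.0 + g * m) / (g + d)
        tot += m
    return tot / n


def _logit(p):
    from scipy.special import logit

    return logit(np.clip(p, 1e-12, 1 - 1e-12))


def _expit(x):
    from scipy.special import expit

    return expit(x)


class _Evaluator:
    """Precomputed-interpolation objective evaluator.

    Free parameters live as a (K, 8) array of logit hazards at the knot
    ages: columns 0 onset, 1-3 progression, 4-7 detection.  Fixed
    hazards (cancer death, other death) are interpolated to months once.
    """

    def __init__(self, knot_ages, cdeath_knots, odeath_knots, targets: CalibrationTargets,
                 w_inc: float, w_mort: float):
        self.knots = np.asarray(knot_ages, float)
        months_age = AgeGrid.cycle_months() / 12.0
        self.mi0, self.mi1, self.mw = self._interp_weights(months_age)
        ann_ages = np.arange(AgeGrid.START_AGE, 61.0)  # sojourn summary ages
        self.ai0, self.ai1, self.aw = self._interp_weights(ann_ages)
        elder_ages = np.arange(61.0, AgeGrid.END_AGE + 1.0)
        self.ei0, self.ei1, self.ew = self._interp_weights(elder_ages)
        self.elder_ratio = 1.6
        self.elder_weight = 0.5
        self.cdeath_m = np.column_stack(
            [np.interp(months_age, self.knots, cdeath_knots[:, j]) for j in range(4)]
        )
        self.odeath_m = np.interp(months_age, self.knots, odeath_knots)
        self.cdeath_knots = np.asarray(cdeath_knots, float)
        self.odeath_knots = np.asarray(odeath_knots, float)
        self.targets = targets
        # per-age relative scaling, floored at 1% of each curve's maximum
        # so near-zero young-age rates cannot dominate the residuals
        t_inc = targets.incidence_per_100k
        self.inc_scale = np.maximum(t_inc, 0.01 * np.maximum(t_inc.max(axis=0), 1e-9))
        t_mort = targets.mortality_per_100k
        self.mort_scale = np.maximum(t_mort, 0.01 * max(t_mort.max(), 1e-9))
        self.w_inc = w_inc
        self.w_mort = w_mort

    def _interp_weights(self, ages):
        idx = np.searchsorted(self.knots, ages, side="right") - 1
        idx = np.clip(idx, 0, len(self.knots) - 2)
        span = self.knots[idx + 1] - self.knots[idx]
        w = np.clip((ages - self.knots[idx]) / span, 0.0, 1.0)
        return idx, idx + 1, w

    def monthly_free(self, free_p: np.ndarray) -> np.ndarray:
        return (free_p[self.mi0, :] * (1 - self.mw)[:, None]
                + free_p[self.mi1, :] * self.mw[:, None])

    def fit_components(self, free_p: np.ndarray):
        """Incidence/mortality objective components, or None if invalid."""
        valid, c = _fit_kernel(
            free_p, self.mi0, self.mi1, self.mw, self.cdeath_m, self.odeath_m,
            self.targets.incidence_per_100k, self.targets.mortality_per_100k,
            self.inc_scale, self.mort_scale, self.w_inc, self.w_mort,
        )
        if not valid:
            return None
        return {"inc_stage1": c[0], "inc_stage2": c[1], "inc_stage3": c[2],
                "inc_stage4": c[3], "mortality": c[4]}

    def sojourn_18_60(self, free_p: np.ndarray) -> float:
        return float(_sojourn_kernel(free_p, self.ai0, self.ai1, self.aw))

    def sojourn_61_85(self, free_p: np.ndarray) -> float:
        return float(_sojourn_kernel(free_p, self.ei0, self.ei1, self.ew))

    def total(self, free_p, sojourn_target=None, w_sojourn=0.0):
        comps = self.fit_components(free_p)
        if comps is None:
            return math.inf, None
        if sojourn_target is not None:
            dev = (self.sojourn_18_60(free_p) - sojourn_target) / 12.0
            excess = max(
                0.0,
                self.sojourn_61_85(free_p) - self.elder_ratio * sojourn_target,
            ) / 12.0
            comps["sojourn"] = w_sojourn * float(
                dev**2 + self.elder_weight * excess**2
            )
        return float(sum(comps.values())), comps

    def to_schedule(self, free_p: np.ndarray) -> TransitionSchedule:
        return TransitionSchedule(
            self.knots.copy(), free_p[:, 0], free_p[:, 1:4], free_p[:, 4:8],
            self.cdeath_knots.copy(), self.odeath_knots.copy(),
        )


def _make_evaluator(targets, life_table, stage_survival, config) -> _Evaluator:
    knots = np.asarray(config.knot_ages, float)
    cdeath = stage_survival.at_ages(knots)
    odeath = life_table.at_ages(knots)
    ev = _Evaluator(knots, cdeath, odeath, targets, config.w_incidence, config.w_mortality)
    ev.elder_ratio = config.sojourn_elder_ratio
    ev.elder_weight = config.sojourn_elder_weight
    return ev


def objective(
    schedule: TransitionSchedule,
    targets: CalibrationTargets,
    w_incidence: float = 1.0,
    w_mortality: float = 1.0,
    sojourn_target: float | None = None,
    w_sojourn: float = 1.0,
):
    """Weighted least-squares calibration objective with breakdown.

    Each incidence/mortality component is the mean over ages of the
    squared relative residual, with the denominator floored at 1% of
    the target curve's maximum so near-zero rates at young ages cannot
    dominate; the optional
    sojourn component is the squared deviation of the mean (ages 18-60)
    sojourn time in years.  Returns ``(total, components)``; the
    components sum to the total.
    """
    from .cohort import cohort_project

    if targets.ages_years.size != AgeGrid.END_AGE - AgeGrid.START_AGE:
        raise ValueError("targets must cover whole-year ages 18..84")
    proj = cohort_project(schedule)
    comps = {}
    t_inc = targets.incidence_per_100k
    inc_scale = np.maximum(t_inc, 0.01 * np.maximum(t_inc.max(axis=0), 1e-9))
    for s in range(4):
        r = (proj.incidence_per_100k[:, s] - t_inc[:, s]) / inc_scale[:, s]
        comps[f"inc_stage{s + 1}"] = w_incidence * float(np.mean(r**2))
    t_mort = targets.mortality_per_100k
    mort_scale = np.maximum(t_mort, 0.01 * max(t_mort.max(), 1e-9))
    r = (proj.mortality_per_100k - t_mort) / mort_scale
    comps["mortality"] = w_mortality * float(np.mean(r**2))
    if sojourn_target is not None:
        dev = (sojourn_profile(schedule).mean_18_60 - sojourn_target) / 12.0
        comps["sojourn"] = w_sojourn * float(dev**2)
    return float(sum(comps.values())), comps


# ----------------------------------------------------------------------
# annealing core
# ----------------------------------------------------------------------
def _anneal(
    ev: _Evaluator,
    x0: np.ndarray,  # (K, 8) logits
    n_steps: int,
    config: CalibrationConfig,
    rng: np.random.Generator,
    blocks,
    sojourn_target: float | None = None,
    w_sojourn: float = 0.0,
    age_invariant: bool = False,
):
    """Blockwise Metropolis annealing on logit knot values.

    ``blocks`` is a cycled list of proposal kinds ("stepwise" updates):
    a list of column indices perturbs those hazards (same increment at
    every knot when ``age_invariant``, per-knot increments otherwise);
    ``'coord'`` perturbs one random (knot, hazard) coordinate — the
    workhorse local move; ``'colshift'`` shifts every knot of one
    random hazard by a common increment (a global rescaling);
    ``'speed'`` shifts all progression and detection logits together,
    which moves the sojourn time while approximately preserving the
    stage mix at diagnosis.
    """
    x = x0.copy()
    n_knots, n_cols = x.shape
    f, comps = ev.total(_expit(x), sojourn_target, w_sojourn)
    if not np.isfinite(f):
        raise ValueError("initial point violates the row-mass constraint")
    best_x, best_f, best_c = x.copy(), f, comps
    t0 = max(f * config.t0_frac, 1e-12)
    cool = config.t_end_frac ** (1.0 / max(n_steps, 1))
    sd_decay = 0.1 ** (1.0 / max(n_steps, 1))
    temp, sd = t0, config.proposal_sd
    trace = np.empty(n_steps)
    n_acc = 0
    since_improve = 0
    for step in range(n_steps):
        blk = blocks[step % len(blocks)]
        prop = x.copy()
        if blk == "speed":
            prop[:, 1:8] += rng.normal(0.0, sd)
        elif blk == "coord":
            prop[rng.integers(n_knots), rng.integers(n_cols)] += rng.normal(0.0, sd)
        elif blk == "colshift":
            prop[:, rng.integers(n_cols)] += rng.normal(0.0, sd)
        elif age_invariant:
            cols = np.asarray(blk)
            prop[:, cols] += rng.normal(0.0, sd, size=cols.size)[None, :]
        else:
            cols = np.asarray(blk)
            prop[:, cols] += rng.normal(0.0, sd, size=(x.shape[0], cols.size))
        f_new, c_new = ev.total(_expit(prop), sojourn_target, w_sojourn)
        if f_new <= f or (np.isfinite(f_new)
                          and rng.random() < math.exp(-(f_new - f) / temp)):
            x, f, comps = prop, f_new, c_new
            n_acc += 1
        if f < best_f:
            best_x, best_f, best_c = x.copy(), f, comps
            since_improve = 0
        else:
            since_improve += 1
        trace[step] = best_f
        temp *= cool
        sd *= sd_decay
        if config.plateau_steps and since_improve >= config.plateau_steps:
            trace = trace[: step + 1]
            break
    return best_x, best_f, best_c, trace, n_acc


def _compass_polish(ev, x, config, sojourn_target=None, w_sojourn=0.0):
    """Zero-temperature coordinate refinement after annealing.

    Classic compass (pattern) search on the logit knot values: try
    +/-delta on each coordinate in turn, keep strict improvements,
    halve delta after a sweep without improvement.  Derivative-free,
    deterministic, and bounded by ``config.polish_max_evals``.
    """
    f, comps = ev.total(_expit(x), sojourn_target, w_sojourn)
    delta = config.polish_delta0
    n_ev = 0
    K, C = x.shape
    while delta > config.polish_delta_min and n_ev < config.polish_max_evals:
        improved = False
        for k in range(K):
            for c in range(C):
                for sgn in (1.0, -1.0):
                    xt = x.copy()
                    xt[k, c] += sgn * delta
                    ft, ct = ev.total(_expit(xt), sojourn_target, w_sojourn)
                    n_ev += 1
                    if ft < f:
                        x, f, comps = xt, ft, ct
                        improved = True
                        break
            if n_ev >= config.polish_max_evals:
                break
        if not improved:
            delta *= 0.5
    return x, f, comps


def _joint_refine(ev, x, config, sojourn_target, w_sojourn):
    """Final derivative-free refinement under the pinned-sojourn objective.

    A coarse compass search is followed by rounds of a Powell
    direction-set pass (much better along curved valleys than axis
    moves) and a fine compass sweep; each Powell restart rebuilds the
    direction set, which keeps the cascade making progress.  Rounds
    stop early once the objective improvement falls below 10%.  All
    steps are deterministic and gradient-free.
    """
    from scipy.optimize import minimize

    x, f, _c = _compass_polish(ev, x, config, sojourn_target, w_sojourn)
    shape = x.shape

    def fun(v):
        val, _ = ev.total(_expit(v.reshape(shape)), sojourn_target, w_sojourn)
        return val if np.isfinite(val) else 1e6

    fine = replace(config, polish_delta0=0.05,
                   polish_delta_min=config.polish_delta_min / 5.0)
    for _ in range(config.refine_rounds):
        res = minimize(fun, x.ravel(), method="Powell",
                       options={"maxfev": config.powell_maxfev, "xtol": 1e-8,
                                "ftol": 1e-14})
        x = res.x.reshape(shape)
        x, f_new, _c = _compass_polish(ev, x, fine, sojourn_target, w_sojourn)
        done = f_new > 0.9 * f
        f = f_new
        if done:
            break
    return x


_INVARIANT_BLOCKS = [[0], [1, 2, 3], [4, 5, 6, 7], [0, 1, 2, 3, 4, 5, 6, 7]]
_FIT_BLOCKS = ["coord", "coord", "coord", "colshift"]
_SOJOURN_BLOCKS = ["coord", "coord", "speed", "colshift", "coord"]


def _result(ev, x, f, comps, trace, n_acc, seed, converged=True, label=""):
    free_p = _expit(x)
    sched = ev.to_schedule(free_p)
    achieved = sojourn_profile(sched).mean_18_60
    return CalibrationResult(sched, f, comps, achieved, trace, n_acc, converged, seed, label)


def _default_start(ev: _Evaluator, rng: np.random.Generator) -> np.ndarray:
    """Random but schedule-valid age-invariant starting point."""
    K = ev.knots.size
    for _ in range(100):
        onset = 10 ** rng.uniform(-6.0, -3.0)
        prog = 10 ** rng.uniform(-2.5, -0.7, 3)
        det = 10 ** rng.uniform(-2.5, -0.7, 4)
        x = np.tile(_logit(np.concatenate([[onset], prog, det])), (K, 1))
        if np.isfinite(ev.total(_expit(x))[0]):
            return x
    raise RuntimeError("could not find a valid starting point")


def anneal_age_invariant(
    targets: CalibrationTargets,
    config: CalibrationConfig,
    life_table: LifeTable,
    stage_survival: StageSurvival,
    init: TransitionSchedule | None = None,
    n_steps: int | None = None,
) -> CalibrationResult:
    """Stage-2 annealing: eight age-constant free hazards, no sojourn term."""
    config.validate()
    ev = _make_evaluator(targets, life_table, stage_survival, config)
    rng = np.random.default_rng(config.seed)
    if init is None:
        x0 = _default_start(ev, rng)
    else:
        s = init.resample(ev.knots)
        x0 = _logit(np.column_stack([s.onset, s.prog, s.det]))
    steps = config.n_steps_invariant if n_steps is None else n_steps
    x, f, c, tr, na = _anneal(ev, x0, steps, config, rng, _INVARIANT_BLOCKS,
                              age_invariant=True)
    return _result(ev, x, f, c, tr, na, config.seed, label="age-invariant")


def anneal_age_variant(
    initial: TransitionSchedule,
    targets: CalibrationTargets,
    config: CalibrationConfig,
    include_sojourn: bool = False,
    n_iter: int | None = None,
    sojourn_target: float | None = None,
    seed_offset: int = 1,
    proposal_sd: float | None = None,
    polish: bool = False,
) -> CalibrationResult:
    """Stage-3/4 annealing: free hazards vary over the knot grid.

    With ``include_sojourn`` the squared sojourn deviation joins the
    objective; its weight is auto-scaled so that at the starting point
    its magnitude matches the incidence component (falling back to the
    full fit objective when the start already attains the target).
    """
    config.validate()
    if include_sojourn and sojourn_target is None:
        sojourn_target = targets.mean_sojourn_target_months
        if sojourn_target is None:
            raise ValueError("include_sojourn requires a sojourn target")
    ev = _make_evaluator(targets, life_table=_LifeView(initial), stage_survival=_SurvView(initial), config=config)
    rng = np.random.default_rng(config.seed + seed_offset)
    s = initial.resample(ev.knots)
    x0 = _logit(np.column_stack([s.onset, s.prog, s.det]))
    w_sojourn = 0.0
    blocks = _FIT_BLOCKS
    if include_sojourn:
        f0, c0 = ev.total(_expit(x0))
        dev0 = (ev.sojourn_18_60(_expit(x0)) - sojourn_target) / 12.0
        inc0 = sum(v for k, v in c0.items() if k.startswith("inc"))
        w_sojourn = max(inc0, f0, 1e-8) / max(dev0**2, 1e-8)
        blocks = _SOJOURN_BLOCKS
    steps = config.n_steps_variant if n_iter is None else n_iter
    cfg = config if proposal_sd is None else replace(config, proposal_sd=proposal_sd)
    x, f, c, tr, na = _anneal(
        ev, x0, steps, cfg, rng, blocks,
        sojourn_target=sojourn_target if include_sojourn else None,
        w_sojourn=w_sojourn,
    )
    if polish:
        x, f, c = _compass_polish(
            ev, x, cfg,
            sojourn_target=sojourn_target if include_sojourn else None,
            w_sojourn=w_sojourn,
        )
    label = "age-variant+sojourn" if include_sojourn else "age-variant"
    return _result(ev, x, f, c, tr, na, config.seed + seed_offset, label=label)


class _LifeView:
    """Adapter exposing a schedule's fixed other-death hazard as a LifeTable."""

    def __init__(self, schedule: TransitionSchedule):
        self._s = schedule

    def at_ages(self, ages):
        return np.interp(ages, self._s.knot_ages, self._s.odeath)


class _SurvView:
    def __init__(self, schedule: TransitionSchedule):
        self._s = schedule

    def at_ages(self, ages):
        return np.column_stack(
            [np.interp(ages, self._s.knot_ages, self._s.cdeath[:, j]) for j in range(4)]
        )


def sequential_calibrate(
    targets: CalibrationTargets,
    sojourn_targets,
    config: CalibrationConfig,
    life_table: LifeTable,
    stage_survival: StageSurvival,
) -> dict:
    """Full stepwise calibration to a descending list of sojourn targets.

    Runs the age-invariant and age-variant fit stages once, then for
    each requested mean sojourn time alternates sojourn-targeted and
    fit-refinement annealing until the achieved sojourn is within
    ``config.sojourn_tol`` of the target and the incidence/mortality
    objective stays below ``fit_ceiling_factor`` times the post-fit
    value.  Returns ``{sojourn_target: CalibrationResult}``; results
    that exhaust ``max_alternations`` carry ``converged=False``.
    """
    sojourn_targets = list(sojourn_targets)
    if sojourn_targets != sorted(sojourn_targets, reverse=True):
        raise ValueError("sojourn_targets must be sorted descending")
    inv = anneal_age_invariant(targets, config, life_table, stage_survival)
    var = anneal_age_variant(inv.schedule, targets, config, include_sojourn=False,
                             seed_offset=1, polish=True)
    ceiling = config.fit_ceiling_factor * max(var.objective_total, 1e-10)
    current = var.schedule
    results: dict = {}
    off = 2
    for tgt in sojourn_targets:
        last = None
        for _ in range(config.max_alternations):
            achieved = sojourn_profile(current).mean_18_60
            if abs(achieved - tgt) <= config.sojourn_tol * tgt:
                break
            r4 = anneal_age_variant(
                current, targets, config, include_sojourn=True,
                n_iter=config.n_steps_sojourn, sojourn_target=tgt, seed_offset=off,
            )
            off += 1
            r3 = anneal_age_variant(
                r4.schedule, targets, config, include_sojourn=False,
                n_iter=config.n_steps_refine, seed_offset=off,
                proposal_sd=config.proposal_sd / 3.0,
            )
            off += 1
            current = r3.schedule
            last = r3
        # joint refinement: fit polished under a sojourn penalty strong
        # enough that a deviation at tolerance costs the whole ceiling
        ev = _make_evaluator(targets, _LifeView(current), _SurvView(current), config)
        s = current.resample(ev.knots)
        x = _logit(np.column_stack([s.onset, s.prog, s.det]))
        w_pin = ceiling / max((config.sojourn_tol * tgt / 12.0) ** 2, 1e-12)
        x = _joint_refine(ev, x, config, tgt, w_pin)
        current = ev.to_schedule(_expit(x))
        fit_now, comps = objective(current, targets, config.w_incidence, config.w_mortality)
        achieved = sojourn_profile(current).mean_18_60
        converged = (abs(achieved - tgt) <= config.sojourn_tol * tgt
                     and fit_now <= ceiling)
        results[tgt] = CalibrationResult(
            current, fit_now, comps, achieved,
            last.trace if last is not None else np.empty(0),
            last.n_accepted if last is not None else 0,
            converged, config.seed, label=f"sj{int(round(tgt))}m",
        )
    return results
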