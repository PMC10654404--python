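"""Mean first passage times and the sojourn-time profile.

The sojourn time of the model is the expected number of monthly steps
from entry into the first preclinical stage (UT1) until first reaching
any clinically detected state, computed as a Markov-chain mean first
passage time: the linear system

    m_i = 1 + sum_{k not in targets} p_ik * m_k

solved over the transient states, with m = 0 on the target set.

Mortality handling is a modelling choice the MFPT definition leaves
open.  By default both death hazards are removed from the sub-chain
(sojourn is a pure disease-progression quantity); alternatively the
surviving transition mass can be renormalised.  The convention is
switchable via ``death_handling``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .schedule import TransitionSchedule, build_transition_matrix
from .states import AgeGrid, HealthState, DEATHS, DETECTED

__all__ = ["mfpt", "sojourn_profile", "SojournProfile", "UnreachableTargetError"]


class UnreachableTargetError(ValueError):
    """The target set cannot be reached: the MFPT is infinite/undefined."""


def _subchain_matrix(P: np.ndarray, death_handling: str) -> np.ndarray:
    """Alive-state sub-matrix of ``P`` with the chosen death convention.

    ``exclude``: death mass is dropped and added back to the stay
    probability (death hazards simply absent from the chain).
    ``renormalize``: rows are renormalised over alive destinations.
    """
    alive = [s for s in range(P.shape[0]) if s not in [int(d) for d in DEATHS]]
    A = P[np.ix_(alive, alive)].copy()
    if death_handling == "exclude":
        # restore row sums to 1 by inflating the diagonal (stay)
        np.fill_diagonal(A, A.diagonal() + (1.0 - A.sum(axis=1)))
    elif death_handling == "renormalize":
        rs = A.sum(axis=1)
        if np.any(rs <= 0):
            raise UnreachableTargetError("a state has zero surviving transition mass")
        A = A / rs[:, None]
    else:
        raise ValueError(f"unknown death_handling {death_handling!r}")
    return A


def mfpt(
    schedule: TransitionSchedule,
    age_month: int,
    source: HealthState,
    target_set: Iterable[HealthState],
    death_handling: str = "exclude",
) -> float:
    """Expected months from ``source`` to first hitting ``target_set``.

    The transition matrix is frozen at ``age_month`` (one homogeneous
    chain per evaluation age).  Raises
    :class:`UnreachableTargetError` when some state reachable from the
    source cannot reach the target set, in which case the expectation
    is infinite.
    """
    targets = {HealthState(t) for t in target_set}
    if not targets:
        raise ValueError("target set must be non-empty")
    source = HealthState(source)
    if source in targets:
        return 0.0
    P = build_transition_matrix(schedule, age_month)
    A = _subchain_matrix(P, death_handling)
    alive = [s for s in range(11) if s not in [int(d) for d in DEATHS]]
    idx = {s: i for i, s in enumerate(alive)}
    if int(source) not in idx:
        raise ValueError(f"source {source.name} is not an alive state")
    tgt = {idx[int(t)] for t in targets if int(t) in idx}

    # forward reachability from source on non-stay edges
    n = A.shape[0]
    edges = (A > 0) & ~np.eye(n, dtype=bool)
    reach = {idx[int(source)]}
    frontier = [idx[int(source)]]
    while frontier:
        i = frontier.pop()
        for j in np.where(edges[i])[0]:
            if j not in reach:
                reach.add(j)
                frontier.append(j)
    # every reachable non-target state must itself reach a target
    for i in reach - tgt:
        seen, stack, ok = {i}, [i], False
        while stack and not ok:
            u = stack.pop()
            for v in np.where(edges[u])[0]:
                if v in tgt:
                    ok = True
                    break
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if not ok:
            raise UnreachableTargetError(
                f"target set unreachable from state index {i} on the "
                f"death-excluded sub-chain at age month {age_month}"
            )

    # restrict to transient states reachable from the source; states the
    # walk cannot visit are irrelevant and would make I - Q singular
    transient = sorted(reach - tgt)
    Q = A[np.ix_(transient, transient)]
    m = np.linalg.solve(np.eye(len(transient)) - Q, np.ones(len(transient)))
    pos = {s: i for i, s in enumerate(transient)}
    return float(m[pos[idx[int(source)]]])


def chain_sojourn_months(prog: np.ndarray, det: np.ndarray) -> np.ndarray:
    """Closed-form MFPT from UT1 to {DT1..DT4} on the progression chain.

    Backward recursion over the linear stage chain with death excluded:
    ``m4 = 1/det4`` and ``m_i = (1 + prog_i * m_{i+1}) / (prog_i + det_i)``.
    Vectorised over leading axes; returns ``inf`` where detection is
    unreachable.  Agrees with :func:`mfpt` (default convention) and is
    used as the fast path inside calibration.
    """
    prog = np.asarray(prog, float)
    det = np.asarray(det, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(det[..., 3] > 0, 1.0 / det[..., 3], np.inf)
        for i in (2, 1, 0):
            exit_p = prog[..., i] + det[..., i]
            # zero progression never visits the downstream stage, so an
            # infinite downstream MFPT must not propagate (0 * inf)
            onward = np.where(prog[..., i] > 0, prog[..., i] * m, 0.0)
            m = np.where(exit_p > 0, (1.0 + onward) / exit_p, np.inf)
    return m


@dataclass
class SojournProfile:
    """Age-dependent mean sojourn time (months) and its 18-60 summary.

    ``mean_18_60`` is the unweighted mean of the age-specific values at
    whole-year ages 18..60 inclusive, the summary used to label model
    variants (e.g. a 36-month model).
    """

    ages_years: np.ndarray
    mfpt_months: np.ndarray

    @property
    def mean_18_60(self) -> float:
        mask = (self.ages_years >= 18) & (self.ages_years <= 60)
        return float(np.mean(self.mfpt_months[mask]))


def sojourn_profile(
    schedule: TransitionSchedule, death_handling: str = "exclude"
) -> SojournProfile:
    """Mean sojourn time at each whole-year age 18..85.

    For each age the transition matrix is frozen at that age and the
    MFPT from UT1 to the lumped detected set {DT1..DT4} is computed.
    """
    ages = np.arange(AgeGrid.START_AGE, AgeGrid.END_AGE + 1)
    if death_handling == "exclude":
        prog = np.stack([schedule.hazards_at_age(a)["prog"] for a in ages])
        det = np.stack([schedule.hazards_at_age(a)["det"] for a in ages])
        vals = chain_sojourn_months(prog, det)
        if not np.all(np.isfinite(vals)):
            raise UnreachableTargetError(
                "detection unreachable from UT1 at some age (zero hazards)"
            )
    else:
        vals = np.array(
            [
                mfpt(schedule, min(int(a) * 12, AgeGrid.END_MONTH - 1), HealthState.UT1,
                     DETECTED, death_handling)
                for a in ages
            ]
        )
    return SojournProfile(ages, vals)
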