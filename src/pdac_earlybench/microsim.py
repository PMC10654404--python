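"""Individual-level Monte-Carlo engine.

Simulates complete monthly state histories for a population that
enters the model cancer-free at exact age 18 and is followed to age 85
or death.  Each person-month resolves the competing exits of the
current state with a single multinomial draw from the transition-matrix
row, the same convention the deterministic cohort projection uses, so
the two engines agree in expectation.

Histories are stored compressed — the entry month of each visited
state — which is all the counterfactual rollback needs and keeps a
million-person run within a small memory footprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._rng import stream_key, uniform
from .schedule import TransitionSchedule
from .states import AgeGrid, HealthState

__all__ = [
    "SimulatedCohort",
    "IndividualHistory",
    "CohortSelection",
    "simulate_population",
    "select_pdac_deaths",
    "sojourn_time_of",
    "preclinical_stage_durations",
]

CAUSE_CENSORED = 0
CAUSE_CANCER = 1
CAUSE_OTHER = 2

_SIM_TAG = 101  # stream tag separating real-world simulation draws


@njit(cache=True)
def _simulate_kernel(onset, prog, det, cdeath, odeath, n, seed):
    start, end = 216, 1020
    ut_entry = np.full((n, 4), -1, np.int16)
    diag_month = np.full(n, -1, np.int16)
    diag_stage = np.zeros(n, np.int8)
    end_month = np.full(n, end, np.int16)
    cause = np.zeros(n, np.int8)
    for p in range(n):
        x = stream_key(seed, _SIM_TAG, p)
        state = 0  # 0 NORMAL, 1..4 UTi, 5..8 DTi
        t = start
        while t < end:
            k = t - start
            x, u = uniform(x)
            od = odeath[k]
            if u < od:
                end_month[p] = t + 1
                cause[p] = CAUSE_OTHER
                break
            if state == 0:
                if u < od + onset[k]:
                    state = 1
                    ut_entry[p, 0] = t + 1
            elif state <= 4:
                i = state - 1
                d = det[k, i]
                g = prog[k, i] if i < 3 else 0.0
                if u < od + d:
                    state = 5 + i
                    diag_month[p] = t + 1
                    diag_stage[p] = i + 1
                elif u < od + d + g:
                    state = state + 1
                    ut_entry[p, i + 1] = t + 1
            else:
                i = state - 5
                if u < od + cdeath[k, i]:
                    end_month[p] = t + 1
                    cause[p] = CAUSE_CANCER
                    break
            t += 1
    return ut_entry, diag_month, diag_stage, end_month, cause


@dataclass
class IndividualHistory:
    """One person's compressed monthly path.

    ``transitions`` lists (entry month, state) in order, starting with
    (216, NORMAL).  ``death`` is ``(cause, month)`` with cause one of
    ``"cancer"``, ``"other"``, ``"censored"`` (alive at 85).
    """

    person_id: int
    transitions: list
    diagnosis: tuple | None  # (stage 1..4, month)
    death: tuple  # (cause str, month)

    @property
    def death_cause(self) -> str:
        return self.death[0]


def sojourn_time_of(history: IndividualHistory) -> int:
    """Months from UT1 entry to clinical detection; requires a diagnosis."""
    if history.diagnosis is None:
        raise ValueError(f"person {history.person_id} was never diagnosed")
    ut1 = next(m for m, s in history.transitions if s == HealthState.UT1)
    return history.diagnosis[1] - ut1


def preclinical_stage_durations(history: IndividualHistory) -> np.ndarray:
    """Months spent in each of UT1..UT4; sums to the sojourn time."""
    if history.diagnosis is None:
        raise ValueError(f"person {history.person_id} was never diagnosed")
    out = np.zeros(4, dtype=int)
    entries = {int(s) - int(HealthState.UT1): m for m, s in history.transitions
               if HealthState(s).is_undetected}
    diag_m = history.diagnosis[1]
    for i, m in entries.items():
        nxt = entries.get(i + 1)
        out[i] = (nxt if nxt is not None else diag_m) - m
    return out


@dataclass
class CohortSelection:
    """Cancer-death cohort with per-person sojourn quantities."""

    person_ids: np.ndarray
    sojourn_months: np.ndarray
    stage_durations: np.ndarray  # (n, 4)
    diag_stage: np.ndarray
    diag_month: np.ndarray
    death_month: np.ndarray

    def __len__(self) -> int:
        return self.person_ids.size


class SimulatedCohort:
    """Array-backed collection of simulated histories."""

    def __init__(self, schedule: TransitionSchedule, n: int, seed: int,
                 ut_entry, diag_month, diag_stage, end_month, cause):
        self.schedule = schedule
        self.n = n
        self.seed = seed
        self.ut_entry = ut_entry
        self.diag_month = diag_month
        self.diag_stage = diag_stage
        self.end_month = end_month
        self.cause = cause

    # -- single-person view ------------------------------------------------
    def history(self, person_id: int) -> IndividualHistory:
        p = int(person_id)
        trans = [(AgeGrid.START_MONTH, HealthState.NORMAL)]
        for i in range(4):
            m = int(self.ut_entry[p, i])
            if m >= 0:
                trans.append((m, HealthState(HealthState.UT1 + i)))
        diag = None
        if self.diag_month[p] >= 0:
            stage = int(self.diag_stage[p])
            diag = (stage, int(self.diag_month[p]))
            trans.append((int(self.diag_month[p]), HealthState(HealthState.DT1 + stage - 1)))
        cause = {CAUSE_CENSORED: "censored", CAUSE_CANCER: "cancer",
                 CAUSE_OTHER: "other"}[int(self.cause[p])]
        if cause == "cancer":
            trans.append((int(self.end_month[p]), HealthState.CANCER_DEATH))
        elif cause == "other":
            trans.append((int(self.end_month[p]), HealthState.OTHER_DEATH))
        return IndividualHistory(p, trans, diag, (cause, int(self.end_month[p])))

    def __iter__(self):
        return (self.history(p) for p in range(self.n))

    # -- cohort summaries --------------------------------------------------
    def select_pdac_deaths(self) -> CohortSelection:
        return select_pdac_deaths(self)

    def sojourn_months_all(self) -> np.ndarray:
        """Sojourn time of every diagnosed person."""
        mask = self.diag_month >= 0
        return (self.diag_month[mask] - self.ut_entry[mask, 0]).astype(int)

    def occupancy_counts(self) -> np.ndarray:
        """(805, 11) person counts per state at each month boundary."""
        months = AgeGrid.END_MONTH - AgeGrid.START_MONTH + 1
        occ = np.zeros((months, 11), dtype=np.int64)

        def interval(row, start, stop):
            delta = np.zeros(months + 1, dtype=np.int64)
            np.add.at(delta, start - AgeGrid.START_MONTH, 1)
            np.add.at(delta, stop - AgeGrid.START_MONTH, -1)
            occ[:, row] += np.cumsum(delta)[:months]

        end = self.end_month.astype(np.int64)
        # censored people still occupy their alive state at the final boundary
        end_stop = np.where(self.cause == CAUSE_CENSORED, AgeGrid.END_MONTH + 1, end)
        ut = self.ut_entry.astype(np.int64)
        diag = self.diag_month.astype(np.int64)
        onset = np.where(ut[:, 0] >= 0, ut[:, 0], end_stop)
        interval(0, np.full(self.n, AgeGrid.START_MONTH, np.int64), onset)
        for i in range(4):
            has = ut[:, i] >= 0
            start = ut[has, i]
            if i < 3:
                nxt = np.where(ut[has, i + 1] >= 0, ut[has, i + 1], -1)
            else:
                nxt = np.full(int(has.sum()), -1, np.int64)
            d = diag[has]
            stop = np.where(nxt >= 0, nxt, np.where(d >= 0, d, end_stop[has]))
            interval(1 + i, start, stop)
        for i in range(4):
            has = (diag >= 0) & (self.diag_stage == i + 1)
            interval(5 + i, diag[has], end_stop[has])
        cd = self.cause == CAUSE_CANCER
        interval(9, end[cd], np.full(cd.sum(), AgeGrid.END_MONTH + 1, np.int64))
        od = self.cause == CAUSE_OTHER
        interval(10, end[od], np.full(od.sum(), AgeGrid.END_MONTH + 1, np.int64))
        return occ

    def incidence_per_100k(self) -> np.ndarray:
        """(67, 4) observed annual stage-specific incidence rates."""
        return self._annual_rates(self._diag_flows())

    def mortality_per_100k(self) -> np.ndarray:
        flows = np.zeros((AgeGrid.N_CYCLES, 1))
        cd = self.cause == CAUSE_CANCER
        np.add.at(flows[:, 0], self.end_month[cd].astype(int) - AgeGrid.START_MONTH - 1, 1)
        return self._annual_rates(flows)[:, 0]

    def _diag_flows(self) -> np.ndarray:
        flows = np.zeros((AgeGrid.N_CYCLES, 4))
        has = self.diag_month >= 0
        np.add.at(
            flows,
            (self.diag_month[has].astype(int) - AgeGrid.START_MONTH - 1,
             self.diag_stage[has].astype(int) - 1),
            1,
        )
        return flows

    def _annual_rates(self, flows: np.ndarray) -> np.ndarray:
        occ = self.occupancy_counts()
        alive = occ[:-1, :9].sum(axis=1).astype(float)
        n_years = AgeGrid.END_AGE - AgeGrid.START_AGE
        f = flows.reshape(n_years, 12, -1).sum(axis=1)
        py = alive.reshape(n_years, 12).sum(axis=1) / 12.0
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(py[:, None] > 0, 1e5 * f / py[:, None], 0.0)


def simulate_population(schedule: TransitionSchedule, n: int, seed: int) -> SimulatedCohort:
    """Simulate ``n`` individual monthly histories under ``schedule``.

    Reproducible: output depends only on (schedule, n, seed); each
    person's draws come from an independent counter-based stream, so
    results do not depend on execution order.
    """
    if n < 1:
        raise ValueError("population size must be at least 1")
    schedule.validate()
    m = schedule.monthly()
    arrays = _simulate_kernel(
        m.onset, np.ascontiguousarray(m.prog), np.ascontiguousarray(m.det),
        np.ascontiguousarray(m.cdeath), m.odeath, n, seed,
    )
    return SimulatedCohort(schedule, n, seed, *arrays)


def select_pdac_deaths(cohort: SimulatedCohort) -> CohortSelection:
    """The counterfactual-eligible cohort: people whose death cause is PDAC."""
    ids = np.where(cohort.cause == CAUSE_CANCER)[0]
    ut = cohort.ut_entry[ids].astype(int)
    diag = cohort.diag_month[ids].astype(int)
    sojourn = diag - ut[:, 0]
    durations = np.zeros((ids.size, 4), dtype=int)
    for i in range(4):
        entered = ut[:, i] >= 0
        if i < 3:
            nxt = np.where(ut[:, i + 1] >= 0, ut[:, i + 1], diag)
        else:
            nxt = diag
        durations[entered, i] = (nxt - ut[:, i])[entered]
    return CohortSelection(
        ids, sojourn, durations, cohort.diag_stage[ids].astype(int), diag,
        cohort.end_month[ids].astype(int),
    )
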