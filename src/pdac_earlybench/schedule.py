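"""Age-indexed monthly transition probabilities.

A :class:`TransitionSchedule` stores the eight free hazards (onset,
three progression, four detection) together with the two fixed hazard
groups (stage-specific cancer death, all-cause other death) at a set of
age knots, and interpolates them piecewise-linearly to the monthly
cycle grid.  The fixed hazards come from cause-specific survival data
and a life table and are never touched by calibration.

Within one monthly cycle the competing risks out of a state are
resolved by a single multinomial draw from the matrix row: exit
probabilities are additive and the residual mass is the probability of
staying put.  This keeps the deterministic cohort projection and the
microsimulation engine exactly consistent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .states import AgeGrid, HealthState, N_STATES

__all__ = [
    "TransitionSchedule",
    "MonthlyHazards",
    "ScheduleValidityError",
    "build_transition_matrix",
]

_HAZARD_COLUMNS = (
    ["p_onset"]
    + [f"p_prog{i}" for i in (1, 2, 3)]
    + [f"p_det{i}" for i in (1, 2, 3, 4)]
    + [f"p_cdeath{i}" for i in (1, 2, 3, 4)]
    + ["p_odeath"]
)


class ScheduleValidityError(ValueError):
    """A transition probability is outside [0,1] or a row's exit mass exceeds 1."""


@dataclass
class MonthlyHazards:
    """Hazards interpolated onto the 804 monthly cycles (months 216..1019)."""

    onset: np.ndarray  # (804,)
    prog: np.ndarray  # (804, 3)
    det: np.ndarray  # (804, 4)
    cdeath: np.ndarray  # (804, 4)
    odeath: np.ndarray  # (804,)


@dataclass
class TransitionSchedule:
    """Hazards at age knots, interpolated linearly to months.

    Parameters
    ----------
    knot_ages : array of float, ascending, spanning [18, 85]
    onset : (K,) NORMAL->UT1 probability per month
    prog : (K, 3) UTi->UTi+1, i=1..3
    det : (K, 4) UTi->DTi, i=1..4
    cdeath : (K, 4) DTi->CANCER_DEATH (fixed during calibration)
    odeath : (K,) alive->OTHER_DEATH (fixed during calibration)
    """

    knot_ages: np.ndarray
    onset: np.ndarray
    prog: np.ndarray
    det: np.ndarray
    cdeath: np.ndarray
    odeath: np.ndarray
    _monthly: MonthlyHazards | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.knot_ages = np.asarray(self.knot_ages, dtype=float)
        self.onset = np.asarray(self.onset, dtype=float)
        self.prog = np.asarray(self.prog, dtype=float)
        self.det = np.asarray(self.det, dtype=float)
        self.cdeath = np.asarray(self.cdeath, dtype=float)
        self.odeath = np.asarray(self.odeath, dtype=float)
        k = self.knot_ages.size
        if np.any(np.diff(self.knot_ages) <= 0):
            raise ValueError("knot ages must be strictly increasing")
        if self.knot_ages[0] > AgeGrid.START_AGE or self.knot_ages[-1] < AgeGrid.END_AGE:
            raise ValueError("knot ages must cover [18, 85]")
        shapes = {
            "onset": (k,),
            "prog": (k, 3),
            "det": (k, 4),
            "cdeath": (k, 4),
            "odeath": (k,),
        }
        for name, shape in shapes.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")

    # ------------------------------------------------------------------
    # interpolation
    # ------------------------------------------------------------------
    def hazards_at_age(self, age_years: float) -> dict[str, np.ndarray]:
        """Interpolated hazards at an exact (possibly fractional) age."""
        x = self.knot_ages

        def itp(y):
            if y.ndim == 1:
                return np.interp(age_years, x, y)
            return np.array([np.interp(age_years, x, y[:, j]) for j in range(y.shape[1])])

        return {
            "onset": itp(self.onset),
            "prog": itp(self.prog),
            "det": itp(self.det),
            "cdeath": itp(self.cdeath),
            "odeath": itp(self.odeath),
        }

    def monthly(self) -> MonthlyHazards:
        """Hazards at the start of each of the 804 monthly cycles (cached)."""
        if self._monthly is None:
            ages = AgeGrid.cycle_months() / 12.0
            x = self.knot_ages

            def itp1(y):
                return np.interp(ages, x, y)

            def itp2(y):
                return np.column_stack([np.interp(ages, x, y[:, j]) for j in range(y.shape[1])])

            self._monthly = MonthlyHazards(
                onset=itp1(self.onset),
                prog=itp2(self.prog),
                det=itp2(self.det),
                cdeath=itp2(self.cdeath),
                odeath=itp1(self.odeath),
            )
        return self._monthly

    def invalidate_cache(self) -> None:
        self._monthly = None

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ScheduleValidityError` on any invalid probability.

        Checks every monthly cycle: all hazards within [0,1] and the
        total exit mass of every state's row at most 1.
        """
        m = self.monthly()
        months = AgeGrid.cycle_months()
        for name, arr in (("onset", m.onset), ("prog", m.prog), ("det", m.det),
                          ("cdeath", m.cdeath), ("odeath", m.odeath)):
            bad = np.where((arr < 0) | (arr > 1))
            if bad[0].size:
                t = int(bad[0][0])
                raise ScheduleValidityError(
                    f"{name} outside [0,1] at age month {months[t]} "
                    f"(age {months[t] / 12:.2f}y)"
                )
        exits = {
            "NORMAL": m.onset + m.odeath,
            **{f"UT{i + 1}": (m.prog[:, i] if i < 3 else 0.0) + m.det[:, i] + m.odeath
               for i in range(4)},
            **{f"DT{i + 1}": m.cdeath[:, i] + m.odeath for i in range(4)},
        }
        for state, mass in exits.items():
            bad = np.where(np.asarray(mass) > 1.0 + 1e-12)[0]
            if bad.size:
                t = int(bad[0])
                raise ScheduleValidityError(
                    f"exit probability mass {mass[t]:.6f} > 1 for state {state} "
                    f"at age month {months[t]} (age {months[t] / 12:.2f}y)"
                )

    # ------------------------------------------------------------------
    # convenience constructors / transforms
    # ------------------------------------------------------------------
    @classmethod
    def age_invariant(cls, onset, prog, det, cdeath, odeath) -> "TransitionSchedule":
        """A schedule constant in age (two boundary knots)."""
        ages = np.array([AgeGrid.START_AGE, AgeGrid.END_AGE], dtype=float)
        tile1 = lambda v: np.full(2, float(v))
        tile2 = lambda v: np.tile(np.asarray(v, dtype=float), (2, 1))
        return cls(ages, tile1(onset), tile2(prog), tile2(det), tile2(cdeath), tile1(odeath))

    def resample(self, knot_ages) -> "TransitionSchedule":
        """Re-express on a new knot grid by sampling the interpolant."""
        knot_ages = np.asarray(knot_ages, dtype=float)
        vals = [self.hazards_at_age(a) for a in knot_ages]
        return TransitionSchedule(
            knot_ages,
            np.array([v["onset"] for v in vals]),
            np.array([v["prog"] for v in vals]),
            np.array([v["det"] for v in vals]),
            np.array([v["cdeath"] for v in vals]),
            np.array([v["odeath"] for v in vals]),
        )

    def replace_free(self, onset, prog, det) -> "TransitionSchedule":
        """New schedule with free hazards replaced; fixed hazards untouched."""
        return TransitionSchedule(
            self.knot_ages.copy(), np.asarray(onset, float), np.asarray(prog, float),
            np.asarray(det, float), self.cdeath.copy(), self.odeath.copy(),
        )

    # ------------------------------------------------------------------
    # CSV round trip
    # ------------------------------------------------------------------
    def to_csv(self, path_or_buf) -> None:
        """Write the knot table; floats use repr precision so the round
        trip is bit-exact."""
        cols = np.column_stack(
            [self.knot_ages, self.onset, self.prog, self.det, self.cdeath, self.odeath]
        )
        header = ",".join(["age_years"] + _HAZARD_COLUMNS)
        buf = io.StringIO()
        buf.write(header + "\n")
        for row in cols:
            buf.write(",".join(repr(float(v)) for v in row) + "\n")
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf) -> "TransitionSchedule":
        import pandas as pd

        df = pd.read_csv(path_or_buf, comment="#", float_precision="round_trip")
        missing = set(["age_years"] + _HAZARD_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"schedule CSV missing columns: {sorted(missing)}")
        return cls(
            df["age_years"].to_numpy(float),
            df["p_onset"].to_numpy(float),
            df[[f"p_prog{i}" for i in (1, 2, 3)]].to_numpy(float),
            df[[f"p_det{i}" for i in (1, 2, 3, 4)]].to_numpy(float),
            df[[f"p_cdeath{i}" for i in (1, 2, 3, 4)]].to_numpy(float),
            df["p_odeath"].to_numpy(float),
        )


def build_transition_matrix(schedule: TransitionSchedule, age_month: int) -> np.ndarray:
    """Row-stochastic 11x11 one-month transition matrix at ``age_month``.

    Rows follow :class:`~pdac_earlybench.states.HealthState` order.  The
    residual probability mass of each row is assigned to staying in the
    same state; the death rows are identity (absorbing).
    """
    if not (AgeGrid.START_MONTH <= age_month < AgeGrid.END_MONTH):
        raise ValueError(f"age_month {age_month} outside the simulation grid")
    h = schedule.hazards_at_age(age_month / 12.0)
    onset, prog, det, cdeath, odeath = (
        float(h["onset"]), h["prog"], h["det"], h["cdeath"], float(h["odeath"]),
    )

    P = np.zeros((N_STATES, N_STATES))
    S = HealthState

    def fill(row: int, moves: dict[int, float]) -> None:
        total = 0.0
        for dst, p in moves.items():
            if not (0.0 <= p <= 1.0):
                raise ScheduleValidityError(
                    f"probability {p} outside [0,1] for state "
                    f"{S(row).name} at age month {age_month}"
                )
            P[row, dst] = p
            total += p
        if total > 1.0 + 1e-12:
            raise ScheduleValidityError(
                f"exit probability mass {total:.6f} > 1 for state {S(row).name} "
                f"at age month {age_month}"
            )
        P[row, row] = 1.0 - total

    fill(S.NORMAL, {S.UT1: onset, S.OTHER_DEATH: odeath})
    for i in range(4):
        moves = {S.DT1 + i: float(det[i]), S.OTHER_DEATH: odeath}
        if i < 3:
            moves[S.UT1 + i + 1] = float(prog[i])
        fill(S.UT1 + i, moves)
    for i in range(4):
        fill(S.DT1 + i, {S.CANCER_DEATH: float(cdeath[i]), S.OTHER_DEATH: odeath})
    P[S.CANCER_DEATH, S.CANCER_DEATH] = 1.0
    P[S.OTHER_DEATH, S.OTHER_DEATH] = 1.0
    return P
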