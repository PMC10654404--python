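"""State space and age grid of the PDAC natural-history model.

The model tracks one person through eleven health states on a monthly
cycle: a cancer-free state, four preclinical screen-detectable tumor
stages (UT1..UT4), four clinically detected stages (DT1..DT4) and two
absorbing death states.  Allowed transitions are onset (NORMAL->UT1),
stage progression while undetected (UTi->UTi+1), clinical detection
(UTi->DTi), cancer death from a detected stage only, and other-cause
death from any alive state.
"""

from __future__ import annotations

import enum


class HealthState(enum.IntEnum):
    """The eleven health states, ordered as they index matrix rows."""

    NORMAL = 0
    UT1 = 1
    UT2 = 2
    UT3 = 3
    UT4 = 4
    DT1 = 5
    DT2 = 6
    DT3 = 7
    DT4 = 8
    CANCER_DEATH = 9
    OTHER_DEATH = 10

    @property
    def is_undetected(self) -> bool:
        return HealthState.UT1 <= self <= HealthState.UT4

    @property
    def is_detected(self) -> bool:
        return HealthState.DT1 <= self <= HealthState.DT4

    @property
    def is_death(self) -> bool:
        return self in (HealthState.CANCER_DEATH, HealthState.OTHER_DEATH)

    @property
    def stage(self) -> int:
        """Tumor stage 1..4 for UT/DT states; raises otherwise."""
        if self.is_undetected:
            return int(self) - int(HealthState.UT1) + 1
        if self.is_detected:
            return int(self) - int(HealthState.DT1) + 1
        raise ValueError(f"{self.name} has no tumor stage")


N_STATES = 11

UNDETECTED = (HealthState.UT1, HealthState.UT2, HealthState.UT3, HealthState.UT4)
DETECTED = (HealthState.DT1, HealthState.DT2, HealthState.DT3, HealthState.DT4)
DEATHS = (HealthState.CANCER_DEATH, HealthState.OTHER_DEATH)
ALIVE = (HealthState.NORMAL,) + UNDETECTED + DETECTED

#: edges other than stay/death, as (source, destination) pairs
ALLOWED_EDGES = frozenset(
    [(HealthState.NORMAL, HealthState.UT1)]
    + [(UNDETECTED[i], UNDETECTED[i + 1]) for i in range(3)]
    + [(UNDETECTED[i], DETECTED[i]) for i in range(4)]
    + [(d, HealthState.CANCER_DEATH) for d in DETECTED]
    + [(s, HealthState.OTHER_DEATH) for s in ALIVE]
)


class AgeGrid:
    """Monthly age grid: people enter at 18 and are censored at 85.

    Months of age are absolute (month 216 = exact age 18).  A cycle
    starting at month ``t`` spans ages ``t/12`` to ``(t+1)/12``; the
    final cycle starts at month 1019 and anyone still alive at month
    1020 is censored.
    """

    START_MONTH = 216  # age 18
    END_MONTH = 1020  # age 85
    START_AGE = 18
    END_AGE = 85
    N_CYCLES = END_MONTH - START_MONTH  # 804 monthly cycles

    @staticmethod
    def month_to_age(month: int) -> float:
        return month / 12.0

    @staticmethod
    def age_to_month(age_years: float) -> int:
        month = round(age_years * 12)
        if abs(month - age_years * 12) > 1e-9:
            raise ValueError(f"age {age_years} is not a whole number of months")
        return int(month)

    @classmethod
    def cycle_months(cls):
        """Start months of the 804 simulated cycles (216..1019)."""
        import numpy as np

        return np.arange(cls.START_MONTH, cls.END_MONTH)
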