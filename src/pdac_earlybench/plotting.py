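"""Convenience plots: fit curves, sojourn profiles, benefit-vs-lead curves.

All figures are regenerable from the tidy tables the pipeline writes;
nothing here feeds back into the analysis.
"""

from __future__ import annotations

import numpy as np


def plot_fit(schedule, targets, ax=None):
    """Model incidence/mortality curves against their targets."""
    import matplotlib.pyplot as plt

    from .cohort import cohort_project

    if ax is None:
        _, ax = plt.subplots()
    proj = cohort_project(schedule)
    ages = targets.ages_years
    for s in range(4):
        (line,) = ax.plot(ages, targets.incidence_per_100k[:, s], ".", ms=3,
                          label=f"stage {'I' * (s + 1) if s < 3 else 'IV'} target")
        ax.plot(ages, proj.incidence_per_100k[:, s], "-", color=line.get_color())
    ax.plot(ages, targets.mortality_per_100k, "k.", ms=3, label="mortality target")
    ax.plot(ages, proj.mortality_per_100k, "k-")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("rate per 100,000")
    ax.legend(fontsize=7)
    return ax


def plot_sojourn_profiles(schedules: dict, ax=None):
    """Age-dependent mean sojourn trendline per model variant."""
    import matplotlib.pyplot as plt

    from .sojourn import sojourn_profile

    if ax is None:
        _, ax = plt.subplots()
    for label, sched in schedules.items():
        prof = sojourn_profile(sched)
        ax.plot(prof.ages_years, prof.mfpt_months, label=label)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("mean sojourn time (months)")
    ax.legend()
    return ax


def plot_benefit(benefit_tables: dict, value="mean_lyg_years", ax=None):
    """Benefit vs lead interval with CI bands, one curve per variant."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, tbl in benefit_tables.items():
        tbl = tbl.sort_values("x")
        x = tbl["x"] / 12.0
        (line,) = ax.plot(x, tbl[value], "-o", ms=3, label=label)
        if {"ci_low_years", "ci_high_years"} <= set(tbl.columns) and value == "mean_lyg_years":
            ax.fill_between(x, tbl["ci_low_years"], tbl["ci_high_years"],
                            alpha=0.2, color=line.get_color())
    ax.set_xlabel("intervention lead (years before clinical diagnosis)")
    ax.set_ylabel(value.replace("_", " "))
    ax.legend()
    return ax


def plot_sojourn_histogram(sojourn_months: np.ndarray, ax=None, **kwargs):
    """Distribution of individual sojourn times in a simulated cohort."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(sojourn_months, bins=np.arange(0, max(sojourn_months) + 4, 3),
            density=True, **kwargs)
    ax.set_xlabel("sojourn time (months)")
    ax.set_ylabel("density")
    return ax
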