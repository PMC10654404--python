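"""Model / Results facade over the calibration and simulation machinery.

``NaturalHistoryModel`` holds the calibration inputs (target curves,
life table, stage-specific survival) and a calibration configuration;
``fit()`` runs the sequential annealing procedure and returns a
``NaturalHistoryResults`` carrying one fitted variant per requested
mean sojourn time, with the usual results-object conveniences:
``summary()``, per-variant diagnostics, ``simulate()`` and the
counterfactual analysis.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .calibration import CalibrationConfig, CalibrationResult, sequential_calibrate
from .counterfactual import DEFAULT_X_GRID, benefit_summary, cohort_counterfactual
from .targets import (
    CalibrationTargets,
    LifeTable,
    StageSurvival,
    SyntheticConfig,
    generate_reference_targets,
)

__all__ = ["NaturalHistoryModel", "NaturalHistoryResults"]


class NaturalHistoryModel:
    """PDAC natural-history model specified by its calibration inputs.

    Parameters
    ----------
    targets : CalibrationTargets
        Smoothed stage-specific incidence and PDAC mortality curves.
    life_table : LifeTable
        All-cause monthly death probabilities (fixed hazards).
    stage_survival : StageSurvival
        Stage-specific monthly cancer-death probabilities (fixed).
    config : CalibrationConfig, optional
        Annealing configuration; defaults are desk-scale.
    """

    def __init__(
        self,
        targets: CalibrationTargets,
        life_table: LifeTable,
        stage_survival: StageSurvival,
        config: CalibrationConfig | None = None,
    ):
        self.targets = targets
        self.life_table = life_table
        self.stage_survival = stage_survival
        self.config = config or CalibrationConfig()

    @classmethod
    def from_synthetic(
        cls,
        synth_config: SyntheticConfig | None = None,
        seed: int = 0,
        config: CalibrationConfig | None = None,
    ) -> "NaturalHistoryModel":
        """Build a model on synthetic SEER/CDC-like study inputs."""
        targets, life, surv = generate_reference_targets(synth_config, seed)
        return cls(targets, life, surv, config)

    @classmethod
    def from_csv(
        cls,
        targets_path,
        life_table_path,
        stage_survival_path,
        config: CalibrationConfig | None = None,
    ) -> "NaturalHistoryModel":
        """Build a model from rate files in the documented CSV schemas."""
        return cls(
            CalibrationTargets.from_csv(targets_path),
            LifeTable.from_csv(life_table_path),
            StageSurvival.from_csv(stage_survival_path),
            config,
        )

    def fit(self, sojourn_targets=(120.0, 60.0, 36.0), seed: int | None = None
            ) -> "NaturalHistoryResults":
        """Calibrate one variant per requested mean sojourn time (months).

        ``sojourn_targets`` must be sorted descending; pass a scalar for
        a single variant.  ``seed`` overrides the config seed.
        """
        if np.isscalar(sojourn_targets):
            sojourn_targets = (float(sojourn_targets),)
        cfg = self.config if seed is None else replace(self.config, seed=int(seed))
        fits = sequential_calibrate(
            self.targets, list(sojourn_targets), cfg, self.life_table, self.stage_survival
        )
        return NaturalHistoryResults(self, fits, cfg)


class NaturalHistoryResults:
    """Fitted model variants and the analyses that hang off them."""

    def __init__(self, model: NaturalHistoryModel, fits: dict, config: CalibrationConfig):
        self.model = model
        self.config = config
        self.variants: dict[str, CalibrationResult] = {r.label: r for r in fits.values()}
        self._by_target = fits

    def __getitem__(self, key) -> CalibrationResult:
        if isinstance(key, str):
            return self.variants[key]
        return self._by_target[key]

    @property
    def labels(self) -> list[str]:
        return list(self.variants)

    def summary(self) -> pd.DataFrame:
        """One row per fitted variant: achieved sojourn, fit, convergence."""
        rows = []
        for label, r in self.variants.items():
            rows.append({
                "variant": label,
                "target_sojourn_months": next(
                    t for t, v in self._by_target.items() if v is r
                ),
                "achieved_sojourn_months": r.achieved_sojourn_months,
                "fit_objective": r.objective_total,
                "converged": r.converged,
                "seed": r.seed,
            })
        return pd.DataFrame(rows)

    def simulate(self, n: int, seed: int = 0, label: str | None = None):
        """Microsimulate ``n`` people under one fitted variant."""
        return self._pick(label).simulate(n, seed)

    def counterfactual(
        self, n: int, x_grid=DEFAULT_X_GRID, n_iterations: int = 10,
        seed: int = 0, label: str | None = None,
    ) -> pd.DataFrame:
        """Simulate a population and run the rollback intervention."""
        cohort = self.simulate(n, seed, label)
        return cohort_counterfactual(cohort, x_grid, n_iterations, seed)

    def benefit_table(self, records: pd.DataFrame, grouping: str = "whole") -> pd.DataFrame:
        return benefit_summary(records, grouping)

    def _pick(self, label: str | None) -> CalibrationResult:
        if label is None:
            if len(self.variants) != 1:
                raise ValueError(f"specify a variant label among {self.labels}")
            return next(iter(self.variants.values()))
        return self.variants[label]
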