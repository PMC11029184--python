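"""End-to-end convenience: fit the full scoring system on a cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import CohortTables
from .evaluation import label_observations
from .features import FeatureDef, default_feature_spec, feature_matrix
from .fusion import (
    DEFAULT_BETA_GRID,
    DEFAULT_TMAX_GRID,
    FusionParameters,
    RiskScoreIndex,
    optimize_fusion_params,
)
from .novelty import VitalSignNoveltyDetector, select_normality_training_set
from .static_risk import StaticRiskClassifier


def compound_labels(cohort: CohortTables) -> pd.Series:
    """Episode-level compound outcome (death or readmission), by admission."""
    out = cohort.outcomes_frame().set_index("admission_id")
    return (out["event_type"] != "none").astype(int)


def fit_rsi_system(cohort: CohortTables,
                   feature_spec: list[FeatureDef] | None = None,
                   seed: int = 0,
                   beta_grid=DEFAULT_BETA_GRID,
                   tmax_grid=DEFAULT_TMAX_GRID,
                   tune_horizon_hours: float = 24.0,
                   max_train: int = 10000,
                   ) -> tuple[RiskScoreIndex, pd.DataFrame]:
    """Fit RS1, RS2 and the fusion parameters on one development cohort.

    Returns the composed scoring system and the scored observation
    frame (columns admission_id, obs_time, t, rs1, rs2, rsi).
    """
    feature_spec = feature_spec or default_feature_spec()

    X = feature_matrix(cohort.admissions, feature_spec)
    y = compound_labels(cohort).reindex(X.index).to_numpy()
    rs1_model = StaticRiskClassifier(seed=seed).fit(X, y)

    training = select_normality_training_set(cohort)
    rs2_model = VitalSignNoveltyDetector(seed=seed, max_train=max_train).fit(
        training)

    system = RiskScoreIndex(rs1_model, rs2_model,
                            FusionParameters(), feature_spec)
    scored = system.score_cohort(cohort)
    labelled = label_observations(scored, cohort.outcomes,
                                  tune_horizon_hours)
    usable = ~labelled["censored"].to_numpy()
    params, report = optimize_fusion_params(
        scored[usable], labelled.loc[usable, "label"],
        beta_grid=beta_grid, tmax_grid=tmax_grid, seed=seed)
    system.params = params
    system.tuning_report_ = report
    scored = system.score_cohort(cohort)
    return system, scored
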