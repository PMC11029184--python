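"""The Risk Score Index: time-decaying fusion of RS1 and RS2.

With ``tau = min(t, t_max) / t_max`` for ``t`` hours since ICU
discharge,

    RSI = beta * (1 - tau) * RS1 + tau * RS2

so the static discharge risk dominates immediately after ICU discharge
and the vital-sign novelty score takes over linearly, completely from
``t_max`` onwards (``tau`` clamps at 1; the blend is continuous and
piecewise linear in ``t``).  ``beta >= 0`` adjusts the weight of RS1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CohortTables, ICUAdmissionRecord, MINUTES_PER_HOUR
from .evaluation import auroc
from .features import FeatureDef, feature_matrix
from .novelty import VitalSignNoveltyDetector
from .static_risk import StaticRiskClassifier

# beta bridges the scale gap between the probability-valued static
# score (mean near the event rate, so well below 1) and the
# percentile-calibrated novelty score; its grid therefore reaches well
# above 1
DEFAULT_BETA_GRID = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)
DEFAULT_TMAX_GRID = (24.0, 48.0, 72.0, 96.0, 120.0, 168.0, 336.0)


@dataclass(frozen=True)
class FusionParameters:
    """Blend weight ``beta`` (on RS1) and horizon ``t_max`` in hours."""

    beta: float = 1.0
    t_max: float = 72.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"beta": self.beta, "t_max": self.t_max})
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FusionParameters":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        return cls(beta=payload["beta"], t_max=payload["t_max"])


def compute_rsi(rs1, rs2, t, params: FusionParameters):
    """Evaluate the blend; scalars or aligned arrays."""
    rs1 = np.asarray(rs1, dtype=float)
    rs2 = np.asarray(rs2, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any((rs1 < 0) | (rs1 > 1)) or np.any((rs2 < 0) | (rs2 > 1)):
        raise ValueError("rs1 and rs2 must lie in [0, 1]")
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    tau = np.minimum(t, params.t_max) / params.t_max
    out = params.beta * (1.0 - tau) * rs1 + tau * rs2
    return float(out) if out.ndim == 0 else out


@dataclass
class RiskTrajectory:
    """Per-observation (t, rs1, rs2, rsi) path for one admission."""

    admission_id: str
    frame: pd.DataFrame = field(repr=False)  # columns t, rs1, rs2, rsi

    def __len__(self) -> int:
        return len(self.frame)


class RiskScoreIndex:
    """Composed scoring system: RS1 model + RS2 model + fusion blend."""

    def __init__(self, rs1_model: StaticRiskClassifier,
                 novelty_model: VitalSignNoveltyDetector,
                 params: FusionParameters,
                 feature_spec: list[FeatureDef]):
        self.rs1_model = rs1_model
        self.novelty_model = novelty_model
        self.params = params
        self.feature_spec = feature_spec

    def score_trajectory(self, admission: ICUAdmissionRecord,
                         observations: pd.DataFrame) -> RiskTrajectory:
        """Score every observation set of one admission, time ordered."""
        obs = observations[
            observations["admission_id"] == admission.admission_id
        ].sort_values("obs_time")
        if (obs["obs_time"] < admission.icu_discharge_time).any():
            raise ValueError("observation predates ICU discharge")
        X = feature_matrix([admission], self.feature_spec)
        rs1 = float(self.rs1_model.predict_proba(X)[0, 1])
        if obs.empty:
            frame = pd.DataFrame(columns=["t", "rs1", "rs2", "rsi"])
            return RiskTrajectory(admission.admission_id, frame)
        t = (obs["obs_time"].to_numpy(float)
             - admission.icu_discharge_time) / MINUTES_PER_HOUR
        rs2 = self.novelty_model.transform(obs)
        rsi = compute_rsi(np.full_like(t, rs1), rs2, t, self.params)
        frame = pd.DataFrame({"t": t, "rs1": rs1, "rs2": rs2, "rsi": rsi})
        return RiskTrajectory(admission.admission_id, frame)

    def score_cohort(self, cohort: CohortTables) -> pd.DataFrame:
        """All component scores for every observation set of a cohort."""
        obs = cohort.observations_frame()
        X = feature_matrix(cohort.admissions, self.feature_spec)
        rs1_by_adm = pd.Series(self.rs1_model.predict_proba(X)[:, 1],
                               index=X.index)
        discharge = pd.Series(cohort.discharge_times())
        out = obs[["admission_id", "obs_time"]].copy()
        out["t"] = (obs["obs_time"].to_numpy(float)
                    - discharge.reindex(obs["admission_id"]).to_numpy(float)
                    ) / MINUTES_PER_HOUR
        out["rs1"] = rs1_by_adm.reindex(obs["admission_id"]).to_numpy(float)
        out["rs2"] = self.novelty_model.transform(obs)
        out["rsi"] = compute_rsi(out["rs1"], out["rs2"], out["t"], self.params)
        return out


def _grouped_folds(groups: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Seeded assignment of admissions to folds; no admission spans folds."""
    unique = np.unique(groups)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique.size)
    fold_of_group = {g: perm[i] % n_folds for i, g in enumerate(unique)}
    return np.array([fold_of_group[g] for g in groups])


def optimize_fusion_params(scores: pd.DataFrame, labels,
                           beta_grid=DEFAULT_BETA_GRID,
                           tmax_grid=DEFAULT_TMAX_GRID,
                           cv_folds: int = 5, seed: int = 0,
                           ) -> tuple[FusionParameters, pd.DataFrame]:
    """Grid-search (beta, t_max) by patient-grouped cross-validated AUROC.

    ``scores`` needs columns admission_id, t, rs1, rs2; ``labels`` is the
    aligned binary 24 h compound-outcome label.  Ties are broken toward
    smaller beta, then smaller t_max.  Returns the chosen parameters and
    the full grid report.
    """
    beta_grid = np.asarray(sorted(beta_grid), dtype=float)
    tmax_grid = np.asarray(sorted(tmax_grid), dtype=float)
    if beta_grid.size == 0 or tmax_grid.size == 0:
        raise ValueError("empty parameter grid")
    y = np.asarray(labels, dtype=int)
    folds = _grouped_folds(scores["admission_id"].to_numpy(), cv_folds, seed)
    rs1 = scores["rs1"].to_numpy(float)
    rs2 = scores["rs2"].to_numpy(float)
    t = scores["t"].to_numpy(float)

    report = []
    for beta in beta_grid:
        for t_max in tmax_grid:
            params = FusionParameters(beta=beta, t_max=t_max)
            rsi = compute_rsi(rs1, rs2, t, params)
            fold_scores = []
            for k in range(cv_folds):
                mask = folds == k
                if mask.sum() == 0 or len(np.unique(y[mask])) < 2:
                    continue
                fold_scores.append(auroc(rsi[mask], y[mask]))
            report.append({"beta": beta, "t_max": t_max,
                           "mean_cv_auroc": float(np.mean(fold_scores)),
                           "n_folds_scored": len(fold_scores)})
    report = pd.DataFrame(report)
    best_score = report["mean_cv_auroc"].max()
    ties = report[report["mean_cv_auroc"] >= best_score - 1e-12]
    best = ties.sort_values(["beta", "t_max"]).iloc[0]
    return (FusionParameters(beta=float(best["beta"]),
                             t_max=float(best["t_max"])), report)
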