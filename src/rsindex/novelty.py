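"""One-class model of ward physiological normality (RS2).

The normality model is a product-Gaussian kernel density estimate fitted
to z-normalised vital-sign sets drawn from the calendar day of hospital
discharge of patients who survived without ICU readmission — the most
"normal" ward physiology available.  The novelty of a probe observation
is the negative log density at its normalised vitals; the dynamic risk
score RS2 is the empirical-CDF position of that novelty within the
training novelty distribution, so RS2 lies in [0, 1] and shares a scale
with the probability-valued static score.

Per-channel bandwidths come from Silverman's rule of thumb for a
d-dimensional product kernel, ``h_j = sd_j * (4 / ((d + 2) n)) ** (1 / (d + 4))``.
Missing channels are marginalised out: both kernel and probe drop the
missing dimensions, giving the marginal density of the observed ones.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin

from .datamodel import CohortTables, MINUTES_PER_HOUR, VITAL_CHANNELS

_LOG_2PI = float(np.log(2.0 * np.pi))


def select_normality_training_set(cohort: CohortTables) -> pd.DataFrame:
    """Discharge-day vital-sign sets of event-free admissions.

    Returns the observation sets recorded on the calendar day of
    hospital discharge, restricted to admissions whose episode ended
    without death or ICU readmission.
    """
    obs = cohort.observations_frame()
    out = cohort.outcomes_frame()
    out = out[(out["event_type"] == "none")
              & out["hospital_discharge_time"].notna()]
    day_start = (out["hospital_discharge_time"] // (24 * 60)) * (24 * 60)
    merged = obs.merge(
        pd.DataFrame({"admission_id": out["admission_id"],
                      "day_start": day_start}),
        on="admission_id", how="inner")
    frame = merged[(merged["obs_time"] >= merged["day_start"])
                   & (merged["obs_time"] < merged["day_start"] + 24 * 60)]
    if frame.empty:
        raise ValueError(
            "no discharge-day observations from event-free admissions; "
            "use a larger cohort")
    return frame[["admission_id", "obs_time", *VITAL_CHANNELS]]


def silverman_bandwidths(sds: np.ndarray, n: int) -> np.ndarray:
    d = sds.size
    return sds * (4.0 / ((d + 2.0) * n)) ** (1.0 / (d + 4.0))


class VitalSignNoveltyDetector(BaseEstimator, OutlierMixin):
    """KDE-based one-class scorer over the five continuous vitals.

    Parameters
    ----------
    bandwidth_rule : 'silverman' or callable (sds, n) -> bandwidths
    max_train : training points are capped at this size by seeded
        subsampling to bound scoring cost (default 10000)
    seed : drives the subsampling only; fitting is otherwise exact
    missing_policy : 'marginalise' (default) or 'strict'
    """

    channels = VITAL_CHANNELS

    def __init__(self, bandwidth_rule="silverman", max_train: int = 10000,
                 seed: int = 0, missing_policy: str = "marginalise"):
        self.bandwidth_rule = bandwidth_rule
        self.max_train = max_train
        self.seed = seed
        self.missing_policy = missing_policy

    def fit(self, X, y=None) -> "VitalSignNoveltyDetector":
        X = self._as_matrix(X)
        complete = ~np.isnan(X).any(axis=1)
        X = X[complete]
        if X.shape[0] < 50:
            raise ValueError(
                f"need >=50 complete training vectors, got {X.shape[0]}")
        if X.shape[0] > self.max_train:
            rng = np.random.default_rng(self.seed)
            idx = np.sort(rng.choice(X.shape[0], self.max_train, replace=False))
            X = X[idx]
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=0)
        if np.any(self.sd_ == 0):
            bad = [c for c, s in zip(self.channels, self.sd_) if s == 0]
            raise ValueError(f"zero-variance channel(s): {bad}")
        self.train_ = (X - self.mean_) / self.sd_
        n, d = self.train_.shape
        rule = (silverman_bandwidths if self.bandwidth_rule == "silverman"
                else self.bandwidth_rule)
        self.bandwidths_ = np.asarray(
            rule(self.train_.std(axis=0, ddof=0), n), dtype=float)
        if np.any(self.bandwidths_ <= 0):
            raise ValueError("bandwidths must be strictly positive")
        self.calibration_ = np.sort(self._novelty(self.train_))
        return self

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.channels)]
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.channels):
            raise ValueError(f"expected {len(self.channels)} channels")
        return X

    def _novelty(self, Z: np.ndarray, chunk: int = 4096) -> np.ndarray:
        """-log density at normalised probes Z (NaN = marginalised out)."""
        n = self.train_.shape[0]
        h = self.bandwidths_
        out = np.empty(Z.shape[0])
        # group probes by missingness pattern so each group is one
        # dense vectorised computation over its observed dimensions
        patterns = np.isnan(Z)
        if patterns.any() and self.missing_policy == "strict":
            raise ValueError("missing vitals under missing_policy='strict'")
        if patterns.all(axis=1).any():
            raise ValueError("observation with all vital channels missing")
        codes = patterns @ (1 << np.arange(Z.shape[1]))
        for code in np.unique(codes):
            sel = np.flatnonzero(codes == code)
            obs_dims = np.flatnonzero(~patterns[sel[0]])
            Ts = self.train_[:, obs_dims] / h[obs_dims]
            t_sq = (Ts * Ts).sum(axis=1)
            log_norm = (np.sum(np.log(h[obs_dims]))
                        + 0.5 * obs_dims.size * _LOG_2PI)
            probes = Z[np.ix_(sel, obs_dims)] / h[obs_dims]
            p_sq = (probes * probes).sum(axis=1)
            for start in range(0, sel.size, chunk):
                block = probes[start:start + chunk]
                sq = np.maximum(
                    p_sq[start:start + chunk, None] + t_sq[None, :]
                    - 2.0 * (block @ Ts.T), 0.0)
                logk = -0.5 * sq
                m = logk.max(axis=1)
                lse = m + np.log(np.exp(logk - m[:, None]).sum(axis=1))
                out[sel[start:start + chunk]] = -lse + np.log(n) + log_norm
        return out

    def normalise(self, X) -> np.ndarray:
        X = self._as_matrix(X)
        return (X - self.mean_) / self.sd_

    def score_samples(self, X) -> np.ndarray:
        """Novelty (-log density); higher = more abnormal."""
        return self._novelty(self.normalise(X))

    def transform(self, X) -> np.ndarray:
        """RS2: empirical-CDF position of the novelty, in [0, 1]."""
        return self.rs2_from_novelty(self.score_samples(X))

    def rs2_from_novelty(self, novelty: np.ndarray) -> np.ndarray:
        cal = self.calibration_
        n = cal.size
        left = np.searchsorted(cal, novelty, side="left")
        right = np.searchsorted(cal, novelty, side="right")
        # midpoint convention for ties
        return np.clip((left + 0.5 * (right - left)) / n, 0.0, 1.0)

    # -- persistence ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "channels": list(self.channels),
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "bandwidths": self.bandwidths_.tolist(),
            "train": self.train_.tolist(),
            "calibration": self.calibration_.tolist(),
            "missing_policy": self.missing_policy,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "VitalSignNoveltyDetector":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        model = cls(missing_policy=payload["missing_policy"])
        model.mean_ = np.asarray(payload["mean"])
        model.sd_ = np.asarray(payload["sd"])
        model.bandwidths_ = np.asarray(payload["bandwidths"])
        model.train_ = np.asarray(payload["train"])
        model.calibration_ = np.asarray(payload["calibration"])
        return model


# -- thin functional wrappers -----------------------------------------

def fit_normality_model(training: pd.DataFrame | np.ndarray,
                        bandwidth_rule="silverman",
                        seed: int = 0, max_train: int = 10000,
                        ) -> VitalSignNoveltyDetector:
    return VitalSignNoveltyDetector(
        bandwidth_rule=bandwidth_rule, seed=seed, max_train=max_train).fit(training)


def novelty_value(model: VitalSignNoveltyDetector, obs,
                  missing_policy: str | None = None) -> float | np.ndarray:
    if missing_policy is not None and missing_policy != model.missing_policy:
        import copy

        model = copy.copy(model)
        model.missing_policy = missing_policy
    values = model.score_samples(_obs_to_row(obs, model))
    return float(values[0]) if values.size == 1 else values


def rs2_score(model: VitalSignNoveltyDetector, obs) -> float | np.ndarray:
    values = model.transform(_obs_to_row(obs, model))
    return float(values[0]) if values.size == 1 else values


def _obs_to_row(obs, model):
    from .datamodel import WardObservationSet

    if isinstance(obs, WardObservationSet):
        return np.array([[np.nan if v is None else v
                          for v in obs.vitals().values()]])
    return obs
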