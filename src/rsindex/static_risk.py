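"""The static ICU-discharge risk model (RS1).

An L1-regularised logistic regression on the ICU-stay feature matrix,
predicting the compound outcome (in-hospital death or ICU readmission at
any point after ICU discharge).  Preprocessing is part of the model:
training-median imputation of missing values followed by per-feature
z-scoring; apply mode reuses the stored training parameters only.

The regularisation strength ``lambda`` (inverse of sklearn's ``C``) is
chosen by maximising mean stratified cross-validated AUROC over a
log-spaced grid whose largest value yields the null (all-zero) model;
the final model is refitted on all data at the chosen strength.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import ICUFeatureVector

# large intercept_scaling makes liblinear's intercept effectively
# unpenalised, so the L1 limit is the empirical-log-odds null model
_INTERCEPT_SCALING = 100.0


def _intercept_mle(offset: np.ndarray, y: np.ndarray, b0: float) -> float:
    """Newton solve of the one-parameter logistic MLE given an offset."""
    b = b0
    for _ in range(100):
        p = 1.0 / (1.0 + np.exp(-(b + offset)))
        grad = float((p - y).mean())
        hess = float((p * (1.0 - p)).mean())
        if hess <= 0:
            break
        step = grad / hess
        b -= step
        if abs(step) < 1e-12:
            break
    return float(b)


def default_lambda_grid(n_values: int = 30, decades: float = 4.0) -> np.ndarray:
    """Relative log-spaced grid; scaled to the data's null point at fit."""
    return np.logspace(0.0, -decades, n_values)


class StaticRiskClassifier(BaseEstimator, ClassifierMixin):
    """L1-logistic compound-outcome risk at ICU discharge.

    Parameters
    ----------
    lambda_grid : array-like or None
        Relative regularisation grid (descending, starting at 1).  The
        grid is multiplied by the data-derived ``lambda_max`` — the
        smallest strength at which every coefficient is zero — so its
        largest value always yields the null model.
    cv_folds : int
        Stratified folds for the AUROC model-selection criterion.
    seed : int
        Seeds the fold assignment; fitting is deterministic given it.
    add_missing_indicators : bool
        Append a 0/1 missingness column per feature that has gaps.
    """

    def __init__(self, lambda_grid=None, cv_folds: int = 5, seed: int = 0,
                 add_missing_indicators: bool = False):
        self.lambda_grid = lambda_grid
        self.cv_folds = cv_folds
        self.seed = seed
        self.add_missing_indicators = add_missing_indicators

    # -- preprocessing -------------------------------------------------
    def _prepare_fit(self, X: pd.DataFrame) -> np.ndarray:
        medians = X.median(axis=0, skipna=True)
        dropped = [c for c in X.columns if not np.isfinite(medians[c])]
        if dropped:
            warnings.warn(f"dropping all-missing features: {dropped}")
        keep = [c for c in X.columns if c not in dropped]
        Xi = X[keep].fillna(medians[keep])
        sds = Xi.std(axis=0, ddof=0)
        zero_var = [c for c in keep if sds[c] == 0 or not np.isfinite(sds[c])]
        if zero_var:
            warnings.warn(f"dropping zero-variance features: {zero_var}")
            keep = [c for c in keep if c not in zero_var]
            Xi = Xi[keep]
        self.feature_names_ = list(keep)
        self.dropped_features_ = dropped + zero_var
        self.imputation_values_ = medians[keep].to_dict()
        self.means_ = Xi.mean(axis=0).to_dict()
        self.sds_ = Xi.std(axis=0, ddof=0).to_dict()
        if self.add_missing_indicators:
            self.indicator_features_ = [
                c for c in keep if X[c].isna().any()
            ]
        else:
            self.indicator_features_ = []
        return self._transform(X)

    def _transform(self, X: pd.DataFrame) -> np.ndarray:
        cols = []
        for c in self.feature_names_:
            col = pd.to_numeric(X[c], errors="coerce") if c in X else pd.Series(
                np.nan, index=X.index)
            col = col.fillna(self.imputation_values_[c])
            cols.append((col - self.means_[c]) / self.sds_[c])
        Z = np.column_stack(cols) if cols else np.empty((len(X), 0))
        if self.indicator_features_:
            ind = np.column_stack(
                [X[c].isna().astype(float) if c in X else np.ones(len(X))
                 for c in self.indicator_features_])
            Z = np.hstack([Z, ind])
        return Z

    # -- fitting -------------------------------------------------------
    def fit(self, X: pd.DataFrame, y) -> "StaticRiskClassifier":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("labels are degenerate: only one class present")
        if (y == 1).sum() < 2 or (y == 0).sum() < 2:
            raise ValueError("need at least 2 events and 2 non-events")
        Z = self._prepare_fit(X)

        # smallest lambda at which the L1 solution is exactly null
        n = len(y)
        lam_max = np.abs(Z.T @ (y - y.mean())).max() / n
        lam_max = max(lam_max, 1e-12)
        rel = (np.asarray(self.lambda_grid, dtype=float)
               if self.lambda_grid is not None else default_lambda_grid())
        grid = np.sort(lam_max * 1.05 * rel)[::-1]

        skf = StratifiedKFold(n_splits=self.cv_folds, shuffle=True,
                              random_state=self.seed)
        folds = list(skf.split(Z, y))
        mean_scores = np.full(grid.size, np.nan)
        for i, lam in enumerate(grid):
            scores = []
            for tr, te in folds:
                clf = self._make_clf(lam, n_train=len(tr))
                clf.fit(Z[tr], y[tr])
                p = clf.decision_function(Z[te])
                scores.append(roc_auc_score(y[te], p))
            mean_scores[i] = float(np.mean(scores))
        best = int(np.nanargmax(mean_scores))
        self.lambda_ = float(grid[best])
        self.cv_report_ = pd.DataFrame(
            {"lambda": grid, "mean_cv_auroc": mean_scores})

        final = self._make_clf(self.lambda_, n_train=n)
        final.fit(Z, y)
        self.classes_ = final.classes_
        coef = final.coef_.ravel()
        # the intercept is unpenalised in the model; refine it to its
        # exact conditional MLE given the coefficients, so the L1 limit
        # is the empirical-log-odds null model
        self.intercept_ = _intercept_mle(Z @ coef, y, float(final.intercept_[0]))
        names = self.feature_names_ + [f"{c}__missing"
                                       for c in self.indicator_features_]
        self.coef_ = coef
        self.coefficients_ = {nm: float(w) for nm, w in zip(names, coef)
                              if w != 0.0}
        self.n_retained_ = len(self.coefficients_)
        self.metadata_ = {"seed": self.seed, "cv_folds": self.cv_folds,
                          "lambda": self.lambda_, "n_train": n}
        return self

    def _make_clf(self, lam: float, n_train: int) -> LogisticRegression:
        # sklearn objective: ||w||_1 + C * sum(loss); our lambda is the
        # penalty per sample, so C = 1 / (n * lambda)
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=1.0 / (n_train * lam),
            intercept_scaling=_INTERCEPT_SCALING, max_iter=2000, tol=1e-5,
            random_state=self.seed)

    # -- prediction ----------------------------------------------------
    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        Z = self._transform(pd.DataFrame(X))
        return self.intercept_ + Z @ self.coef_

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    # -- persistence ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "intercept": self.intercept_,
            "coefficients": self.coefficients_,
            "lambda": self.lambda_,
            "feature_names": self.feature_names_,
            "indicator_features": self.indicator_features_,
            "imputation_values": self.imputation_values_,
            "means": self.means_,
            "sds": self.sds_,
            "metadata": self.metadata_,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StaticRiskClassifier":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        model = cls()
        model.intercept_ = payload["intercept"]
        model.coefficients_ = payload["coefficients"]
        model.lambda_ = payload["lambda"]
        model.feature_names_ = payload["feature_names"]
        model.indicator_features_ = payload["indicator_features"]
        model.imputation_values_ = payload["imputation_values"]
        model.means_ = payload["means"]
        model.sds_ = payload["sds"]
        model.metadata_ = payload["metadata"]
        names = model.feature_names_ + [f"{c}__missing"
                                        for c in model.indicator_features_]
        model.coef_ = np.array([model.coefficients_.get(nm, 0.0)
                                for nm in names])
        model.dropped_features_ = []
        model.classes_ = np.array([0, 1])
        return model


# -- thin functional wrappers -----------------------------------------

def impute_and_standardise(X: pd.DataFrame, model: StaticRiskClassifier | None
                           = None) -> tuple[np.ndarray, StaticRiskClassifier]:
    """Fit (or apply, given a fitted model) the preprocessing alone."""
    if model is None:
        model = StaticRiskClassifier()
        Z = model._prepare_fit(pd.DataFrame(X))
    else:
        Z = model._transform(pd.DataFrame(X))
    return Z, model


def fit_rs1(X: pd.DataFrame, y, lambda_grid=None, cv_folds: int = 5,
            seed: int = 0) -> StaticRiskClassifier:
    return StaticRiskClassifier(lambda_grid=lambda_grid, cv_folds=cv_folds,
                                seed=seed).fit(X, y)


def predict_rs1(model: StaticRiskClassifier,
                features: ICUFeatureVector | pd.DataFrame) -> np.ndarray:
    if isinstance(features, ICUFeatureVector):
        features = features.to_series().to_frame().T
    return model.predict_proba(pd.DataFrame(features))[:, 1]
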