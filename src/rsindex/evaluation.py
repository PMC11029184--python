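"""Observation-level validation framework.

The unit of analysis is a vital-sign observation set.  Each set is
labelled positive when the admission's first adverse event (in-hospital
death or ICU readmission, or either alone) occurs within the next N
hours, censored at/after the event, and negative otherwise, for
N in {12, 24, 36, 48, 72} hours.  Discrimination is AUROC in the
Mann-Whitney rank formulation; uncertainty comes from a percentile
bootstrap over admissions (patients, not observation sets, are
resampled, respecting within-patient correlation); calibration is
Hosmer-Lemeshow C over risk deciles, the Brier score and Cox's
calibration regression (intercept alpha near 0 and slope beta near 1
indicate good calibration); clinical workload is the trigger-burden
curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .datamodel import CohortTables, MINUTES_PER_HOUR, OutcomeRecord

HORIZONS = (12.0, 24.0, 36.0, 48.0, 72.0)

ENDPOINTS = ("compound", "death", "readmission")


def label_observations(observations: pd.DataFrame,
                       outcomes: Sequence[OutcomeRecord] | pd.DataFrame,
                       n_hours: float,
                       endpoint: str = "compound",
                       censor_near_discharge: bool = False) -> pd.DataFrame:
    """Attach the N-hour outcome label to each observation set.

    Returns a copy of ``observations`` with ``label`` (0/1) and
    ``censored`` columns.  An observation is positive iff the
    admission's first event of the chosen endpoint falls in
    ``(obs_time, obs_time + N]``; observations at or after the event are
    censored.  With ``censor_near_discharge``, event-free observations
    within N hours of hospital discharge are censored instead of
    negative.
    """
    if n_hours <= 0:
        raise ValueError("N must be positive")
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if not isinstance(outcomes, pd.DataFrame):
        outcomes = pd.DataFrame(
            [{"admission_id": o.admission_id, "event_type": o.event_type,
              "event_time": o.event_time,
              "hospital_discharge_time": o.hospital_discharge_time}
             for o in outcomes])
    out = observations.copy()
    idx = outcomes.set_index("admission_id")
    event_time = idx["event_time"].reindex(out["admission_id"]).to_numpy(float)
    event_type = idx["event_type"].reindex(out["admission_id"]).to_numpy(object)
    hosp = idx["hospital_discharge_time"].reindex(
        out["admission_id"]).to_numpy(float)
    obs_time = out["obs_time"].to_numpy(float)
    window = n_hours * MINUTES_PER_HOUR

    matches = (event_type == "death") | (event_type == "readmission") \
        if endpoint == "compound" else (event_type == endpoint)
    has_any_event = ~np.isnan(event_time)
    delta = event_time - obs_time

    # censor at/after the first adverse event of ANY type
    censored = has_any_event & (delta <= 0)
    label = (matches & ~np.isnan(delta) & (delta > 0)
             & (delta <= window)).astype(int)
    if censor_near_discharge:
        near = (~has_any_event) & ~np.isnan(hosp) \
            & (hosp - obs_time <= window)
        censored = censored | near
    label[censored] = 0
    out["label"] = label
    out["censored"] = censored
    out["horizon_n"] = n_hours
    return out


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def bootstrap_ci(metric_fn: Callable[[pd.DataFrame], float],
                 data: pd.DataFrame, b_resamples: int = 500,
                 seed: int = 0, group_col: str = "admission_id",
                 max_undefined_frac: float = 0.10,
                 ) -> tuple[float, float]:
    """Percentile bootstrap CI over admissions.

    Resamples whole admissions with replacement ``b_resamples`` times
    (default 500), applies ``metric_fn`` to each resampled frame and
    returns the 2.5/97.5 percentiles.  Resamples on which the metric is
    undefined are skipped; more than ``max_undefined_frac`` of them is
    an error.
    """
    if b_resamples < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    rng = np.random.default_rng(seed)
    groups = data[group_col].to_numpy()
    unique = np.unique(groups)
    indices = {g: np.flatnonzero(groups == g) for g in unique}
    values = []
    n_undefined = 0
    for _ in range(b_resamples):
        chosen = rng.choice(unique, size=unique.size, replace=True)
        rows = np.concatenate([indices[g] for g in chosen])
        try:
            values.append(float(metric_fn(data.iloc[rows])))
        except ValueError:
            n_undefined += 1
    if n_undefined > max_undefined_frac * b_resamples:
        raise ValueError(
            f"metric undefined on {n_undefined}/{b_resamples} resamples")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def calibration_report(probabilities, labels, n_groups: int = 10,
                       ) -> dict[str, float]:
    """Hosmer-Lemeshow C, Brier score and Cox calibration regression.

    HL-C groups by equal-count deciles of predicted risk (stable sort)
    and sums ``(O - E)^2 / (E * (1 - pbar))`` over groups; groups whose
    expected count is zero are merged into their neighbour.  The Cox
    regression refits the labels on ``logit(p)`` by unpenalised maximum
    likelihood; ``alpha`` is the intercept and ``beta`` the slope.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.any((p <= 0) | (p >= 1)):
        p = np.clip(p, 1e-6, 1 - 1e-6)
    order = np.argsort(p, kind="stable")
    edges = np.linspace(0, p.size, n_groups + 1).astype(int)
    groups = [(order[a:b]) for a, b in zip(edges, edges[1:]) if b > a]
    # merge groups with zero expected events into the next one
    merged: list[np.ndarray] = []
    carry: np.ndarray | None = None
    for g in groups:
        if carry is not None:
            g = np.concatenate([carry, g])
            carry = None
        if p[g].sum() < 1e-2:  # (near-)zero expected events
            warnings.warn("merging risk group with zero expected events")
            carry = g
            continue
        merged.append(g)
    if carry is not None and merged:
        merged[-1] = np.concatenate([merged[-1], carry])
    hl = 0.0
    for g in merged:
        obs = y[g].sum()
        exp = p[g].sum()
        pbar = p[g].mean()
        hl += (obs - exp) ** 2 / (exp * (1.0 - pbar))
    brier = float(np.mean((p - y) ** 2))
    logit_p = np.log(p / (1.0 - p))
    if np.std(logit_p) < 1e-12:
        # constant predictor: the slope is unidentified
        alpha = float(np.log(y.mean() / (1 - y.mean()))) - float(logit_p[0])
        beta = np.nan
    else:
        fit = sm.Logit(y, sm.add_constant(logit_p)).fit(disp=0)
        alpha, beta = float(fit.params[0]), float(fit.params[1])
    return {
        "hosmer_lemeshow_c": float(hl),
        "brier": brier,
        "cox_alpha": alpha,
        "cox_beta": beta,
    }


def trigger_burden(scores, labels, thresholds) -> pd.DataFrame:
    """Triggered observation sets per correctly identified pre-event set.

    Per threshold: ``triggers`` = sets scoring at or above it, ``tp`` =
    triggered sets labelled positive, ``burden`` = triggers/tp (infinity
    when no true positive, flagged in ``undefined``).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    rows = []
    for thr in thresholds:
        fired = scores >= thr
        triggers = int(fired.sum())
        tp = int((fired & (y == 1)).sum())
        rows.append({
            "threshold": thr,
            "triggers": triggers,
            "true_positive_triggers": tp,
            "burden": (triggers / tp) if tp else np.inf,
            "undefined": tp == 0,
        })
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Windowed discrimination, calibration and burden for one system."""

    system: str
    discrimination: pd.DataFrame  # per horizon: auroc, ci_low, ci_high, n...
    calibration: dict[str, float] = field(default_factory=dict)
    burden: pd.DataFrame | None = None


def evaluate_scores(scored: pd.DataFrame,
                    outcomes: Sequence[OutcomeRecord] | pd.DataFrame,
                    score_col: str,
                    horizons: Sequence[float] = HORIZONS,
                    endpoint: str = "compound",
                    b_resamples: int = 500,
                    seed: int = 0,
                    with_ci: bool = True) -> pd.DataFrame:
    """AUROC (with bootstrap CI) of one score column per horizon."""
    rows = []
    for n_hours in horizons:
        lab = label_observations(scored, outcomes, n_hours, endpoint)
        lab = lab[~lab["censored"]]
        point = auroc(lab[score_col], lab["label"])
        row = {"horizon": n_hours, "endpoint": endpoint,
               "auroc": point, "n_obs": len(lab),
               "n_pos": int(lab["label"].sum()),
               "label_checksum": int(
                   pd.util.hash_pandas_object(
                       lab[["admission_id", "obs_time", "label"]]
                       .reset_index(drop=True)).sum() & 0xFFFFFFFF)}
        if with_ci:
            lo, hi = bootstrap_ci(
                lambda d: auroc(d[score_col], d["label"]), lab,
                b_resamples=b_resamples, seed=seed)
            row["ci_low"], row["ci_high"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def compare_systems(scored: pd.DataFrame,
                    outcomes: Sequence[OutcomeRecord] | pd.DataFrame,
                    systems: Mapping[str, str],
                    horizons: Sequence[float] = HORIZONS,
                    endpoints: Sequence[str] = ENDPOINTS,
                    b_resamples: int = 500,
                    seed: int = 0,
                    with_ci: bool = True) -> pd.DataFrame:
    """AUROC comparison table across scoring systems.

    ``systems`` maps a display name to a score column of ``scored``.
    Every system is evaluated on identical labelled observation sets;
    the shared ``label_checksum`` column is the audit trail of that.
    """
    tables = []
    for endpoint in endpoints:
        for name, col in systems.items():
            tab = evaluate_scores(scored, outcomes, col, horizons, endpoint,
                                  b_resamples, seed, with_ci)
            tab.insert(0, "system", name)
            tables.append(tab)
    return pd.concat(tables, ignore_index=True)
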