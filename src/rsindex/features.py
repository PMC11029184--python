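"""ICU-stay feature derivation for the static discharge risk model.

A *feature spec* is a list of ``{name, channel, operator, window_hours}``
entries.  Operators summarise a time-varying channel over a trailing
window ending at ICU discharge (``window_hours=None`` means the whole
stay):

``last / min / max / mean / sd``
    the obvious summaries of the channel values in the window
``slope``
    least-squares slope per hour of value against time
``present``
    1.0 if an intervention channel is "on" at any point in the window
    (interval semantics: a sample with value>0 keeps the intervention on
    until the next sample), else 0.0
``count``
    number of samples in the window
``static``
    value of a static variable (``age`` and ``sex`` resolve to the
    admission fields; anything else to ``static_vars``)

The default spec (161 features) spans ward-style physiology, renal and
hepatic chemistry, electrolytes, inflammation markers and treatment
intensity over the channels the synthetic cohort generator emits; it is
a plain data structure and fully user-replaceable via YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import ICUAdmissionRecord, MINUTES_PER_HOUR

OPERATORS = ("last", "min", "max", "mean", "sd", "slope", "present",
             "count", "static")


@dataclass(frozen=True)
class FeatureDef:
    name: str
    channel: str
    operator: str
    window_hours: float | None = None

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")


@dataclass
class ICUFeatureVector:
    """Ordered named features for one admission, with provenance."""

    admission_id: str
    values: dict[str, float | None]
    provenance: dict[str, FeatureDef] = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {k: (np.nan if v is None else v) for k, v in self.values.items()},
            dtype=float, name=self.admission_id,
        )


def _summarise(operator: str, t_hours: np.ndarray, values: np.ndarray,
               window_end: float) -> float | None:
    if operator == "count":
        return float(values.size)
    if values.size == 0:
        return None if operator != "present" else None
    if operator == "last":
        return float(values[-1])
    if operator == "min":
        return float(values.min())
    if operator == "max":
        return float(values.max())
    if operator == "mean":
        return float(values.mean())
    if operator == "sd":
        return float(values.std(ddof=0))
    if operator == "slope":
        if values.size < 2 or np.ptp(t_hours) == 0:
            return 0.0
        return float(np.polyfit(t_hours, values, 1)[0])
    raise AssertionError(operator)


def extract_features(admission: ICUAdmissionRecord,
                     feature_spec: list[FeatureDef]) -> ICUFeatureVector:
    """Derive one value (or missing flag) per spec entry."""
    discharge_h = admission.icu_discharge_time / MINUTES_PER_HOUR
    admit_h = admission.icu_admit_time / MINUTES_PER_HOUR
    values: dict[str, float | None] = {}
    provenance: dict[str, FeatureDef] = {}
    for fd in feature_spec:
        provenance[fd.name] = fd
        if fd.operator == "static":
            if fd.channel == "age":
                values[fd.name] = float(admission.age)
            elif fd.channel == "sex":
                values[fd.name] = 1.0 if admission.sex in ("M", "male", "m") else 0.0
            elif fd.channel == "icu_los_hours":
                values[fd.name] = discharge_h - admit_h
            elif fd.channel in admission.static_vars:
                values[fd.name] = float(admission.static_vars[fd.channel])
            else:
                values[fd.name] = None
            continue
        if fd.channel not in admission.channels:
            raise KeyError(
                f"feature {fd.name!r} references unknown channel {fd.channel!r}"
            )
        times, chan_values = admission.channels[fd.channel]
        t_hours = np.asarray(times, dtype=float) / MINUTES_PER_HOUR
        window_start = admit_h if fd.window_hours is None else max(
            admit_h, discharge_h - fd.window_hours)
        if fd.operator == "present":
            # interval semantics: the last sample at or before window start
            # also determines the state inside the window
            on = False
            in_window = (t_hours >= window_start)
            if np.any(chan_values[in_window] > 0):
                on = True
            before = np.flatnonzero(t_hours < window_start)
            if before.size and chan_values[before[-1]] > 0:
                on = True
            values[fd.name] = 1.0 if on else 0.0
            continue
        mask = t_hours >= window_start
        values[fd.name] = _summarise(
            fd.operator, t_hours[mask] - discharge_h, np.asarray(
                chan_values, dtype=float)[mask], discharge_h)
    return ICUFeatureVector(admission.admission_id, values, provenance)


def feature_matrix(admissions, feature_spec: list[FeatureDef]) -> pd.DataFrame:
    """Stack per-admission feature vectors into a design DataFrame."""
    rows = [extract_features(a, feature_spec).to_series() for a in admissions]
    df = pd.DataFrame(rows)
    df.index.name = "admission_id"
    return df[[fd.name for fd in feature_spec]]


_VITALS = ("heart_rate", "systolic_bp", "resp_rate", "temperature", "spo2")
_LABS = ("sodium", "potassium", "creatinine", "urea", "bilirubin", "albumin",
         "lactate", "haemoglobin", "wbc", "crp", "platelets", "glucose")
_INTERVENTIONS = ("ventilation", "vasopressor", "dialysis")


def default_feature_spec() -> list[FeatureDef]:
    """161 candidate features over the synthetic generator's channels."""
    spec: list[FeatureDef] = []
    for v in _VITALS:
        for op in ("last", "min", "max", "mean", "sd", "slope"):
            spec.append(FeatureDef(f"{v}_{op}_last24h", v, op, 24.0))
        for op in ("min", "max", "mean", "slope"):
            spec.append(FeatureDef(f"{v}_{op}_stay", v, op, None))
    for lab in _LABS:
        # labs are sampled roughly daily, so spread (sd) and trend
        # (slope) are summarised over the whole stay
        for op in ("last", "min", "max", "mean"):
            spec.append(FeatureDef(f"{lab}_{op}_last24h", lab, op, 24.0))
        for op in ("min", "max", "sd", "slope"):
            spec.append(FeatureDef(f"{lab}_{op}_stay", lab, op, None))
    for iv in _INTERVENTIONS:
        spec.append(FeatureDef(f"{iv}_last24h", iv, "present", 24.0))
        spec.append(FeatureDef(f"{iv}_stay", iv, "present", None))
    spec.append(FeatureDef("n_obs_last24h", "heart_rate", "count", 24.0))
    for name in ("age", "sex", "icu_los_hours", "elective_admission",
                 "apache_score", "weight", "surgical_admission",
                 "prior_icu_admissions"):
        spec.append(FeatureDef(name, name, "static"))
    assert len(spec) == 161
    return spec


def load_feature_spec(path: str | Path) -> list[FeatureDef]:
    raw = yaml.safe_load(Path(path).read_text())
    return [
        FeatureDef(r["name"], r["channel"], r["operator"],
                   r.get("window_hours"))
        for r in raw
    ]


def save_feature_spec(spec: list[FeatureDef], path: str | Path) -> None:
    rows = [
        {"name": fd.name, "channel": fd.channel, "operator": fd.operator,
         "window_hours": fd.window_hours}
        for fd in spec
    ]
    Path(path).write_text(yaml.safe_dump(rows, sort_keys=False))
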