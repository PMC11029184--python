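"""Seeded synthetic post-ICU cohort generator.

Emulates the study conditions the scoring system assumes: ICU
admissions with static fields and time-varying channels (ward-style
physiology, labs, interventions), ward vital-sign sets every 4-6 hours
for up to 14 days after ICU discharge, and first-event outcomes with
adverse-event rates near the post-ICU development subgroup (ICU
readmission 6.6%, in-hospital death 2.2%).

Generative structure
--------------------
* Each admission carries a latent severity ``z ~ N(0, 1)``; elective
  surgical admissions (ventilated until shortly before discharge) get a
  downward severity shift.  The event probability is a logistic link
  ``p = sigmoid(alpha + slope * z_eff)`` with ``alpha`` solved so the
  cohort event rate matches the configured rates exactly in
  expectation; the event type splits death/readmission at the
  configured ratio and the event time is uniform over the ward episode
  (within the 14-day follow-up).
* ICU channels load on ``z`` (the planted effects recorded in the
  ground truth), so last-24 h summaries are informative for the static
  risk model.
* Ward vitals are patient-level Gaussian baselines (population means
  near textbook normals, mildly loaded on ``z``) plus AR(1) noise,
  rounded to chart precision.  Deterioration is imposed retrospectively
  on event admissions: a linear drift (HR and RR up, SBP and SpO2 down,
  temperature up) from ``lead_hours`` before the event until the event,
  with AVPU dropping from Alert and supplemental oxygen becoming more
  likely as the drift progresses.  Pre-onset observations are
  bit-identical to the event-free counterfactual under a shared seed.
* Observation sets stop at the first adverse event (death ends the
  episode; readmission moves the patient back to the ICU).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.special import expit

from .datamodel import (
    CohortTables,
    ICUAdmissionRecord,
    MINUTES_PER_HOUR,
    OutcomeRecord,
    VITAL_BOUNDS,
    WardObservationSet,
)

_DAY_MIN = 24 * 60

# ward vital-sign population model: baseline mean, z-loading,
# between-patient sd, AR(1) innovation sd, rounding step
_WARD_MODEL = {
    "heart_rate": (76.0, 3.0, 7.0, 5.0, 1.0),
    "systolic_bp": (122.0, -4.0, 10.0, 8.0, 1.0),
    "resp_rate": (16.0, 1.0, 1.6, 1.5, 1.0),
    "temperature": (36.8, 0.08, 0.25, 0.22, 0.1),
    "spo2": (96.8, -0.5, 1.0, 1.0, 1.0),
}
_WARD_AR1_RHO = 0.5

# ICU vital channels: mean, z-loading, AR(1) sd; sampled hourly
_ICU_VITALS = {
    "heart_rate": (85.0, 7.0, 6.0),
    "systolic_bp": (118.0, -9.0, 9.0),
    "resp_rate": (17.0, 2.8, 2.0),
    "temperature": (37.1, 0.3, 0.3),
    "spo2": (96.5, -1.3, 1.3),
}
_ICU_AR1_RHO = 0.8

# labs: (base, z-loading, noise sd, lognormal?)  sampled ~daily
_ICU_LABS = {
    "sodium": (139.0, -0.5, 3.0, False),
    "potassium": (4.2, 0.15, 0.4, False),
    "creatinine": (85.0, 0.30, 0.25, True),
    "urea": (6.5, 0.35, 0.30, True),
    "bilirubin": (12.0, 0.30, 0.35, True),
    "albumin": (32.0, -2.2, 4.0, False),
    "lactate": (1.3, 0.35, 0.30, True),
    "haemoglobin": (105.0, -3.0, 12.0, False),
    "wbc": (10.0, 0.20, 0.25, True),
    "crp": (60.0, 0.40, 0.50, True),
    "platelets": (220.0, -0.15, 0.25, True),
    "glucose": (7.5, 0.15, 0.20, True),
}


@dataclass(frozen=True)
class DeteriorationConfig:
    """Linear pre-event drift of ward vitals.

    Deterioration usually — but not always clearly — precedes an
    adverse event: per event the onset lead is drawn uniformly from
    ``lead_hours_range`` and the drift magnitudes are scaled by a
    severity factor drawn from ``severity_range``, so some events have
    long florid prodromes and others are near-sudden.  ``lead_hours``
    is the fixed lead used when a single trajectory is transformed
    directly.
    """

    lead_hours: float = 24.0
    lead_hours_range: tuple[float, float] = (4.0, 44.0)
    severity_range: tuple[float, float] = (0.3, 1.2)
    drift: dict[str, float] = field(default_factory=lambda: {
        "heart_rate": 25.0,
        "resp_rate": 10.0,
        "systolic_bp": -30.0,
        "spo2": -8.0,
        "temperature": 1.0,
    })

    def __post_init__(self) -> None:
        if self.lead_hours <= 0 or self.lead_hours_range[0] <= 0:
            raise ValueError("onset lead time must be positive")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_admissions: int = 5000
    readmission_rate: float = 0.066
    death_rate: float = 0.022
    obs_interval_hours: tuple[float, float] = (4.0, 6.0)
    followup_days: float = 14.0
    risk_slope: float = 1.2
    elective_fraction: float = 0.30
    elective_risk_shift: float = -0.8
    deterioration: DeteriorationConfig = field(
        default_factory=DeteriorationConfig)
    supplemental_o2_rate: float = 0.15
    missingness_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.readmission_rate, self.death_rate,
                  self.missingness_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.readmission_rate + self.death_rate > 1.0:
            raise ValueError("readmission_rate + death_rate exceeds 1")
        if self.followup_days <= 0:
            raise ValueError("followup_days must be positive")


@dataclass
class GroundTruth:
    """Latent state behind a generated cohort."""

    admissions: pd.DataFrame  # admission_id, latent_risk, p_event,
    #                           event_type, event_time, onset_time
    risk_link: dict[str, float]  # alpha, slope of the logistic link
    planted_effects: dict[str, float]  # channel -> z-loading


def ward_trajectory(config: SyntheticCohortConfig, z: float,
                    discharge_time: int, end_time: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Event-free ward vital trajectory for one admission.

    Observation times step by U(4, 6) hours from ICU discharge until
    ``end_time``.  Deterministic given the generator state.
    """
    lo_h, hi_h = config.obs_interval_hours
    times = []
    t = float(discharge_time)
    while True:
        t += rng.uniform(lo_h, hi_h) * MINUTES_PER_HOUR
        if t > end_time:
            break
        times.append(int(round(t)))
    k = len(times)
    cols: dict[str, np.ndarray] = {}
    for name, (mu, load, sd_b, sd_e, step) in _WARD_MODEL.items():
        base = rng.normal(mu + load * z, sd_b)
        noise = lfilter([1.0], [1.0, -_WARD_AR1_RHO],
                        rng.normal(0.0, sd_e, size=k))
        lo, hi = VITAL_BOUNDS[name]
        cols[name] = np.clip(np.round((base + noise) / step) * step, lo, hi)
    o2 = rng.random(k) < config.supplemental_o2_rate
    frame = pd.DataFrame({"obs_time": np.asarray(times, dtype=int), **cols})
    frame["supplemental_o2"] = o2
    frame["avpu"] = "A"
    return frame


def inject_deterioration(trajectory: pd.DataFrame, event_time: int,
                         discharge_time: int,
                         config: DeteriorationConfig,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[pd.DataFrame, bool]:
    """Impose the pre-event drift on an event-free trajectory.

    Returns the drifted copy (truncated at the event) and a flag set
    when the lead window was truncated at ICU discharge.  Observations
    strictly before onset are untouched.
    """
    lead_min = config.lead_hours * MINUTES_PER_HOUR
    onset = event_time - lead_min
    truncated = onset < discharge_time
    if truncated:
        onset = discharge_time
    out = trajectory[trajectory["obs_time"] < event_time].copy()
    span = max(event_time - onset, 1.0)
    progress = (out["obs_time"].to_numpy(float) - onset) / span
    active = progress > 0
    progress = np.clip(progress, 0.0, 1.0)
    for name, magnitude in config.drift.items():
        if magnitude == 0 or name not in out:
            continue
        step = _WARD_MODEL[name][4]
        lo, hi = VITAL_BOUNDS[name]
        drifted = out[name].to_numpy(float) + magnitude * progress
        out[name] = np.clip(np.round(drifted / step) * step, lo, hi)
    if rng is not None and active.any():
        # consciousness drops and supplemental oxygen rises with the drift
        u = rng.random((len(out), 2))
        avpu = out["avpu"].to_numpy(object)
        p_v = 0.25 * progress
        p_p = 0.10 * progress
        avpu[active & (u[:, 0] < p_p)] = "P"
        avpu[active & (u[:, 0] >= p_p) & (u[:, 0] < p_p + p_v)] = "V"
        out["avpu"] = avpu
        extra_o2 = u[:, 1] < 0.6 * progress
        out["supplemental_o2"] = out["supplemental_o2"].to_numpy(bool) \
            | (active & extra_o2)
    return out, truncated


def _icu_channels(z: float, admit: int, discharge: int, elective: bool,
                  rng: np.random.Generator) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    stay_min = discharge - admit
    hours = np.arange(0, stay_min, 60.0)
    times = (admit + hours).astype(float)
    channels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, (mu, load, sd_e) in _ICU_VITALS.items():
        k = times.size
        noise = lfilter([1.0], [1.0, -_ICU_AR1_RHO],
                        rng.normal(0.0, sd_e, size=k))
        lo, hi = VITAL_BOUNDS[name]
        channels[name] = (times.copy(),
                          np.clip(mu + load * z + noise, lo, hi))
    lab_times = np.arange(admit + 240.0, discharge, _DAY_MIN)
    if lab_times.size == 0:
        lab_times = np.array([admit + stay_min / 2.0])
    for name, (base, load, sd, lognorm) in _ICU_LABS.items():
        k = lab_times.size
        eps = rng.normal(0.0, sd, size=k)
        if lognorm:
            values = base * np.exp(load * z + eps)
        else:
            values = base + load * z + eps
        channels[name] = (lab_times.copy(), values)

    # interventions as on/off edges sampled at interval boundaries
    if elective:
        vent_end = discharge - rng.uniform(2, 20) * MINUTES_PER_HOUR
        vent = [(admit, 1.0), (max(admit + 1, int(vent_end)), 0.0)]
    elif rng.random() < expit(-0.4 + 0.8 * z):
        frac = rng.uniform(0.3, 1.0)
        vent_end = admit + frac * stay_min
        vent = [(admit, 1.0), (min(discharge, int(vent_end)), 0.0)]
    else:
        vent = [(admit, 0.0)]
    channels["ventilation"] = (
        np.array([t for t, _ in vent], dtype=float),
        np.array([v for _, v in vent], dtype=float))
    for name, p_on in (("vasopressor", expit(-1.2 + 0.9 * z)),
                       ("dialysis", expit(-3.0 + 1.0 * z))):
        if rng.random() < p_on:
            end = admit + rng.uniform(0.2, 0.9) * stay_min
            channels[name] = (np.array([admit, int(end)], dtype=float),
                              np.array([1.0, 0.0]))
        else:
            channels[name] = (np.array([admit], dtype=float),
                              np.array([0.0]))
    return channels


def generate_cohort(config: SyntheticCohortConfig | None = None,
                    ) -> tuple[CohortTables, GroundTruth]:
    """Generate a full cohort plus its ground truth; seed-deterministic."""
    config = config or SyntheticCohortConfig()
    n = config.n_admissions
    master = np.random.SeedSequence(config.seed)
    global_ss, *adm_ss = master.spawn(n + 1)
    rng = np.random.default_rng(global_ss)

    event_rate = config.readmission_rate + config.death_rate
    z = rng.normal(0.0, 1.0, size=n)
    elective = rng.random(n) < config.elective_fraction
    z_eff = z + config.elective_risk_shift * elective

    def mean_rate(alpha: float) -> float:
        return float(expit(alpha + config.risk_slope * z_eff).mean())

    if event_rate in (0.0, 1.0):
        p_event = np.full(n, event_rate)
        alpha = -np.inf if event_rate == 0 else np.inf
    else:
        alpha = brentq(lambda a: mean_rate(a) - event_rate, -20.0, 20.0)
        p_event = expit(alpha + config.risk_slope * z_eff)

    has_event = rng.random(n) < p_event
    is_readm = rng.random(n) < (
        config.readmission_rate / event_rate if event_rate else 0.0)

    age = np.clip(rng.normal(62, 16, size=n), 18, 95).round(0)
    sex = np.where(rng.random(n) < 0.41, "F", "M")
    icu_los_h = np.clip(np.exp(rng.normal(np.log(1.9 * 24), 1.1, size=n)),
                        12.0, 24.0 * 30)
    ward_los_h = np.clip(np.exp(rng.normal(np.log(8 * 24), 0.6, size=n)),
                         48.0, 24.0 * 60)
    followup_min = config.followup_days * _DAY_MIN

    admissions: list[ICUAdmissionRecord] = []
    observations: list[WardObservationSet] = []
    outcomes: list[OutcomeRecord] = []
    truth_rows = []

    for i in range(n):
        aid = f"adm{i:05d}"
        ward_rng_ss, det_ss = adm_ss[i].spawn(2)
        adm_rng = np.random.default_rng(ward_rng_ss)
        admit = int(i * 70 * _DAY_MIN)  # stagger episodes on the calendar
        discharge = admit + int(round(icu_los_h[i] * 60))
        end = discharge + int(min(ward_los_h[i] * 60, followup_min))

        event_time: int | None = None
        onset_time: float | None = None
        etype = "none"
        if has_event[i]:
            etype = "readmission" if is_readm[i] else "death"
            lo = discharge + 2 * MINUTES_PER_HOUR
            event_time = int(rng.uniform(lo, max(lo + 60, end)))

        traj = ward_trajectory(config, z[i], discharge, end, adm_rng)
        if event_time is not None:
            det = config.deterioration
            lead = rng.uniform(*det.lead_hours_range)
            severity = rng.uniform(*det.severity_range)
            per_event = replace(
                det, lead_hours=lead,
                drift={k: v * severity for k, v in det.drift.items()})
            det_rng = np.random.default_rng(det_ss)
            traj, _ = inject_deterioration(
                traj, event_time, discharge, per_event, det_rng)
            onset_time = max(discharge,
                             event_time - lead * MINUTES_PER_HOUR)

        channels = _icu_channels(z[i], admit, discharge, bool(elective[i]),
                                 adm_rng)
        statics = {
            "elective_admission": float(elective[i]),
            "apache_score": float(np.clip(
                np.round(14 + 4.5 * z[i] + adm_rng.normal(0, 3)), 0, 71)),
            "weight": float(np.round(adm_rng.normal(78, 15), 1)),
            "surgical_admission": float(
                elective[i] or adm_rng.random() < 0.25),
            "prior_icu_admissions": float(adm_rng.poisson(0.15)),
        }
        admissions.append(ICUAdmissionRecord(
            admission_id=aid, age=float(age[i]), sex=str(sex[i]),
            icu_admit_time=admit, icu_discharge_time=discharge,
            discharge_status="alive", static_vars=statics,
            channels=channels))
        for row in traj.itertuples(index=False):
            observations.append(WardObservationSet(
                admission_id=aid, obs_time=int(row.obs_time),
                heart_rate=row.heart_rate, systolic_bp=row.systolic_bp,
                resp_rate=row.resp_rate, temperature=round(row.temperature, 1),
                spo2=row.spo2, supplemental_o2=bool(row.supplemental_o2),
                avpu=str(row.avpu)))
        hosp_discharge = event_time if etype == "death" else end
        outcomes.append(OutcomeRecord(
            admission_id=aid, event_type=etype, event_time=event_time,
            hospital_discharge_time=hosp_discharge))
        truth_rows.append({
            "admission_id": aid, "latent_risk": float(z_eff[i]),
            "latent_severity": float(z[i]),
            "p_event": float(p_event[i]), "event_type": etype,
            "event_time": event_time, "onset_time": onset_time,
        })

    truth = GroundTruth(
        admissions=pd.DataFrame(truth_rows),
        risk_link={"alpha": float(alpha), "slope": config.risk_slope,
                   "elective_shift": config.elective_risk_shift},
        planted_effects={
            **{k: v[1] for k, v in _ICU_VITALS.items()},
            **{k: v[1] for k, v in _ICU_LABS.items()},
        },
    )
    cohort = CohortTables(admissions, observations, outcomes)
    if config.missingness_rate > 0:
        cohort = make_missing(cohort, config.missingness_rate,
                              seed=config.seed + 1)
    return cohort, truth


def make_missing(cohort: CohortTables, rates: float | dict[str, float],
                 seed: int = 0) -> CohortTables:
    """Independently mask ward vital cells at the configured rates.

    Timestamps, identifiers and outcome fields are never masked.
    """
    if isinstance(rates, dict):
        rate_of = lambda c: rates.get(c, 0.0)
    else:
        rate_of = lambda c: float(rates)
    for c in list(VITAL_BOUNDS) + ["supplemental_o2", "avpu"]:
        if not 0.0 <= rate_of(c) < 1.0:
            raise ValueError("missingness rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    masked: list[WardObservationSet] = []
    fields = list(VITAL_BOUNDS) + ["supplemental_o2", "avpu"]
    for obs in cohort.observations:
        u = rng.random(len(fields))
        updates = {f: None for f, ui in zip(fields, u) if ui < rate_of(f)}
        masked.append(replace(obs, **updates) if updates else obs)
    return CohortTables(cohort.admissions, masked, cohort.outcomes)


def make_sparse_logistic_problem(n: int = 2000, d: int = 50,
                                 n_informative: int = 5,
                                 effect: float = 1.0, seed: int = 0,
                                 ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Plain sparse-logistic benchmark: X, y and the planted log-odds.

    The first ``n_informative`` features carry log-odds ``+/- effect``
    (alternating signs); the rest are noise.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    w = np.zeros(d)
    w[:n_informative] = effect * np.where(
        np.arange(n_informative) % 2 == 0, 1.0, -1.0)
    eta = X @ w - 1.5
    y = (rng.random(n) < expit(eta)).astype(int)
    cols = [f"f{j:02d}" for j in range(d)]
    return pd.DataFrame(X, columns=cols), y, w
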