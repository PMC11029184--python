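"""Domain types for post-ICU risk scoring.

Timestamps are stored as integer minutes since an arbitrary epoch; all
elapsed times are computed in hours as floats (the fusion blend is a
function of hours since ICU discharge).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MINUTES_PER_HOUR = 60.0

#: Plausibility bounds for the five continuous ward vital-sign channels.
VITAL_BOUNDS: dict[str, tuple[float, float]] = {
    "heart_rate": (10.0, 300.0),
    "systolic_bp": (30.0, 300.0),
    "resp_rate": (0.0, 80.0),
    "temperature": (30.0, 43.0),
    "spo2": (50.0, 100.0),
}

VITAL_CHANNELS = tuple(VITAL_BOUNDS)

AVPU_CODES = ("A", "V", "P", "U")

DISCHARGE_STATUSES = ("alive", "dead", "palliative", "transferred_out", "unknown")

EVENT_TYPES = ("none", "death", "readmission")


@dataclass(frozen=True)
class WardObservationSet:
    """One timestamped set of ward vital signs — the unit of analysis.

    Any vital may be ``None`` (missing).  ``obs_time`` is minutes since
    the cohort epoch.
    """

    admission_id: str
    obs_time: int
    heart_rate: float | None = None
    systolic_bp: float | None = None
    resp_rate: float | None = None
    temperature: float | None = None
    spo2: float | None = None
    supplemental_o2: bool | None = None
    avpu: str | None = None

    def __post_init__(self) -> None:
        if self.avpu is not None and self.avpu not in AVPU_CODES:
            raise ValueError(f"unknown AVPU code {self.avpu!r}")
        for name in VITAL_CHANNELS:
            value = getattr(self, name)
            if value is None:
                continue
            lo, hi = VITAL_BOUNDS[name]
            if not (lo <= value <= hi):
                raise ValueError(
                    f"{name}={value} outside plausibility bounds [{lo}, {hi}]"
                )

    def vitals(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in VITAL_CHANNELS}


@dataclass
class ICUAdmissionRecord:
    """One ICU stay: static fields plus named time-varying channels.

    ``channels`` maps a channel name to a ``(times, values)`` pair of
    equal-length arrays; intervention channels use values 0/1 sampled at
    the interval edges (on at the timestamp, until the next edge).
    """

    admission_id: str
    age: float
    sex: str
    icu_admit_time: int
    icu_discharge_time: int
    discharge_status: str = "alive"
    static_vars: dict[str, float] = field(default_factory=dict)
    channels: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.discharge_status not in DISCHARGE_STATUSES:
            raise ValueError(f"unknown discharge status {self.discharge_status!r}")
        if not self.icu_admit_time < self.icu_discharge_time:
            raise ValueError(
                f"admission {self.admission_id}: icu_admit_time must precede "
                "icu_discharge_time"
            )
        for name, (times, values) in self.channels.items():
            times = np.asarray(times, dtype=float)
            values = np.asarray(values, dtype=float)
            if times.shape != values.shape:
                raise ValueError(f"channel {name}: times/values length mismatch")
            if times.size and (
                times.min() < self.icu_admit_time
                or times.max() > self.icu_discharge_time
            ):
                raise ValueError(
                    f"channel {name}: timestamps outside the ICU stay of "
                    f"admission {self.admission_id}"
                )
            self.channels[name] = (times, values)


@dataclass(frozen=True)
class OutcomeRecord:
    """First adverse event (death/readmission) for one admission."""

    admission_id: str
    event_type: str = "none"
    event_time: int | None = None
    hospital_discharge_time: int | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.event_type != "none" and self.event_time is None:
            raise ValueError("adverse event requires an event_time")


@dataclass
class CohortTables:
    """Admissions, ward observations and outcomes for one cohort."""

    admissions: list[ICUAdmissionRecord]
    observations: list[WardObservationSet]
    outcomes: list[OutcomeRecord]

    def __post_init__(self) -> None:
        ids = {a.admission_id for a in self.admissions}
        for obs in self.observations:
            if obs.admission_id not in ids:
                raise ValueError(f"observation references unknown admission "
                                 f"{obs.admission_id!r}")
        for out in self.outcomes:
            if out.admission_id not in ids:
                raise ValueError(f"outcome references unknown admission "
                                 f"{out.admission_id!r}")

    def observations_frame(self) -> pd.DataFrame:
        """Ward observations as a DataFrame (one row per observation set)."""
        rows = [
            {
                "admission_id": o.admission_id,
                "obs_time": o.obs_time,
                **o.vitals(),
                "supplemental_o2": o.supplemental_o2,
                "avpu": o.avpu,
            }
            for o in self.observations
        ]
        cols = ["admission_id", "obs_time", *VITAL_CHANNELS,
                "supplemental_o2", "avpu"]
        return pd.DataFrame(rows, columns=cols)

    def outcomes_frame(self) -> pd.DataFrame:
        rows = [
            {
                "admission_id": o.admission_id,
                "event_type": o.event_type,
                "event_time": o.event_time,
                "hospital_discharge_time": o.hospital_discharge_time,
            }
            for o in self.outcomes
        ]
        return pd.DataFrame(
            rows, columns=["admission_id", "event_type", "event_time",
                           "hospital_discharge_time"]
        )

    def discharge_times(self) -> dict[str, int]:
        return {a.admission_id: a.icu_discharge_time for a in self.admissions}


def apply_inclusion_criteria(
    admissions: Sequence[ICUAdmissionRecord],
    outcomes: Mapping[str, OutcomeRecord] | None = None,
) -> tuple[list[ICUAdmissionRecord], pd.DataFrame]:
    """Apply the cohort inclusion criteria.

    Included admissions are those discharged alive from the ICU whose
    hospital-episode outcome is known.  Palliative discharges, deaths in
    ICU, transfers to another organisation and unknown-status episodes
    are excluded; the returned log counts each exclusion reason.
    """
    seen: set[str] = set()
    for adm in admissions:
        if adm.admission_id in seen:
            raise ValueError(f"duplicate admission_id {adm.admission_id!r}")
        seen.add(adm.admission_id)

    reasons = {
        "dead": "not discharged alive",
        "palliative": "palliative care discharge",
        "transferred_out": "transferred to another organisation",
        "unknown": "hospital-episode outcome unknown",
    }
    included: list[ICUAdmissionRecord] = []
    counts: dict[str, int] = {r: 0 for r in reasons.values()}
    counts["no linked outcome"] = 0
    for adm in admissions:
        if adm.discharge_status != "alive":
            counts[reasons[adm.discharge_status]] += 1
            continue
        if outcomes is not None and adm.admission_id not in outcomes:
            counts["no linked outcome"] += 1
            continue
        included.append(adm)
    log = pd.DataFrame(
        [(reason, n) for reason, n in counts.items() if n > 0],
        columns=["reason", "n_excluded"],
    )
    return included, log


def link_outcomes(
    admissions: Sequence[ICUAdmissionRecord],
    raw_events: pd.DataFrame,
    hospital_discharge_times: Mapping[str, int] | None = None,
) -> list[OutcomeRecord]:
    """Link raw adverse events to admissions, keeping the first event only.

    ``raw_events`` has columns (admission_id, type, time); admissions with
    no event get ``event_type='none'``.  Events recorded before ICU
    discharge raise.
    """
    discharge = {a.admission_id: a.icu_discharge_time for a in admissions}
    first: dict[str, tuple[int, str]] = {}
    for row in raw_events.itertuples(index=False):
        aid, etype, etime = str(row.admission_id), str(row.type), int(row.time)
        if aid not in discharge:
            continue
        if etype not in ("death", "readmission"):
            raise ValueError(f"unknown event type {etype!r}")
        if etime <= discharge[aid]:
            raise ValueError(
                f"event for admission {aid} at {etime} precedes ICU discharge"
            )
        if aid not in first or (etime, etype) < first[aid]:
            first[aid] = (etime, etype)
    records = []
    for adm in admissions:
        hosp = None
        if hospital_discharge_times is not None:
            hosp = hospital_discharge_times.get(adm.admission_id)
        if adm.admission_id in first:
            etime, etype = first[adm.admission_id]
            records.append(
                OutcomeRecord(adm.admission_id, etype, etime, hosp)
            )
        else:
            records.append(OutcomeRecord(adm.admission_id, "none", None, hosp))
    return records
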