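"""Read/write the four cohort tables as headered CSV files.

Layout (one directory per cohort):

* ``admissions.csv`` — admission_id, age, sex, icu_admit_time,
  icu_discharge_time, discharge_status plus wide static columns
* ``channels.csv``   — admission_id, channel, time, value
* ``observations.csv`` — admission_id, obs_time and the vital columns
* ``outcomes.csv``   — admission_id, event_type, event_time,
  hospital_discharge_time

Timestamps are ISO-8601 at minute resolution; an empty cell means the
value is missing.  A write→read round trip reproduces the cohort
exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    AVPU_CODES,
    CohortTables,
    ICUAdmissionRecord,
    OutcomeRecord,
    VITAL_CHANNELS,
    WardObservationSet,
)

_EPOCH = pd.Timestamp("2000-01-01 00:00")

_STATIC_PREFIX = "static_"


def minutes_to_iso(minutes: float | None) -> str:
    if minutes is None or (isinstance(minutes, float) and np.isnan(minutes)):
        return ""
    return (_EPOCH + pd.Timedelta(minutes=int(round(minutes)))).isoformat(sep=" ")


def iso_to_minutes(text: str, row: int | None = None) -> int | None:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return None
    try:
        ts = pd.Timestamp(text)
    except (ValueError, TypeError) as exc:
        where = f" at row {row}" if row is not None else ""
        raise ValueError(f"unparseable timestamp {text!r}{where}") from exc
    return int(round((ts - _EPOCH).total_seconds() / 60.0))


def write_cohort(cohort: CohortTables, directory: str | os.PathLike) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    static_names = sorted({k for a in cohort.admissions for k in a.static_vars})
    adm_rows = []
    chan_rows: list[tuple[str, str, str, float]] = []
    for a in cohort.admissions:
        row = {
            "admission_id": a.admission_id,
            "age": a.age,
            "sex": a.sex,
            "icu_admit_time": minutes_to_iso(a.icu_admit_time),
            "icu_discharge_time": minutes_to_iso(a.icu_discharge_time),
            "discharge_status": a.discharge_status,
        }
        for name in static_names:
            row[_STATIC_PREFIX + name] = a.static_vars.get(name, "")
        adm_rows.append(row)
        for channel, (times, values) in sorted(a.channels.items()):
            for t, v in zip(times, values):
                chan_rows.append((a.admission_id, channel, minutes_to_iso(t), v))
    pd.DataFrame(adm_rows).to_csv(directory / "admissions.csv", index=False)
    pd.DataFrame(
        chan_rows, columns=["admission_id", "channel", "time", "value"]
    ).to_csv(directory / "channels.csv", index=False)

    obs = cohort.observations_frame()
    obs["obs_time"] = obs["obs_time"].map(minutes_to_iso)
    obs["supplemental_o2"] = obs["supplemental_o2"].map(
        lambda v: "" if v is None else ("true" if v else "false")
    )
    obs["avpu"] = obs["avpu"].map(lambda v: "" if v is None else v)
    obs.to_csv(directory / "observations.csv", index=False)

    out = cohort.outcomes_frame()
    out["event_time"] = out["event_time"].map(minutes_to_iso)
    out["hospital_discharge_time"] = out["hospital_discharge_time"].map(
        minutes_to_iso
    )
    out.to_csv(directory / "outcomes.csv", index=False)


def _read_bool(text, row: int) -> bool | None:
    if text is None or text == "" or (isinstance(text, float) and np.isnan(text)):
        return None
    text = str(text).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"unparseable boolean {text!r} at row {row}")


def read_cohort(directory: str | os.PathLike) -> CohortTables:
    directory = Path(directory)
    adm_df = pd.read_csv(directory / "admissions.csv", dtype=str,
                         keep_default_na=False)
    chan_df = pd.read_csv(directory / "channels.csv", dtype=str,
                          keep_default_na=False)
    obs_df = pd.read_csv(directory / "observations.csv", dtype=str,
                         keep_default_na=False)
    out_df = pd.read_csv(directory / "outcomes.csv", dtype=str,
                         keep_default_na=False)

    channels: dict[str, dict[str, tuple[list, list]]] = {}
    for i, row in enumerate(chan_df.itertuples(index=False)):
        per = channels.setdefault(str(row.admission_id), {})
        times, values = per.setdefault(str(row.channel), ([], []))
        times.append(iso_to_minutes(row.time, row=i))
        values.append(float(row.value))

    static_cols = [c for c in adm_df.columns if c.startswith(_STATIC_PREFIX)]
    admissions = []
    for i, row in adm_df.iterrows():
        statics = {
            c[len(_STATIC_PREFIX):]: float(row[c])
            for c in static_cols
            if row[c] != ""
        }
        chans = {
            name: (np.asarray(t, dtype=float), np.asarray(v, dtype=float))
            for name, (t, v) in channels.get(row["admission_id"], {}).items()
        }
        admissions.append(
            ICUAdmissionRecord(
                admission_id=row["admission_id"],
                age=float(row["age"]),
                sex=row["sex"],
                icu_admit_time=iso_to_minutes(row["icu_admit_time"], row=i),
                icu_discharge_time=iso_to_minutes(row["icu_discharge_time"], row=i),
                discharge_status=row["discharge_status"],
                static_vars=statics,
                channels=chans,
            )
        )

    observations = []
    for i, row in obs_df.iterrows():
        avpu = row["avpu"] or None
        if avpu is not None and avpu not in AVPU_CODES:
            raise ValueError(f"unknown AVPU code {avpu!r} at row {i}")
        vitals = {}
        for name in VITAL_CHANNELS:
            cell = row[name]
            vitals[name] = float(cell) if cell != "" else None
        observations.append(
            WardObservationSet(
                admission_id=row["admission_id"],
                obs_time=iso_to_minutes(row["obs_time"], row=i),
                supplemental_o2=_read_bool(row["supplemental_o2"], i),
                avpu=avpu,
                **vitals,
            )
        )

    outcomes = []
    for i, row in out_df.iterrows():
        outcomes.append(
            OutcomeRecord(
                admission_id=row["admission_id"],
                event_type=row["event_type"],
                event_time=iso_to_minutes(row["event_time"], row=i),
                hospital_discharge_time=iso_to_minutes(
                    row["hospital_discharge_time"], row=i
                ),
            )
        )

    return CohortTables(admissions, observations, outcomes)
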