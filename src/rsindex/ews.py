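"""Table-driven Early Warning Score systems (MEWS, SEWS, NEWS, CEWS).

Each system is a band table: per vital, an ordered list of closed
``[lower, upper]`` bands with non-negative integer points, contiguous at
the chart's measurement precision (integers for heart rate, systolic
blood pressure, respiratory rate and SpO2; 0.1 degC for temperature) and
covering the full plausibility range.  AVPU levels map directly to
points; NEWS additionally scores supplemental oxygen.

Band files for the four published systems are bundled (transcribed from
the primary publications named inside each file) and are user
replaceable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import AVPU_CODES, VITAL_BOUNDS, WardObservationSet

SYSTEMS = ("MEWS", "SEWS", "NEWS", "CEWS")

#: Measurement precision (band grid step) per component.
PRECISION = {
    "heart_rate": 1.0,
    "systolic_bp": 1.0,
    "resp_rate": 1.0,
    "temperature": 0.1,
    "spo2": 1.0,
}


@dataclass(frozen=True)
class Band:
    lower: float
    upper: float
    points: int


@dataclass
class ScoringTable:
    """A validated band-and-points table for one EWS system."""

    system_id: str
    bands: dict[str, list[Band]]
    avpu_points: dict[str, int]
    o2_points: dict[bool, int] = field(default_factory=dict)
    source: str = ""

    @property
    def components(self) -> list[str]:
        comps = list(self.bands)
        comps.append("avpu")
        if self.o2_points:
            comps.append("supplemental_o2")
        return comps

    def validate(self) -> None:
        for vital, bands in self.bands.items():
            if vital not in VITAL_BOUNDS:
                raise ValueError(f"{self.system_id}: unknown vital {vital!r}")
            step = PRECISION[vital]
            lo, hi = VITAL_BOUNDS[vital]
            bands.sort(key=lambda b: b.lower)
            if abs(bands[0].lower - lo) > 1e-9 or abs(bands[-1].upper - hi) > 1e-9:
                raise ValueError(
                    f"{self.system_id}/{vital}: bands do not cover the "
                    f"plausibility range [{lo}, {hi}]"
                )
            for a, b in zip(bands, bands[1:]):
                gap = b.lower - a.upper
                if abs(gap - step) > 1e-6:
                    kind = "gap" if gap > step else "overlap"
                    raise ValueError(
                        f"{self.system_id}/{vital}: {kind} between bands at "
                        f"boundary {a.upper}/{b.lower}"
                    )
            for b in bands:
                if b.points < 0 or int(b.points) != b.points:
                    raise ValueError(
                        f"{self.system_id}/{vital}: points must be "
                        f"non-negative integers (got {b.points})"
                    )
        if set(self.avpu_points) != set(AVPU_CODES):
            raise ValueError(f"{self.system_id}: AVPU mapping must cover A/V/P/U")
        for pts in list(self.avpu_points.values()) + list(self.o2_points.values()):
            if pts < 0 or int(pts) != pts:
                raise ValueError(f"{self.system_id}: negative or non-integer points")


def load_scoring_table(system_id: str | None = None,
                       table_file: str | Path | None = None) -> ScoringTable:
    """Load and validate a band file; defaults to the bundled table."""
    if table_file is None:
        if system_id is None:
            raise ValueError("give a system_id or a table_file")
        ref = resources.files("rsindex") / "ews_tables" / f"{system_id.lower()}.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(table_file).read_text())
    sid = str(raw.get("system", system_id or "")).upper()
    bands: dict[str, list[Band]] = {}
    for row in raw["bands"]:
        bands.setdefault(str(row["component"]), []).append(
            Band(float(row["lower"]), float(row["upper"]), int(row["points"]))
        )
    avpu = {str(k): int(v) for k, v in raw.get("avpu", {}).items()}
    o2 = {bool(k): int(v) for k, v in raw.get("supplemental_o2", {}).items()}
    table = ScoringTable(sid, bands, avpu, o2, source=str(raw.get("source", "")))
    table.validate()
    return table


def _band_points(bands: list[Band], value: float) -> int:
    for b in bands:
        if b.lower <= value <= b.upper:
            return b.points
    # value between grid points (e.g. 40.5 against integer bands): use the
    # band whose interval [lower, upper + step) contains it
    for b in bands:
        if b.lower <= value < b.upper + 1.0:
            return b.points
    raise ValueError(f"value {value} outside table coverage")


def score_ews(table: ScoringTable, obs: WardObservationSet,
              missing_policy: str = "zero") -> tuple[int, dict[str, int]]:
    """Score one observation set; returns (total, per-component breakdown).

    Under ``missing_policy='zero'`` a missing component contributes 0
    points (with a warning); under ``'strict'`` it raises.
    """
    if missing_policy not in ("zero", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    breakdown: dict[str, int] = {}
    for vital, bands in table.bands.items():
        value = getattr(obs, vital)
        if value is None:
            if missing_policy == "strict":
                raise ValueError(f"missing vital {vital!r}")
            warnings.warn(f"missing {vital}: scored 0", stacklevel=2)
            breakdown[vital] = 0
        else:
            breakdown[vital] = _band_points(bands, value)
    if obs.avpu is None:
        if missing_policy == "strict":
            raise ValueError("missing AVPU")
        warnings.warn("missing AVPU: scored 0", stacklevel=2)
        breakdown["avpu"] = 0
    else:
        breakdown["avpu"] = table.avpu_points[obs.avpu]
    if table.o2_points:
        if obs.supplemental_o2 is None:
            if missing_policy == "strict":
                raise ValueError("missing supplemental_o2")
            warnings.warn("missing supplemental_o2: scored 0", stacklevel=2)
            breakdown["supplemental_o2"] = 0
        else:
            breakdown["supplemental_o2"] = table.o2_points[bool(obs.supplemental_o2)]
    return sum(breakdown.values()), breakdown


def score_frame(table: ScoringTable, obs: pd.DataFrame,
                missing_policy: str = "zero") -> pd.DataFrame:
    """Vectorised scoring of an observation DataFrame.

    Returns one points column per component plus ``total``.  Missing
    cells contribute 0 under the default policy.
    """
    if missing_policy not in ("zero", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    out = pd.DataFrame(index=obs.index)
    for vital, bands in table.bands.items():
        values = pd.to_numeric(obs[vital], errors="coerce").to_numpy(dtype=float)
        missing = np.isnan(values)
        if missing.any() and missing_policy == "strict":
            raise ValueError(f"missing vital {vital!r}")
        edges = np.array([b.lower for b in bands[1:]])
        pts = np.array([b.points for b in bands])
        idx = np.searchsorted(edges, np.nan_to_num(values), side="right")
        col = pts[idx]
        col[missing] = 0
        out[vital] = col
    avpu = obs["avpu"].astype(object)
    avpu_pts = avpu.map(lambda a: 0 if a is None or (isinstance(a, float))
                        else table.avpu_points[a])
    if missing_policy == "strict" and avpu.isna().any():
        raise ValueError("missing AVPU")
    out["avpu"] = avpu_pts.astype(int)
    if table.o2_points:
        o2 = obs["supplemental_o2"]
        if missing_policy == "strict" and o2.isna().any():
            raise ValueError("missing supplemental_o2")
        out["supplemental_o2"] = o2.map(
            lambda v: 0 if v is None or (isinstance(v, float) and np.isnan(v))
            else table.o2_points[bool(v)]
        ).astype(int)
    out["total"] = out.sum(axis=1)
    return out


class EWSScorer:
    """Stateless transformer-style wrapper around one scoring table."""

    def __init__(self, system_id: str = "NEWS",
                 table_file: str | Path | None = None,
                 missing_policy: str = "zero"):
        self.system_id = system_id
        self.table_file = table_file
        self.missing_policy = missing_policy
        self.table_ = load_scoring_table(system_id, table_file)

    def transform(self, observations: pd.DataFrame) -> np.ndarray:
        """Total score per observation row."""
        return score_frame(self.table_, observations,
                           self.missing_policy)["total"].to_numpy()

    def __call__(self, obs: WardObservationSet) -> int:
        return score_ews(self.table_, obs, self.missing_policy)[0]
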