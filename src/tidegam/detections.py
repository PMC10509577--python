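"""From raw camera-trap triggers to the modelling table.

Triggers less than 30 s apart at one camera form a *sequence*; each sequence
carries the maximum simultaneous individual count seen in its triggers (the
standard camera-trap convention, avoiding double counting).  Only sequences
with at least one animal enter the model — an absent detection does not imply
an absent animal, so zeros are never modelled.  Set-up and collection days
are excluded because human presence disturbs behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    ArgumentError,
    DegenerateScaleError,
    EmptyInputError,
    FormatError,
    OrphanRecordError,
)
from .tide_clock import TideTable, hours_to_nearest_low

GROUPS = ("tool", "nontool")
SEASONS = ("dry", "wet")
DRY_MONTHS = frozenset({12, 1, 2, 3, 4})  # December–April; May–November is wet


@dataclass(frozen=True)
class TriggerRecord:
    camera_id: str
    timestamp: datetime
    species: str
    count: int

    def __post_init__(self):
        if self.count < 0:
            raise FormatError(f"negative count {self.count} at {self.camera_id}")


@dataclass(frozen=True)
class SequenceRecord:
    camera_id: str
    start_ts: datetime
    count: int  # >= 1; zero-count sequences never reach the model

    def __post_init__(self):
        if self.count < 1:
            raise FormatError("sequence count must be >= 1")


@dataclass(frozen=True)
class Deployment:
    camera_id: str
    site_id: str
    start_date: date
    end_date: date
    distance_to_coast_m: float
    group: str  # "tool" | "nontool"
    medium: str = "still"

    def __post_init__(self):
        if self.start_date > self.end_date:
            raise FormatError(f"{self.camera_id}: start_date after end_date")
        if self.distance_to_coast_m < 0:
            raise FormatError(f"{self.camera_id}: negative distance to coast")
        if self.group not in GROUPS:
            raise FormatError(f"{self.camera_id}: unknown group {self.group!r}")


@dataclass(frozen=True)
class Standardizer:
    """z-transform: (x - mean) / sd, with sample (n-1) sd."""

    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise DegenerateScaleError("standardizer sd must be > 0")

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


@dataclass
class ModelTable:
    """One row per retained sequence, with z-scored covariates.

    ``data`` columns: count, t_hours, d_m, hour, t_z, d_z, h_z, season,
    group, camera_id.  The three standardizers are kept for back-transforming
    model output to hours and metres.
    """

    data: pd.DataFrame
    t_std: Standardizer
    d_std: Standardizer
    h_std: Standardizer
    tide_interval_h: float  # mean low–low gap of the tide table used

    def __post_init__(self):
        required = {
            "count", "t_hours", "d_m", "hour", "t_z", "d_z", "h_z",
            "season", "group", "camera_id",
        }
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"model table missing columns: {sorted(missing)}")
        if self.data.isna().any().any():
            raise FormatError("model table contains missing values")
        if (self.data["count"] < 1).any():
            raise FormatError("model table counts must be >= 1")

    def __len__(self):
        return len(self.data)

    def subset(self, **levels) -> "ModelTable":
        """Rows matching e.g. ``group='tool'``; standardizers unchanged."""
        mask = np.ones(len(self.data), dtype=bool)
        for col, val in levels.items():
            mask &= (self.data[col] == val).to_numpy()
        return ModelTable(
            self.data.loc[mask].reset_index(drop=True),
            self.t_std, self.d_std, self.h_std, self.tide_interval_h,
        )


def season_of(d: Union[date, datetime]) -> str:
    """Dry season December–April, wet season May–November."""
    return "dry" if d.month in DRY_MONTHS else "wet"


def fit_standardizer(values: Iterable[float]) -> Standardizer:
    x = np.asarray(list(values), dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateScaleError("need >= 2 distinct values to z-transform")
    return Standardizer(float(x.mean()), float(x.std(ddof=1)))


def assemble_sequences(
    triggers: Sequence[TriggerRecord], gap_s: float = 30.0
) -> list[SequenceRecord]:
    """Chain per-camera triggers less than ``gap_s`` seconds apart into
    sequences (start = first trigger, count = max over the chain); drop
    zero-count sequences."""
    if gap_s < 0:
        raise ArgumentError(f"gap_s must be non-negative, got {gap_s}")
    ordered = sorted(triggers, key=lambda t: (t.camera_id, t.timestamp))
    sequences: list[SequenceRecord] = []
    chain: list[TriggerRecord] = []

    def flush():
        if chain:
            peak = max(t.count for t in chain)
            if peak >= 1:
                sequences.append(
                    SequenceRecord(chain[0].camera_id, chain[0].timestamp, peak)
                )

    for trig in ordered:
        if chain and (
            trig.camera_id != chain[-1].camera_id
            or (trig.timestamp - chain[-1].timestamp).total_seconds() >= gap_s
        ):
            flush()
            chain = []
        chain.append(trig)
    flush()
    return sequences


def _covering_deployment(
    seq: SequenceRecord, by_camera: dict[str, list[Deployment]]
) -> Optional[Deployment]:
    d = seq.start_ts.date()
    for dep in by_camera.get(seq.camera_id, ()):
        if dep.start_date <= d <= dep.end_date:
            return dep
    return None


def filter_service_days(
    sequences: Sequence[SequenceRecord], deployments: Sequence[Deployment]
) -> list[SequenceRecord]:
    """Drop sequences dated on their deployment's set-up or collection day.

    Raises :class:`OrphanRecordError` if any sequence has no covering
    deployment.
    """
    by_camera: dict[str, list[Deployment]] = {}
    for dep in deployments:
        by_camera.setdefault(dep.camera_id, []).append(dep)
    kept: list[SequenceRecord] = []
    orphans: list[str] = []
    for seq in sequences:
        dep = _covering_deployment(seq, by_camera)
        if dep is None:
            orphans.append(f"{seq.camera_id}@{seq.start_ts.isoformat()}")
            continue
        d = seq.start_ts.date()
        if d == dep.start_date or d == dep.end_date:
            continue
        kept.append(seq)
    if orphans:
        raise OrphanRecordError(orphans)
    return kept


def build_model_table(
    sequences: Sequence[SequenceRecord],
    deployments: Sequence[Deployment],
    tides: TideTable,
) -> ModelTable:
    """Join covariates onto retained sequences and fit the three z-transforms
    (time to low tide, distance to coast, hour of day) on the final table."""
    if not sequences:
        raise EmptyInputError("no sequences to model")
    by_camera: dict[str, list[Deployment]] = {}
    for dep in deployments:
        by_camera.setdefault(dep.camera_id, []).append(dep)

    rows = []
    orphans = []
    for seq in sequences:
        dep = _covering_deployment(seq, by_camera)
        if dep is None:
            orphans.append(f"{seq.camera_id}@{seq.start_ts.isoformat()}")
            continue
        rows.append(
            {
                "count": seq.count,
                "start_ts": seq.start_ts,
                "t_hours": hours_to_nearest_low(seq.start_ts, tides),
                "d_m": dep.distance_to_coast_m,
                "hour": seq.start_ts.hour,  # integer 0–23
                "season": season_of(seq.start_ts),
                "group": dep.group,
                "camera_id": seq.camera_id,
            }
        )
    if orphans:
        raise OrphanRecordError(orphans)
    df = pd.DataFrame(rows).sort_values(["camera_id", "start_ts"], kind="stable")
    df = df.drop(columns=["start_ts"]).reset_index(drop=True)

    t_std = fit_standardizer(df["t_hours"])
    d_std = fit_standardizer(df["d_m"])
    h_std = fit_standardizer(df["hour"])
    df["t_z"] = t_std.transform(df["t_hours"])
    df["d_z"] = d_std.transform(df["d_m"])
    df["h_z"] = h_std.transform(df["hour"])
    return ModelTable(df, t_std, d_std, h_std, tides.mean_low_interval_h)


# ---------------------------------------------------------------------------
# CSV interfaces


def read_triggers(
    path: Union[str, Path], species_filter: str = "capuchin"
) -> list[TriggerRecord]:
    """Read ``detections.csv`` (camera_id, timestamp, species, count),
    keeping rows whose species contains ``species_filter`` (case-insensitive)."""
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no detection rows")
    for col in ("camera_id", "timestamp", "species", "count"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    try:
        stamps = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamp ({exc})") from exc
    keep = df["species"].astype(str).str.lower().str.contains(species_filter.lower())
    return [
        TriggerRecord(str(c), ts.to_pydatetime(), str(s), int(n))
        for c, ts, s, n, k in zip(
            df["camera_id"], stamps, df["species"], df["count"], keep
        )
        if k
    ]


def read_deployments(path: Union[str, Path]) -> list[Deployment]:
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no deployment rows")
    required = (
        "camera_id", "site_id", "start_date", "end_date",
        "distance_to_coast_m", "group",
    )
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    medium = df["medium"] if "medium" in df.columns else pd.Series(["still"] * len(df))
    return [
        Deployment(
            str(r.camera_id),
            str(r.site_id),
            pd.Timestamp(r.start_date).date(),
            pd.Timestamp(r.end_date).date(),
            float(r.distance_to_coast_m),
            str(r.group),
            str(m),
        )
        for r, m in zip(df.itertuples(), medium)
    ]


def descriptive_summary(
    sequences: Sequence[SequenceRecord], deployments: Sequence[Deployment]
) -> dict:
    """Dataset descriptives: sequence total, per-sequence count moments and
    range, sampling nights per group and mean nights per camera (nights
    exclude the set-up and collection days)."""
    counts = np.array([s.count for s in sequences], dtype=float)
    nights_per_dep = [
        ((dep.end_date - dep.start_date).days - 1, dep.group, dep.camera_id)
        for dep in deployments
    ]
    nights_by_group = {g: 0 for g in GROUPS}
    nights_by_camera: dict[str, int] = {}
    for n, g, cam in nights_per_dep:
        n = max(n, 0)
        nights_by_group[g] += n
        nights_by_camera[cam] = nights_by_camera.get(cam, 0) + n
    return {
        "n_sequences": int(counts.size),
        "count_mean": float(counts.mean()) if counts.size else float("nan"),
        "count_sd": float(counts.std(ddof=1)) if counts.size > 1 else float("nan"),
        "count_min": int(counts.min()) if counts.size else 0,
        "count_max": int(counts.max()) if counts.size else 0,
        "sampling_nights": {g: int(v) for g, v in nights_by_group.items()},
        "mean_nights_per_camera": float(np.mean(list(nights_by_camera.values())))
        if nights_by_camera
        else float("nan"),
    }
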