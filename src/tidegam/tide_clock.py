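"""Tide tables and the time-to-nearest-low-tide covariate.

A mixed semidiurnal tide schedule has two low tides of unequal height roughly
every 12.5 hours.  The analysis covariate is the signed time (hours) from a
detection timestamp to the *nearest* low tide: negative before the low (tide
receding), positive after (tide rising), so values span roughly -6 to +6 h.
High tides are carried in the table but do not enter the covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ArgumentError, CoverageError, EmptyInputError, FormatError

_KINDS = frozenset({"low", "high"})

#: low–low gaps outside this band trigger a warning; gaps above the hard
#: ceiling are treated as data errors (a missing tide).
LOW_GAP_SOFT_H = (11.0, 14.0)
LOW_GAP_HARD_MAX_H = 24.0


@dataclass(frozen=True)
class TideEvent:
    """A single tidal extreme (minute resolution)."""

    timestamp: datetime
    kind: str  # "low" | "high"
    height_m: Optional[float] = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise FormatError(f"unknown tide kind {self.kind!r} (expected low|high)")


@dataclass
class TideTable:
    """Ordered low/high tide events; the temporal reference frame.

    Invariants checked on construction: timestamps strictly increasing and
    consecutive low tides separated by a plausible semidiurnal gap.
    """

    events: list[TideEvent]
    _low_times: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if not self.events:
            raise EmptyInputError("tide table has no events")
        ts = [e.timestamp for e in self.events]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise FormatError("tide event timestamps are not strictly increasing")
        lows = np.array(
            [e.timestamp for e in self.events if e.kind == "low"], dtype="datetime64[us]"
        )
        if lows.size == 0:
            raise FormatError("tide table contains no low tides")
        gaps_h = np.diff(lows).astype("timedelta64[us]").astype(float) / 3.6e9
        if gaps_h.size:
            if np.any(gaps_h > LOW_GAP_HARD_MAX_H):
                raise FormatError(
                    f"low–low gap exceeds {LOW_GAP_HARD_MAX_H} h: "
                    f"max {gaps_h.max():.1f} h (missing tides?)"
                )
            bad = (gaps_h < LOW_GAP_SOFT_H[0]) | (gaps_h > LOW_GAP_SOFT_H[1])
            if np.any(bad):
                warnings.warn(
                    f"{int(bad.sum())} low–low gap(s) outside "
                    f"[{LOW_GAP_SOFT_H[0]}, {LOW_GAP_SOFT_H[1]}] h",
                    stacklevel=2,
                )
        object.__setattr__(self, "_low_times", lows)

    @property
    def low_times(self) -> np.ndarray:
        """Low-tide timestamps as datetime64[us], ascending."""
        return self._low_times

    @property
    def mean_low_interval_h(self) -> float:
        """Mean gap between consecutive low tides in hours (12.5 if single low)."""
        if self._low_times.size < 2:
            return 12.5
        gaps = np.diff(self._low_times).astype("timedelta64[us]").astype(float)
        return float(gaps.mean()) / 3.6e9

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": [e.timestamp for e in self.events],
                "kind": [e.kind for e in self.events],
                "height_m": [e.height_m for e in self.events],
            }
        )


def read_tide_table(path: Union[str, Path]) -> TideTable:
    """Read a tide table CSV (columns ``timestamp``, ``kind``, optional
    ``height_m``; extra columns tolerated).  Rows are sorted by timestamp."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: tide file has no rows")
    for col in ("timestamp", "kind"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    try:
        stamps = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamp ({exc})") from exc
    kinds = df["kind"].astype(str).str.strip().str.lower()
    bad = ~kinds.isin(_KINDS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: row {row}: unknown kind {df['kind'].iloc[row]!r} (expected low|high)"
        )
    heights = df["height_m"] if "height_m" in df.columns else pd.Series([None] * len(df))
    events = [
        TideEvent(ts.to_pydatetime(), k, None if pd.isna(h) else float(h))
        for ts, k, h in zip(stamps, kinds, heights)
    ]
    events.sort(key=lambda e: e.timestamp)
    return TideTable(events)


def write_tide_table(table: TideTable, path: Union[str, Path]) -> None:
    table.to_frame().to_csv(path, index=False)


def synth_tide_schedule(
    start: datetime,
    n_days: int,
    low_interval_h: float = 12.5,
    first_low_offset_h: float = 0.0,
) -> TideTable:
    """Regular semidiurnal schedule: lows every ``low_interval_h`` hours from
    ``start + first_low_offset_h``, highs at the midpoints between lows.

    At the default 12.5 h interval the double-tide cycle is 25 h, so the clock
    time of low tide advances one hour per day.
    """
    if n_days < 1:
        raise ArgumentError(f"n_days must be >= 1, got {n_days}")
    if not (LOW_GAP_SOFT_H[0] <= low_interval_h <= LOW_GAP_SOFT_H[1]):
        raise ArgumentError(
            f"low_interval_h must lie in {list(LOW_GAP_SOFT_H)}, got {low_interval_h}"
        )
    end = start + timedelta(days=n_days)
    events: list[TideEvent] = []
    k = 0
    prev_low = None
    while True:
        low_ts = start + timedelta(hours=first_low_offset_h + k * low_interval_h)
        if low_ts >= end:
            break
        if prev_low is not None:
            events.append(
                TideEvent(prev_low + (low_ts - prev_low) / 2, "high")
            )
        events.append(TideEvent(low_ts, "low"))
        prev_low = low_ts
        k += 1
    if not events:
        raise ArgumentError("schedule produced no events; check offsets")
    return TideTable(events)


def hours_to_nearest_low(
    ts: Union[datetime, Sequence[datetime], np.ndarray], table: TideTable
) -> Union[float, np.ndarray]:
    """Signed hours from ``ts`` to the nearest low tide.

    Negative values: the tide is still receding toward the low; positive: the
    low has passed and the tide is rising.  A timestamp exactly midway between
    two lows is assigned to the *earlier* low (positive lag) — a deterministic
    tie-break for a measure-zero case.  Scalar in, scalar out.

    Raises :class:`CoverageError` for timestamps outside the table's low-tide
    span padded by one mean low–low interval.
    """
    scalar = isinstance(ts, datetime)
    arr = np.asarray([ts] if scalar else ts, dtype="datetime64[us]")
    lows = table.low_times
    pad_us = table.mean_low_interval_h * 3.6e9
    t = arr.astype("int64").astype(float)
    lo = lows.astype("int64").astype(float)
    if np.any(t < lo[0] - pad_us) or np.any(t > lo[-1] + pad_us):
        raise CoverageError(
            "timestamp(s) outside tide table span padded by one low–low interval"
        )
    idx = np.searchsorted(lo, t)  # first low >= ts
    prev_i = np.clip(idx - 1, 0, lo.size - 1)
    next_i = np.clip(idx, 0, lo.size - 1)
    d_prev = t - lo[prev_i]  # >= 0 where a previous low exists
    d_next = lo[next_i] - t
    # nearest low; exact tie -> earlier low (positive lag)
    use_prev = (idx == lo.size) | ((idx > 0) & (d_prev <= d_next))
    hours = np.where(use_prev, d_prev, -d_next) / 3.6e9
    return float(hours[0]) if scalar else hours
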