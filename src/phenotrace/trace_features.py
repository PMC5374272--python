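"""Behavioral features from phone digital-trace logs.

Raw traces are streams of timestamped events — outgoing/incoming calls and
SMS with de-identified counterpart descriptors, GPS fixes, and screen on/off
toggles.  Features are descriptive statistics (sums, counts, means, SDs)
over a fixed window (by default the week preceding the clinical assessment),
covering the social and location data sources.  Activity (accelerometer /
gyroscope) and device-interaction streams are tolerated on input and
ignored.

All timestamps are UTC epoch seconds and all windows are half-open
``[start, end)``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
"""IUGG mean Earth radius used for all great-circle distances."""

DEFAULT_JITTER_FLOOR_KM = 0.03
"""GPS segments shorter than this are treated as positioning jitter."""

#: The trace feature catalogue: descriptive statistics over social (calls,
#: SMS) and location (GPS) events in the analysis window.
TRACE_FEATURE_NAMES: tuple[str, ...] = (
    "call.out.sum",
    "call.out.count",
    "call.in.sum",
    "call.in.count",
    "call.dur.mean",
    "call.dur.sd",
    "sms.out.count",
    "sms.in.count",
    "sms.address.count",
    "sms.in.address.count",
    "travel.distance.sum",
    "travel.distance.daily.mean",
    "travel.distance.daily.sd",
    "gps.radius.max",
)

EVENT_KINDS = frozenset(
    {"call_out", "call_in", "sms_out", "sms_in", "gps", "screen_on", "screen_off"}
)

_CALL_KINDS = frozenset({"call_out", "call_in"})
_SMS_KINDS = frozenset({"sms_out", "sms_in"})


class TraceLogError(ValueError):
    """A trace log line violated the event schema."""


@dataclass(frozen=True, slots=True)
class TraceEvent:
    """One timestamped phone event.

    Parameters
    ----------
    t
        UTC epoch seconds.
    kind
        One of ``call_out, call_in, sms_out, sms_in, gps, screen_on,
        screen_off``.
    peer
        Opaque hashed counterpart descriptor (calls and SMS only).
    dur_s
        Call duration in seconds (calls only, nonnegative).
    lat, lon
        WGS84 decimal degrees (GPS fixes only).
    """

    t: int
    kind: str
    peer: str | None = None
    dur_s: float | None = None
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise TraceLogError(f"unknown event kind {self.kind!r}")
        if self.kind in _CALL_KINDS:
            if self.dur_s is None or self.dur_s < 0:
                raise TraceLogError(f"{self.kind} event requires nonnegative dur_s")
            if self.peer is None:
                raise TraceLogError(f"{self.kind} event requires a peer descriptor")
        elif self.kind in _SMS_KINDS:
            if self.peer is None:
                raise TraceLogError(f"{self.kind} event requires a peer descriptor")
        elif self.kind == "gps":
            if self.lat is None or self.lon is None:
                raise TraceLogError("gps event requires lat and lon")
            if abs(self.lat) > 90 or abs(self.lon) > 180:
                raise TraceLogError(
                    f"gps coordinates out of range: lat={self.lat}, lon={self.lon}"
                )


def event_to_json(event: TraceEvent) -> str:
    """Serialize one event to the canonical JSONL dialect."""
    return json.dumps(
        {
            "t": int(event.t),
            "kind": event.kind,
            "peer": event.peer,
            "dur_s": event.dur_s,
            "lat": event.lat,
            "lon": event.lon,
        },
        sort_keys=True,
    )


def read_trace_log(path) -> list[TraceEvent]:
    """Read a JSONL trace log into a time-sorted event list.

    Each line is an object ``{"t", "kind", "peer", "dur_s", "lat", "lon"}``
    with kind-specific payload requirements.  A malformed line raises
    :class:`TraceLogError` naming the 1-based line number.
    """
    events: list[TraceEvent] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise TraceLogError(f"{path}:{lineno}: unparseable JSON: {exc}") from exc
            if not isinstance(obj, dict) or "t" not in obj or "kind" not in obj:
                raise TraceLogError(f"{path}:{lineno}: event must have 't' and 'kind'")
            try:
                events.append(
                    TraceEvent(
                        t=int(obj["t"]),
                        kind=obj["kind"],
                        peer=obj.get("peer"),
                        dur_s=obj.get("dur_s"),
                        lat=obj.get("lat"),
                        lon=obj.get("lon"),
                    )
                )
            except (TraceLogError, TypeError, ValueError) as exc:
                raise TraceLogError(f"{path}:{lineno}: {exc}") from exc
    events.sort(key=lambda e: e.t)
    return events


def write_trace_log(events: Iterable[TraceEvent], path) -> None:
    """Write events to JSONL, one event per line, in the given order."""
    with open(path, "w", encoding="utf-8") as fh:
        for event in events:
            fh.write(event_to_json(event) + "\n")


def window_events(
    events: Sequence[TraceEvent], assessment_time: float, days: float = 7
) -> list[TraceEvent]:
    """Keep events in the half-open window ``[assessment - days*86400, assessment)``."""
    if not math.isfinite(assessment_time):
        raise ValueError("assessment_time must be finite")
    start = assessment_time - days * 86400.0
    return [e for e in events if start <= e.t < assessment_time]


def call_out_sum(events: Sequence[TraceEvent]) -> float:
    """Total outbound-call duration in minutes."""
    return sum(e.dur_s for e in events if e.kind == "call_out") / 60.0


def sms_address_count(events: Sequence[TraceEvent]) -> int:
    """Number of unique counterparts texted (outgoing SMS only)."""
    return len({e.peer for e in events if e.kind == "sms_out"})


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two WGS84 points, in km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def _gps_fixes(events: Sequence[TraceEvent]) -> list[TraceEvent]:
    return sorted((e for e in events if e.kind == "gps"), key=lambda e: e.t)


def travel_distance_sum(
    events: Sequence[TraceEvent], jitter_floor_km: float = DEFAULT_JITTER_FLOOR_KM
) -> float:
    """Total distance traveled over consecutive GPS fixes, in km.

    Segments shorter than ``jitter_floor_km`` are dropped so that a
    stationary phone with positioning jitter does not accumulate distance.
    Pass ``jitter_floor_km=0`` to disable the floor.
    """
    fixes = _gps_fixes(events)
    total = 0.0
    for prev, cur in zip(fixes, fixes[1:]):
        d = haversine_km(prev.lat, prev.lon, cur.lat, cur.lon)
        if d >= jitter_floor_km:
            total += d
    return total


@dataclass
class FeatureTable:
    """Participants x named-features matrix with an explicit missing mask.

    ``values`` is a pandas DataFrame indexed by participant id; missing
    entries are NaN.  ``window`` is the half-open analysis window shared by
    every row.
    """

    values: pd.DataFrame
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")

    @property
    def participant_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "participant_id", out.index)
        out.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, window: tuple[float, float] | None = None) -> "FeatureTable":
        df = pd.read_csv(path, dtype={"participant_id": str})
        df = df.set_index("participant_id")
        df.index.name = None
        return cls(values=df, window=window)


def _sample_sd(x: Sequence[float]) -> float:
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        return math.nan
    return float(np.std(arr, ddof=1))


def _participant_features(
    events: Sequence[TraceEvent],
    window: tuple[float, float],
    jitter_floor_km: float,
) -> dict[str, float]:
    start, end = window
    calls_out = [e for e in events if e.kind == "call_out"]
    calls_in = [e for e in events if e.kind == "call_in"]
    all_call_minutes = [e.dur_s / 60.0 for e in calls_out + calls_in]
    sms_out = [e for e in events if e.kind == "sms_out"]
    sms_in = [e for e in events if e.kind == "sms_in"]
    fixes = _gps_fixes(events)

    feats: dict[str, float] = {
        "call.out.sum": call_out_sum(events),
        "call.out.count": float(len(calls_out)),
        "call.in.sum": sum(e.dur_s for e in calls_in) / 60.0,
        "call.in.count": float(len(calls_in)),
        "call.dur.mean": float(np.mean(all_call_minutes)) if all_call_minutes else math.nan,
        "call.dur.sd": _sample_sd(all_call_minutes),
        "sms.out.count": float(len(sms_out)),
        "sms.in.count": float(len(sms_in)),
        "sms.address.count": float(sms_address_count(events)),
        "sms.in.address.count": float(len({e.peer for e in sms_in})),
        "travel.distance.sum": travel_distance_sum(events, jitter_floor_km),
    }

    n_days = max(1, int(round((end - start) / 86400.0)))
    if fixes:
        daily = np.zeros(n_days)
        for prev, cur in zip(fixes, fixes[1:]):
            d = haversine_km(prev.lat, prev.lon, cur.lat, cur.lon)
            if d < jitter_floor_km:
                continue
            day = min(n_days - 1, max(0, int((prev.t - start) // 86400)))
            daily[day] += d
        med_lat = float(np.median([f.lat for f in fixes]))
        med_lon = float(np.median([f.lon for f in fixes]))
        radius_max = max(haversine_km(med_lat, med_lon, f.lat, f.lon) for f in fixes)
        feats["travel.distance.daily.mean"] = float(np.mean(daily))
        feats["travel.distance.daily.sd"] = float(np.std(daily, ddof=1)) if n_days > 1 else math.nan
        feats["gps.radius.max"] = radius_max
    else:
        feats["travel.distance.daily.mean"] = math.nan
        feats["travel.distance.daily.sd"] = math.nan
        feats["gps.radius.max"] = math.nan
    return feats


def compute_feature_table(
    streams: dict[str, Sequence[TraceEvent]],
    window: tuple[float, float],
    participant_ids: Sequence[str] | None = None,
    jitter_floor_km: float = DEFAULT_JITTER_FLOOR_KM,
) -> FeatureTable:
    """Compute the 14-feature trace catalogue for every participant.

    Parameters
    ----------
    streams
        Map participant id -> events already windowed to ``window``.
    window
        Half-open ``(start, end)`` of the analysis window, epoch seconds.
    participant_ids
        Row order; defaults to the keys of ``streams``.  A participant with
        no stream gets a fully masked row (logged as a warning).
    """
    if participant_ids is None:
        participant_ids = list(streams)
    rows = []
    for pid in participant_ids:
        if pid not in streams:
            logger.warning("participant %s has no trace stream; row masked", pid)
            rows.append({name: math.nan for name in TRACE_FEATURE_NAMES})
            continue
        rows.append(_participant_features(streams[pid], window, jitter_floor_km))
    df = pd.DataFrame(rows, index=list(participant_ids), columns=list(TRACE_FEATURE_NAMES))
    return FeatureTable(values=df, window=window)
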