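"""Alert-threshold engine: turn a time-ordered stream of parsed signals into
triggered health events.

Two kinds of community alert thresholds exist:

* single-report CCDs (e.g. fever-and-rash): every signal triggers one event;
* a spatiotemporal cluster CCD (acute diarrhoeal disease): an event triggers
  when ``threshold_count`` same-code signals arrive within ``window_hours``
  (a rolling window, 168 h = 7 days by default) and within ``radius_km``
  (20 km by default) of an *anchor* signal — the earliest not-yet-assigned
  signal about which the cluster forms.

The engine is deterministic and online: pushing signals one at a time yields
exactly the same events as processing the whole batch, and ties in arrival
time are broken by (timestamp, volunteer_id, report_id).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .ledger import (
    CCDDefinition,
    HealthEvent,
    Ledger,
    ParseStatus,
    RawReport,
    VerificationStatus,
    Volunteer,
)

__all__ = [
    "GeoPoint",
    "Signal",
    "ClusterWindow",
    "haversine_km",
    "AlertEngine",
    "evaluate_stream",
    "pending_notifications",
    "signals_from_ledger",
    "cluster_window_valid",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


class GeoPoint(BaseModel):
    """A WGS84 point in decimal degrees."""

    model_config = ConfigDict(frozen=True)

    latitude: float
    longitude: float

    @model_validator(mode="after")
    def _in_range(self) -> "GeoPoint":
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} out of range")
        return self


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in km (haversine formula).

    Symmetric, non-negative, and zero exactly for identical coordinates.
    """
    lat1, lon1 = math.radians(a.latitude), math.radians(a.longitude)
    lat2, lon2 = math.radians(b.latitude), math.radians(b.longitude)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = (math.sin(dlat / 2.0) ** 2
         + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass(frozen=True)
class Signal:
    """A parsed signal ready for threshold evaluation."""

    report_id: str
    volunteer_id: str
    received_at: datetime
    code: int
    location: GeoPoint

    @property
    def sort_key(self):
        return (_utc(self.received_at), self.volunteer_id, self.report_id)


@dataclass(frozen=True)
class ClusterWindow:
    """The anchor-based neighbourhood within which same-code signals count
    toward a cluster threshold."""

    anchor_id: str
    anchor_time: datetime
    anchor_location: GeoPoint
    member_ids: tuple[str, ...]
    window_hours: float = 168.0
    radius_km: float = 20.0
    threshold_count: int = 5


def _utc(ts: datetime) -> datetime:
    if ts.tzinfo is None:
        return ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _hours(a: datetime, b: datetime) -> float:
    return (_utc(a) - _utc(b)).total_seconds() / 3600.0


def cluster_window_valid(signals_by_id: dict, event: HealthEvent,
                         ccd: CCDDefinition) -> bool:
    """Re-validate an emitted cluster event against its CCD: every member is
    the same code, within the rolling window after the earliest member, and
    within the radius of the earliest member's location."""
    members = sorted(
        (signals_by_id[rid] for rid in event.member_report_ids),
        key=lambda s: s.sort_key,
    )
    anchor = members[0]
    if len(members) < ccd.threshold_count:
        return False
    for s in members:
        if s.code != event.code:
            return False
        if not 0.0 <= _hours(s.received_at, anchor.received_at) <= ccd.window_hours:
            return False
        if haversine_km(s.location, anchor.location) > ccd.radius_km:
            return False
    return True


@dataclass
class _OpenCluster:
    event_id: str
    ccd: CCDDefinition
    anchor: Signal
    members: list  # Signal, arrival order
    triggered_at: datetime


class AlertEngine:
    """Online threshold evaluator.

    Push signals in arrival order with :meth:`push`; completed state is
    queried with :meth:`events`.  A batch convenience wrapper is
    :func:`evaluate_stream`.  Signals are consumed by the event they trigger
    or join (one event membership per signal per code); later qualifying
    signals join an open cluster until it is verified (batch evaluation never
    verifies, so open clusters stay joinable).
    """

    def __init__(self, ccd_config: Sequence[CCDDefinition]):
        self.ccd_config = tuple(ccd_config)
        self._single_events: list[HealthEvent] = []
        self._open_clusters: list[_OpenCluster] = []
        self._unassigned: dict[int, list[Signal]] = {}
        self._last_key = None

    # -- config ----------------------------------------------------------
    def _ccd_for(self, code: int, at: datetime) -> CCDDefinition:
        for ccd in self.ccd_config:
            if ccd.code == code and ccd.active_at(_utc(at)):
                return ccd
        raise KeyError(
            f"no CCD configured for code {code} at {at.isoformat()}"
        )

    # -- online processing ------------------------------------------------
    def push(self, signal: Signal) -> None:
        key = signal.sort_key
        if self._last_key is not None and key < self._last_key:
            raise ValueError("signals must be pushed in arrival order")
        self._last_key = key
        ccd = self._ccd_for(signal.code, signal.received_at)

        if ccd.threshold_count == 1:
            self._single_events.append(HealthEvent(
                event_id=f"EV-{signal.code}-{signal.report_id}",
                code=signal.code,
                member_report_ids=(signal.report_id,),
                triggered_at=_utc(signal.received_at),
                anchor_latitude=signal.location.latitude,
                anchor_longitude=signal.location.longitude,
            ))
            return

        # join the earliest-anchored open cluster the signal qualifies for
        for oc in sorted(self._open_clusters,
                         key=lambda c: c.anchor.sort_key):
            if oc.ccd.code != signal.code:
                continue
            dt = _hours(signal.received_at, oc.anchor.received_at)
            if 0.0 <= dt <= oc.ccd.window_hours and haversine_km(
                    signal.location, oc.anchor.location) <= oc.ccd.radius_km:
                oc.members.append(signal)
                return

        # signals older than one window before the newest arrival are inert:
        # any cluster they could still belong to would be anchored even
        # earlier and can no longer grow, so they are dropped from the pool.
        pool = self._unassigned.setdefault(signal.code, [])
        cutoff_ok = [s for s in pool
                     if _hours(signal.received_at, s.received_at)
                     <= ccd.window_hours]
        if len(cutoff_ok) != len(pool):
            self._unassigned[signal.code] = cutoff_ok
        self._unassigned[signal.code].append(signal)
        self._scan(signal, ccd)

    def _scan(self, new_signal: Signal, ccd: CCDDefinition) -> None:
        """Anchor-greedy cluster formation over the unassigned pool.

        Anchors are tried in arrival order; the first anchor whose qualifying
        set reaches the threshold consumes that whole set as a new event.
        Only anchors whose neighbourhood admits the newest arrival can have
        changed since the previous scan, and at most one event can form per
        arrival (every candidate set contains the new signal, so consuming it
        drops all others back below threshold).
        """
        code = new_signal.code
        pool = self._unassigned.get(code, [])
        for anchor in sorted(pool, key=lambda s: s.sort_key):
            dt_new = _hours(new_signal.received_at, anchor.received_at)
            if not (0.0 <= dt_new <= ccd.window_hours):
                continue
            if haversine_km(new_signal.location, anchor.location) > ccd.radius_km:
                continue
            qualifying = [
                s for s in pool
                if 0.0 <= _hours(s.received_at, anchor.received_at)
                <= ccd.window_hours
                and haversine_km(s.location, anchor.location) <= ccd.radius_km
            ]
            if len(qualifying) >= ccd.threshold_count:
                qualifying.sort(key=lambda s: s.sort_key)
                trigger = qualifying[ccd.threshold_count - 1]
                self._open_clusters.append(_OpenCluster(
                    event_id=f"EV-{code}-{anchor.report_id}",
                    ccd=ccd,
                    anchor=anchor,
                    members=list(qualifying),
                    triggered_at=_utc(trigger.received_at),
                ))
                self._unassigned[code] = [
                    s for s in pool if s not in qualifying
                ]
                return

    # -- results ----------------------------------------------------------
    def events(self) -> list[HealthEvent]:
        """All events triggered so far, in (triggered_at, event_id) order."""
        out = list(self._single_events)
        for oc in self._open_clusters:
            out.append(HealthEvent(
                event_id=oc.event_id,
                code=oc.ccd.code,
                member_report_ids=tuple(s.report_id for s in oc.members),
                triggered_at=oc.triggered_at,
                anchor_latitude=oc.anchor.location.latitude,
                anchor_longitude=oc.anchor.location.longitude,
            ))
        out.sort(key=lambda e: (e.triggered_at, e.event_id))
        return out

    def unassigned(self) -> list[Signal]:
        return [s for pool in self._unassigned.values() for s in pool]


def evaluate_stream(signals: Iterable[Signal],
                    ccd_config: Sequence[CCDDefinition]) -> list[HealthEvent]:
    """Batch threshold evaluation: sort by (time, volunteer, report) and push
    through an :class:`AlertEngine`.  Equivalent to online processing."""
    engine = AlertEngine(ccd_config)
    for signal in sorted(signals, key=lambda s: s.sort_key):
        engine.push(signal)
    return engine.events()


@dataclass(frozen=True)
class PendingNotification:
    event_id: str
    triggered_at: datetime
    elapsed_hours: float
    breached_12h: bool


def pending_notifications(events: Iterable[HealthEvent], now: datetime,
                          sla_hours: float = 12.0) -> list[PendingNotification]:
    """Events still awaiting supervisor verification, with the elapsed time
    and whether the 12 h verification target is breached (elapsed > 12 h)."""
    now = _utc(now)
    out = []
    for e in events:
        if e.verification_status is not VerificationStatus.PENDING:
            continue
        elapsed = _hours(now, e.triggered_at)
        out.append(PendingNotification(
            event_id=e.event_id,
            triggered_at=e.triggered_at,
            elapsed_hours=elapsed,
            breached_12h=elapsed > sla_hours,
        ))
    out.sort(key=lambda n: (n.triggered_at, n.event_id))
    return out


def signals_from_ledger(reports: Iterable[RawReport],
                        volunteers: Iterable[Volunteer]) -> list[Signal]:
    """Pair signal reports with their volunteer's registered village point."""
    loc = {v.volunteer_id: GeoPoint(latitude=v.latitude, longitude=v.longitude)
           for v in volunteers}
    out = []
    for r in reports:
        if r.parse_status is not ParseStatus.SIGNAL:
            continue
        if r.volunteer_id not in loc:
            raise KeyError(f"report {r.report_id}: unknown volunteer")
        out.append(Signal(
            report_id=r.report_id,
            volunteer_id=r.volunteer_id,
            received_at=r.received_at,
            code=r.code,
            location=loc[r.volunteer_id],
        ))
    return out
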