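"""Domain types and the alert lifecycle state machine for community-based
surveillance (CBS).

The model mirrors how a CBS programme moves information:

    coded report -> signal -> health event (threshold reached)
                 -> supervisor verification (kept / dismissed)
                 -> alert escalated to the health authority
                 -> alert closed, with an outcome record in the event log.

All state lives in an immutable :class:`Ledger`.  Transition operations
(:func:`verify_event`, :func:`escalate_event`, :func:`close_alert`) are pure
functions returning a new ledger; every applied transition is appended to the
ledger's event log so a run can be replayed deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from typing import Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "CCDDefinition",
    "Volunteer",
    "RawReport",
    "HealthEvent",
    "Alert",
    "OutcomeRecord",
    "Ledger",
    "LedgerSummary",
    "ParseStatus",
    "VerificationStatus",
    "DismissalReason",
    "AlertStatus",
    "LedgerError",
    "UnknownEntityError",
    "InvalidTransitionError",
    "TimestampOrderError",
    "IntegrityError",
    "verify_event",
    "escalate_event",
    "close_alert",
    "summarize",
    "replay",
]


# ---------------------------------------------------------------------------
# errors

class LedgerError(Exception):
    """Base class for rejected ledger operations."""


class UnknownEntityError(LedgerError):
    """An id does not resolve to an entity in the ledger."""


class InvalidTransitionError(LedgerError):
    """The entity is not in a state that admits the requested transition."""


class TimestampOrderError(LedgerError):
    """A transition timestamp precedes the state it must follow."""


class IntegrityError(LedgerError):
    """A record violates a structural invariant."""


# ---------------------------------------------------------------------------
# enums

class ParseStatus(str, Enum):
    SIGNAL = "signal"
    ZERO = "zero"
    MALFORMED = "malformed"


class VerificationStatus(str, Enum):
    PENDING = "pending"
    KEPT = "kept"
    DISMISSED = "dismissed"


class DismissalReason(str, Enum):
    NOT_MATCHING_CCD = "not_matching_ccd"
    DUPLICATE = "duplicate"
    SENT_INCORRECTLY = "sent_incorrectly"
    NONE = "none"


class AlertStatus(str, Enum):
    ESCALATED = "escalated"
    CLOSED = "closed"
    DISMISSED_BY_AUTHORITIES = "dismissed_by_authorities"


# ---------------------------------------------------------------------------
# records

class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class CCDDefinition(_Frozen):
    """One configured health signal with its community case definition (CCD)
    and alert threshold.

    Single-report CCDs (``threshold_count == 1``) trigger one event per kept
    signal.  Multi-report CCDs additionally carry a temporal window and a
    spatial radius: the alert threshold is met when ``threshold_count``
    same-code signals fall within ``window_hours`` and ``radius_km`` of an
    anchor signal.
    """

    code: int
    name: str
    case_definition: str = ""
    target_events: str = ""
    threshold_count: int = 1
    window_hours: Optional[float] = None
    radius_km: Optional[float] = None
    # config versioning: the definition applies to signals with
    # valid_from <= t < valid_to (None = unbounded).
    valid_from: Optional[datetime] = None
    valid_to: Optional[datetime] = None

    @field_validator("code")
    @classmethod
    def _positive_code(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("signal code must be a positive integer")
        return v

    @model_validator(mode="after")
    def _threshold_consistency(self) -> "CCDDefinition":
        if self.threshold_count < 1:
            raise ValueError("threshold_count must be >= 1")
        clustered = self.threshold_count > 1
        has_window = self.window_hours is not None
        has_radius = self.radius_km is not None
        if clustered and not (has_window and has_radius):
            raise ValueError(
                "multi-report CCDs require both window_hours and radius_km"
            )
        if not clustered and (has_window or has_radius):
            raise ValueError(
                "single-report CCDs must not set window_hours or radius_km"
            )
        if has_window and self.window_hours <= 0:
            raise ValueError("window_hours must be positive")
        if has_radius and self.radius_km <= 0:
            raise ValueError("radius_km must be positive")
        return self

    def active_at(self, at: datetime) -> bool:
        if self.valid_from is not None and at < self.valid_from:
            return False
        if self.valid_to is not None and at >= self.valid_to:
            return False
        return True


class Volunteer(_Frozen):
    """A community health volunteer, registered with a static village-level
    coordinate (a random point within the village, not a household)."""

    volunteer_id: str
    village_id: str
    phone_token: str = ""
    latitude: float
    longitude: float
    active_from: datetime
    active_to: datetime

    @model_validator(mode="after")
    def _check(self) -> "Volunteer":
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError("longitude out of range")
        if not self.active_from < self.active_to:
            raise ValueError("active_from must precede active_to")
        return self


class RawReport(_Frozen):
    """One volunteer SMS-style submission, after classification."""

    report_id: str
    volunteer_id: str
    received_at: datetime
    payload: str
    parse_status: ParseStatus
    code: Optional[int] = None

    @model_validator(mode="after")
    def _code_iff_signal(self) -> "RawReport":
        if (self.parse_status is ParseStatus.SIGNAL) != (self.code is not None):
            raise ValueError("code must be present iff parse_status is signal")
        return self


class HealthEvent(_Frozen):
    """A group of signals that reached a CCD's alert threshold and awaits or
    underwent supervisor verification."""

    event_id: str
    code: int
    member_report_ids: tuple[str, ...]
    triggered_at: datetime
    anchor_latitude: float
    anchor_longitude: float
    verification_status: VerificationStatus = VerificationStatus.PENDING
    dismissal_reason: DismissalReason = DismissalReason.NONE
    verified_at: Optional[datetime] = None

    @model_validator(mode="after")
    def _check(self) -> "HealthEvent":
        if not self.member_report_ids:
            raise ValueError("an event must have at least one member signal")
        if self.verified_at is not None and self.verified_at < self.triggered_at:
            raise ValueError("verified_at precedes triggered_at")
        dismissed = self.verification_status is VerificationStatus.DISMISSED
        if dismissed != (self.dismissal_reason is not DismissalReason.NONE):
            raise ValueError("dismissal_reason set iff status is dismissed")
        return self


class OutcomeRecord(_Frozen):
    """What the event log records about an alert after investigation."""

    documented: bool = False
    action_taken: bool = False
    lab_confirmed: bool = False
    notes: str = ""

    @model_validator(mode="after")
    def _documented_implies(self) -> "OutcomeRecord":
        if (self.action_taken or self.lab_confirmed) and not self.documented:
            raise ValueError(
                "action_taken or lab_confirmed requires documented=True"
            )
        return self


class Alert(_Frozen):
    """A kept event escalated to the health authority."""

    alert_id: str
    event_id: str
    escalated_at: datetime
    status: AlertStatus = AlertStatus.ESCALATED
    closed_at: Optional[datetime] = None
    outcome: OutcomeRecord = OutcomeRecord()

    @model_validator(mode="after")
    def _check(self) -> "Alert":
        terminal = self.status in (
            AlertStatus.CLOSED,
            AlertStatus.DISMISSED_BY_AUTHORITIES,
        )
        if terminal and self.closed_at is None:
            raise ValueError("terminal alerts must carry closed_at")
        if self.closed_at is not None and self.closed_at < self.escalated_at:
            raise ValueError("closed_at precedes escalated_at")
        return self


class Ledger(_Frozen):
    """Immutable container for one region-period of CBS data.

    ``log`` is the append-only transition log: each entry records one applied
    operation, so :func:`replay` can rebuild the final state from the initial
    ledger.
    """

    region: str = ""
    period_start: Optional[datetime] = None
    period_end: Optional[datetime] = None
    ccd_config: tuple[CCDDefinition, ...] = ()
    volunteers: tuple[Volunteer, ...] = ()
    reports: tuple[RawReport, ...] = ()
    events: tuple[HealthEvent, ...] = ()
    alerts: tuple[Alert, ...] = ()
    log: tuple[dict, ...] = ()

    @model_validator(mode="after")
    def _referential_integrity(self) -> "Ledger":
        codes = [c.code for c in self.ccd_config]
        # codes unique within overlapping validity is enough; simple check here
        vol_ids = {v.volunteer_id for v in self.volunteers}
        report_by_id = {r.report_id: r for r in self.reports}
        if len(report_by_id) != len(self.reports):
            raise IntegrityError("duplicate report ids")
        event_ids = set()
        for r in self.reports:
            if vol_ids and r.volunteer_id not in vol_ids:
                raise IntegrityError(f"report {r.report_id}: unknown volunteer")
        for e in self.events:
            if e.event_id in event_ids:
                raise IntegrityError("duplicate event ids")
            event_ids.add(e.event_id)
            for rid in e.member_report_ids:
                rep = report_by_id.get(rid)
                if rep is None:
                    raise IntegrityError(
                        f"event {e.event_id}: unknown member report {rid}"
                    )
                if rep.parse_status is not ParseStatus.SIGNAL or rep.code != e.code:
                    raise IntegrityError(
                        f"event {e.event_id}: member {rid} is not a matching signal"
                    )
        seen_alert_ids = set()
        alerted_events = set()
        kept = {
            e.event_id
            for e in self.events
            if e.verification_status is VerificationStatus.KEPT
        }
        for a in self.alerts:
            if a.alert_id in seen_alert_ids:
                raise IntegrityError("duplicate alert ids")
            seen_alert_ids.add(a.alert_id)
            if a.event_id not in event_ids:
                raise IntegrityError(f"alert {a.alert_id}: unknown event")
            if a.event_id not in kept:
                raise IntegrityError(
                    f"alert {a.alert_id}: only kept events may carry an alert"
                )
            if a.event_id in alerted_events:
                raise IntegrityError(f"event {a.event_id}: multiple alerts")
            alerted_events.add(a.event_id)
        return self

    # convenience lookups -------------------------------------------------
    def event(self, event_id: str) -> HealthEvent:
        for e in self.events:
            if e.event_id == event_id:
                return e
        raise UnknownEntityError(f"unknown event_id {event_id!r}")

    def alert(self, alert_id: str) -> Alert:
        for a in self.alerts:
            if a.alert_id == alert_id:
                return a
        raise UnknownEntityError(f"unknown alert_id {alert_id!r}")

    def alert_for_event(self, event_id: str) -> Optional[Alert]:
        for a in self.alerts:
            if a.event_id == event_id:
                return a
        return None


# ---------------------------------------------------------------------------
# transitions

def _utc(ts: datetime) -> datetime:
    """Normalise to timezone-aware UTC; naive timestamps are taken as UTC."""
    if ts.tzinfo is None:
        return ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _replace_event(ledger: Ledger, new_event: HealthEvent,
                   log_entry: dict) -> Ledger:
    events = tuple(
        new_event if e.event_id == new_event.event_id else e
        for e in ledger.events
    )
    return ledger.model_copy(update={"events": events,
                                     "log": ledger.log + (log_entry,)})


def verify_event(ledger: Ledger, event_id: str, decision: str,
                 at: datetime,
                 reason: str | DismissalReason = DismissalReason.NONE) -> Ledger:
    """Record the supervisor's verification decision for a pending event.

    ``decision`` is ``"kept"`` or ``"dismissed"``; a dismissal must name a
    reason (not matching the CCD, duplicate, or sent incorrectly).  Supervisors
    are expected to verify within 12 h of the threshold being reached; the
    delay ``at - triggered_at`` feeds the timeliness metrics.
    """
    event = ledger.event(event_id)
    if event.verification_status is not VerificationStatus.PENDING:
        raise InvalidTransitionError(
            f"event {event_id} already {event.verification_status.value}"
        )
    at = _utc(at)
    if at < _utc(event.triggered_at):
        raise TimestampOrderError("verification precedes event trigger time")
    decision = VerificationStatus(decision)
    if decision not in (VerificationStatus.KEPT, VerificationStatus.DISMISSED):
        raise InvalidTransitionError("decision must be 'kept' or 'dismissed'")
    reason = DismissalReason(reason)
    if decision is VerificationStatus.DISMISSED:
        if reason is DismissalReason.NONE:
            raise InvalidTransitionError("a dismissal must carry a reason")
    elif reason is not DismissalReason.NONE:
        raise InvalidTransitionError("a kept event cannot carry a dismissal reason")
    new_event = event.model_copy(update={
        "verification_status": decision,
        "dismissal_reason": reason,
        "verified_at": at,
    })
    entry = {"op": "verify_event", "event_id": event_id,
             "decision": decision.value, "reason": reason.value,
             "at": at.isoformat()}
    return _replace_event(ledger, new_event, entry)


def escalate_event(ledger: Ledger, event_id: str, at: datetime) -> Ledger:
    """Escalate a kept event as an alert to the health authority."""
    event = ledger.event(event_id)
    if event.verification_status is not VerificationStatus.KEPT:
        raise InvalidTransitionError(
            f"cannot escalate a {event.verification_status.value} event"
        )
    if ledger.alert_for_event(event_id) is not None:
        raise InvalidTransitionError(f"event {event_id} already escalated")
    at = _utc(at)
    if event.verified_at is not None and at < _utc(event.verified_at):
        raise TimestampOrderError("escalation precedes verification")
    alert = Alert(alert_id=f"AL-{event_id}", event_id=event_id,
                  escalated_at=at, status=AlertStatus.ESCALATED)
    entry = {"op": "escalate_event", "event_id": event_id,
             "at": at.isoformat()}
    return ledger.model_copy(update={"alerts": ledger.alerts + (alert,),
                                     "log": ledger.log + (entry,)})


def close_alert(ledger: Ledger, alert_id: str, at: datetime,
                outcome: OutcomeRecord,
                dismissed_by_authorities: bool = False) -> Ledger:
    """Close an escalated alert, storing the outcome in the event log.

    When ``dismissed_by_authorities`` is set the alert ends in the distinct
    terminal status used when the authority found no disease; descriptive
    summaries count it within closed alerts.
    """
    alert = ledger.alert(alert_id)
    if alert.status is not AlertStatus.ESCALATED:
        raise InvalidTransitionError(
            f"cannot close an alert with status {alert.status.value}"
        )
    at = _utc(at)
    if at < _utc(alert.escalated_at):
        raise TimestampOrderError("closure precedes escalation")
    status = (AlertStatus.DISMISSED_BY_AUTHORITIES if dismissed_by_authorities
              else AlertStatus.CLOSED)
    new_alert = alert.model_copy(update={
        "status": status, "closed_at": at, "outcome": outcome,
    })
    alerts = tuple(new_alert if a.alert_id == alert_id else a
                   for a in ledger.alerts)
    entry = {"op": "close_alert", "alert_id": alert_id, "at": at.isoformat(),
             "dismissed_by_authorities": dismissed_by_authorities,
             "outcome": outcome.model_dump()}
    return ledger.model_copy(update={"alerts": alerts,
                                     "log": ledger.log + (entry,)})


def replay(initial: Ledger, log: Sequence[Mapping]) -> Ledger:
    """Re-apply an ordered transition log to an initial ledger.

    Applying the same log to the same initial state always yields an
    identical final ledger (replay determinism).
    """
    ledger = initial
    for entry in log:
        op = entry["op"]
        at = datetime.fromisoformat(entry["at"])
        if op == "verify_event":
            ledger = verify_event(ledger, entry["event_id"],
                                  entry["decision"], at,
                                  reason=entry.get("reason", "none"))
        elif op == "escalate_event":
            ledger = escalate_event(ledger, entry["event_id"], at)
        elif op == "close_alert":
            ledger = close_alert(
                ledger, entry["alert_id"], at,
                OutcomeRecord(**entry["outcome"]),
                dismissed_by_authorities=entry["dismissed_by_authorities"],
            )
        else:
            raise LedgerError(f"unknown log operation {op!r}")
    return ledger


# ---------------------------------------------------------------------------
# summary

@dataclass
class LedgerSummary:
    """Exact counts over one ledger — every quantity the attribute metrics
    (usefulness, simplicity, data quality, sensitivity, timeliness) consume."""

    # reports
    reports_total: int = 0
    reports_correct_format: int = 0
    reports_malformed: int = 0
    reports_zero: int = 0
    signals_sent: int = 0
    # signal-level verification (membership in verified / kept events)
    signals_verified: int = 0
    signals_kept: int = 0
    # events
    events_triggered: int = 0
    events_kept: int = 0
    events_dismissed_by_supervisor: int = 0
    events_pending: int = 0
    dismissal_reasons: dict = field(default_factory=dict)
    # alerts
    alerts_escalated: int = 0
    alerts_closed: int = 0                  # includes dismissed_by_authorities
    alerts_dismissed_by_authorities: int = 0
    alerts_open: int = 0
    alerts_documented_outcome: int = 0
    alerts_action_taken: int = 0
    alerts_lab_confirmed: int = 0
    escalated_by_code: dict = field(default_factory=dict)
    # timeliness
    verified_within_12h: int = 0
    verified_within_24h: int = 0
    closed_within_48h: int = 0
    verification_delays_h: list = field(default_factory=list)
    closure_delays_h: list = field(default_factory=list)
    # weekly presence: (volunteer_id, iso_year, iso_week) -> report count
    weekly_presence: dict = field(default_factory=dict)


def summarize(ledger: Ledger) -> LedgerSummary:
    """Count every quantity the system-attribute metrics need.

    All counts are exact set cardinalities; delay comparisons use closed
    upper bounds (a delay of exactly 12 h counts as within 12 h).
    """
    s = LedgerSummary()
    for r in ledger.reports:
        s.reports_total += 1
        if r.parse_status is ParseStatus.MALFORMED:
            s.reports_malformed += 1
        else:
            s.reports_correct_format += 1
        if r.parse_status is ParseStatus.ZERO:
            s.reports_zero += 1
        elif r.parse_status is ParseStatus.SIGNAL:
            s.signals_sent += 1
        iso = _utc(r.received_at).isocalendar()
        key = (r.volunteer_id, iso.year, iso.week)
        s.weekly_presence[key] = s.weekly_presence.get(key, 0) + 1

    event_by_id = {}
    for e in ledger.events:
        event_by_id[e.event_id] = e
        s.events_triggered += 1
        if e.verification_status is VerificationStatus.KEPT:
            s.events_kept += 1
        elif e.verification_status is VerificationStatus.DISMISSED:
            s.events_dismissed_by_supervisor += 1
            reason = e.dismissal_reason.value
            s.dismissal_reasons[reason] = s.dismissal_reasons.get(reason, 0) + 1
        else:
            s.events_pending += 1
        if e.verification_status is not VerificationStatus.PENDING:
            s.signals_verified += len(e.member_report_ids)
            if e.verification_status is VerificationStatus.KEPT:
                s.signals_kept += len(e.member_report_ids)
        if e.verified_at is not None:
            delay = (_utc(e.verified_at) - _utc(e.triggered_at)).total_seconds() / 3600.0
            s.verification_delays_h.append(delay)
            if delay <= 12.0:
                s.verified_within_12h += 1
            if delay <= 24.0:
                s.verified_within_24h += 1

    for a in ledger.alerts:
        s.alerts_escalated += 1
        code = event_by_id[a.event_id].code
        s.escalated_by_code[code] = s.escalated_by_code.get(code, 0) + 1
        if a.status is AlertStatus.ESCALATED:
            s.alerts_open += 1
            continue
        s.alerts_closed += 1
        if a.status is AlertStatus.DISMISSED_BY_AUTHORITIES:
            s.alerts_dismissed_by_authorities += 1
        if a.outcome.documented:
            s.alerts_documented_outcome += 1
        if a.outcome.action_taken:
            s.alerts_action_taken += 1
        if a.outcome.lab_confirmed:
            s.alerts_lab_confirmed += 1
        if a.closed_at is not None:
            delay = (_utc(a.closed_at) - _utc(a.escalated_at)).total_seconds() / 3600.0
            s.closure_delays_h.append(delay)
            if delay <= 48.0:
                s.closed_within_48h += 1

    assert s.events_kept + s.events_dismissed_by_supervisor + s.events_pending \
        == s.events_triggered
    return s
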