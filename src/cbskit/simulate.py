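"""Synthetic CBS programmes.

Two generators live here:

* :func:`simulate_programme` — a stochastic generator with the statistical
  structure of a real volunteer programme: weekly zero-report compliance,
  malformed submissions, per-code background signal rates, injected
  spatiotemporal outbreak clusters, supervisor verification delays and
  dismissals, escalation, closure delays, and outcome documentation.
  Background signals are spatially dispersed over the village set, so
  clustering arises (essentially) only through injections — which keeps
  detection recall and false-alarm behaviour separately testable.

* :func:`fixture_from_marginals` — a deterministic constructor that lays a
  ledger out on an hourly grid so that :func:`~cbskit.ledger.summarize`
  reproduces a given set of marginal counts *exactly*.  The packaged
  :data:`AWDAL_MARGINALS` and :data:`TOGDHEER_MARGINALS` carry the 2021
  descriptive counts of the two evaluated regions.

:func:`parameter_recovery_report` closes the loop: simulate at configured
rates, push the ledger through the metrics, and report how far the
estimates sit from the rates that generated them.
"""

from __future__ import annotations

import math
from datetime import date, datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .config import CLUSTER_CODE, default_ccd_config, default_dialect
from .engine import GeoPoint, evaluate_stream, haversine_km, signals_from_ledger
from .ingest import DialectConfig, iso_weeks, parse_report, weekly_completeness
from .ledger import (
    CCDDefinition,
    DismissalReason,
    Ledger,
    OutcomeRecord,
    RawReport,
    Volunteer,
    close_alert,
    escalate_event,
    summarize,
    verify_event,
)

__all__ = [
    "OutbreakSpec",
    "SimConfig",
    "simulate_programme",
    "FixtureSpec",
    "fixture_from_marginals",
    "AWDAL_MARGINALS",
    "TOGDHEER_MARGINALS",
    "parameter_recovery_report",
    "implied_weekly_completeness",
]

UTC = timezone.utc


def _utc(ts: datetime) -> datetime:
    if ts.tzinfo is None:
        return ts.replace(tzinfo=UTC)
    return ts.astimezone(UTC)


# ---------------------------------------------------------------------------
# stochastic generator

class OutbreakSpec(BaseModel):
    """One injected spatiotemporal cluster of signals.

    With ``spread_km`` at most half the cluster radius and ``spread_h``
    within the rolling window, every injected outbreak of at least the
    threshold size satisfies the cluster CCD about its earliest signal by
    construction (triangle inequality on the epicentre).
    """

    model_config = ConfigDict(frozen=True)

    code: int = CLUSTER_CODE
    start: datetime
    epicentre_lat: float
    epicentre_lon: float
    n_signals: int = 8
    spread_km: float = 10.0
    spread_h: float = 72.0

    @model_validator(mode="after")
    def _check(self) -> "OutbreakSpec":
        if self.n_signals < 1:
            raise ValueError("n_signals must be >= 1")
        if not 0.0 < self.spread_km <= 10.0:
            raise ValueError("spread_km must be in (0, 10] (half the 20 km radius)")
        if not 0.0 < self.spread_h <= 168.0:
            raise ValueError("spread_h must be in (0, 168] hours")
        return self


def _prob(v: float) -> float:
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"probability {v} outside [0, 1]")
    return v


class SimConfig(BaseModel):
    """Parameters of one synthetic programme.

    Default rates follow the conditions reported for the evaluated 2021
    programmes: weekly zero-report compliance around two thirds, a few
    percent of malformed submissions, three quarters of events verified
    within 12 h, two thirds of alerts closed within 48 h, and roughly
    three-fifths of closed alerts with a documented outcome.
    """

    model_config = ConfigDict(frozen=True)

    region: str = "synthetic"
    n_villages: int = 50
    volunteers_per_village: int = 2
    lat_range: tuple[float, float] = (8.0, 11.0)
    lon_range: tuple[float, float] = (43.0, 47.0)
    period_start: datetime = datetime(2021, 1, 1, tzinfo=UTC)
    period_end: datetime = datetime(2021, 12, 31, 23, 59, tzinfo=UTC)
    weekly_zero_report_prob: float = 0.66
    malformed_prob: float = 0.03
    background_signal_rate: dict[int, float] = {
        2: 0.035, 4: 0.007, 9: 0.011, 14: 0.0005,
    }
    outbreaks: tuple[OutbreakSpec, ...] = ()
    verify_within_12h_prob: float = 0.75
    verify_tail_sigma: float = 0.8
    dismissal_prob: float = 0.17
    dismissal_reason_probs: dict[str, float] = {
        "not_matching_ccd": 0.7, "duplicate": 0.15, "sent_incorrectly": 0.15,
    }
    close_within_48h_prob: float = 0.67
    close_tail_sigma: float = 0.8
    dismissed_by_authorities_prob: float = 0.09
    documented_prob: float = 0.63
    action_given_documented_prob: float = 0.85
    lab_given_action_prob: float = 0.11
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.n_villages < 1 or self.volunteers_per_village < 1:
            raise ValueError("need at least one village and one volunteer per village")
        for name in ("weekly_zero_report_prob", "malformed_prob",
                     "verify_within_12h_prob", "dismissal_prob",
                     "close_within_48h_prob", "dismissed_by_authorities_prob",
                     "documented_prob", "action_given_documented_prob",
                     "lab_given_action_prob"):
            _prob(getattr(self, name))
        for code, rate in self.background_signal_rate.items():
            if rate < 0:
                raise ValueError(f"background rate for code {code} is negative")
            _prob(rate)  # Bernoulli per volunteer-week
        if abs(sum(self.dismissal_reason_probs.values()) - 1.0) > 1e-9:
            raise ValueError("dismissal_reason_probs must sum to 1")
        if self.lat_range[0] >= self.lat_range[1] or self.lon_range[0] >= self.lon_range[1]:
            raise ValueError("coordinate ranges must be increasing")
        if _utc(self.period_start) >= _utc(self.period_end):
            raise ValueError("period_start must precede period_end")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        return self


def implied_weekly_completeness(config: SimConfig) -> float:
    """The weekly-presence probability the configuration implies: a
    volunteer-week is present when the zero report is sent or at least one
    background signal occurs (injections excluded)."""
    p_absent = 1.0 - config.weekly_zero_report_prob
    for rate in config.background_signal_rate.values():
        p_absent *= 1.0 - rate
    return 1.0 - p_absent


def _week_spans(start: datetime, end: datetime) -> list[tuple[datetime, datetime]]:
    """UTC datetime span of every ISO week intersected with the period."""
    spans = []
    start, end = _utc(start), _utc(end)
    for (year, week) in iso_weeks(start, end):
        monday = datetime.combine(date.fromisocalendar(year, week, 1),
                                  datetime.min.time(), tzinfo=UTC)
        w_start = max(monday, start)
        w_end = min(monday + timedelta(days=7), end)
        spans.append((w_start, w_end))
    return spans


def simulate_programme(config: SimConfig) -> Ledger:
    """Generate a full synthetic programme ledger.

    Reproducible: identical (config, seed) yields an identical ledger,
    asserted on serialised bytes in the test suite.
    """
    rng = np.random.default_rng(config.seed)
    ccds = default_ccd_config()
    known_codes = {c.code for c in ccds}
    for code in config.background_signal_rate:
        if code not in known_codes:
            raise ValueError(f"background rate for unconfigured code {code}")
    dialect = default_dialect()

    # roster ------------------------------------------------------------
    start, end = _utc(config.period_start), _utc(config.period_end)
    volunteers = []
    vol_points = []
    for v_idx in range(config.n_villages):
        lat = float(rng.uniform(*config.lat_range))
        lon = float(rng.uniform(*config.lon_range))
        for k in range(config.volunteers_per_village):
            vid = f"V{len(volunteers):04d}"
            volunteers.append(Volunteer(
                volunteer_id=vid,
                village_id=f"G{v_idx:03d}",
                phone_token=f"tok{len(volunteers):04d}",
                latitude=lat, longitude=lon,
                active_from=start, active_to=end,
            ))
            vol_points.append(GeoPoint(latitude=lat, longitude=lon))

    # weekly reporting ---------------------------------------------------
    spans = _week_spans(start, end)
    raw = []  # (time, seq, volunteer_id, payload, protected)
    seq = 0
    codes_sorted = sorted(config.background_signal_rate)
    for vol in volunteers:
        for (w_start, w_end) in spans:
            span_h = (w_end - w_start).total_seconds() / 3600.0
            if rng.random() < config.weekly_zero_report_prob:
                t = w_start + timedelta(hours=float(rng.uniform(0, span_h)))
                raw.append((t, seq, vol.volunteer_id, dialect.zero_token, False))
                seq += 1
            for code in codes_sorted:
                if rng.random() < config.background_signal_rate[code]:
                    t = w_start + timedelta(hours=float(rng.uniform(0, span_h)))
                    raw.append((t, seq, vol.volunteer_id, str(code), False))
                    seq += 1

    # injected outbreaks -------------------------------------------------
    for ob in config.outbreaks:
        epi = GeoPoint(latitude=ob.epicentre_lat, longitude=ob.epicentre_lon)
        dists = [haversine_km(p, epi) for p in vol_points]
        near = [i for i, d in enumerate(dists) if d <= ob.spread_km]
        if not near:
            # no village inside the spread: all members come from the single
            # nearest village, keeping pairwise distances zero
            nearest = min(range(len(dists)), key=lambda i: (dists[i], i))
            vill = volunteers[nearest].village_id
            near = [i for i, v in enumerate(volunteers) if v.village_id == vill]
        offsets = np.sort(rng.uniform(0.0, ob.spread_h, size=ob.n_signals))
        picks = rng.integers(0, len(near), size=ob.n_signals)
        for off, pick in zip(offsets, picks):
            vol = volunteers[near[int(pick)]]
            t = _utc(ob.start) + timedelta(hours=float(off))
            raw.append((t, seq, vol.volunteer_id, str(ob.code), True))
            seq += 1

    # malformed corruption (injected outbreak reports are exempt so the
    # constructed clusters stay intact)
    reports = []
    raw.sort(key=lambda item: (item[0], item[2], item[1]))
    for i, (t, _, vid, payload, protected) in enumerate(raw):
        if not protected and rng.random() < config.malformed_prob:
            payload = "##"
        reports.append(parse_report(payload, t, vid, dialect,
                                    report_id=f"R{i:05d}"))

    # threshold evaluation ------------------------------------------------
    events = evaluate_stream(signals_from_ledger(reports, volunteers), ccds)
    ledger = Ledger(
        region=config.region, period_start=start, period_end=end,
        ccd_config=ccds, volunteers=tuple(volunteers),
        reports=tuple(reports), events=tuple(events),
    )

    # verification, escalation, closure -----------------------------------
    reasons = sorted(config.dismissal_reason_probs)
    reason_p = np.array([config.dismissal_reason_probs[r] for r in reasons])
    reason_p = reason_p / reason_p.sum()
    for event in sorted(events, key=lambda e: (e.triggered_at, e.event_id)):
        if rng.random() < config.verify_within_12h_prob:
            delay = float(rng.uniform(0.0, 12.0))
        else:
            delay = 12.0 + float(rng.lognormal(mean=math.log(12.0),
                                               sigma=config.verify_tail_sigma))
        verified_at = _utc(event.triggered_at) + timedelta(hours=delay)
        if rng.random() < config.dismissal_prob:
            reason = reasons[int(rng.choice(len(reasons), p=reason_p))]
            ledger = verify_event(ledger, event.event_id, "dismissed",
                                  verified_at, reason=reason)
            continue
        ledger = verify_event(ledger, event.event_id, "kept", verified_at)
        ledger = escalate_event(ledger, event.event_id, verified_at)
        alert = ledger.alert_for_event(event.event_id)
        if rng.random() < config.close_within_48h_prob:
            c_delay = float(rng.uniform(0.0, 48.0))
        else:
            c_delay = 48.0 + float(rng.lognormal(mean=math.log(24.0),
                                                 sigma=config.close_tail_sigma))
        closed_at = verified_at + timedelta(hours=c_delay)
        if rng.random() < config.dismissed_by_authorities_prob:
            ledger = close_alert(ledger, alert.alert_id, closed_at,
                                 OutcomeRecord(), dismissed_by_authorities=True)
            continue
        documented = rng.random() < config.documented_prob
        action = documented and rng.random() < config.action_given_documented_prob
        lab = action and rng.random() < config.lab_given_action_prob
        ledger = close_alert(ledger, alert.alert_id, closed_at,
                             OutcomeRecord(documented=documented,
                                           action_taken=action,
                                           lab_confirmed=lab))
    return ledger


# ---------------------------------------------------------------------------
# deterministic fixtures from marginal counts

class FixtureSpec(BaseModel):
    """The marginal counts of one region-period, to be realised exactly."""

    model_config = ConfigDict(frozen=True)

    region: str
    events_triggered: int
    alerts_escalated: int
    events_dismissed_by_supervisor: int
    escalated_by_code: dict[int, int]
    alerts_closed: int
    alerts_dismissed_by_authorities: int
    alerts_documented_outcome: int
    alerts_action_taken: int
    alerts_lab_confirmed: int
    reports_total: int
    reports_correct_format: int
    signals_sent: int
    signals_verified: int
    signals_kept: int
    verified_within_12h: int
    verified_within_24h: int
    closed_within_48h: int

    @model_validator(mode="after")
    def _consistent(self) -> "FixtureSpec":
        def require(ok: bool, inequality: str) -> None:
            if not ok:
                raise ValueError(f"inconsistent fixture spec: {inequality}")

        s = self
        require(s.alerts_escalated + s.events_dismissed_by_supervisor
                == s.events_triggered,
                "escalated + dismissed_by_supervisor == events_triggered")
        require(sum(s.escalated_by_code.values()) == s.alerts_escalated,
                "sum(escalated_by_code) == alerts_escalated")
        require(s.alerts_closed <= s.alerts_escalated,
                "alerts_closed <= alerts_escalated")
        require(s.alerts_dismissed_by_authorities <= s.alerts_closed,
                "dismissed_by_authorities <= alerts_closed")
        require(s.alerts_documented_outcome + s.alerts_dismissed_by_authorities
                <= s.alerts_closed,
                "documented_outcome + dismissed_by_authorities <= alerts_closed")
        require(s.alerts_action_taken <= s.alerts_documented_outcome,
                "action_taken <= documented_outcome")
        require(s.alerts_lab_confirmed <= s.alerts_action_taken,
                "lab_confirmed <= action_taken")
        require(s.verified_within_12h <= s.verified_within_24h,
                "verified_within_12h <= verified_within_24h")
        require(s.verified_within_24h <= s.events_triggered,
                "verified_within_24h <= events_triggered")
        require(s.closed_within_48h <= s.alerts_closed,
                "closed_within_48h <= alerts_closed")
        require(s.reports_correct_format <= s.reports_total,
                "reports_correct_format <= reports_total")
        require(s.signals_sent <= s.reports_correct_format,
                "signals_sent <= reports_correct_format")
        require(s.signals_verified <= s.signals_sent,
                "signals_verified <= signals_sent")
        require(s.signals_kept <= s.signals_verified,
                "signals_kept <= signals_verified")
        # member-signal budgets under the CCD thresholds
        cluster_kept = s.escalated_by_code.get(CLUSTER_CODE, 0)
        single_kept = s.alerts_escalated - cluster_kept
        require(single_kept + 5 * cluster_kept <= s.signals_kept,
                "signals_kept >= kept singles + 5 * kept clusters")
        if cluster_kept == 0:
            require(s.signals_kept == single_kept,
                    "signals_kept == kept single-report events "
                    "(no cluster events to absorb extras)")
        excess = (s.signals_verified - s.signals_kept) \
            - s.events_dismissed_by_supervisor
        require(excess >= 0,
                "dismissed signals >= dismissed events")
        if excess > 0:
            require(excess >= 4 and s.events_dismissed_by_supervisor >= 1,
                    "extra dismissed signals require a dismissed cluster "
                    "event (adds at least 4 signals)")
        return self


AWDAL_MARGINALS = FixtureSpec(
    region="Awdal",
    events_triggered=138,
    alerts_escalated=115,
    events_dismissed_by_supervisor=23,
    escalated_by_code={9: 53, 4: 31, 2: 29, 14: 2},
    alerts_closed=115,
    alerts_dismissed_by_authorities=10,
    alerts_documented_outcome=72,
    alerts_action_taken=61,
    alerts_lab_confirmed=0,
    reports_total=4318,
    reports_correct_format=4144,
    signals_sent=395,
    signals_verified=331,
    signals_kept=295,
    verified_within_12h=104,
    verified_within_24h=116,
    closed_within_48h=77,
)

TOGDHEER_MARGINALS = FixtureSpec(
    region="Togdheer",
    events_triggered=218,
    alerts_escalated=213,
    events_dismissed_by_supervisor=5,
    escalated_by_code={9: 122, 4: 35, 2: 44, 14: 12},
    alerts_closed=213,
    alerts_dismissed_by_authorities=2,
    alerts_documented_outcome=136,
    alerts_action_taken=133,
    alerts_lab_confirmed=15,
    reports_total=5243,
    reports_correct_format=5210,
    signals_sent=548,
    signals_verified=507,
    signals_kept=502,
    verified_within_12h=202,
    verified_within_24h=212,
    closed_within_48h=161,
)


def _site(i: int) -> tuple[float, float]:
    """Deterministic, mutually distant locations (>= 70 km apart) so that
    distinct events can never contaminate each other's cluster windows."""
    return (-40.0 + (i // 200) * 1.0, -150.0 + (i % 200) * 1.0)


def fixture_from_marginals(spec: FixtureSpec) -> Ledger:
    """Materialise a ledger whose :func:`~cbskit.ledger.summarize` output
    reproduces every count in ``spec`` exactly.

    No randomness is involved: events sit on an hourly grid, cluster-event
    members share a site well inside the 20 km radius, sub-threshold signals
    each occupy their own isolated site and week, and verification / closure
    delays are placed on the relevant side of each 12 h / 24 h / 48 h cut.
    """
    t0 = datetime(2021, 1, 4, 9, 0, tzinfo=UTC)  # first Monday of 2021
    period_start = datetime(2021, 1, 1, tzinfo=UTC)
    period_end = datetime(2021, 12, 31, 23, 59, tzinfo=UTC)
    ccds = default_ccd_config()
    threshold = next(c.threshold_count for c in ccds if c.code == CLUSTER_CODE)

    # --- plan event sizes -------------------------------------------------
    # kept events, grouped by code (ascending); cluster events absorb the
    # extra kept signals beyond one-per-single and threshold-per-cluster
    kept_plan: list[tuple[int, int]] = []  # (code, n_members)
    cluster_kept = spec.escalated_by_code.get(CLUSTER_CODE, 0)
    single_kept = spec.alerts_escalated - cluster_kept
    extra = spec.signals_kept - single_kept - threshold * cluster_kept
    cluster_sizes = [threshold] * cluster_kept
    for j in range(extra):
        cluster_sizes[j % cluster_kept] += 1
    for code in sorted(spec.escalated_by_code):
        n_events = spec.escalated_by_code[code]
        if code == CLUSTER_CODE:
            kept_plan += [(code, size) for size in cluster_sizes]
        else:
            kept_plan += [(code, 1)] * n_events

    # dismissed events: singles, plus one cluster event absorbing any excess
    dismissed_signals = spec.signals_verified - spec.signals_kept
    excess = dismissed_signals - spec.events_dismissed_by_supervisor
    dismissed_plan: list[tuple[int, int]] = []
    if excess > 0:
        dismissed_plan.append((CLUSTER_CODE, threshold + (excess - 4)))
        dismissed_plan += [(4, 1)] * (spec.events_dismissed_by_supervisor - 1)
    else:
        dismissed_plan += [(4, 1)] * spec.events_dismissed_by_supervisor

    event_plan = kept_plan + dismissed_plan  # index order = event order
    assert len(event_plan) == spec.events_triggered

    # --- lay out reports, volunteers, events ------------------------------
    from .ledger import HealthEvent, ParseStatus, VerificationStatus

    volunteers: list[Volunteer] = []
    reports: list[RawReport] = []
    events: list[HealthEvent] = []

    def new_volunteer(lat: float, lon: float, village: str) -> Volunteer:
        vol = Volunteer(
            volunteer_id=f"V{len(volunteers):04d}",
            village_id=village,
            phone_token=f"tok{len(volunteers):04d}",
            latitude=lat, longitude=lon,
            active_from=period_start, active_to=period_end,
        )
        volunteers.append(vol)
        return vol

    def new_report(t: datetime, vol: Volunteer, payload: str,
                   status: ParseStatus, code: Optional[int]) -> RawReport:
        rep = RawReport(
            report_id=f"R{len(reports):05d}",
            volunteer_id=vol.volunteer_id,
            received_at=t, payload=payload,
            parse_status=status, code=code,
        )
        reports.append(rep)
        return rep

    site = 0
    for idx, (code, n_members) in enumerate(event_plan):
        lat, lon = _site(site)
        village = f"S{site:03d}"
        site += 1
        triggered = t0 + timedelta(hours=idx)
        member_ids = []
        for j in range(n_members):
            t = triggered - timedelta(minutes=5 * (n_members - 1 - j))
            vol = new_volunteer(lat + 0.001 * j, lon, village)
            rep = new_report(t, vol, str(code), ParseStatus.SIGNAL, code)
            member_ids.append(rep.report_id)
        events.append(HealthEvent(
            event_id=f"E{idx:03d}", code=code,
            member_report_ids=tuple(member_ids),
            triggered_at=triggered,
            anchor_latitude=lat, anchor_longitude=lon,
        ))

    # sub-threshold cluster-code signals: isolated in space and time
    n_unassigned = spec.signals_sent - sum(n for _, n in event_plan)
    for k in range(n_unassigned):
        lat, lon = _site(site)
        vol = new_volunteer(lat, lon, f"S{site:03d}")
        site += 1
        t = t0 + timedelta(days=60, hours=50 * k)
        new_report(t, vol, str(CLUSTER_CODE), ParseStatus.SIGNAL, CLUSTER_CODE)

    # zero reports and malformed reports, spread over the year
    n_malformed = spec.reports_total - spec.reports_correct_format
    n_zero = spec.reports_correct_format - spec.signals_sent
    n_vol = len(volunteers)
    for k in range(n_zero):
        vol = volunteers[k % n_vol]
        t = period_start + timedelta(days=7 * (k // n_vol),
                                     minutes=k % n_vol)
        new_report(t, vol, "0", ParseStatus.ZERO, None)
    for k in range(n_malformed):
        vol = volunteers[k % n_vol]
        t = period_start + timedelta(days=7 * (k // n_vol),
                                     minutes=k % n_vol, seconds=30)
        new_report(t, vol, "##", ParseStatus.MALFORMED, None)

    ledger = Ledger(
        region=spec.region,
        period_start=period_start, period_end=period_end,
        ccd_config=ccds,
        volunteers=tuple(volunteers),
        reports=tuple(reports),
        events=tuple(events),
    )

    # --- drive the lifecycle through the state machine ---------------------
    # verification delays by event index: 6 h | 18 h | 30 h around the cuts
    for idx, event in enumerate(events):
        if idx < spec.verified_within_12h:
            delay = 6.0
        elif idx < spec.verified_within_24h:
            delay = 18.0
        else:
            delay = 30.0
        at = event.triggered_at + timedelta(hours=delay)
        if idx < len(kept_plan):
            ledger = verify_event(ledger, event.event_id, "kept", at)
        else:
            ledger = verify_event(ledger, event.event_id, "dismissed", at,
                                  reason=DismissalReason.NOT_MATCHING_CCD)

    # escalate every kept event; close per the marginal counts
    n_kept = len(kept_plan)
    dba_start = spec.alerts_closed - spec.alerts_dismissed_by_authorities
    for idx in range(n_kept):
        event_id = f"E{idx:03d}"
        escalated_at = ledger.event(event_id).verified_at
        ledger = escalate_event(ledger, event_id, escalated_at)
        if idx >= spec.alerts_closed:
            continue  # stays escalated (open)
        close_delay = 24.0 if idx < spec.closed_within_48h else 72.0
        closed_at = escalated_at + timedelta(hours=close_delay)
        if idx >= dba_start:
            ledger = close_alert(ledger, f"AL-{event_id}", closed_at,
                                 OutcomeRecord(),
                                 dismissed_by_authorities=True)
            continue
        documented = idx < spec.alerts_documented_outcome
        action = idx < spec.alerts_action_taken
        lab = idx < spec.alerts_lab_confirmed
        ledger = close_alert(ledger, f"AL-{event_id}", closed_at,
                             OutcomeRecord(documented=documented,
                                           action_taken=action,
                                           lab_confirmed=lab))
    return ledger


# ---------------------------------------------------------------------------
# parameter recovery

_RATE_ROWS = (
    "weekly_completeness",
    "correct_format",
    "verified_within_12h",
    "closed_within_48h",
    "documented_outcome",
)


def parameter_recovery_report(config: SimConfig,
                              n_replicates: int) -> pd.DataFrame:
    """Simulate ``n_replicates`` programmes and compare each estimated rate
    with the value the configuration implies.

    Each rate is an indicator average, so the natural yardstick is the
    exact binomial standard error at the configured rate over the pooled
    denominator.  Returns a frame with one row per rate: ``configured``,
    ``mean_estimate`` (mean of per-replicate fractions), ``sd`` (their
    spread), ``pooled_estimate`` and ``n`` (pooled counts across
    replicates), ``se`` (binomial SE of the pooled estimate at the
    configured rate) and ``z`` (pooled deviation in SE units).  With
    outbreak injections present the correct-format and completeness
    comparisons are approximate (injected reports are exempt from
    corruption); recovery configs normally leave ``outbreaks`` empty.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    configured = {
        "weekly_completeness": implied_weekly_completeness(config),
        "correct_format": 1.0 - config.malformed_prob,
        "verified_within_12h": config.verify_within_12h_prob,
        "closed_within_48h": config.close_within_48h_prob,
        "documented_outcome": (config.documented_prob
                               * (1.0 - config.dismissed_by_authorities_prob)),
    }
    fractions: dict[str, list[float]] = {k: [] for k in _RATE_ROWS}
    num: dict[str, int] = {k: 0 for k in _RATE_ROWS}
    den: dict[str, int] = {k: 0 for k in _RATE_ROWS}

    def tally(name: str, numerator: int, denominator: int) -> None:
        num[name] += numerator
        den[name] += denominator
        fractions[name].append(
            numerator / denominator if denominator else np.nan)

    for i in range(n_replicates):
        seed_i = (config.seed + 1_000_003 * i) % (2**31 - 1)
        ledger = simulate_programme(config.model_copy(update={"seed": seed_i}))
        s = summarize(ledger)
        wc = weekly_completeness(ledger.reports, ledger.volunteers,
                                 ledger.period_start, ledger.period_end)
        present = int(round(float((wc.weekly * wc.denominators).fillna(0).sum())))
        tally("weekly_completeness", present, int(wc.denominators.sum()))
        tally("correct_format", s.reports_correct_format, s.reports_total)
        tally("verified_within_12h", s.verified_within_12h, s.events_triggered)
        tally("closed_within_48h", s.closed_within_48h, s.alerts_closed)
        tally("documented_outcome", s.alerts_documented_outcome, s.alerts_closed)

    rows = []
    for name in _RATE_ROWS:
        vals = np.asarray(fractions[name], dtype=float)
        p0 = configured[name]
        pooled = num[name] / den[name] if den[name] else float("nan")
        se = math.sqrt(p0 * (1.0 - p0) / den[name]) if den[name] else float("nan")
        if se > 0:
            z = (pooled - p0) / se
        else:
            z = 0.0 if pooled == p0 else float("inf")
        rows.append({
            "rate": name,
            "configured": p0,
            "mean_estimate": float(np.nanmean(vals)),
            "sd": float(np.nanstd(vals, ddof=1)),
            "pooled_estimate": pooled,
            "n": den[name],
            "se": se,
            "z": z,
        })
    return pd.DataFrame(rows).set_index("rate")
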