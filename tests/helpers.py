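"""Independent oracles used by the test suite.

Everything here is deliberately written from scratch, without reusing the
package's engine internals: a second distance formula (spherical law of
cosines) and a plain O(n^2) re-implementation of the anchor-greedy cluster
rule that keeps no incremental state and applies no pruning.
"""

from __future__ import annotations

import math
from datetime import datetime, timedelta, timezone

UTC = timezone.utc
R_EARTH = 6371.0088


def sloc_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Spherical law of cosines great-circle distance."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return R_EARTH * math.acos(max(-1.0, min(1.0, c)))


def brute_force_cluster_events(signals, threshold=5, window_h=168.0,
                               radius_km=20.0):
    """Exhaustive anchor-greedy cluster detection over a signal stream.

    ``signals`` is a sequence of (report_id, volunteer_id, time, lat, lon)
    tuples, all of one code.  Returns a list of (anchor_id, trigger_time,
    frozenset(member_ids)), in formation order.  Arrivals are processed in
    (time, volunteer, report) order; each arrival first tries to join the
    earliest-anchored open cluster whose window/radius admit it, otherwise
    every unassigned signal is re-tried as an anchor in time order and the
    first anchor with a full qualifying set consumes that set.
    """
    def key(s):
        return (s[2], s[1], s[0])

    def hours(a, b):
        return (a - b).total_seconds() / 3600.0

    def qualifies(s, anchor):
        return (0.0 <= hours(s[2], anchor[2]) <= window_h
                and sloc_km(s[3], s[4], anchor[3], anchor[4]) <= radius_km)

    open_clusters = []  # [anchor, trigger_time, [members]]
    pool = []
    for sig in sorted(signals, key=key):
        joined = False
        for oc in sorted(open_clusters, key=lambda c: key(c[0])):
            if qualifies(sig, oc[0]):
                oc[2].append(sig)
                joined = True
                break
        if joined:
            continue
        pool.append(sig)
        formed = True
        while formed:
            formed = False
            for anchor in sorted(pool, key=key):
                qual = [s for s in pool if qualifies(s, anchor)]
                if len(qual) >= threshold:
                    qual.sort(key=key)
                    open_clusters.append(
                        [anchor, qual[threshold - 1][2], qual])
                    pool = [s for s in pool if s not in qual]
                    formed = True
                    break
    return [(oc[0][0], oc[1], frozenset(s[0] for s in oc[2]))
            for oc in open_clusters]


def random_stream(rng, n_max=12, code=2):
    """A random small same-code stream over a handful of nearby villages,
    dense enough in space and time that clusters form in a useful share of
    draws.  Returns engine Signals and the oracle's tuple form."""
    from cbskit.engine import GeoPoint, Signal

    n = int(rng.integers(1, n_max + 1))
    base = datetime(2021, 3, 1, tzinfo=UTC)
    # villages ~0-60 km apart so radius decisions genuinely vary
    villages = [(9.0 + 0.13 * i, 45.0 + 0.13 * j)
                for i in range(3) for j in range(3)]
    signals, tuples = [], []
    for i in range(n):
        lat, lon = villages[int(rng.integers(0, len(villages)))]
        # ~50% of streams fit one window; ties in time occur via rounding
        t = base + timedelta(hours=round(float(rng.uniform(0, 330)), 1))
        rid = f"s{i:02d}"
        vid = f"v{int(rng.integers(0, 5)):02d}"
        signals.append(Signal(report_id=rid, volunteer_id=vid,
                              received_at=t, code=code,
                              location=GeoPoint(latitude=lat, longitude=lon)))
        tuples.append((rid, vid, t, lat, lon))
    return signals, tuples


def recount(ledger):
    """Brute-force recount of the summary quantities by independent iteration
    over the raw collections (no reuse of summarize internals)."""
    from cbskit.ledger import AlertStatus, ParseStatus, VerificationStatus

    out = {}
    out["reports_total"] = len(ledger.reports)
    out["reports_malformed"] = sum(
        1 for r in ledger.reports if r.parse_status == ParseStatus.MALFORMED)
    out["reports_correct_format"] = out["reports_total"] - out["reports_malformed"]
    out["signals_sent"] = sum(
        1 for r in ledger.reports if r.parse_status == ParseStatus.SIGNAL)
    out["events_triggered"] = len(ledger.events)
    out["events_kept"] = sum(
        1 for e in ledger.events
        if e.verification_status == VerificationStatus.KEPT)
    out["events_dismissed_by_supervisor"] = sum(
        1 for e in ledger.events
        if e.verification_status == VerificationStatus.DISMISSED)
    out["events_pending"] = sum(
        1 for e in ledger.events
        if e.verification_status == VerificationStatus.PENDING)
    out["signals_verified"] = sum(
        len(e.member_report_ids) for e in ledger.events
        if e.verification_status != VerificationStatus.PENDING)
    out["signals_kept"] = sum(
        len(e.member_report_ids) for e in ledger.events
        if e.verification_status == VerificationStatus.KEPT)
    out["alerts_escalated"] = len(ledger.alerts)
    closed = [a for a in ledger.alerts if a.status != AlertStatus.ESCALATED]
    out["alerts_closed"] = len(closed)
    out["alerts_dismissed_by_authorities"] = sum(
        1 for a in closed if a.status == AlertStatus.DISMISSED_BY_AUTHORITIES)
    out["alerts_documented_outcome"] = sum(
        1 for a in closed if a.outcome.documented)
    out["alerts_action_taken"] = sum(1 for a in closed if a.outcome.action_taken)
    out["alerts_lab_confirmed"] = sum(1 for a in closed if a.outcome.lab_confirmed)
    code_of = {e.event_id: e.code for e in ledger.events}
    by_code = {}
    for a in ledger.alerts:
        c = code_of[a.event_id]
        by_code[c] = by_code.get(c, 0) + 1
    out["escalated_by_code"] = by_code
    out["verified_within_12h"] = sum(
        1 for e in ledger.events if e.verified_at is not None
        and (e.verified_at - e.triggered_at) <= timedelta(hours=12))
    out["verified_within_24h"] = sum(
        1 for e in ledger.events if e.verified_at is not None
        and (e.verified_at - e.triggered_at) <= timedelta(hours=24))
    out["closed_within_48h"] = sum(
        1 for a in closed if a.closed_at is not None
        and (a.closed_at - a.escalated_at) <= timedelta(hours=48))
    return out
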