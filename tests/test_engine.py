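"""Threshold engine: distances, the spatiotemporal cluster rule, online
equivalence, and the exhaustive brute-force oracle."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from cbskit import CCDDefinition, GeoPoint, Signal
from cbskit.config import default_ccd_config
from cbskit.engine import (
    AlertEngine,
    EARTH_RADIUS_KM,
    cluster_window_valid,
    evaluate_stream,
    haversine_km,
    pending_notifications,
)
from cbskit.ledger import VerificationStatus

import helpers

UTC = timezone.utc
T0 = datetime(2021, 3, 1, tzinfo=UTC)
CCDS = default_ccd_config()


def sig(rid, t_hours, lat, lon, code=2, vol=None):
    return Signal(report_id=rid, volunteer_id=vol or f"v-{rid}",
                  received_at=T0 + timedelta(hours=t_hours), code=code,
                  location=GeoPoint(latitude=lat, longitude=lon))


class TestHaversine:
    def test_identity_and_symmetry(self):
        a = GeoPoint(latitude=9.56, longitude=44.06)
        b = GeoPoint(latitude=9.41, longitude=45.53)
        assert haversine_km(a, a) == 0.0
        assert haversine_km(a, b) == pytest.approx(haversine_km(b, a))
        assert haversine_km(a, b) > 0

    def test_antipodal_points_are_half_circumference(self):
        a = GeoPoint(latitude=0.0, longitude=0.0)
        b = GeoPoint(latitude=0.0, longitude=180.0)
        assert haversine_km(a, b) == pytest.approx(np.pi * EARTH_RADIUS_KM,
                                                   rel=1e-9)

    def test_agrees_with_law_of_cosines_on_random_pairs(self):
        """Second-formula oracle: 50 random pairs agree to 1e-6 km."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            lat1, lat2 = rng.uniform(-80, 80, 2)
            lon1, lon2 = rng.uniform(-179, 179, 2)
            d_hav = haversine_km(GeoPoint(latitude=lat1, longitude=lon1),
                                 GeoPoint(latitude=lat2, longitude=lon2))
            d_sloc = helpers.sloc_km(lat1, lon1, lat2, lon2)
            assert abs(d_hav - d_sloc) < 1e-6 or \
                abs(d_hav - d_sloc) / max(d_hav, 1.0) < 1e-9

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError):
            GeoPoint(latitude=91.0, longitude=0.0)


class TestSingleReportCCDs:
    def test_one_event_per_signal(self):
        signals = [sig(f"r{i}", i, 9.5, 44.0, code=4) for i in range(3)]
        signals += [sig("r9", 1.5, 9.5, 44.0, code=9)]
        events = evaluate_stream(signals, CCDS)
        assert len(events) == 4
        singles = [e for e in events if e.code == 4]
        assert all(len(e.member_report_ids) == 1 for e in singles)
        assert {e.triggered_at for e in singles} == \
            {s.received_at for s in signals if s.code == 4}

    def test_unconfigured_code_rejected(self):
        with pytest.raises(KeyError):
            evaluate_stream([sig("r0", 0, 9.5, 44.0, code=99)], CCDS)


# 0.09 degrees latitude ~ 10 km; 0.17 ~ 19 km; 0.23 ~ 25.6 km
NEAR = [(9.5 + 0.01 * i, 44.0) for i in range(5)]


class TestClusterRule:
    def test_five_reports_in_a_village_over_two_days_trigger_once(self):
        signals = [sig(f"r{i}", 10 * i, *NEAR[i]) for i in range(5)]
        events = evaluate_stream(signals, CCDS)
        assert len(events) == 1
        event = events[0]
        assert event.code == 2
        assert len(event.member_report_ids) == 5
        # triggered at the exact arrival of the 5th qualifying signal
        assert event.triggered_at == signals[4].received_at
        assert cluster_window_valid({s.report_id: s for s in signals}, event,
                                    next(c for c in CCDS if c.code == 2))

    def test_four_reports_do_not_trigger(self):
        events = evaluate_stream(
            [sig(f"r{i}", 10 * i, *NEAR[i]) for i in range(4)], CCDS)
        assert events == []

    def test_fifth_report_beyond_the_window_does_not_trigger(self):
        times = [0, 10, 20, 30, 8 * 24]  # last one 8 days after the anchor
        events = evaluate_stream(
            [sig(f"r{i}", times[i], *NEAR[i]) for i in range(5)], CCDS)
        assert events == []

    def test_radius_boundary_decides_the_event(self):
        base = [sig(f"r{i}", 10 * i, *NEAR[i]) for i in range(4)]
        far = base + [sig("r4", 40, 9.5 + 0.23, 44.0)]     # ~25.6 km away
        near = base + [sig("r4", 40, 9.5 + 0.17, 44.0)]    # ~18.9 km away
        assert evaluate_stream(far, CCDS) == []
        assert len(evaluate_stream(near, CCDS)) == 1

    def test_late_qualifying_signal_joins_the_open_event(self):
        signals = [sig(f"r{i}", 10 * i, *NEAR[i]) for i in range(5)]
        signals.append(sig("r5", 60, 9.5, 44.0))
        events = evaluate_stream(signals, CCDS)
        assert len(events) == 1
        assert len(events[0].member_report_ids) == 6

    def test_signals_are_not_reused_across_events(self):
        # ten signals at one site: one event of ten members, not two of five
        signals = [sig(f"r{i}", 5 * i, 9.5, 44.0) for i in range(10)]
        events = evaluate_stream(signals, CCDS)
        assert len(events) == 1
        assert len(events[0].member_report_ids) == 10

    def test_matches_exhaustive_oracle_on_random_streams(self):
        """Engine output equals the from-scratch anchor-greedy detector on
        500 random streams of up to 12 signals."""
        rng = np.random.default_rng(123)
        n_clustered = 0
        for _ in range(500):
            signals, tuples = helpers.random_stream(rng)
            events = [e for e in evaluate_stream(signals, CCDS)]
            expected = helpers.brute_force_cluster_events(tuples)
            got = sorted((frozenset(e.member_report_ids), e.triggered_at)
                         for e in events)
            want = sorted((members, trigger)
                          for _, trigger, members in expected)
            assert got == want
            n_clustered += len(expected)
        assert n_clustered > 50  # the scenario genuinely exercises clustering

    def test_online_equals_batch(self):
        rng = np.random.default_rng(456)
        for _ in range(50):
            signals, _ = helpers.random_stream(rng)
            ordered = sorted(signals, key=lambda s: s.sort_key)
            online = AlertEngine(CCDS)
            for s in ordered:
                online.push(s)
            assert online.events() == evaluate_stream(signals, CCDS)

    def test_determinism_of_event_ids(self):
        rng = np.random.default_rng(789)
        signals, _ = helpers.random_stream(rng, n_max=10)
        first = evaluate_stream(signals, CCDS)
        second = evaluate_stream(list(reversed(signals)), CCDS)
        assert first == second


class TestConfigVersioning:
    def test_signal_uses_the_ccd_active_at_its_timestamp(self):
        """A CCD revision mid-programme (validity intervals) changes how
        later signals are evaluated without bespoke code paths."""
        cut = T0 + timedelta(days=10)
        old = CCDDefinition(code=9, name="respiratory v1", threshold_count=1,
                            valid_to=cut)
        new = CCDDefinition(code=9, name="respiratory v2", threshold_count=1,
                            valid_from=cut)
        before = sig("a", 0, 9.5, 44.0, code=9)
        after = sig("b", 11 * 24, 9.5, 44.0, code=9)
        events = evaluate_stream([before, after], (old, new))
        assert len(events) == 2
        # outside every validity interval -> rejected
        orphan = sig("c", 0, 9.5, 44.0, code=9)
        with pytest.raises(KeyError):
            evaluate_stream([orphan], (new,))


class TestPendingNotifications:
    def test_breach_flag_on_the_12h_target(self):
        signals = [sig("r0", 0, 9.5, 44.0, code=4),
                   sig("r1", 10, 9.5, 44.0, code=4)]
        events = evaluate_stream(signals, CCDS)
        now = T0 + timedelta(hours=13)
        notes = pending_notifications(events, now)
        assert [n.breached_12h for n in notes] == [True, False]

    def test_verified_events_not_listed(self):
        events = evaluate_stream([sig("r0", 0, 9.5, 44.0, code=4)], CCDS)
        kept = events[0].model_copy(update={
            "verification_status": VerificationStatus.KEPT,
            "verified_at": T0 + timedelta(hours=1),
        })
        assert pending_notifications([kept], T0 + timedelta(hours=13)) == []
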