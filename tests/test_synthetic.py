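"""Synthetic programmes: seed determinism, fixture identity, outbreak
recall, false-alarm agreement, parameter recovery."""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pytest

from cbskit import (
    AWDAL_MARGINALS,
    TOGDHEER_MARGINALS,
    FixtureSpec,
    OutbreakSpec,
    SimConfig,
    fixture_from_marginals,
    simulate_programme,
    summarize,
)
from cbskit.config import CLUSTER_CODE, default_ccd_config
from cbskit.engine import cluster_window_valid, signals_from_ledger
from cbskit.io import canonical_bytes
from cbskit.simulate import implied_weekly_completeness, parameter_recovery_report
from cbskit.ingest import weekly_completeness

from conftest import small_sim_config
import helpers

UTC = timezone.utc


class TestSeedDeterminism:
    def test_identical_config_gives_byte_identical_ledgers(self):
        cfg = small_sim_config(seed=7)
        assert canonical_bytes(simulate_programme(cfg)) == \
            canonical_bytes(simulate_programme(cfg))

    def test_different_seeds_differ(self):
        a = simulate_programme(small_sim_config(seed=1))
        b = simulate_programme(small_sim_config(seed=2))
        assert canonical_bytes(a) != canonical_bytes(b)


class TestOutbreakInjection:
    def test_zero_background_single_outbreak_gives_exactly_one_event(self):
        cfg = small_sim_config(
            seed=11,
            background_signal_rate={},
            malformed_prob=0.0,
            outbreaks=(OutbreakSpec(
                start=datetime(2021, 2, 1, tzinfo=UTC),
                epicentre_lat=9.5, epicentre_lon=45.0, n_signals=6),),
        )
        ledger = simulate_programme(cfg)
        s = summarize(ledger)
        assert s.events_triggered == 1
        event = ledger.events[0]
        assert event.code == CLUSTER_CODE
        assert len(event.member_report_ids) == 6

    def test_injected_outbreak_recall_is_total(self):
        """Every injected outbreak of at least the threshold size is
        detected under zero background, across epicentres and seeds."""
        ccd = next(c for c in default_ccd_config() if c.code == CLUSTER_CODE)
        for k in range(10):
            cfg = small_sim_config(
                seed=100 + k,
                background_signal_rate={},
                malformed_prob=0.0,
                outbreaks=(
                    OutbreakSpec(start=datetime(2021, 1, 20, tzinfo=UTC),
                                 epicentre_lat=8.5 + 0.2 * k,
                                 epicentre_lon=44.5, n_signals=5,
                                 spread_km=3.0 + 0.5 * k, spread_h=24.0),
                    OutbreakSpec(start=datetime(2021, 3, 10, tzinfo=UTC),
                                 epicentre_lat=10.2, epicentre_lon=46.0,
                                 n_signals=7, spread_h=96.0),
                ),
            )
            ledger = simulate_programme(cfg)
            clusters = [e for e in ledger.events if e.code == CLUSTER_CODE]
            assert len(clusters) == 2
            signals = {s.report_id: s
                       for s in signals_from_ledger(ledger.reports,
                                                    ledger.volunteers)}
            for event in clusters:
                assert cluster_window_valid(signals, event, ccd)

    def test_background_cluster_rate_matches_brute_force_detector(self):
        """With background-only ADD signals, the engine's cluster count per
        replicate equals the exhaustive detector run on the same streams."""
        engine_counts, oracle_counts = [], []
        for k in range(15):
            cfg = small_sim_config(
                seed=900 + k,
                background_signal_rate={CLUSTER_CODE: 0.08},
                malformed_prob=0.0, n_villages=6,
            )
            ledger = simulate_programme(cfg)
            engine_counts.append(
                sum(1 for e in ledger.events if e.code == CLUSTER_CODE))
            tuples = [(s.report_id, s.volunteer_id, s.received_at,
                       s.location.latitude, s.location.longitude)
                      for s in signals_from_ledger(ledger.reports,
                                                   ledger.volunteers)
                      if s.code == CLUSTER_CODE]
            oracle_counts.append(len(helpers.brute_force_cluster_events(tuples)))
        assert engine_counts == oracle_counts


class TestFixtures:
    @pytest.mark.parametrize("spec", [AWDAL_MARGINALS, TOGDHEER_MARGINALS],
                             ids=["awdal", "togdheer"])
    def test_summarize_is_the_identity_on_every_marginal(self, spec):
        s = summarize(fixture_from_marginals(spec))
        assert s.events_triggered == spec.events_triggered
        assert s.alerts_escalated == spec.alerts_escalated
        assert s.events_dismissed_by_supervisor == spec.events_dismissed_by_supervisor
        assert s.escalated_by_code == spec.escalated_by_code
        assert s.alerts_closed == spec.alerts_closed
        assert s.alerts_dismissed_by_authorities == spec.alerts_dismissed_by_authorities
        assert s.alerts_documented_outcome == spec.alerts_documented_outcome
        assert s.alerts_action_taken == spec.alerts_action_taken
        assert s.alerts_lab_confirmed == spec.alerts_lab_confirmed
        assert s.reports_total == spec.reports_total
        assert s.reports_correct_format == spec.reports_correct_format
        assert s.signals_sent == spec.signals_sent
        assert s.signals_verified == spec.signals_verified
        assert s.signals_kept == spec.signals_kept
        assert s.verified_within_12h == spec.verified_within_12h
        assert s.verified_within_24h == spec.verified_within_24h
        assert s.closed_within_48h == spec.closed_within_48h

    def test_fixture_construction_is_deterministic(self):
        a = fixture_from_marginals(AWDAL_MARGINALS)
        b = fixture_from_marginals(AWDAL_MARGINALS)
        assert canonical_bytes(a) == canonical_bytes(b)

    def test_cluster_events_satisfy_their_ccd(self, awdal_ledger):
        ccd = next(c for c in default_ccd_config() if c.code == CLUSTER_CODE)
        signals = {s.report_id: s
                   for s in signals_from_ledger(awdal_ledger.reports,
                                                awdal_ledger.volunteers)}
        clusters = [e for e in awdal_ledger.events if e.code == CLUSTER_CODE]
        assert clusters
        for event in clusters:
            assert cluster_window_valid(signals, event, ccd)

    def test_inconsistent_spec_rejected_with_named_inequality(self):
        data = AWDAL_MARGINALS.model_dump()
        data["alerts_documented_outcome"] = 200  # > closed alerts
        with pytest.raises(ValueError,
                           match="documented_outcome"):
            FixtureSpec(**data)

    def test_invalid_probability_rejected_before_generation(self):
        with pytest.raises(ValueError):
            small_sim_config(seed=1, dismissal_prob=1.5)


class TestParameterRecovery:
    def test_degenerate_config_recovers_every_rate_exactly(self):
        cfg = small_sim_config(
            seed=3,
            weekly_zero_report_prob=1.0, malformed_prob=0.0,
            verify_within_12h_prob=1.0, dismissal_prob=0.0,
            close_within_48h_prob=1.0, dismissed_by_authorities_prob=0.0,
            documented_prob=1.0, action_given_documented_prob=1.0,
            lab_given_action_prob=1.0,
            background_signal_rate={4: 0.05},
        )
        table = parameter_recovery_report(cfg, n_replicates=2)
        assert (table["mean_estimate"] == 1.0).all()

    def test_rates_recovered_within_three_standard_errors(self):
        """A full-size programme at the observed rates (completeness ~0.64,
        correct format 0.96, 12 h verification 0.75, 48 h closure 0.67)
        returns estimates within 3 Monte-Carlo standard errors."""
        cfg = SimConfig(
            seed=64, n_villages=50, volunteers_per_village=2,
            weekly_zero_report_prob=0.64, malformed_prob=0.04,
            verify_within_12h_prob=0.75, close_within_48h_prob=0.67,
        )
        table = parameter_recovery_report(cfg, n_replicates=8)
        assert (table["z"].abs() < 3).all()

    def test_completeness_average_tracks_the_implied_rate(self):
        cfg = small_sim_config(seed=12, weekly_zero_report_prob=0.64,
                               background_signal_rate={}, malformed_prob=0.0)
        ledger = simulate_programme(cfg)
        wc = weekly_completeness(ledger.reports, ledger.volunteers,
                                 ledger.period_start, ledger.period_end)
        implied = implied_weekly_completeness(cfg)
        assert implied == 0.64
        n = 20 * 13  # volunteers x weeks
        se = (implied * (1 - implied) / n) ** 0.5
        assert abs(wc.average - implied) < 3 * se
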