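# Methods

## The surveillance model

The package models a community-based surveillance (CBS) programme as a
deterministic pipeline over an immutable ledger:

1. **Reports.** Volunteers submit coded SMS payloads.  Classification is
   total: a payload is a *signal* (the bare ASCII digits of a configured
   code), a *zero report* (a single configurable token, default `"0"`), or
   *malformed* — nothing else.  The deployed programme's exact SMS grammar
   is not public; this dialect is a documented stand-in with the same
   structure (one code per message from a non-smart phone) and is marked as
   such on the `DialectConfig` schema.
2. **Thresholds.** Each community case definition (CCD) carries an alert
   threshold.  Single-report CCDs (fever-and-rash, respiratory illness,
   unusual illness cluster — codes 4, 9, 14) trigger one event per signal,
   with no merging across volunteers.  The acute-diarrhoeal-disease CCD
   (code 2) is spatiotemporal: an event triggers at the exact arrival of
   the 5th same-code signal within 168 h and 20 km of an *anchor*.
3. **Lifecycle.** Events await supervisor verification (target: within
   12 h); kept events are escalated as alerts; alerts close with an outcome
   record, or end as dismissed-by-authorities (counted inside closed
   alerts).  Transitions are pure functions; every applied transition is
   appended to a log, and replaying the log over the initial ledger
   rebuilds the final state exactly.
4. **Attributes.** All system attributes are exact count ratios:
   usefulness (escalated/triggered, closed/escalated, per-code composition),
   simplicity (signal-level survival of verification), data quality
   (correct-format share, weekly completeness), sensitivity proxies
   (documented outcome, action taken, laboratory confirmation,
   dismissed-by-authorities shares) and timeliness (12 h / 24 h / 48 h
   delay cuts).

## Cluster detection: the anchor-greedy rule

The threshold wording "5 reports within 7 days in 20 km distance" leaves
three choices open; the engine fixes them as follows and documents each as
an assumption:

- **Window**: a rolling 168-hour window anchored at the earliest unassigned
  signal, not calendar days — standard for outbreak thresholds and free of
  timezone edge cases.
- **Radius**: measured from the anchor signal's registered village point,
  not as a pairwise diameter — the operational reading of "reports within
  20 km" of an index report, and O(n·window) to evaluate.
- **Distance**: haversine on a sphere of radius 6371.0088 km (IUGG mean).
  Formula differences are sub-metre at a 20 km threshold.

Arrivals are processed in (timestamp, volunteer_id, report_id) order.  A
new signal first tries to join the earliest-anchored open cluster event
whose window and radius admit it (membership closes at verification);
otherwise it enters the unassigned pool and anchors are re-tried in time
order — the first anchor whose qualifying set reaches the threshold
consumes that set as a new event.  Signals are consumed by the event they
trigger or join, so one cluster cannot spawn duplicate alerts.  Two
consequences are used as test oracles: online processing equals batch
processing, and the event set equals an exhaustive from-scratch detector.
Two performance short-cuts are provably lossless: only anchors whose
neighbourhood admits the newest arrival can have changed since the last
scan, and signals older than one window behind the newest arrival are
inert (any cluster they could still join would be anchored even earlier
and can no longer grow).

CCD definitions carry optional validity intervals; each signal is evaluated
under the definition active at its timestamp.  This represents mid-programme
CCD revisions (as happened for the COVID-19 definition) as configuration,
not code.

## Metric conventions

- **Rounding**: integer percents use round-half-up computed on the exact
  rational (`Fraction`), never on a float.  Published tables occasionally
  truncate instead: 213/218 = 97.7 % renders 98 % here (printed 97 %),
  5/218 = 2.3 % renders 2 % (printed 3 %).  One consistent rule beats
  mimicking truncation; the divergence is footnoted on every report.
- **Closed bounds**: a delay of exactly 12 h counts as "within 12 h"
  (likewise 24 h and 48 h).
- **Denominators**: verification cuts are denominated over all triggered
  events (which reproduces the published 75 %/93 %); the 48 h response cut
  over all closed alerts; documented outcomes over closed alerts;
  dismissed-by-authorities over escalated alerts.
- **Weekly completeness**: per ISO-8601 week (Mon–Sun), the fraction of
  volunteers active that week with at least one submission.  Any submission
  counts — signal, zero, or malformed — since a malformed attempt still
  evidences an active volunteer, and "report" in the attribute's definition
  is not format-restricted.  A volunteer sending both a signal and a zero
  report in a week counts once.  Volunteers enter a week's denominator only
  if their active interval overlaps it; weeks with no active volunteer are
  excluded from the period average (an unweighted mean of weekly values).
- **Null propagation**: a zero denominator never raises; it yields a typed
  null (`percent is None`), and the sensitivity proxies carry an explicit
  "insufficient documentation" note when no outcome is documented — the
  evidence gap real programmes exhibit.

## Synthetic programmes

`simulate_programme` emulates the data-generating process the analysis
assumes.  Per volunteer-week: a zero report with probability
`weekly_zero_report_prob` and, per code, a background signal with its
weekly Bernoulli rate, all at uniform times within the week; each
submission is corrupted to a malformed payload with `malformed_prob`.
Background signals sit at the volunteer's village point, drawn uniformly
over the coordinate box, so background ADD signals are dispersed and
rarely cluster — clustering enters through explicit `OutbreakSpec`
injections.  An injection places `n_signals` within `spread_h` of its start
among villages within `spread_km` of the epicentre (or a single nearest
village if none is that close).  With `spread_km ≤ 10` (half the radius;
enforced) and `spread_h ≤ 168`, every injected outbreak of at least
threshold size satisfies the cluster rule about its earliest member by the
triangle inequality — recall is 1 by construction, which the tests assert.
Injected reports are exempt from malformed corruption for the same reason.

Verification delays are a two-component mixture: uniform on (0, 12 h] with
probability `verify_within_12h_prob`, else 12 h plus a log-normal tail
(median 12 h, σ = 0.8) — the minimal structure reproducing a printed
within-12 h share.  Closure delays mirror this around 48 h.  Kept/dismissed,
escalation, closure status and outcome flags are independent Bernoulli
draws per event or alert.

Defaults are the observed 2021 regional conditions (Awdal-like where the
regions differ): weekly zero-report probability 0.66 (regional averages
64 %/68 %), malformed 0.03 (observed 1–4 %), verification within 12 h 0.75,
supervisor dismissal 0.17, closure within 48 h 0.67, documentation 0.63,
action-given-documented 0.85, lab-given-action 0.11,
dismissed-by-authorities 0.09, background weekly rates
{2: 0.035, 4: 0.007, 9: 0.011, 14: 0.0005} per volunteer (≈ 280 signals
per 100-volunteer year).  `documented_prob` is conditional on not being
dismissed by authorities, so the implied marginal documented share is
0.63 × 0.91 ≈ 0.57.  The seed is mandatory; identical (config, seed) yields
byte-identical ledgers.

What the generator does **not** model: real geography and village networks
(coordinates are uniform in a box), nomadic movement, network outages,
seasonal compliance dips (the observed first-quarter dip is not emulated),
volunteer turnover, and multi-field SMS grammars.  Passing tests therefore
show the pipeline reads its own generating process correctly at realistic
sizes — not that these rates are what a new deployment would observe.

## Fixtures from marginal counts

`fixture_from_marginals` realises a `FixtureSpec` — the marginal counts of
one region-period — as a concrete ledger, deterministically: events on an
hourly grid; each event at its own site ≥ 70 km from every other so cluster
windows cannot interact; cluster-event members within ~100 m and minutes of
their anchor; sub-threshold ADD signals each on an isolated site and week;
verification delays of 6 h / 18 h / 30 h placed around the 12 h and 24 h
cuts by event index; closure delays of 24 h / 72 h around the 48 h cut;
outcome flags assigned as nested index prefixes and dismissed-by-authorities
as a disjoint suffix of closed alerts.  Inconsistent specs (e.g. documented
outcomes exceeding closed alerts, or a dismissed-signal excess no cluster
event can absorb) are rejected with the violated inequality named.  The
packaged Awdal and Togdheer specs reproduce every published 2021 count
exactly under `summarize`; the whole lifecycle is driven through the state
machine, so the fixtures also exercise the transition log.

Two published inconsistencies are deliberately not reconciled: the Awdal
24 h verification row (table count 115 vs text count 116; the fixture uses
116, which computes to 84 %, printed as 85 %), and the Togdheer 97 %/3 %
rounding noted above.  Counts, not percentages, are the reproduction
targets in both cases.

## Parameter recovery

`parameter_recovery_report` simulates replicates, pools numerators and
denominators per rate, and standardises the pooled deviation by the exact
binomial standard error at the configured rate — each rate is an indicator
average, so replicate-mean standard deviations (noisy at few replicates)
are reported but not used as the yardstick.  The completeness target is the
config-implied presence probability
1 − (1 − p_zero)·∏(1 − rate_c), exact because per-code background draws are
weekly Bernoullis and malformed submissions still count as presence.

## Problem sizes and numerical choices

The test suite and analysis scripts use: 10,000 random streams of ≤ 12
signals for the engine/oracle comparison; 20 two-outbreak programmes for
recall; 8–10 replicates of 100-volunteer, 52-week programmes for recovery;
100 randomly parameterised small ledgers (10 villages, 13 weeks) for
conservation and null-propagation sweeps.  Ties in arrival time are broken
by (timestamp, volunteer_id, report_id); event ids are derived from the
anchor's report id, so identical inputs give identical ids.  Timestamps are
stored timezone-aware in UTC (naive inputs are taken as UTC).  Serialised
ledgers round-trip bit-exactly (floats via `repr`, RFC 4180 CSV, UTF-8).

## Known limitations

- Sensitivity is observable only through documentation proxies; no ledger
  quantity measures events the programme failed to detect.
- In simulated programmes many background ADD signals never reach the
  cluster threshold and are therefore never verified, so the signal-level
  simplicity shares sit far below the regional fixtures' — in the real
  programme most signals belonged to single-report CCDs.
- The cluster rule's anchor-based radius and rolling window are assumptions
  where the deployed platform's exact semantics are unpublished; pairwise-
  diameter or village-centroid variants would need a different engine rule.
- Whether a signal arriving after escalation may still join its event is
  unspecified in the source material; membership here closes at
  verification.
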