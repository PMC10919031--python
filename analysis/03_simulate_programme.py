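"""Simulate one year of a volunteer programme and evaluate it end to end.

A 50-village programme (two volunteers per village, 52 weeks) at the
observed regional rates, with two injected acute-diarrhoeal-disease
outbreak clusters, pushed through threshold evaluation, the lifecycle state
machine, and the attribute metrics — the same path a real ledger would take.

Finding: the simulated attribute report lands near the configured rates
(escalation ~83%, verification within 12 h ~75%, closure within 48 h ~67%)
and both injected outbreaks surface as cluster events among the escalated
alerts.
"""

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

from cbskit import OutbreakSpec, SimConfig, simulate_programme, summarize
from cbskit.cli import compute_metrics
from cbskit.config import CLUSTER_CODE
from cbskit.io import write_ledger
from cbskit.metrics import report_markdown

UTC = timezone.utc
RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

config = SimConfig(
    region="simulated",
    seed=2021,
    outbreaks=(
        OutbreakSpec(start=datetime(2021, 4, 12, tzinfo=UTC),
                     epicentre_lat=9.6, epicentre_lon=44.2, n_signals=9,
                     spread_km=8.0, spread_h=96.0),
        OutbreakSpec(start=datetime(2021, 9, 3, tzinfo=UTC),
                     epicentre_lat=10.4, epicentre_lon=46.1, n_signals=6,
                     spread_km=5.0, spread_h=48.0),
    ),
)
ledger = simulate_programme(config)
summary = summarize(ledger)
report = compute_metrics(ledger)

clusters = [e for e in ledger.events if e.code == CLUSTER_CODE]
print(report_markdown(report))
print(f"cluster events detected: {len(clusters)} "
      f"(2 injected outbreaks plus any background coincidences)")

scratch = Path(__file__).resolve().parents[1] / "scratch"
write_ledger(ledger, scratch / "simulated_ledger")
(RESULTS / "simulated_programme_metrics.json").write_text(
    json.dumps(dataclasses.asdict(report), indent=2, default=str) + "\n")
(RESULTS / "simulated_programme_metrics.md").write_text(
    report_markdown(report))
print(f"wrote {RESULTS / 'simulated_programme_metrics.json'} and the ledger")
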