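"""Ledger serialisation.

A ledger round-trips through a directory of four RFC 4180 CSV tables
(`volunteers.csv`, `reports.csv`, `events.csv`, `alerts.csv`) plus
`ccd_config.json`, `log.json` and `meta.json`.  All files are UTF-8,
timestamps are ISO-8601 with explicit offset, floats are written with
`repr` so write-then-read is the identity on every field.
"""

from __future__ import annotations

import csv
import hashlib
import json
from datetime import datetime
from pathlib import Path
from typing import Optional

from .ledger import (
    Alert,
    AlertStatus,
    CCDDefinition,
    DismissalReason,
    HealthEvent,
    Ledger,
    OutcomeRecord,
    ParseStatus,
    RawReport,
    VerificationStatus,
    Volunteer,
)

__all__ = [
    "write_ledger",
    "read_ledger",
    "canonical_bytes",
    "events_geojson",
    "signals_geojson",
    "sha256_file",
]


def _ts(ts: Optional[datetime]) -> str:
    return "" if ts is None else ts.isoformat()


def _parse_ts(text: str) -> Optional[datetime]:
    return None if text == "" else datetime.fromisoformat(text)


def _write_csv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def _read_csv(path: Path) -> list[dict[str, str]]:
    with path.open("r", encoding="utf-8", newline="") as fh:
        return list(csv.DictReader(fh))


def write_ledger(ledger: Ledger, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _write_csv(out / "volunteers.csv",
               ["volunteer_id", "village_id", "phone_token",
                "latitude", "longitude", "active_from", "active_to"],
               [[v.volunteer_id, v.village_id, v.phone_token,
                 repr(v.latitude), repr(v.longitude),
                 _ts(v.active_from), _ts(v.active_to)]
                for v in ledger.volunteers])

    _write_csv(out / "reports.csv",
               ["report_id", "volunteer_id", "received_at", "payload",
                "parse_status", "code"],
               [[r.report_id, r.volunteer_id, _ts(r.received_at), r.payload,
                 r.parse_status.value, "" if r.code is None else str(r.code)]
                for r in ledger.reports])

    _write_csv(out / "events.csv",
               ["event_id", "code", "member_report_ids", "triggered_at",
                "anchor_latitude", "anchor_longitude", "verification_status",
                "dismissal_reason", "verified_at"],
               [[e.event_id, str(e.code), ";".join(e.member_report_ids),
                 _ts(e.triggered_at), repr(e.anchor_latitude),
                 repr(e.anchor_longitude), e.verification_status.value,
                 e.dismissal_reason.value, _ts(e.verified_at)]
                for e in ledger.events])

    _write_csv(out / "alerts.csv",
               ["alert_id", "event_id", "escalated_at", "status", "closed_at",
                "documented", "action_taken", "lab_confirmed", "notes"],
               [[a.alert_id, a.event_id, _ts(a.escalated_at), a.status.value,
                 _ts(a.closed_at), str(int(a.outcome.documented)),
                 str(int(a.outcome.action_taken)),
                 str(int(a.outcome.lab_confirmed)), a.outcome.notes]
                for a in ledger.alerts])

    (out / "ccd_config.json").write_text(json.dumps(
        [c.model_dump(mode="json") for c in ledger.ccd_config],
        indent=2, sort_keys=True) + "\n", encoding="utf-8")
    (out / "log.json").write_text(json.dumps(
        list(ledger.log), indent=2, sort_keys=True) + "\n", encoding="utf-8")
    (out / "meta.json").write_text(json.dumps({
        "region": ledger.region,
        "period_start": _ts(ledger.period_start),
        "period_end": _ts(ledger.period_end),
    }, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return out


def read_ledger(in_dir: str | Path) -> Ledger:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text(encoding="utf-8"))
    ccds = tuple(
        CCDDefinition(**d)
        for d in json.loads((src / "ccd_config.json").read_text(encoding="utf-8"))
    )
    log = tuple(json.loads((src / "log.json").read_text(encoding="utf-8")))

    volunteers = tuple(Volunteer(
        volunteer_id=row["volunteer_id"], village_id=row["village_id"],
        phone_token=row["phone_token"],
        latitude=float(row["latitude"]), longitude=float(row["longitude"]),
        active_from=_parse_ts(row["active_from"]),
        active_to=_parse_ts(row["active_to"]),
    ) for row in _read_csv(src / "volunteers.csv"))

    reports = tuple(RawReport(
        report_id=row["report_id"], volunteer_id=row["volunteer_id"],
        received_at=_parse_ts(row["received_at"]), payload=row["payload"],
        parse_status=ParseStatus(row["parse_status"]),
        code=None if row["code"] == "" else int(row["code"]),
    ) for row in _read_csv(src / "reports.csv"))

    events = tuple(HealthEvent(
        event_id=row["event_id"], code=int(row["code"]),
        member_report_ids=tuple(row["member_report_ids"].split(";")),
        triggered_at=_parse_ts(row["triggered_at"]),
        anchor_latitude=float(row["anchor_latitude"]),
        anchor_longitude=float(row["anchor_longitude"]),
        verification_status=VerificationStatus(row["verification_status"]),
        dismissal_reason=DismissalReason(row["dismissal_reason"]),
        verified_at=_parse_ts(row["verified_at"]),
    ) for row in _read_csv(src / "events.csv"))

    alerts = tuple(Alert(
        alert_id=row["alert_id"], event_id=row["event_id"],
        escalated_at=_parse_ts(row["escalated_at"]),
        status=AlertStatus(row["status"]),
        closed_at=_parse_ts(row["closed_at"]),
        outcome=OutcomeRecord(
            documented=bool(int(row["documented"])),
            action_taken=bool(int(row["action_taken"])),
            lab_confirmed=bool(int(row["lab_confirmed"])),
            notes=row["notes"],
        ),
    ) for row in _read_csv(src / "alerts.csv"))

    return Ledger(
        region=meta["region"],
        period_start=_parse_ts(meta["period_start"]),
        period_end=_parse_ts(meta["period_end"]),
        ccd_config=ccds, volunteers=volunteers, reports=reports,
        events=events, alerts=alerts, log=log,
    )


def canonical_bytes(ledger: Ledger) -> bytes:
    """A canonical byte serialisation, used to assert seed determinism."""
    return json.dumps(ledger.model_dump(mode="json"), sort_keys=True,
                      separators=(",", ":")).encode("utf-8")


def events_geojson(ledger: Ledger) -> dict:
    """Event anchor points as a GeoJSON FeatureCollection."""
    alert_by_event = {a.event_id: a for a in ledger.alerts}
    features = []
    for e in ledger.events:
        alert = alert_by_event.get(e.event_id)
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [e.anchor_longitude, e.anchor_latitude]},
            "properties": {
                "event_id": e.event_id,
                "code": e.code,
                "n_signals": len(e.member_report_ids),
                "triggered_at": _ts(e.triggered_at),
                "verification_status": e.verification_status.value,
                "alert_status": None if alert is None else alert.status.value,
            },
        })
    return {"type": "FeatureCollection", "features": features}


def signals_geojson(ledger: Ledger) -> dict:
    """Signal report points (at the reporting volunteer's village point)."""
    loc = {v.volunteer_id: (v.longitude, v.latitude) for v in ledger.volunteers}
    features = []
    for r in ledger.reports:
        if r.parse_status is not ParseStatus.SIGNAL:
            continue
        lon, lat = loc[r.volunteer_id]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [lon, lat]},
            "properties": {"report_id": r.report_id, "code": r.code,
                           "received_at": _ts(r.received_at)},
        })
    return {"type": "FeatureCollection", "features": features}


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()
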