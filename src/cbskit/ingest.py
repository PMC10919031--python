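"""Parsing of coded volunteer submissions and report-level data-quality
metrics.

Volunteers report with a simple coded SMS from a non-smart phone: the payload
is the bare digits of a configured signal code ("2" for acute diarrhoeal
disease, "4" fever-and-rash, ...), a single zero token (default "0") for the
weekly "nothing to report" submission, and anything else is malformed.  The
classification is total: every payload maps to exactly one parse status.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .ledger import ParseStatus, RawReport, Volunteer
from .metrics import Pct, pct

__all__ = [
    "DialectConfig",
    "parse_report",
    "correct_format_rate",
    "WeeklyCompleteness",
    "weekly_completeness",
    "iso_weeks",
]


class DialectConfig(BaseModel):
    """The SMS coding dialect: how payloads map to signal codes and the
    weekly zero report.

    This dialect is a documented stand-in for the deployed reporting scheme
    (bare code digits for a signal, one token for the zero report); the
    classification rule is total by construction.
    """

    model_config = ConfigDict(frozen=True)

    allowed_codes: tuple[int, ...]
    zero_token: str = "0"

    @model_validator(mode="after")
    def _zero_token_not_a_code(self) -> "DialectConfig":
        token = self.zero_token.strip()
        if token.isdigit() and int(token) in self.allowed_codes:
            raise ValueError("zero_token must not parse as a signal code")
        if not self.allowed_codes:
            raise ValueError("at least one signal code must be configured")
        return self

    def classify(self, payload: str) -> tuple[ParseStatus, Optional[int]]:
        text = payload.strip()
        if text == self.zero_token.strip():
            return ParseStatus.ZERO, None
        # ASCII digits only: characters like '²' pass str.isdigit but are
        # not part of the coded dialect
        if text.isascii() and text.isdigit() and int(text) in self.allowed_codes:
            return ParseStatus.SIGNAL, int(text)
        return ParseStatus.MALFORMED, None


def parse_report(payload: str, received_at: datetime, volunteer_id: str,
                 dialect: DialectConfig,
                 report_id: Optional[str] = None) -> RawReport:
    """Classify one submission into a :class:`RawReport`.

    Pure in (payload, dialect): the same payload always yields the same
    parse status and code.  A malformed payload is a classification, not an
    error.
    """
    status, code = dialect.classify(payload)
    if report_id is None:
        report_id = f"R-{volunteer_id}-{received_at.isoformat()}"
    return RawReport(
        report_id=report_id,
        volunteer_id=volunteer_id,
        received_at=received_at,
        payload=payload,
        parse_status=status,
        code=code,
    )


def correct_format_rate(reports: Iterable[RawReport]) -> Pct:
    """Share of reports sent in the correct format (signal or zero) out of
    all reports sent; integer percent under round-half-up, null when no
    reports exist."""
    total = 0
    correct = 0
    for r in reports:
        total += 1
        if r.parse_status is not ParseStatus.MALFORMED:
            correct += 1
    return pct(correct, total)


# ---------------------------------------------------------------------------
# weekly completeness

def _utc(ts: datetime) -> datetime:
    if ts.tzinfo is None:
        return ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def iso_weeks(start: datetime, end: datetime) -> list[tuple[int, int]]:
    """All ISO-8601 (year, week) pairs touched by [start, end]."""
    if end < start:
        raise ValueError("period end precedes start")
    out = []
    day = _utc(start).date()
    last = _utc(end).date()
    seen = set()
    while day <= last:
        iso = day.isocalendar()
        key = (iso.year, iso.week)
        if key not in seen:
            seen.add(key)
            out.append(key)
        day = day + timedelta(days=1)
    return out


@dataclass
class WeeklyCompleteness:
    """Per-week fraction of active volunteers with at least one report, and
    the unweighted mean over weeks with at least one active volunteer."""

    weekly: "pd.Series"         # index (iso_year, iso_week), values in [0, 1]
    average: Optional[float]    # None when no week had an active volunteer
    denominators: "pd.Series"   # active volunteers per week


def weekly_completeness(reports: Iterable[RawReport],
                        roster: Sequence[Volunteer],
                        period_start: datetime,
                        period_end: datetime) -> WeeklyCompleteness:
    """Weekly reporting completeness: for every ISO week of the period, the
    fraction of volunteers active in that week who submitted at least one
    report (of any kind — a submission, even malformed, evidences activity).

    Volunteers enter the denominator only for weeks overlapping their active
    interval; weeks with zero active volunteers are excluded from the
    average.
    """
    weeks = iso_weeks(period_start, period_end)
    week_index = pd.MultiIndex.from_tuples(weeks, names=["iso_year", "iso_week"])

    # denominator: active volunteers per week (interval overlap at day level)
    denom = pd.Series(0, index=week_index, dtype=int)
    active_sets: dict[tuple[int, int], set] = {w: set() for w in weeks}
    for v in roster:
        day = max(_utc(v.active_from).date(), _utc(period_start).date())
        last = min(_utc(v.active_to).date(), _utc(period_end).date())
        while day <= last:
            iso = day.isocalendar()
            key = (iso.year, iso.week)
            if key in active_sets:
                active_sets[key].add(v.volunteer_id)
            day += timedelta(days=1)
    for key, vols in active_sets.items():
        denom.loc[key] = len(vols)

    # numerator: active volunteers with >= 1 report that week
    reporters: dict[tuple[int, int], set] = {w: set() for w in weeks}
    for r in reports:
        iso = _utc(r.received_at).isocalendar()
        key = (iso.year, iso.week)
        if key in reporters and r.volunteer_id in active_sets[key]:
            reporters[key].add(r.volunteer_id)

    values = []
    for key in weeks:
        n = denom.loc[key]
        values.append(len(reporters[key]) / n if n > 0 else float("nan"))
    weekly = pd.Series(values, index=week_index, dtype=float)
    nonempty = weekly.dropna()
    average = float(nonempty.mean()) if len(nonempty) else None
    return WeeklyCompleteness(weekly=weekly, average=average,
                              denominators=denom)
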