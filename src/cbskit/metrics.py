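"""Surveillance-system attribute metrics.

Every attribute is a ratio of ledger counts rendered as an integer percent
under a single round-half-up rule.  Zero denominators never raise: they
yield typed nulls (``percent is None``) so the report can state *why* a
metric is unavailable (the sensitivity proxies in particular depend on
outcome documentation that real programmes often lack).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .ledger import LedgerSummary

__all__ = [
    "Pct",
    "pct",
    "usefulness",
    "simplicity",
    "sensitivity_proxies",
    "timeliness",
    "AttributeReport",
    "attribute_report",
    "report_markdown",
]


@dataclass(frozen=True)
class Pct:
    """A ratio of counts with its integer-percent rendering."""

    numerator: int
    denominator: int
    fraction: Optional[float]
    percent: Optional[int]

    def __str__(self) -> str:
        if self.percent is None:
            return f"{self.numerator}/{self.denominator} (–)"
        return f"{self.numerator}/{self.denominator} ({self.percent}%)"


def pct(numerator: int, denominator: int) -> Pct:
    """Integer percent of ``numerator/denominator`` under round-half-up.

    Exact: the rounding is done on the rational value, never on a float.
    A zero denominator yields a null percent rather than raising.
    """
    if numerator < 0 or denominator < 0:
        raise ValueError("counts must be non-negative")
    if numerator > denominator:
        raise ValueError(f"numerator {numerator} exceeds denominator {denominator}")
    if denominator == 0:
        return Pct(numerator, denominator, None, None)
    value = Fraction(100 * numerator, denominator)
    rendered = math.floor(value + Fraction(1, 2))
    return Pct(numerator, denominator, float(value) / 100.0, rendered)


# ---------------------------------------------------------------------------
# attribute operations

@dataclass(frozen=True)
class Usefulness:
    escalation: Pct            # alerts escalated / events triggered
    supervisor_dismissal: Pct  # events dismissed by supervisor / triggered
    response: Pct              # alerts closed / alerts escalated
    composition_by_code: dict  # code -> Pct of escalated alerts


def usefulness(summary: "LedgerSummary") -> Usefulness:
    """Share of triggered events escalated as alerts, share responded to
    (closed), and the composition of escalated alerts by signal code."""
    escalated = summary.alerts_escalated
    composition = {
        code: pct(n, escalated)
        for code, n in sorted(summary.escalated_by_code.items())
    }
    return Usefulness(
        escalation=pct(escalated, summary.events_triggered),
        supervisor_dismissal=pct(summary.events_dismissed_by_supervisor,
                                 summary.events_triggered),
        response=pct(summary.alerts_closed, escalated),
        composition_by_code=composition,
    )


@dataclass(frozen=True)
class Simplicity:
    verified_of_sent: Pct   # signals in verified events / all signals sent
    kept_of_verified: Pct   # signals in kept events / signals verified


def simplicity(summary: "LedgerSummary") -> Simplicity:
    """How often lay volunteers' signals survive supervisor verification —
    a proxy for how well the simplified case definitions are understood."""
    return Simplicity(
        verified_of_sent=pct(summary.signals_verified, summary.signals_sent),
        kept_of_verified=pct(summary.signals_kept, summary.signals_verified),
    )


@dataclass(frozen=True)
class SensitivityProxies:
    documented_outcome: Pct        # documented / closed alerts
    action_taken_of_documented: Pct
    action_taken_of_escalated: Pct
    lab_confirmed_of_actioned: Pct
    dismissed_by_authorities: Pct  # of escalated alerts
    note: Optional[str] = None


def sensitivity_proxies(summary: "LedgerSummary") -> SensitivityProxies:
    """Outcome-documentation proxies for sensitivity.

    True sensitivity (all community health events detected) is not
    computable from the ledger alone; these proxies quantify how far the
    documented outcomes can support a sensitivity claim, and carry an
    explicit note when documentation is absent altogether.
    """
    note = None
    if summary.alerts_closed > 0 and summary.alerts_documented_outcome == 0:
        note = "insufficient documentation: no alert has a documented outcome"
    return SensitivityProxies(
        documented_outcome=pct(summary.alerts_documented_outcome,
                               summary.alerts_closed),
        action_taken_of_documented=pct(summary.alerts_action_taken,
                                       summary.alerts_documented_outcome),
        action_taken_of_escalated=pct(summary.alerts_action_taken,
                                      summary.alerts_escalated),
        lab_confirmed_of_actioned=pct(summary.alerts_lab_confirmed,
                                      summary.alerts_action_taken),
        dismissed_by_authorities=pct(summary.alerts_dismissed_by_authorities,
                                     summary.alerts_escalated),
        note=note,
    )


@dataclass(frozen=True)
class Timeliness:
    verified_within_12h: Pct  # of all triggered events
    verified_within_24h: Pct  # of all triggered events
    closed_within_48h: Pct    # of all closed alerts


def timeliness(summary: "LedgerSummary") -> Timeliness:
    """Delay-cut shares, with closed-interval comparisons (a delay of
    exactly 12 h counts as within 12 h).

    Verification cuts are denominated over all triggered events; the 48 h
    response cut over all closed alerts.
    """
    return Timeliness(
        verified_within_12h=pct(summary.verified_within_12h,
                                summary.events_triggered),
        verified_within_24h=pct(summary.verified_within_24h,
                                summary.events_triggered),
        closed_within_48h=pct(summary.closed_within_48h,
                              summary.alerts_closed),
    )


# ---------------------------------------------------------------------------
# assembled report

@dataclass(frozen=True)
class AttributeReport:
    """All computed system attributes for one region-period."""

    region: str
    events_triggered: int
    signals_sent: int
    reports_total: int
    usefulness: Usefulness
    simplicity: Simplicity
    sensitivity: SensitivityProxies
    timeliness: Timeliness
    correct_format: Pct
    weekly_completeness_avg_pct: Optional[float] = None
    footnotes: tuple[str, ...] = ()


_ROUNDING_FOOTNOTE = (
    "Percentages use round-half-up on the exact ratio; published tables "
    "occasionally truncate instead (e.g. 213/218 renders 98% here)."
)


def attribute_report(summary: "LedgerSummary", region: str = "",
                     weekly_completeness_avg: Optional[float] = None,
                     ) -> AttributeReport:
    """Assemble the full attribute report from a ledger summary."""
    return AttributeReport(
        region=region,
        events_triggered=summary.events_triggered,
        signals_sent=summary.signals_sent,
        reports_total=summary.reports_total,
        usefulness=usefulness(summary),
        simplicity=simplicity(summary),
        sensitivity=sensitivity_proxies(summary),
        timeliness=timeliness(summary),
        correct_format=pct(summary.reports_correct_format,
                           summary.reports_total),
        weekly_completeness_avg_pct=(
            None if weekly_completeness_avg is None
            else 100.0 * weekly_completeness_avg),
        footnotes=(_ROUNDING_FOOTNOTE,),
    )


_CODE_LABELS = {
    2: "Acute diarrhoeal disease (ADD)",
    4: "Fever and rash",
    9: "Fever, cough, difficulty breathing, tiredness",
    14: "Cluster of unusual illnesses or death in people",
}


def report_markdown(report: AttributeReport) -> str:
    """Human-readable summary table, mirroring the descriptive-results row
    order of a regional CBS evaluation."""
    u, s, p, t = (report.usefulness, report.simplicity,
                  report.sensitivity, report.timeliness)
    rows = [
        ("Total signals triggered (events)", str(report.events_triggered)),
        ("Events verified within 12 h", str(t.verified_within_12h)),
        ("Events verified within 24 h", str(t.verified_within_24h)),
        ("Signals dismissed by supervisor", str(u.supervisor_dismissal)),
        ("Alerts escalated", str(u.escalation)),
    ]
    for code, share in u.composition_by_code.items():
        label = _CODE_LABELS.get(code, f"code {code}")
        rows.append((f"  … {label}", str(share)))
    rows += [
        ("Alerts closed (response)", str(u.response)),
        ("Alerts dismissed by authorities", str(p.dismissed_by_authorities)),
        ("Alerts with documented outcome", str(p.documented_outcome)),
        ("  … action taken", str(p.action_taken_of_documented)),
        ("  … lab-confirmed positive", str(p.lab_confirmed_of_actioned)),
        ("Alerts closed within 48 h", str(t.closed_within_48h)),
        ("Total reports sent", str(report.reports_total)),
        ("Correct format of report", str(report.correct_format)),
        ("Total signals sent", str(report.signals_sent)),
        ("Signals verified", str(s.verified_of_sent)),
        ("  … kept as health events", str(s.kept_of_verified)),
    ]
    if report.weekly_completeness_avg_pct is not None:
        rows.append(("Weekly completeness (period average)",
                     f"{report.weekly_completeness_avg_pct:.1f}%"))
    width = max(len(name) for name, _ in rows)
    lines = [f"System attributes — {report.region or 'ledger'}", ""]
    lines += [f"{name.ljust(width)}  {value}" for name, value in rows]
    if p.note:
        lines += ["", f"Note: {p.note}"]
    for fn in report.footnotes:
        lines += ["", f"Footnote: {fn}"]
    return "\n".join(lines) + "\n"
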