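"""Harvester -> interpreter chain.

``harvest`` emulates the SMS-harvester server: it persists raw messages in
arrival order, rejects unparseable timestamps, and collapses exact duplicate
texts (same sender, same text, same calendar day) to the latest copy.
``interpret`` emulates the interpreter server: it resolves each sender phone
to a facility, decodes the coded text, and emits structured session reports
(FS/OS) and weekly plan records (WK), with everything else landing in the
reject log.

Conservation holds throughout: every harvested input message ends up as
exactly one session report, weekly plan, or reject record.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .codec import (
    CodedReport,
    CodeTable,
    Issue,
    UnclassifiableMessage,
    decode_message,
)
from .registry import UNKNOWN_SENDER, Registry, resolve_sender

#: Reporting timezone (Nigeria, UTC+01:00); naive timestamps are taken as local.
DEFAULT_TZ = dt.timezone(dt.timedelta(hours=1))

REJECT_REASONS = ("unknown_sender", "unclassifiable_type", "malformed_tokens",
                  "duplicate", "bad_timestamp")


@dataclass(frozen=True)
class RawMessage:
    message_id: str
    sender_phone: str
    received_at: dt.datetime
    text: str


@dataclass
class SessionReport:
    """Structured per-antigen data for one facility-session."""

    facility_id: str
    session_date: dt.date
    session_type: str  # fixed_post | outreach
    antigen_data: dict[str, dict[str, int | None]]
    source_message_id: str
    conducted_sessions: int | None = None
    issues: list[Issue] = field(default_factory=list)

    def children(self, antigen: str) -> int | None:
        return self.antigen_data.get(antigen, {}).get("children")

    def doses_opened(self, antigen: str) -> int | None:
        return self.antigen_data.get(antigen, {}).get("doses_opened")


@dataclass
class WeeklyPlan:
    facility_id: str
    plan_date: dt.date
    planned_fixed: int | None
    planned_outreach: int | None
    source_message_id: str
    issues: list[Issue] = field(default_factory=list)


@dataclass(frozen=True)
class RejectRecord:
    message_id: str
    reason: str
    detail: str = ""


@dataclass
class HarvestResult:
    log: list[RawMessage]          # ordered by received_at
    rejects: list[RejectRecord]    # duplicates + bad timestamps

    @property
    def n_input(self) -> int:
        return len(self.log) + len(self.rejects)


@dataclass
class InterpretResult:
    session_reports: list[SessionReport]
    weekly_plans: list[WeeklyPlan]
    rejects: list[RejectRecord]

    def conservation_total(self) -> int:
        return len(self.session_reports) + len(self.weekly_plans) + len(self.rejects)


def _parse_timestamp(value) -> dt.datetime:
    if isinstance(value, dt.datetime):
        ts = value
    else:
        ts = pd.Timestamp(str(value)).to_pydatetime()
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=DEFAULT_TZ)
    return ts.astimezone(DEFAULT_TZ)


def harvest(stream: Iterable[dict | RawMessage], registry: Registry | None = None
            ) -> HarvestResult:
    """Collect raw messages into an ordered log with exact-duplicate removal.

    Exact duplicates (same sender, same text, same calendar day) collapse to
    the latest copy; earlier copies are logged as ``duplicate`` rejects.
    Records with unparseable timestamps are rejected. The registry argument
    is accepted for interface symmetry but sender resolution happens at
    interpret time (an unknown sender is still harvested: the harvester's
    job is to secure data from loss).
    """
    parsed: list[RawMessage] = []
    rejects: list[RejectRecord] = []
    for i, rec in enumerate(stream):
        if isinstance(rec, RawMessage):
            msg = rec
            try:
                msg = RawMessage(msg.message_id, msg.sender_phone,
                                 _parse_timestamp(msg.received_at), msg.text)
            except (ValueError, TypeError) as exc:
                rejects.append(RejectRecord(msg.message_id, "bad_timestamp", str(exc)))
                continue
        else:
            mid = str(rec.get("message_id", f"msg{i}"))
            try:
                ts = _parse_timestamp(rec["received_at"])
            except (ValueError, TypeError, KeyError) as exc:
                rejects.append(RejectRecord(mid, "bad_timestamp", repr(exc)))
                continue
            msg = RawMessage(mid, str(rec["sender_phone"]), ts, str(rec["text"]))
        parsed.append(msg)

    parsed.sort(key=lambda m: (m.received_at, m.message_id))

    latest: dict[tuple, RawMessage] = {}
    for msg in parsed:
        key = (msg.sender_phone, msg.received_at.date(), msg.text.strip())
        if key in latest:
            rejects.append(
                RejectRecord(latest[key].message_id, "duplicate",
                             f"exact duplicate of {msg.message_id}")
            )
        latest[key] = msg
    kept_ids = {m.message_id for m in latest.values()}
    log = [m for m in parsed if m.message_id in kept_ids]
    return HarvestResult(log=log, rejects=rejects)


def load_raw_log(path: str | Path) -> list[dict]:
    """Read a raw message log from CSV or line-delimited JSON."""
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson", ".json"):
        df = pd.read_json(path, lines=True, dtype=str, convert_dates=False)
    else:
        df = pd.read_csv(path, dtype=str)
    return df.to_dict("records")


def _session_report_from(report: CodedReport, table: CodeTable,
                         facility_id: str, date: dt.date,
                         message_id: str, issues: list[Issue]) -> SessionReport:
    antigen_data: dict[str, dict[str, int | None]] = {}
    conducted = None
    for letter, value in report.values.items():
        f = table.field(report.message_type, letter)
        if f.measure == "conducted_sessions":
            conducted = value
        elif f.measure in ("children_vaccinated", "doses_opened") and f.antigen:
            slot = antigen_data.setdefault(
                f.antigen, {"children": None, "doses_opened": None}
            )
            key = "children" if f.measure == "children_vaccinated" else "doses_opened"
            slot[key] = value
    session_type = "fixed_post" if report.message_type == "FS" else "outreach"
    return SessionReport(
        facility_id=facility_id,
        session_date=date,
        session_type=session_type,
        antigen_data=antigen_data,
        source_message_id=message_id,
        conducted_sessions=conducted,
        issues=issues,
    )


def interpret(harvested: HarvestResult, registry: Registry,
              table: CodeTable) -> InterpretResult:
    """Decode the harvested log into session reports, plans, and rejects.

    The session date is the calendar date of message receipt (the design is
    same-day reporting). When a facility sends two *different* texts of the
    same type on one day, the later supersedes: the earlier becomes a
    ``duplicate`` reject whose detail names the superseding message, which
    doubles as the audit trail.
    """
    session_reports: list[SessionReport] = []
    weekly_plans: list[WeeklyPlan] = []
    rejects: list[RejectRecord] = list(harvested.rejects)

    for msg in harvested.log:
        facility_id = resolve_sender(registry, msg.sender_phone)
        if facility_id == UNKNOWN_SENDER:
            rejects.append(
                RejectRecord(msg.message_id, "unknown_sender", msg.sender_phone)
            )
            continue
        try:
            report, issues = decode_message(msg.text, table)
        except UnclassifiableMessage as exc:
            rejects.append(
                RejectRecord(msg.message_id, "unclassifiable_type", str(exc))
            )
            continue
        date = msg.received_at.date()
        if not report.values:
            rejects.append(
                RejectRecord(msg.message_id, "malformed_tokens",
                             "no parseable tokens: " + msg.text[:60])
            )
            continue
        if report.message_type == "WK":
            wk_letters = table.letters("WK")
            planned = {
                table.field("WK", letter).session_type: report.values.get(letter)
                for letter in wk_letters
            }
            weekly_plans.append(
                WeeklyPlan(
                    facility_id=facility_id,
                    plan_date=date,
                    planned_fixed=planned.get("fixed_post"),
                    planned_outreach=planned.get("outreach"),
                    source_message_id=msg.message_id,
                    issues=issues,
                )
            )
        else:
            session_reports.append(
                _session_report_from(report, table, facility_id, date,
                                     msg.message_id, issues)
            )

    # Supersede rule: one report per (facility, date, session type); the log
    # is time-ordered, so the last one wins.
    final: dict[tuple, SessionReport] = {}
    for rep in session_reports:
        key = (rep.facility_id, rep.session_date, rep.session_type)
        if key in final:
            rejects.append(
                RejectRecord(final[key].source_message_id, "duplicate",
                             f"superseded by {rep.source_message_id}")
            )
        final[key] = rep
    kept = [r for r in session_reports
            if final[(r.facility_id, r.session_date, r.session_type)] is r]

    final_plans: dict[tuple, WeeklyPlan] = {}
    for plan in weekly_plans:
        key = (plan.facility_id, plan.plan_date.isocalendar()[:2])
        if key in final_plans:
            rejects.append(
                RejectRecord(final_plans[key].source_message_id, "duplicate",
                             f"superseded by {plan.source_message_id}")
            )
        final_plans[key] = plan
    kept_plans = [p for p in weekly_plans
                  if final_plans[(p.facility_id, p.plan_date.isocalendar()[:2])] is p]

    return InterpretResult(session_reports=kept, weekly_plans=kept_plans,
                           rejects=rejects)


def run_pipeline(stream: Iterable[dict | RawMessage], registry: Registry,
                 table: CodeTable) -> InterpretResult:
    """Convenience: harvest then interpret in one call."""
    return interpret(harvest(stream), registry, table)


# ---------------------------------------------------------------------------
# Tabular exports (stable column orders)

def session_reports_frame(reports: list[SessionReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for antigen in sorted(r.antigen_data):
            slot = r.antigen_data[antigen]
            rows.append({
                "facility_id": r.facility_id,
                "session_date": r.session_date.isoformat(),
                "session_type": r.session_type,
                "antigen": antigen,
                "children": slot.get("children"),
                "doses_opened": slot.get("doses_opened"),
                "source_message_id": r.source_message_id,
            })
    return pd.DataFrame(rows, columns=["facility_id", "session_date",
                                       "session_type", "antigen", "children",
                                       "doses_opened", "source_message_id"])


def rejects_frame(rejects: list[RejectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"message_id": r.message_id, "reason": r.reason, "detail": r.detail}
         for r in rejects],
        columns=["message_id", "reason", "detail"],
    )


def weekly_plans_frame(plans: list[WeeklyPlan]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "facility_id": p.facility_id,
            "plan_date": p.plan_date.isoformat(),
            "planned_fixed": p.planned_fixed,
            "planned_outreach": p.planned_outreach,
            "source_message_id": p.source_message_id,
        } for p in plans],
        columns=["facility_id", "plan_date", "planned_fixed",
                 "planned_outreach", "source_message_id"],
    )
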