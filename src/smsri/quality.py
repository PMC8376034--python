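"""Data-quality statistics and anomaly flags for the daily reporting stream.

The quality engine answers the questions a district immunization officer
asks of administrative data: which facilities are reporting at all
(participation), how much of the expected reporting arrives (completeness,
received-vs-expected), when during the week reports arrive (weekday
profile), whether per-antigen counts are internally consistent (a child
count above the doses made available by opening vials is impossible), how
much vaccine is wasted (open-vial wastage), and how much of service
delivery is supervised.

Flag semantics
--------------
For one antigen within one session report, exactly one of four states
holds (mutual exclusivity):

* IMPOSSIBLE_COUNT — children > doses, both present (includes the
  degenerate doses == 0 with children > 0, where the rate is undefined;
  on evaluable sessions the condition is exactly rate < 0);
* not evaluable — children or doses absent, or doses == 0 without excess
  children;
* consistent — 0 <= wastage rate <= threshold;
* HIGH_WASTAGE — rate above the threshold (default 0.80).

Absent values never count as zero: a facility that texted only children
counts is non-evaluable, not impossible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codec import PENTA_SHARED
from .ingest import SessionReport
from .registry import ExpectedCounts, Registry

FLAG_TYPES = ("IMPOSSIBLE_COUNT", "HIGH_WASTAGE", "ZERO_DOSES_OUTREACH",
              "MISSING_REPORT", "MALFORMED")

DEFAULT_WASTAGE_THRESHOLD = 0.80

WEEKDAYS = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday",
            "Saturday", "Sunday")


@dataclass(frozen=True)
class Window:
    """Inclusive analysis window [start, end]."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("window end precedes start")

    @property
    def days(self) -> int:
        """Number of calendar days, both endpoints inclusive."""
        return (self.end - self.start).days + 1

    @property
    def weekdays(self) -> int:
        return sum(1 for d in self.dates() if d.weekday() < 5)

    @property
    def weeks(self) -> float:
        """Window length in weeks, from the weekday count (sessions and
        expectations attach to weekdays only)."""
        return self.weekdays / 5.0

    def dates(self) -> Iterable[dt.date]:
        for i in range(self.days):
            yield self.start + dt.timedelta(days=i)

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end

    def iso_weeks(self) -> list[tuple[int, int]]:
        seen: list[tuple[int, int]] = []
        for d in self.dates():
            wk = d.isocalendar()[:2]
            if not seen or seen[-1] != wk:
                seen.append(wk)
        return seen


#: The pilot ran 151 days, December 2017 through April 2018.
PILOT_WINDOW = Window(dt.date(2017, 12, 1), dt.date(2018, 4, 30))


@dataclass(frozen=True)
class QualityFlag:
    flag_type: str
    facility_id: str
    session_date: dt.date
    antigen: str | None = None
    session_type: str | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        if self.flag_type not in FLAG_TYPES:
            raise ValueError(f"unknown flag type {self.flag_type!r}")


@dataclass(frozen=True)
class WastageValue:
    """Open-vial wastage for one antigen in one session.

    rate = (doses_opened - children) / doses_opened; rate <= 1 always, and
    on evaluable sessions rate < 0 exactly when the impossible-count
    condition (children > doses) holds. Not evaluable when doses == 0 or
    either value is absent.
    """

    antigen: str
    doses_opened: int | None
    children: int | None
    evaluable: bool
    rate: float | None

    @classmethod
    def compute(cls, antigen: str, children: int | None,
                doses_opened: int | None) -> "WastageValue":
        if children is None or doses_opened is None or doses_opened == 0:
            return cls(antigen, doses_opened, children, False, None)
        rate = (doses_opened - children) / doses_opened
        return cls(antigen, doses_opened, children, True, rate)


@dataclass
class CompletenessSummary:
    participation_rate: float
    participation_percent: int
    n_reporting: int
    n_selected: int
    per_facility_completeness: dict[str, float]
    window: Window


def _round_percent(numerator: float, denominator: float) -> int:
    """Nearest-integer percentage, the display convention throughout."""
    if denominator == 0:
        return 0
    return int(round(100.0 * numerator / denominator))


def participation(reports: Sequence[SessionReport], registry: Registry,
                  window: Window) -> CompletenessSummary:
    """Participation and per-facility completeness over the window.

    Participation counts distinct facilities with at least one report in the
    window against *all* registry rows (selected facilities, including those
    later excluded — matching how the pilot's overall rate was reported).
    Per-facility completeness divides reports received by reports expected
    (planned weekly sessions x weeks in window, weekday-only); values above
    1 indicate over-reporting and are preserved, not clipped.
    """
    if len(registry) == 0:
        raise ValueError("empty registry")
    in_window = [r for r in reports if window.contains(r.session_date)]
    reporters = {r.facility_id for r in in_window}
    weeks = window.weeks
    per_fac: dict[str, float] = {}
    received: dict[str, int] = {}
    for r in in_window:
        received[r.facility_id] = received.get(r.facility_id, 0) + 1
    for fac in registry:
        expected = (fac.planned_fixed_per_week + fac.planned_outreach_per_week) * weeks
        got = received.get(fac.facility_id, 0)
        per_fac[fac.facility_id] = got / expected if expected > 0 else float("nan")
    rate = len(reporters) / registry.n_selected
    return CompletenessSummary(
        participation_rate=rate,
        participation_percent=_round_percent(len(reporters), registry.n_selected),
        n_reporting=len(reporters),
        n_selected=registry.n_selected,
        per_facility_completeness=per_fac,
        window=window,
    )


def weekly_received_vs_expected(reports: Sequence[SessionReport],
                                expected: ExpectedCounts,
                                week: tuple[int, int]) -> dict:
    """Received vs expected session reports for one ISO (year, week)."""
    fixed = outreach = 0
    for r in reports:
        if r.session_date.isocalendar()[:2] != week:
            continue
        if r.session_type == "fixed_post":
            fixed += 1
        else:
            outreach += 1
    return {
        "fixed": (fixed, expected.fleet_fixed_per_week),
        "outreach": (outreach, expected.fleet_outreach_per_week),
    }


def day_of_week_profile(reports: Sequence[SessionReport],
                        window: Window) -> dict[str, int]:
    """Facility-reporting counts per weekday, aggregated over the window.

    For each calendar date the distinct reporting facilities are counted,
    then summed by weekday. Weekends are included: observed zeros are data.
    """
    by_date: dict[dt.date, set[str]] = {}
    for r in reports:
        if window.contains(r.session_date):
            by_date.setdefault(r.session_date, set()).add(r.facility_id)
    profile = {day: 0 for day in WEEKDAYS}
    for date, facs in by_date.items():
        profile[WEEKDAYS[date.weekday()]] += len(facs)
    return profile


def _antigen_pairs(report: SessionReport):
    """Yield (antigen, children, doses) pairs to evaluate for consistency.

    Pentavalent doses travel in a shared vial: the shared doses value is
    compared against the summed Penta1-3 children counts.
    """
    for antigen, slot in report.antigen_data.items():
        if antigen == PENTA_SHARED:
            continue
        if antigen.startswith("PENTA"):
            continue  # handled jointly below
        yield antigen, slot.get("children"), slot.get("doses_opened")
    shared = report.antigen_data.get(PENTA_SHARED, {})
    doses = shared.get("doses_opened")
    penta_children = [report.antigen_data.get(a, {}).get("children")
                      for a in ("PENTA1", "PENTA2", "PENTA3")]
    present = [c for c in penta_children if c is not None]
    if doses is not None or present:
        children = sum(present) if present else None
        yield PENTA_SHARED, children, doses


def consistency_flags(report: SessionReport,
                      wastage_threshold: float = DEFAULT_WASTAGE_THRESHOLD
                      ) -> list[QualityFlag]:
    """Per-antigen internal-consistency flags for one session report.

    children > doses -> IMPOSSIBLE_COUNT (a data-entry error: more children
    vaccinated than doses available from the opened vials); wastage rate
    above the threshold -> HIGH_WASTAGE. An outreach report that records
    zero doses opened for an antigen while reporting any activity at all
    earns an informational ZERO_DOSES_OUTREACH flag.
    """
    flags: list[QualityFlag] = []
    any_activity = any(
        v is not None and v > 0
        for slot in report.antigen_data.values()
        for v in slot.values()
    )
    for antigen, children, doses in _antigen_pairs(report):
        wv = WastageValue.compute(antigen, children, doses)
        if children is not None and doses is not None and children > doses:
            # Covers doses == 0 with children > 0: impossible even though
            # the wastage rate itself is undefined there.
            flags.append(QualityFlag(
                "IMPOSSIBLE_COUNT", report.facility_id, report.session_date,
                antigen, report.session_type,
                f"children={children} > doses_opened={doses}",
            ))
        elif wv.evaluable:
            if wv.rate > wastage_threshold:
                flags.append(QualityFlag(
                    "HIGH_WASTAGE", report.facility_id, report.session_date,
                    antigen, report.session_type,
                    f"wastage_rate={wv.rate:.2f} children={children} doses={doses}",
                ))
        if (report.session_type == "outreach" and doses == 0 and any_activity):
            flags.append(QualityFlag(
                "ZERO_DOSES_OUTREACH", report.facility_id, report.session_date,
                antigen, report.session_type,
                "no doses opened during an active outreach session",
            ))
    return flags


def all_flags(reports: Sequence[SessionReport],
              wastage_threshold: float = DEFAULT_WASTAGE_THRESHOLD
              ) -> list[QualityFlag]:
    out: list[QualityFlag] = []
    for r in reports:
        out.extend(consistency_flags(r, wastage_threshold))
    return out


@dataclass
class DiscrepancySummary:
    """Facilities with >=1 impossible count, per antigen and jointly.

    Two denominators are reported because administrative summaries switch
    between them: facilities that ever reported, and facilities included
    (active). The joint condition requires a flag for *every* antigen in
    the requested set. A facility is counted on its first flagged session
    (>=1 rule, stated here as output metadata).
    """

    per_antigen: dict[str, dict]
    joint: dict
    n_reporting: int
    n_included: int
    session_type: str | None
    rule: str = "facility counted if >=1 flagged session in window"


def discrepancy_summary(reports: Sequence[SessionReport], registry: Registry,
                        antigens: Sequence[str], window: Window,
                        session_type: str | None = None) -> DiscrepancySummary:
    """Count facilities with impossible counts, per antigen and jointly."""
    in_window = [r for r in reports if window.contains(r.session_date)]
    reporting = {r.facility_id for r in in_window}
    flagged: dict[str, set[str]] = {a: set() for a in antigens}
    for r in in_window:
        if session_type is not None and r.session_type != session_type:
            continue
        for f in consistency_flags(r):
            if f.flag_type == "IMPOSSIBLE_COUNT" and f.antigen in flagged:
                flagged[f.antigen].add(r.facility_id)
    n_reporting = len(reporting)
    n_included = registry.n_active
    per_antigen = {
        a: {
            "n_facilities": len(facs),
            "percent_of_reporting": _round_percent(len(facs), n_reporting),
            "percent_of_included": _round_percent(len(facs), n_included),
        }
        for a, facs in flagged.items()
    }
    joint_facs = set.intersection(*flagged.values()) if flagged else set()
    joint = {
        "n_facilities": len(joint_facs),
        "percent_of_reporting": _round_percent(len(joint_facs), n_reporting),
        "percent_of_included": _round_percent(len(joint_facs), n_included),
    }
    return DiscrepancySummary(per_antigen=per_antigen, joint=joint,
                              n_reporting=n_reporting, n_included=n_included,
                              session_type=session_type)


@dataclass
class SupervisionCoverage:
    ratio: float | None        # total supervised / total conducted; None if 0 conducted
    per_day: pd.DataFrame      # date, conducted, supervised
    violations: list[str]      # facility-days where supervised > conducted


def supervision_coverage(log: pd.DataFrame, window: Window) -> SupervisionCoverage:
    """Mean supervision coverage over the window.

    ``log`` columns: facility_id, date, sessions_conducted, sessions_supervised.
    The ratio is recomputed from window totals (never an average of daily
    ratios). Facility-days with supervised > conducted are flagged as
    violations but still counted.
    """
    df = log.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df = df[(df["date"] >= window.start) & (df["date"] <= window.end)]
    violations = [
        f"{r.facility_id}@{r.date}"
        for r in df.itertuples(index=False)
        if r.sessions_supervised > r.sessions_conducted
    ]
    per_day = (df.groupby("date", as_index=False)
                 [["sessions_conducted", "sessions_supervised"]].sum()
                 .rename(columns={"sessions_conducted": "conducted",
                                  "sessions_supervised": "supervised"}))
    total_c = int(per_day["conducted"].sum()) if len(per_day) else 0
    total_s = int(per_day["supervised"].sum()) if len(per_day) else 0
    ratio = (total_s / total_c) if total_c > 0 else None
    return SupervisionCoverage(ratio=ratio, per_day=per_day, violations=violations)


@dataclass
class DoseChildrenSeries:
    """Fleet-aggregated daily (children, doses opened) totals for one antigen."""

    antigen: str
    session_type: str
    daily: pd.DataFrame        # date, children, doses_opened
    children_slope: float
    children_slope_se: float
    doses_slope: float
    doses_slope_se: float

    @property
    def no_trend(self) -> bool:
        """Descriptive: both OLS slopes within 2 standard errors of zero."""
        return (abs(self.children_slope) <= 2 * self.children_slope_se
                and abs(self.doses_slope) <= 2 * self.doses_slope_se)


def _ols_slope(y: np.ndarray) -> tuple[float, float]:
    """Slope and its standard error for y against day index (descriptive)."""
    n = len(y)
    if n < 3:
        return 0.0, float("inf")
    x = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sxx = float(((x - x.mean()) ** 2).sum())
    se = float(np.sqrt(resid.var(ddof=2) / sxx)) if sxx > 0 else float("inf")
    return float(slope), se


def dose_children_series(reports: Sequence[SessionReport], antigen: str,
                         session_type: str, window: Window) -> DoseChildrenSeries:
    """Daily fleet totals of children vaccinated and doses opened.

    Suitable for trend plotting; also carries descriptive OLS slopes (no
    hypothesis test is implied) so a stationary stream can be summarised as
    showing no evidence of a trend.
    """
    totals: dict[dt.date, list[int]] = {}
    for r in reports:
        if r.session_type != session_type or not window.contains(r.session_date):
            continue
        c = r.children(antigen)
        d = r.doses_opened(antigen)
        if c is None and d is None:
            continue
        slot = totals.setdefault(r.session_date, [0, 0])
        slot[0] += c or 0
        slot[1] += d or 0
    dates = sorted(totals)
    daily = pd.DataFrame(
        {"date": dates,
         "children": [totals[d][0] for d in dates],
         "doses_opened": [totals[d][1] for d in dates]}
    )
    c_slope, c_se = _ols_slope(daily["children"].to_numpy(dtype=float)
                               if len(daily) else np.array([]))
    d_slope, d_se = _ols_slope(daily["doses_opened"].to_numpy(dtype=float)
                               if len(daily) else np.array([]))
    return DoseChildrenSeries(antigen=antigen, session_type=session_type,
                              daily=daily, children_slope=c_slope,
                              children_slope_se=c_se, doses_slope=d_slope,
                              doses_slope_se=d_se)


def flags_frame(flags: Sequence[QualityFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "flag_type": f.flag_type,
            "facility_id": f.facility_id,
            "session_date": f.session_date.isoformat(),
            "session_type": f.session_type,
            "antigen": f.antigen,
            "detail": f.detail,
        } for f in flags],
        columns=["flag_type", "facility_id", "session_date", "session_type",
                 "antigen", "detail"],
    )
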