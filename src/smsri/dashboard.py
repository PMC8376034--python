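"""Dashboard aggregation and export.

Rolls the structured session reports and quality outputs up into the
indicator series a district dashboard displays, and exports them in an
aggregate data-value layout (dataElement, orgUnit, period, value) modelled
on DHIS2's, without claiming API compatibility.

Ratios are always recomputed from aggregated numerators and denominators
at every granularity — averaging per-facility ratios across facilities of
different sizes is exactly the administrative-data error this tool exists
to expose.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .ingest import SessionReport, WeeklyPlan
from .quality import (
    QualityFlag,
    Window,
    day_of_week_profile,
    participation,
    supervision_coverage,
)
from .registry import Registry, expected_counts

FLEET = "FLEET"

INDICATORS = (
    "sessions_conducted_vs_planned",
    "children_by_antigen",
    "wastage_rate",
    "participation",
    "completeness",
    "supervision_coverage",
    "weekday_profile",
)

GRANULARITIES = ("day", "week", "month")


class DashboardError(ValueError):
    pass


@dataclass
class IndicatorSeries:
    scope: str                   # facility_id or FLEET
    indicator: str
    granularity: str             # day | week | month
    values: dict[str, float]     # period label -> value
    dimension: str | None = None  # e.g. antigen or weekday, when applicable

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise DashboardError(f"unknown indicator {self.indicator!r}")
        if self.granularity not in GRANULARITIES:
            raise DashboardError(f"unknown granularity {self.granularity!r}")

    @property
    def data_element(self) -> str:
        if self.dimension:
            return f"{self.indicator}.{self.dimension}"
        return self.indicator


def _iso_week_label(date: dt.date) -> str:
    year, week, _ = date.isocalendar()
    return f"{year}W{week:02d}"


def _month_label(date: dt.date) -> str:
    return f"{date.year}{date.month:02d}"


def build_dashboard(reports: Sequence[SessionReport],
                    plans: Sequence[WeeklyPlan],
                    flags: Sequence[QualityFlag],
                    registry: Registry,
                    window: Window,
                    supervision_log: pd.DataFrame | None = None
                    ) -> list[IndicatorSeries]:
    """Assemble the indicator series collection for one analysis window.

    Count indicators (children by antigen) roll up by summation; ratio
    indicators (sessions conducted vs planned, wastage) are recomputed from
    rolled-up numerators/denominators per period.
    """
    in_window = [r for r in reports if window.contains(r.session_date)]
    series: list[IndicatorSeries] = []
    if not in_window and not plans and supervision_log is None:
        return series

    # Fleet participation: one summary value (percent).
    summary = participation(in_window, registry, window)
    series.append(IndicatorSeries(
        scope=FLEET, indicator="participation", granularity="month",
        values={_month_label(window.end): float(summary.participation_percent)},
    ))
    for fid, completeness in sorted(summary.per_facility_completeness.items()):
        series.append(IndicatorSeries(
            scope=fid, indicator="completeness", granularity="month",
            values={_month_label(window.end): round(completeness, 4)},
        ))

    # Children vaccinated by antigen: daily fleet counts.
    by_antigen: dict[str, dict[str, float]] = {}
    for r in in_window:
        for antigen, slot in r.antigen_data.items():
            c = slot.get("children")
            if c is None:
                continue
            day = r.session_date.isoformat()
            by_antigen.setdefault(antigen, {}).setdefault(day, 0.0)
            by_antigen[antigen][day] += c
    for antigen in sorted(by_antigen):
        series.append(IndicatorSeries(
            scope=FLEET, indicator="children_by_antigen", granularity="day",
            values=dict(sorted(by_antigen[antigen].items())),
            dimension=antigen,
        ))

    # Weekly sessions conducted vs planned, per facility and fleet-wide:
    # ratio of received session reports to the planned weekly schedule.
    exp = expected_counts(registry)
    weekly_by_fac: dict[str, dict[str, int]] = {}
    for r in in_window:
        wk = _iso_week_label(r.session_date)
        weekly_by_fac.setdefault(r.facility_id, {}).setdefault(wk, 0)
        weekly_by_fac[r.facility_id][wk] += 1
    fleet_weekly_planned = (exp.fleet_fixed_per_week
                            + exp.fleet_outreach_per_week)
    fleet_weekly: dict[str, float] = {}
    for fid in sorted(weekly_by_fac):
        planned = sum(exp.per_facility[fid].values())
        if planned == 0:
            continue
        values = {wk: round(n / planned, 4)
                  for wk, n in sorted(weekly_by_fac[fid].items())}
        series.append(IndicatorSeries(
            scope=fid, indicator="sessions_conducted_vs_planned",
            granularity="week", values=values,
        ))
        for wk, n in weekly_by_fac[fid].items():
            fleet_weekly[wk] = fleet_weekly.get(wk, 0.0) + n
    if fleet_weekly and fleet_weekly_planned > 0:
        series.append(IndicatorSeries(
            scope=FLEET, indicator="sessions_conducted_vs_planned",
            granularity="week",
            values={wk: round(n / fleet_weekly_planned, 4)
                    for wk, n in sorted(fleet_weekly.items())},
        ))

    # Fleet wastage rate per antigen, weekly, from summed numerators.
    wastage_num: dict[str, dict[str, float]] = {}
    wastage_den: dict[str, dict[str, float]] = {}
    for r in in_window:
        wk = _iso_week_label(r.session_date)
        for antigen, slot in r.antigen_data.items():
            c, d = slot.get("children"), slot.get("doses_opened")
            if c is None or d is None or d == 0:
                continue
            wastage_num.setdefault(antigen, {}).setdefault(wk, 0.0)
            wastage_den.setdefault(antigen, {}).setdefault(wk, 0.0)
            wastage_num[antigen][wk] += d - c
            wastage_den[antigen][wk] += d
    for antigen in sorted(wastage_num):
        values = {wk: round(wastage_num[antigen][wk] / wastage_den[antigen][wk], 4)
                  for wk in sorted(wastage_num[antigen])
                  if wastage_den[antigen][wk] > 0}
        series.append(IndicatorSeries(
            scope=FLEET, indicator="wastage_rate", granularity="week",
            values=values, dimension=antigen,
        ))

    # Weekday reporting profile over the window.
    profile = day_of_week_profile(in_window, window)
    series.append(IndicatorSeries(
        scope=FLEET, indicator="weekday_profile", granularity="month",
        values={day: float(n) for day, n in profile.items()},
    ))

    if supervision_log is not None and len(supervision_log):
        cov = supervision_coverage(supervision_log, window)
        if cov.ratio is not None:
            series.append(IndicatorSeries(
                scope=FLEET, indicator="supervision_coverage",
                granularity="month",
                values={_month_label(window.end): round(cov.ratio, 4)},
            ))
    return series


def series_frame(series: Sequence[IndicatorSeries]) -> pd.DataFrame:
    """Long-format aggregate data-value table, deterministically ordered."""
    rows = [
        {"dataElement": s.data_element, "orgUnit": s.scope,
         "period": period, "value": value}
        for s in series
        for period, value in s.values.items()
    ]
    df = pd.DataFrame(rows, columns=["dataElement", "orgUnit", "period",
                                     "value"])
    return df.sort_values(["dataElement", "orgUnit", "period"],
                          kind="mergesort").reset_index(drop=True)


def export_dashboard(series: Sequence[IndicatorSeries], out_dir: str | Path,
                     formats: Sequence[str] = ("csv", "json")) -> list[Path]:
    """Write indicators.csv and/or dashboard.json; re-export is
    byte-identical for the same series."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    df = series_frame(series)
    if "csv" in formats:
        path = out_dir / "indicators.csv"
        df.to_csv(path, index=False)
        written.append(path)
    if "json" in formats:
        path = out_dir / "dashboard.json"
        payload = [
            {"dataElement": s.data_element, "orgUnit": s.scope,
             "granularity": s.granularity,
             "values": dict(sorted(s.values.items()))}
            for s in sorted(series, key=lambda s: (s.data_element, s.scope))
        ]
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
        written.append(path)
    return written


def import_dashboard(path: str | Path) -> pd.DataFrame:
    """Read back an exported indicators.csv (round-trip counterpart)."""
    return pd.read_csv(path, dtype={"dataElement": str, "orgUnit": str,
                                    "period": str})
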