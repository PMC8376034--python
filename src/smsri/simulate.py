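"""Synthetic facility fleets and raw SMS streams, with retained ground truth.

Two entry points:

* :func:`simulate_fleet` — a configurable generator whose defaults mirror
  the pilot's structure: ~50 facilities in two districts with a 6%/12%/82%
  hospital / urban-PHC / primary mix, weekday-only sessions with a Tuesday
  reporting peak decaying through the week, partial reporting, and
  injectable pathologies (impossible counts, malformed tokens, missing
  reports, zero-dose outreach sessions). Every emitted message maps to one
  ground-truth record so detection can be scored.

* :func:`pilot_fixture` — a deterministic dataset emulating the pilot
  itself: 55 facilities selected (25 urban-district, 30 rural-district),
  50 included, 47 ever reporting over a 151-day window, fleet expectations
  of 66 fixed-post and 33 outreach sessions per week, and anomaly counts
  pinned to the pilot's published figures.

Generator constraint: uncorrupted sessions always satisfy
doses_opened >= children per antigen (doses come from whole opened vials),
so an impossible-count flag on clean data is a false positive by
construction — there are none.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codec import PENTA_SHARED, CodeTable, default_code_table
from .ingest import InterpretResult, RawMessage
from .quality import PILOT_WINDOW, WEEKDAYS, Window, all_flags
from .registry import HealthFacility, Registry, expected_counts

SINGLE_VIAL_ANTIGENS = ("BCG", "OPV", "MEASLES", "YELLOW_FEVER", "IPV")
PENTA_DOSES = ("PENTA1", "PENTA2", "PENTA3")

#: Standard vial presentations (doses per vial); pentavalent ships in
#: single-dose vials, so its shared-vial wastage is structurally zero here.
DEFAULT_VIAL_SIZES = {
    "BCG": 20,
    "OPV": 20,
    PENTA_SHARED: 1,
    "MEASLES": 10,
    "YELLOW_FEVER": 10,
    "IPV": 10,
}

#: Mean children vaccinated per session, per antigen (Poisson means).
DEFAULT_MEAN_CHILDREN = {
    "BCG": 6,
    "OPV": 8,
    "PENTA1": 8,
    "PENTA2": 7,
    "PENTA3": 6,
    "MEASLES": 8,
    "YELLOW_FEVER": 8,
    "IPV": 5,
}

#: Tuesday peak with decay through the week; no weekend sessions.
DEFAULT_WEEKDAY_P = {
    "Monday": 0.50,
    "Tuesday": 0.70,
    "Wednesday": 0.55,
    "Thursday": 0.45,
    "Friday": 0.35,
    "Saturday": 0.0,
    "Sunday": 0.0,
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ErrorRates:
    impossible_count: float = 0.0    # fraction of reported sessions
    malformed_token: float = 0.0     # fraction of messages
    missing_report: float = 0.0      # extra drop applied to scheduled sessions
    zero_dose_outreach: float = 0.0  # fraction of outreach sessions

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"error rate {name}={v} outside [0,1]")


@dataclass
class FleetConfig:
    n_facilities: int = 50
    type_fractions: dict[str, float] = field(default_factory=lambda: {
        "hospital": 0.06, "urban_phc": 0.12, "primary_hf": 0.82})
    inactive_fraction: float = 0.0
    district_fractions: dict[str, float] = field(default_factory=lambda: {
        "Keffi": 25 / 55, "Keana": 30 / 55})
    weekday_report_probability: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEEKDAY_P))
    outreach_report_factor: float = 0.4
    wk_report_probability: float = 0.3
    error_rates: ErrorRates = field(default_factory=ErrorRates)
    mean_children: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_CHILDREN))
    vial_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VIAL_SIZES))
    extra_vial_rate: float = 0.05
    supervised_fraction: float = 0.3
    #: When set, clean sessions are clamped so their wastage rate never
    #: exceeds this value (children raised to the minimum consistent fill).
    max_clean_wastage: float | None = None
    #: Minimum children per antigen on outreach sessions (>=1 removes
    #: structural zero-dose outreach from clean streams).
    outreach_min_children: int = 0
    window: Window = PILOT_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_fractions.values()) - 1.0) > 1e-9:
            raise SimulationError("type_fractions must sum to 1")
        for p in self.weekday_report_probability.values():
            if not 0.0 <= p <= 1.0:
                raise SimulationError("weekday probabilities must lie in [0,1]")
        if not 0.0 <= self.inactive_fraction <= 1.0:
            raise SimulationError("inactive_fraction outside [0,1]")
        if self.window.days < 7:
            raise SimulationError("window shorter than one week")


@dataclass
class GroundTruth:
    """Per scheduled session: what really happened, before corruption."""

    sessions: list[dict]
    config: FleetConfig

    def by_message(self) -> dict[str, dict]:
        return {s["message_id"]: s for s in self.sessions
                if s.get("message_id") is not None}

    @property
    def n_scheduled(self) -> int:
        return len(self.sessions)

    @property
    def n_reported(self) -> int:
        return sum(1 for s in self.sessions if s["reported"])

    def corrupted(self, kind: str) -> set[str]:
        return {s["message_id"] for s in self.sessions
                if s.get("message_id") and kind in s["corruptions"]}


@dataclass
class SimulatedFleet:
    registry: Registry
    messages: list[RawMessage]
    supervision_log: pd.DataFrame
    truth: GroundTruth
    schedules: dict[str, dict[str, list[int]]]


def _apportion(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n items over named fractions."""
    raw = {k: n * f for k, f in fractions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


_DEFAULT_FIXED = {"hospital": 5, "urban_phc": 2, "primary_hf": 1}
_FIXED_DAY_SETS = {
    5: [0, 1, 2, 3, 4],
    4: [0, 1, 2, 3],
    3: [0, 1, 3],
    2: [1, 3],        # Tue, Thu
    1: None,          # single day: cycled per facility
}
_PRIMARY_DAY_CYCLE = [1, 2, 3, 0, 4]    # Tuesday-first session assignment
_OUTREACH_DAY_CYCLE = [2, 3, 1, 4, 0]


def build_fleet_registry(config: FleetConfig) -> tuple[Registry, dict]:
    """Deterministic registry + session-day schedules from a FleetConfig."""
    district_counts = _apportion(config.n_facilities, config.district_fractions)
    facilities: list[HealthFacility] = []
    schedules: dict[str, dict[str, list[int]]] = {}
    idx = 0
    cycle_seq = 0
    for district in config.district_fractions:
        type_counts = _apportion(district_counts[district], config.type_fractions)
        ordered = (["hospital"] * type_counts.get("hospital", 0)
                   + ["urban_phc"] * type_counts.get("urban_phc", 0)
                   + ["primary_hf"] * type_counts.get("primary_hf", 0))
        for ftype in ordered:
            idx += 1
            fid = f"HF{idx:03d}"
            fixed = _DEFAULT_FIXED[ftype]
            facilities.append(HealthFacility(
                facility_id=fid,
                name=f"{district} {ftype} {idx}",
                district=district,
                facility_type=ftype,
                phone=f"0803{idx:07d}",
                planned_fixed_per_week=fixed,
                planned_outreach_per_week=1,
                active=True,
            ))
            days = _FIXED_DAY_SETS[fixed]
            if days is None:
                days = [_PRIMARY_DAY_CYCLE[cycle_seq % 5]]
            schedules[fid] = {
                "fixed_days": list(days),
                "outreach_days": [_OUTREACH_DAY_CYCLE[cycle_seq % 5]],
            }
            cycle_seq += 1
    n_inactive = int(round(config.n_facilities * config.inactive_fraction))
    if n_inactive:
        facilities = [
            replace(f, active=False) if i >= len(facilities) - n_inactive else f
            for i, f in enumerate(facilities)
        ]
    return Registry(facilities), schedules


def _draw_session_values(rng: np.random.Generator, config: FleetConfig,
                         session_type: str) -> tuple[dict, dict]:
    """Clean per-antigen children/doses for one session (doses >= children)."""
    children = {a: int(rng.poisson(config.mean_children[a]))
                for a in DEFAULT_MEAN_CHILDREN}
    if session_type == "outreach" and config.outreach_min_children > 0:
        children = {a: max(c, config.outreach_min_children)
                    for a, c in children.items()}
    doses: dict[str, int] = {}
    for a in SINGLE_VIAL_ANTIGENS:
        vial = config.vial_sizes[a]
        d = 0 if children[a] == 0 else int(math.ceil(children[a] / vial)) * vial
        if d > 0 and rng.random() < config.extra_vial_rate:
            d += vial
        doses[a] = d
    penta_total = sum(children[a] for a in PENTA_DOSES)
    vial = config.vial_sizes[PENTA_SHARED]
    doses[PENTA_SHARED] = (0 if penta_total == 0
                           else int(math.ceil(penta_total / vial)) * vial)
    if config.max_clean_wastage is not None:
        min_fill = 1.0 - config.max_clean_wastage
        for a in SINGLE_VIAL_ANTIGENS:
            if doses[a] > 0:
                children[a] = max(children[a],
                                  int(math.ceil(min_fill * doses[a])))
    return children, doses


_CHILD_LETTERS = dict(zip("abcdefgh", ["BCG", "OPV", "PENTA1", "PENTA2",
                                       "PENTA3", "MEASLES", "YELLOW_FEVER",
                                       "IPV"]))
_DOSE_LETTERS = dict(zip("ijklmn", ["BCG", "OPV", PENTA_SHARED, "MEASLES",
                                    "YELLOW_FEVER", "IPV"]))


def session_text(session_type: str, children: dict[str, int],
                 doses: dict[str, int], conducted: int = 1) -> str:
    """Render one session as canonical coded text under the default table."""
    prefix = "FS" if session_type == "fixed_post" else "OS"
    tokens = [prefix]
    tokens += [f"{letter}{children[a]}" for letter, a in _CHILD_LETTERS.items()]
    tokens += [f"{letter}{doses[a]}" for letter, a in _DOSE_LETTERS.items()]
    tokens.append(f"o{conducted}")
    return " ".join(tokens)


def _malform(text: str) -> str:
    """Damage the yellow-fever children token so it no longer parses."""
    tokens = text.split(" ")
    for i, tok in enumerate(tokens):
        if tok.startswith("g"):
            tokens[i] = tok + "x"
            break
    return " ".join(tokens)


def _generate_stream(registry: Registry, schedules: dict, config: FleetConfig,
                     rng: np.random.Generator) -> SimulatedFleet:
    """Core generator: one pass over dates x facilities in registry order.

    Draw order is fixed (chronological; per facility: fixed-post then
    outreach; then Monday WK plans; then supervision), which guarantees
    stream-level reproducibility for a given seed.
    """
    err = config.error_rates
    messages: list[RawMessage] = []
    truth_sessions: list[dict] = []
    supervision_rows: list[dict] = []
    seq = 0
    for date in config.window.dates():
        day_name = WEEKDAYS[date.weekday()]
        p_day = config.weekday_report_probability.get(day_name, 0.0)
        for fac in registry:
            if not fac.active:
                continue
            sched = schedules[fac.facility_id]
            for session_type, days, factor in (
                ("fixed_post", sched["fixed_days"], 1.0),
                ("outreach", sched["outreach_days"],
                 config.outreach_report_factor),
            ):
                if date.weekday() not in days:
                    continue
                record = {
                    "facility_id": fac.facility_id,
                    "date": date,
                    "session_type": session_type,
                    "reported": False,
                    "message_id": None,
                    "true_children": None,
                    "true_doses": None,
                    "corruptions": [],
                }
                p = p_day * factor * (1.0 - err.missing_report)
                if rng.random() < p:
                    children, doses = _draw_session_values(rng, config,
                                                           session_type)
                    record["true_children"] = dict(children)
                    record["true_doses"] = dict(doses)
                    if (session_type == "outreach"
                            and rng.random() < err.zero_dose_outreach):
                        children["MEASLES"] = 0
                        doses["MEASLES"] = 0
                        record["corruptions"].append("zero_dose_outreach")
                    if rng.random() < err.impossible_count:
                        candidates = [a for a in SINGLE_VIAL_ANTIGENS
                                      if doses[a] > 0]
                        if candidates:
                            a = candidates[int(rng.integers(len(candidates)))]
                            children[a] = doses[a] + 1 + int(rng.integers(5))
                            record["corruptions"].append("impossible_count")
                    text = session_text(session_type, children, doses)
                    if ("impossible_count" not in record["corruptions"]
                            and rng.random() < err.malformed_token):
                        text = _malform(text)
                        record["corruptions"].append("malformed_token")
                    seq += 1
                    mid = f"m{seq:06d}"
                    record["reported"] = True
                    record["message_id"] = mid
                    messages.append(RawMessage(
                        message_id=mid,
                        sender_phone=fac.phone,
                        received_at=dt.datetime(date.year, date.month,
                                                date.day,
                                                int(rng.integers(9, 17)),
                                                int(rng.integers(0, 60))),
                        text=text,
                    ))
                truth_sessions.append(record)
        if date.weekday() == 0:   # weekly-plan messages go out on Mondays
            for fac in registry:
                if fac.active and rng.random() < config.wk_report_probability:
                    seq += 1
                    messages.append(RawMessage(
                        message_id=f"m{seq:06d}",
                        sender_phone=fac.phone,
                        received_at=dt.datetime(date.year, date.month,
                                                date.day, 8,
                                                int(rng.integers(0, 60))),
                        text=(f"WK a{fac.planned_fixed_per_week} "
                              f"b{fac.planned_outreach_per_week}"),
                    ))
        for fac in registry:   # supervision of conducted fixed-post sessions
            if not fac.active:
                continue
            if date.weekday() in schedules[fac.facility_id]["fixed_days"]:
                supervision_rows.append({
                    "facility_id": fac.facility_id,
                    "date": date.isoformat(),
                    "sessions_conducted": 1,
                    "sessions_supervised":
                        int(rng.random() < config.supervised_fraction),
                })
    supervision_log = pd.DataFrame(
        supervision_rows,
        columns=["facility_id", "date", "sessions_conducted",
                 "sessions_supervised"],
    )
    return SimulatedFleet(
        registry=registry,
        messages=messages,
        supervision_log=supervision_log,
        truth=GroundTruth(sessions=truth_sessions, config=config),
        schedules=schedules,
    )


def simulate_fleet(config: FleetConfig) -> SimulatedFleet:
    """Generate a registry, raw SMS stream, supervision log, and ground truth.

    Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    registry, schedules = build_fleet_registry(config)
    return _generate_stream(registry, schedules, config, rng)


def recovery_report(result: InterpretResult, truth: GroundTruth) -> dict:
    """Score anomaly detection against the generator's ground truth.

    Precision/recall of IMPOSSIBLE_COUNT flags and malformed-token detection
    (both matched by source message id), plus the bias of the recovered mean
    wastage rate against the rate implied by the true, uncorrupted values.
    Degenerate cases (no positives expected and none detected) report None.
    """
    flags = all_flags(result.session_reports)
    by_message_flags: dict[str, list] = {}
    for r in result.session_reports:
        by_message_flags[r.source_message_id] = all_flags([r])
    detected_impossible = {
        mid for mid, fs in by_message_flags.items()
        if any(f.flag_type == "IMPOSSIBLE_COUNT" for f in fs)
    }
    true_impossible = truth.corrupted("impossible_count")
    detected_malformed = {
        r.source_message_id for r in result.session_reports
        if any(i.kind == "malformed_token" for i in r.issues)
    } | {rej.message_id for rej in result.rejects
         if rej.reason == "malformed_tokens"}
    true_malformed = truth.corrupted("malformed_token")

    def _pr(detected: set, positives: set) -> dict:
        tp = len(detected & positives)
        return {
            "n_true": len(positives),
            "n_detected": len(detected),
            "precision": tp / len(detected) if detected else None,
            "recall": tp / len(positives) if positives else None,
        }

    # Wastage bias: observed evaluable rates on clean messages vs the truth.
    msg_truth = truth.by_message()
    obs_rates: list[float] = []
    true_rates: list[float] = []
    for r in result.session_reports:
        rec = msg_truth.get(r.source_message_id)
        if rec is None or rec["corruptions"]:
            continue
        for a in SINGLE_VIAL_ANTIGENS:
            c, d = r.children(a), r.doses_opened(a)
            if c is not None and d is not None and d > 0:
                obs_rates.append((d - c) / d)
            if rec["true_doses"][a] > 0:
                true_rates.append(
                    (rec["true_doses"][a] - rec["true_children"][a])
                    / rec["true_doses"][a])
    bias = (float(np.mean(obs_rates)) - float(np.mean(true_rates))
            if obs_rates and true_rates else 0.0)

    return {
        "impossible_count": _pr(detected_impossible, true_impossible),
        "malformed": _pr(detected_malformed, true_malformed),
        "wastage_rate_bias": bias,
        "n_flags": len(flags),
    }


# ---------------------------------------------------------------------------
# The pilot fixture

#: Clean base sessions in the pilot fixture stay at or below the flag
#: threshold so the published high-wastage counts remain exact.
_PILOT_CLEAN_WASTAGE_CAP = 0.80

#: Facilities precluded from ever reporting in the fixture (participation
#: 47 of 55) — included but silent throughout the pilot window.
_PILOT_SILENT = ("HF049", "HF050", "HF051")

PILOT_TRAINING = {
    "state_officers": 8,
    "lga_officers": 11,
    "ward_focal_persons": 20,
    "hf_staff": 106,
    "total_trained": 145,
}


@dataclass
class PilotFixture:
    registry: Registry
    messages: list[RawMessage]
    supervision_log: pd.DataFrame
    metadata: dict
    code_table: CodeTable
    window: Window


class PilotMetadataError(ValueError):
    pass


def _build_pilot_registry() -> tuple[Registry, dict]:
    """55 selected facilities (25 Keffi, 30 Keana); 50 active (24 + 26).

    Schedules are configured so active-fleet expectations total exactly 66
    fixed-post and 33 outreach sessions per week: hospitals plan 5/4/4,
    urban PHCs 2 each, primaries 1 each; 33 of the 50 active facilities
    plan one outreach session.
    """
    facilities: list[HealthFacility] = []
    schedules: dict[str, dict[str, list[int]]] = {}
    hospital_fixed = {"HF001": 5, "HF026": 4, "HF027": 4}
    urban = {"HF002", "HF003", "HF004", "HF028", "HF029", "HF030"}
    cycle_seq = 0
    for i in range(1, 56):
        fid = f"HF{i:03d}"
        district = "Keffi" if i <= 25 else "Keana"
        active = fid not in {"HF025", "HF052", "HF053", "HF054", "HF055"}
        if fid in hospital_fixed:
            ftype, fixed = "hospital", hospital_fixed[fid]
        elif fid in urban:
            ftype, fixed = "urban_phc", 2
        else:
            ftype, fixed = "primary_hf", 1
        # 33 outreach planners: the 26 active Keana + the first 7 Keffi.
        outreach = 1 if active and (i > 25 or i <= 7) else 0
        facilities.append(HealthFacility(
            facility_id=fid,
            name=f"{district} {ftype} {i}",
            district=district,
            facility_type=ftype,
            phone=f"0803{i:07d}",
            planned_fixed_per_week=fixed,
            planned_outreach_per_week=outreach,
            active=active,
        ))
        days = _FIXED_DAY_SETS[fixed]
        if days is None:
            days = [_PRIMARY_DAY_CYCLE[cycle_seq % 5]]
        schedules[fid] = {
            "fixed_days": list(days),
            "outreach_days": ([_OUTREACH_DAY_CYCLE[cycle_seq % 5]]
                              if outreach else []),
        }
        cycle_seq += 1
    return Registry(facilities), schedules


def _free_weekday(used: set[tuple], facility_id: str, session_type: str,
                  window: Window, offset: int) -> dt.date:
    """First weekday (cyclically offset into the window) with no message
    yet for this facility and session type."""
    weekdays = [d for d in window.dates() if d.weekday() < 5]
    n = len(weekdays)
    for i in range(n):
        date = weekdays[(offset * 7 + i) % n]
        if (facility_id, date, session_type) not in used:
            used.add((facility_id, date, session_type))
            return date
    raise SimulationError("no free weekday left for injection")


def _consistent_values() -> tuple[dict[str, int], dict[str, int]]:
    """A fully consistent session: every antigen below the wastage threshold."""
    children = {"BCG": 5, "OPV": 8, "PENTA1": 3, "PENTA2": 3, "PENTA3": 3,
                "MEASLES": 8, "YELLOW_FEVER": 3, "IPV": 3}
    doses = {"BCG": 20, "OPV": 20, PENTA_SHARED: 9, "MEASLES": 10,
             "YELLOW_FEVER": 10, "IPV": 10}
    return children, doses


def pilot_fixture(seed: int = 20171201) -> PilotFixture:
    """The packaged pilot-emulating dataset, generated deterministically.

    A clean simulated base stream over the 151-day window is overlaid with
    deterministic injections that pin the published anomaly counts:

    * 24 facilities with a fixed-post measles impossible count, of which
      18 also show a BCG impossible count (the joint condition);
    * 2 facilities with an outreach measles impossible count;
    * 17 facilities reporting zero measles doses on an outreach session;
    * 15 facilities with BCG wastage above 80% and 2 facility-sessions
      with measles wastage above 80%.

    Three included facilities never report, so 47 of the 55 selected
    facilities participate.
    """
    registry, schedules = _build_pilot_registry()
    config = FleetConfig(
        n_facilities=len(registry),
        outreach_report_factor=0.4,
        max_clean_wastage=_PILOT_CLEAN_WASTAGE_CAP,
        outreach_min_children=1,
        window=PILOT_WINDOW,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    base = _generate_stream(registry, schedules, config, rng)
    messages = [m for m in base.messages
                if registry.phone_index[m.sender_phone] not in _PILOT_SILENT]

    used: set[tuple] = set()
    for m in messages:
        fid = registry.phone_index[m.sender_phone]
        st = ("fixed_post" if m.text.startswith("FS")
              else "outreach" if m.text.startswith("OS") else "wk")
        used.add((fid, m.received_at.date(), st))

    session_reporters = {registry.phone_index[m.sender_phone]
                         for m in messages if not m.text.startswith("WK")}
    seq = len(base.messages)

    def inject(fid: str, session_type: str, children: dict, doses: dict,
               offset: int) -> None:
        nonlocal seq
        date = _free_weekday(used, fid, session_type, PILOT_WINDOW, offset)
        seq += 1
        messages.append(RawMessage(
            message_id=f"x{seq:06d}",
            sender_phone=registry.get(fid).phone,
            received_at=dt.datetime(date.year, date.month, date.day, 12, 30),
            text=session_text(session_type, children, doses),
        ))

    reporters = [f"HF{i:03d}" for i in range(1, 56)
                 if registry.get(f"HF{i:03d}").active
                 and f"HF{i:03d}" not in _PILOT_SILENT]
    # Any designated reporter the random base left silent still reports once.
    for k, fid in enumerate(reporters):
        if fid not in session_reporters:
            inject(fid, "fixed_post", *_consistent_values(), offset=k)

    for k, fid in enumerate(reporters[:24]):       # measles impossibility
        children, doses = _consistent_values()
        children["MEASLES"], doses["MEASLES"] = 12, 10
        if k < 18:                                 # jointly impossible for BCG
            children["BCG"], doses["BCG"] = 25, 20
        inject(fid, "fixed_post", children, doses, offset=k)

    for k, fid in enumerate(reporters[24:39]):     # BCG wastage 0.85
        children, doses = _consistent_values()
        children["BCG"], doses["BCG"] = 3, 20
        inject(fid, "fixed_post", children, doses, offset=k)

    for k, fid in enumerate(reporters[39:41]):     # measles wastage 0.90
        children, doses = _consistent_values()
        children["MEASLES"], doses["MEASLES"] = 1, 10
        inject(fid, "fixed_post", children, doses, offset=k)

    for k, fid in enumerate(("HF043", "HF044")):   # outreach impossibility
        children, doses = _consistent_values()
        children["MEASLES"], doses["MEASLES"] = 12, 10
        inject(fid, "outreach", children, doses, offset=k)

    zero_dose = [f"HF{i:03d}" for i in range(26, 43)]   # 17 facilities
    for k, fid in enumerate(zero_dose):
        children, doses = _consistent_values()
        children["MEASLES"], doses["MEASLES"] = 0, 0
        inject(fid, "outreach", children, doses, offset=k)

    messages.sort(key=lambda m: (m.received_at, m.message_id))
    supervision_log = base.supervision_log[
        ~base.supervision_log["facility_id"].isin(_PILOT_SILENT)
    ].reset_index(drop=True)

    metadata = {
        "training": dict(PILOT_TRAINING),
        "window": {"start": PILOT_WINDOW.start.isoformat(),
                   "end": PILOT_WINDOW.end.isoformat(),
                   "days": PILOT_WINDOW.days},
        "expected_weekly": {"fixed": 66, "outreach": 33},
        "districts_selected": {"Keffi": 25, "Keana": 30},
        "n_selected": 55,
        "n_included": 50,
        "n_reporting": 47,
    }
    return PilotFixture(
        registry=registry,
        messages=messages,
        supervision_log=supervision_log,
        metadata=metadata,
        code_table=default_code_table(),
        window=PILOT_WINDOW,
    )


def validate_pilot_metadata(fixture: PilotFixture) -> dict:
    """Cross-check fixture metadata against the data it ships with.

    Verifies the training-cohort bookkeeping (component counts sum to the
    stated total), the window length, the registry composition, and that
    the stated weekly fleet expectations equal the registry-derived totals.
    Raises :class:`PilotMetadataError` on any mismatch.
    """
    meta = fixture.metadata
    t = meta["training"]
    cohort_sum = (t["state_officers"] + t["lga_officers"]
                  + t["ward_focal_persons"] + t["hf_staff"])
    if cohort_sum != t["total_trained"]:
        raise PilotMetadataError(
            f"training cohort components sum to {cohort_sum}, "
            f"not {t['total_trained']}")
    window = Window(dt.date.fromisoformat(meta["window"]["start"]),
                    dt.date.fromisoformat(meta["window"]["end"]))
    if window.days != meta["window"]["days"]:
        raise PilotMetadataError(
            f"window spans {window.days} days, metadata says "
            f"{meta['window']['days']}")
    if fixture.registry.n_selected != meta["n_selected"]:
        raise PilotMetadataError("selected-facility count mismatch")
    if fixture.registry.n_active != meta["n_included"]:
        raise PilotMetadataError("included-facility count mismatch")
    by_district = fixture.registry.counts_by_district()
    if by_district != meta["districts_selected"]:
        raise PilotMetadataError("district composition mismatch")
    exp = expected_counts(fixture.registry)
    if (exp.fleet_fixed_per_week != meta["expected_weekly"]["fixed"]
            or exp.fleet_outreach_per_week
            != meta["expected_weekly"]["outreach"]):
        raise PilotMetadataError("fleet weekly expectations mismatch")
    return {
        "total_trained": cohort_sum,
        "window_days": window.days,
        "n_selected": fixture.registry.n_selected,
        "n_included": fixture.registry.n_active,
        "expected_weekly_fixed": exp.fleet_fixed_per_week,
        "expected_weekly_outreach": exp.fleet_outreach_per_week,
    }
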