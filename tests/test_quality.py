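import datetime as dt
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smsri.ingest import SessionReport
from smsri.quality import (
    PILOT_WINDOW,
    WastageValue,
    Window,
    consistency_flags,
    day_of_week_profile,
    discrepancy_summary,
    dose_children_series,
    participation,
    supervision_coverage,
    weekly_received_vs_expected,
)
from smsri.registry import HealthFacility, Registry, expected_counts


def _registry(n, fixed=1, outreach=0):
    return Registry([
        HealthFacility(f"F{i:02d}", f"fac {i}", "D", "primary_hf",
                       f"0801{i:07d}", fixed, outreach, True)
        for i in range(1, n + 1)
    ])


def _report(fid, date, session_type="fixed_post", **antigens):
    """antigens: name=(children, doses) with None for absent."""
    data = {a: {"children": c, "doses_opened": d}
            for a, (c, d) in antigens.items()}
    return SessionReport(fid, date, session_type, data, f"{fid}-{date}")


TUESDAY = dt.date(2018, 1, 9)


class TestWindow:
    def test_pilot_window_is_151_days(self):
        assert PILOT_WINDOW.days == 151

    def test_single_day(self):
        w = Window(TUESDAY, TUESDAY)
        assert w.days == 1 and w.weekdays == 1

    def test_reversed_window_rejected(self):
        with pytest.raises(ValueError):
            Window(TUESDAY, TUESDAY - dt.timedelta(days=1))

    def test_one_iso_week_has_five_weekdays(self, one_week):
        assert one_week.weekdays == 5
        assert one_week.weeks == 1.0


class TestParticipation:
    def test_no_reports_zero_participation(self, one_week):
        summary = participation([], _registry(5), one_week)
        assert summary.participation_rate == 0.0

    def test_rounded_percent_47_of_55(self, one_week):
        reports = [_report(f"F{i:02d}", TUESDAY, BCG=(1, 20))
                   for i in range(1, 48)]
        summary = participation(reports, _registry(55), one_week)
        assert summary.n_reporting == 47
        assert summary.participation_percent == 85

    def test_saturation_gives_unit_completeness(self, one_week):
        reg = _registry(3, fixed=1, outreach=0)
        reports = [_report(f.facility_id, TUESDAY, BCG=(1, 20)) for f in reg]
        summary = participation(reports, reg, one_week)
        assert all(v == 1.0
                   for v in summary.per_facility_completeness.values())

    def test_empty_registry_rejected(self, one_week):
        with pytest.raises(ValueError):
            participation([], Registry([]), one_week)

    def test_order_invariant(self, one_week):
        reports = [_report(f"F{i:02d}", TUESDAY, BCG=(1, 20))
                   for i in range(1, 20)]
        shuffled = list(reports)
        random.Random(1).shuffle(shuffled)
        a = participation(reports, _registry(30), one_week)
        b = participation(shuffled, _registry(30), one_week)
        assert a.participation_rate == b.participation_rate
        assert a.per_facility_completeness == b.per_facility_completeness


class TestWeeklyReceivedVsExpected:
    def test_zero_reports(self, one_week):
        exp = expected_counts(_registry(10, fixed=2, outreach=1))
        out = weekly_received_vs_expected([], exp, (2018, 2))
        assert out == {"fixed": (0, 20), "outreach": (0, 10)}

    def test_saturated_week_matches_expectation(self, one_week):
        reg = _registry(4, fixed=1, outreach=1)
        reports = []
        for f in reg:
            reports.append(_report(f.facility_id, TUESDAY, BCG=(1, 20)))
            reports.append(_report(f.facility_id, TUESDAY, "outreach",
                                   BCG=(1, 20)))
        out = weekly_received_vs_expected(reports, expected_counts(reg),
                                          (2018, 2))
        assert out["fixed"] == (4, 4)
        assert out["outreach"] == (4, 4)


class TestDayOfWeekProfile:
    def test_empty_profile_is_all_zero(self, one_week):
        profile = day_of_week_profile([], one_week)
        assert set(profile.values()) == {0}

    def test_single_day_reports(self, one_week):
        reports = [_report(f"F{i:02d}", TUESDAY, BCG=(1, 20))
                   for i in range(1, 4)]
        profile = day_of_week_profile(reports, one_week)
        assert profile["Tuesday"] == 3
        assert sum(profile.values()) == 3

    def test_distinct_facilities_counted_once_per_day(self, one_week):
        reports = [
            _report("F01", TUESDAY, BCG=(1, 20)),
            _report("F01", TUESDAY, "outreach", BCG=(1, 20)),
        ]
        assert day_of_week_profile(reports, one_week)["Tuesday"] == 1


class TestConsistencyFlags:
    def test_children_above_doses_is_impossible(self):
        flags = consistency_flags(_report("F01", TUESDAY, BCG=(10, 8)))
        assert [f.flag_type for f in flags] == ["IMPOSSIBLE_COUNT"]

    def test_high_wastage_above_threshold(self):
        flags = consistency_flags(_report("F01", TUESDAY, MEASLES=(3, 20)))
        assert [f.flag_type for f in flags] == ["HIGH_WASTAGE"]
        assert "0.85" in flags[0].detail

    def test_equal_counts_no_flags(self):
        assert consistency_flags(_report("F01", TUESDAY, BCG=(20, 20))) == []

    def test_absent_values_never_flag(self):
        assert consistency_flags(_report("F01", TUESDAY, BCG=(10, None))) == []
        assert consistency_flags(_report("F01", TUESDAY, BCG=(None, 5))) == []

    def test_threshold_is_strict(self):
        # exactly at the threshold: consistent, not high wastage
        assert consistency_flags(_report("F01", TUESDAY, BCG=(4, 20))) == []

    def test_zero_dose_outreach_flagged(self):
        rep = _report("F01", TUESDAY, "outreach",
                      MEASLES=(0, 0), BCG=(5, 20))
        flags = consistency_flags(rep)
        assert [f.flag_type for f in flags] == ["ZERO_DOSES_OUTREACH"]
        assert flags[0].antigen == "MEASLES"

    def test_zero_dose_fixed_post_not_flagged(self):
        rep = _report("F01", TUESDAY, MEASLES=(0, 0), BCG=(5, 20))
        assert consistency_flags(rep) == []

    def test_penta_shared_vial_compared_to_summed_children(self):
        rep = _report("F01", TUESDAY, PENTA1=(4, None), PENTA2=(3, None),
                      PENTA3=(3, None), PENTA=(None, 9))
        flags = consistency_flags(rep)
        assert [f.flag_type for f in flags] == ["IMPOSSIBLE_COUNT"]
        assert flags[0].antigen == "PENTA"


@given(children=st.integers(0, 100), doses=st.integers(0, 100))
@settings(max_examples=300, derandomize=True)
def test_wastage_and_flag_states_mutually_exclusive(children, doses):
    """For one evaluable antigen exactly one state holds; rate <= 1 always
    and rate < 0 iff the impossible-count condition."""
    wv = WastageValue.compute("BCG", children, doses)
    flags = consistency_flags(_report("F01", TUESDAY, BCG=(children, doses)))
    kinds = [f.flag_type for f in flags]
    if children > doses:
        assert kinds == ["IMPOSSIBLE_COUNT"]
    elif not wv.evaluable:
        assert kinds == []
    else:
        assert 0 <= wv.rate <= 1
        assert kinds == (["HIGH_WASTAGE"] if wv.rate > 0.80 else [])


def _brute_force_discrepancy(reports, antigens, session_type):
    """Independent oracle: scan every (facility, report, antigen) triple."""
    flagged = {a: set() for a in antigens}
    for r in reports:
        if r.session_type != session_type:
            continue
        for a in antigens:
            slot = r.antigen_data.get(a, {})
            c, d = slot.get("children"), slot.get("doses_opened")
            if c is not None and d is not None and c > d:
                flagged[a].add(r.facility_id)
    joint = set.intersection(*flagged.values())
    return {a: len(s) for a, s in flagged.items()}, len(joint)


def test_discrepancy_summary_matches_brute_force_oracle(one_week):
    rng = np.random.default_rng(17)
    for _ in range(25):
        n_fac = int(rng.integers(2, 11))
        reg = _registry(n_fac)
        reports = []
        for i in range(1, n_fac + 1):
            for day in range(5):
                date = one_week.start + dt.timedelta(days=day)
                def pair():
                    if rng.random() < 0.2:
                        return (None, None)
                    d = int(rng.integers(0, 30))
                    c = int(rng.integers(0, 35))
                    return (c, d)
                reports.append(_report(
                    f"F{i:02d}", date,
                    "fixed_post" if rng.random() < 0.7 else "outreach",
                    BCG=pair(), MEASLES=pair(),
                ))
        summary = discrepancy_summary(reports, reg, ["BCG", "MEASLES"],
                                      one_week, session_type="fixed_post")
        oracle_counts, oracle_joint = _brute_force_discrepancy(
            reports, ["BCG", "MEASLES"], "fixed_post")
        for a in ("BCG", "MEASLES"):
            assert summary.per_antigen[a]["n_facilities"] == oracle_counts[a]
        assert summary.joint["n_facilities"] == oracle_joint


def test_discrepancy_percentages_from_printed_counts(one_week):
    """24 flagged of 47 reporting -> 51%; 18 joint of 50 included -> 36%."""
    reg = _registry(50)
    reports = []
    for i in range(1, 48):                       # 47 reporting facilities
        fid = f"F{i:02d}"
        if i <= 24:                              # measles impossibility
            antigens = {"MEASLES": (12, 10)}
            if i <= 18:                          # joint with BCG
                antigens["BCG"] = (25, 20)
            reports.append(_report(fid, TUESDAY, **antigens))
        else:
            reports.append(_report(fid, TUESDAY, MEASLES=(8, 10)))
    summary = discrepancy_summary(reports, reg, ["BCG", "MEASLES"], one_week,
                                  session_type="fixed_post")
    assert summary.per_antigen["MEASLES"]["n_facilities"] == 24
    assert summary.per_antigen["MEASLES"]["percent_of_reporting"] == 51
    assert summary.joint["n_facilities"] == 18
    assert summary.joint["percent_of_included"] == 36


def test_discrepancy_no_flags_all_zero(one_week):
    reports = [_report("F01", TUESDAY, BCG=(5, 20))]
    summary = discrepancy_summary(reports, _registry(5), ["BCG"], one_week)
    assert summary.per_antigen["BCG"]["n_facilities"] == 0
    assert summary.per_antigen["BCG"]["percent_of_reporting"] == 0


def test_discrepancy_order_invariant(one_week):
    rng = np.random.default_rng(3)
    reports = [
        _report(f"F{int(rng.integers(1, 8)):02d}",
                one_week.start + dt.timedelta(days=int(rng.integers(0, 5))),
                BCG=(int(rng.integers(0, 30)), int(rng.integers(0, 30))))
        for _ in range(60)
    ]
    shuffled = list(reports)
    random.Random(9).shuffle(shuffled)
    a = discrepancy_summary(reports, _registry(8), ["BCG"], one_week)
    b = discrepancy_summary(shuffled, _registry(8), ["BCG"], one_week)
    assert a.per_antigen == b.per_antigen and a.joint == b.joint


class TestSupervisionCoverage:
    def _log(self, rows):
        return pd.DataFrame(rows, columns=["facility_id", "date",
                                           "sessions_conducted",
                                           "sessions_supervised"])

    def test_three_in_ten_ratio(self, one_week):
        rows = [("F01", "2018-01-08", 1, 1 if i < 3 else 0)
                for i in range(10)]
        log = self._log([(f, d, c, s) for (f, d, c, s) in rows])
        cov = supervision_coverage(log, one_week)
        assert cov.ratio == pytest.approx(0.3)

    def test_full_supervision(self, one_week):
        cov = supervision_coverage(
            self._log([("F01", "2018-01-08", 2, 2)]), one_week)
        assert cov.ratio == 1.0

    def test_zero_supervised(self, one_week):
        cov = supervision_coverage(
            self._log([("F01", "2018-01-08", 2, 0)]), one_week)
        assert cov.ratio == 0.0

    def test_no_conducted_sessions_not_evaluable(self, one_week):
        cov = supervision_coverage(
            self._log([("F01", "2018-01-08", 0, 0)]), one_week)
        assert cov.ratio is None

    def test_supervised_above_conducted_flagged_not_rejected(self, one_week):
        cov = supervision_coverage(
            self._log([("F01", "2018-01-08", 1, 2)]), one_week)
        assert cov.violations == ["F01@2018-01-08"]
        assert cov.ratio == 2.0


class TestDoseChildrenSeries:
    def test_single_report_single_point(self, one_week):
        series = dose_children_series(
            [_report("F01", TUESDAY, BCG=(15, 20))], "BCG", "fixed_post",
            one_week)
        assert len(series.daily) == 1
        row = series.daily.iloc[0]
        assert (row.children, row.doses_opened) == (15, 20)

    def test_two_days_two_points_summed(self, one_week):
        wed = TUESDAY + dt.timedelta(days=1)
        reports = [
            _report("F01", TUESDAY, BCG=(5, 20)),
            _report("F02", TUESDAY, BCG=(7, 20)),
            _report("F01", wed, BCG=(4, 20)),
        ]
        series = dose_children_series(reports, "BCG", "fixed_post", one_week)
        assert series.daily["children"].tolist() == [12, 4]

    def test_stationary_stream_shows_no_trend(self):
        rng = np.random.default_rng(21)
        window = Window(dt.date(2018, 1, 1), dt.date(2018, 3, 31))
        reports = []
        for i, date in enumerate(window.dates()):
            if date.weekday() >= 5:
                continue
            c = int(rng.poisson(40))
            reports.append(_report("F01", date, BCG=(c, c + 10)))
        series = dose_children_series(reports, "BCG", "fixed_post", window)
        assert series.no_trend
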