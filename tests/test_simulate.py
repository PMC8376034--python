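import datetime as dt

import numpy as np
import pytest

from smsri.codec import default_code_table
from smsri.ingest import run_pipeline
from smsri.quality import WEEKDAYS, Window, all_flags
from smsri.registry import expected_counts
from smsri.simulate import (
    ErrorRates,
    FleetConfig,
    PilotMetadataError,
    SimulationError,
    pilot_fixture,
    recovery_report,
    simulate_fleet,
    validate_pilot_metadata,
)

SHORT_WINDOW = Window(dt.date(2018, 1, 1), dt.date(2018, 2, 25))


def test_same_seed_gives_identical_streams():
    cfg = FleetConfig(n_facilities=12, window=SHORT_WINDOW, seed=99)
    a = simulate_fleet(cfg)
    b = simulate_fleet(cfg)
    assert a.messages == b.messages
    assert a.supervision_log.equals(b.supervision_log)


def test_different_seeds_differ():
    cfg_a = FleetConfig(n_facilities=12, window=SHORT_WINDOW, seed=1)
    cfg_b = FleetConfig(n_facilities=12, window=SHORT_WINDOW, seed=2)
    assert simulate_fleet(cfg_a).messages != simulate_fleet(cfg_b).messages


def test_clean_fleet_emits_no_error_flags(table):
    fleet = simulate_fleet(FleetConfig(n_facilities=15, window=SHORT_WINDOW,
                                       seed=4))
    result = run_pipeline(fleet.messages, fleet.registry, table)
    kinds = {f.flag_type for f in all_flags(result.session_reports)}
    assert "IMPOSSIBLE_COUNT" not in kinds
    assert not any(i.kind == "malformed_token"
                   for r in result.session_reports for i in r.issues)


def test_clean_sessions_always_satisfy_doses_at_least_children():
    """Generator constraint: zero false-positive rate for impossible counts."""
    fleet = simulate_fleet(FleetConfig(n_facilities=20, window=SHORT_WINDOW,
                                       seed=8))
    for rec in fleet.truth.sessions:
        if not rec["reported"]:
            continue
        for a in ("BCG", "OPV", "MEASLES", "YELLOW_FEVER", "IPV"):
            assert rec["true_doses"][a] >= rec["true_children"][a]


def test_type_mix_follows_configured_fractions():
    fleet = simulate_fleet(FleetConfig(n_facilities=50, window=SHORT_WINDOW))
    counts = fleet.registry.counts_by_type()
    assert counts == {"hospital": 3, "urban_phc": 6, "primary_hf": 41}


def test_scheduled_sessions_scale_linearly_with_fleet_size():
    # composition chosen to apportion without rounding at both sizes
    kwargs = dict(type_fractions={"hospital": 0.1, "urban_phc": 0.2,
                                  "primary_hf": 0.7},
                  district_fractions={"Keffi": 1.0},
                  window=SHORT_WINDOW, seed=0)
    small = simulate_fleet(FleetConfig(n_facilities=10, **kwargs))
    large = simulate_fleet(FleetConfig(n_facilities=20, **kwargs))
    assert large.truth.n_scheduled == 2 * small.truth.n_scheduled


def test_window_shorter_than_one_week_rejected():
    with pytest.raises(SimulationError):
        FleetConfig(window=Window(dt.date(2018, 1, 1), dt.date(2018, 1, 5)))


def test_bad_error_rate_rejected():
    with pytest.raises(SimulationError):
        ErrorRates(impossible_count=1.5)


def test_weekday_histogram_matches_configured_probabilities():
    cfg = FleetConfig(n_facilities=50, seed=13)
    fleet = simulate_fleet(cfg)
    scheduled = {day: 0 for day in WEEKDAYS}
    reported = {day: 0 for day in WEEKDAYS}
    for rec in fleet.truth.sessions:
        if rec["session_type"] != "fixed_post":
            continue
        day = WEEKDAYS[rec["date"].weekday()]
        scheduled[day] += 1
        reported[day] += rec["reported"]
    for day in ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday"):
        n, p = scheduled[day], cfg.weekday_report_probability[day]
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(reported[day] - n * p) <= 3 * sigma


def test_injected_impossible_fraction_recovers_configured_rate(table):
    rate = 0.1
    cfg = FleetConfig(n_facilities=75,
                      error_rates=ErrorRates(impossible_count=rate), seed=29)
    fleet = simulate_fleet(cfg)
    n = fleet.truth.n_reported
    assert n >= 1000
    result = run_pipeline(fleet.messages, fleet.registry, table)
    rec = recovery_report(result, fleet.truth)
    flagged_fraction = rec["impossible_count"]["n_detected"] / n
    sigma = np.sqrt(rate * (1 - rate) / n)
    assert abs(flagged_fraction - rate) <= 3 * sigma
    assert rec["impossible_count"]["precision"] == 1.0
    assert rec["impossible_count"]["recall"] == 1.0


def test_recovery_degenerate_on_clean_stream(table):
    fleet = simulate_fleet(FleetConfig(n_facilities=10, window=SHORT_WINDOW,
                                       seed=6))
    result = run_pipeline(fleet.messages, fleet.registry, table)
    rec = recovery_report(result, fleet.truth)
    assert rec["impossible_count"] == {"n_true": 0, "n_detected": 0,
                                       "precision": None, "recall": None}
    assert rec["wastage_rate_bias"] == 0.0


def test_malformed_injection_detected_with_full_recall(table):
    cfg = FleetConfig(n_facilities=30, window=SHORT_WINDOW,
                      error_rates=ErrorRates(malformed_token=0.2), seed=31)
    fleet = simulate_fleet(cfg)
    result = run_pipeline(fleet.messages, fleet.registry, table)
    rec = recovery_report(result, fleet.truth)
    assert rec["malformed"]["n_true"] > 0
    assert rec["malformed"]["recall"] == 1.0
    assert rec["malformed"]["precision"] == 1.0


class TestPilotFixture:
    def test_registry_composition(self, pilot):
        fx, _ = pilot
        assert fx.registry.n_selected == 55
        assert fx.registry.n_active == 50
        assert fx.registry.counts_by_district() == {"Keffi": 25, "Keana": 30}

    def test_window_length(self, pilot):
        fx, _ = pilot
        assert fx.window.days == 151

    def test_fleet_expectations_configured_to_66_and_33(self, pilot):
        fx, _ = pilot
        exp = expected_counts(fx.registry)
        assert exp.fleet_fixed_per_week == 66
        assert exp.fleet_outreach_per_week == 33

    def test_exactly_47_facilities_ever_report(self, pilot):
        fx, result = pilot
        assert len({r.facility_id for r in result.session_reports}) == 47

    def test_metadata_validator_passes_then_catches_tampering(self, pilot):
        fx, _ = pilot
        checks = validate_pilot_metadata(fx)
        assert checks["total_trained"] == 145
        fx.metadata["training"]["hf_staff"] = 100
        with pytest.raises(PilotMetadataError):
            validate_pilot_metadata(fx)
        fx.metadata["training"]["hf_staff"] = 106

    def test_fixture_deterministic_across_calls(self):
        a = pilot_fixture(seed=5)
        b = pilot_fixture(seed=5)
        assert a.messages == b.messages
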