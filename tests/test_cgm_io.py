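"""CGM/diary/protocol readers, interpolation, matching and exclusion rules."""

import numpy as np
import pandas as pd
import pytest

from ppgr_pipeline.cgm_io import (
    CGMGapError,
    MealRecord,
    OutOfRangeError,
    ProtocolEntry,
    apply_exclusion_rules,
    bg_at,
    exclusion_report,
    match_protocol_to_diary,
    read_cgm,
    read_diary,
    read_protocol,
)

from conftest import START, exclusion_fixture, make_series


class TestBgAt:
    def test_exact_sample_hit(self):
        s = make_series([0, 5, 10], [5.4, 6.0, 5.8])
        assert bg_at(s, 5.0) == 6.0

    def test_midpoint_interpolation(self):
        s = make_series([0, 5], [5.0, 6.0])
        assert bg_at(s, 2.5) == pytest.approx(5.5)

    def test_gap_wider_than_20min_raises(self):
        s = make_series([0, 5, 35, 40], [5.0, 5.0, 5.0, 5.0])
        with pytest.raises(CGMGapError):
            bg_at(s, 20.0)

    def test_edge_tolerance_clamps_to_end_samples(self):
        s = make_series([0, 5], [5.0, 6.0])
        assert bg_at(s, -2.0) == 5.0
        assert bg_at(s, 7.0) == 6.0

    def test_outside_span_raises(self):
        s = make_series([0, 5], [5.0, 6.0])
        with pytest.raises(OutOfRangeError):
            bg_at(s, 30.0)


def _protocol(minutes):
    return [ProtocolEntry("P0", START + pd.Timedelta(minutes=m), None) for m in minutes]


def _diary(minutes):
    return [
        MealRecord("P0", START + pd.Timedelta(minutes=m), "snack", (("apple", 100.0),))
        for m in minutes
    ]


class TestMatching:
    def test_nearest_diary_record_wins(self):
        matches, unmatched = match_protocol_to_diary(
            _protocol([480]), _diary([475, 570]), max_gap_min=60
        )
        assert unmatched == 0
        assert matches[0].meal_record.diary_time == START + pd.Timedelta(minutes=475)
        # meal start comes from the protocol, not the diary
        assert matches[0].meal_start == START + pd.Timedelta(minutes=480)

    def test_protocol_without_nearby_diary_is_ignored(self):
        matches, unmatched = match_protocol_to_diary(
            _protocol([480]), _diary([660]), max_gap_min=60
        )
        assert matches == [] and unmatched == 1

    def test_greedy_assignment_closer_protocol_wins(self):
        # two protocol entries nearest to one diary record: 10 min vs 20 min
        matches, unmatched = match_protocol_to_diary(
            _protocol([470, 500]), _diary([480]), max_gap_min=60
        )
        assert unmatched == 1
        assert len(matches) == 1
        assert matches[0].protocol_entry.meal_start == START + pd.Timedelta(minutes=470)

    def test_translation_invariance(self):
        shift = pd.Timedelta(hours=30)
        base_p, base_d = _protocol([480, 700]), _diary([475, 705])
        m1, _ = match_protocol_to_diary(base_p, base_d)
        p2 = [ProtocolEntry(e.patient_id, e.meal_start + shift, None) for e in base_p]
        d2 = [MealRecord(r.patient_id, r.diary_time + shift, r.meal_type, r.items) for r in base_d]
        m2, _ = match_protocol_to_diary(p2, d2)
        assert [m.meal_start + shift for m in m1] == [m.meal_start for m in m2]


class TestExclusionRules:
    def test_hand_built_fixture_triggers_each_rule_once(self):
        series, protocol, diary, expected = exclusion_fixture()
        matched, _ = match_protocol_to_diary(protocol, diary)
        annotated, counts = apply_exclusion_rules(matched, series)
        reasons = {
            series.minutes(m.meal_start): m.exclusion for m in annotated if m.exclusion
        }
        assert reasons == expected
        assert counts["kept"] == 8
        for rule in ("late_report", "falling_edge", "prior_meal", "subsequent_meal"):
            assert counts[rule] == 1

    def test_flat_trace_with_isolated_meals_excludes_nothing(self, flat_series):
        protocol = _protocol([200, 400, 600])
        diary = _diary([200, 400, 600])
        matched, _ = match_protocol_to_diary(protocol, diary)
        annotated, counts = apply_exclusion_rules(matched, flat_series)
        assert counts["kept"] == 3
        assert all(m.exclusion is None for m in annotated)

    def test_every_excluded_meal_has_exactly_one_reason(self):
        series, protocol, diary, _ = exclusion_fixture()
        matched, _ = match_protocol_to_diary(protocol, diary)
        annotated, counts = apply_exclusion_rules(matched, series)
        n_excluded = sum(1 for m in annotated if m.exclusion is not None)
        assert counts["kept"] + n_excluded == len(matched)

    def test_missing_trace_window_gives_cgm_unavailable(self, flat_series):
        protocol = _protocol([20])  # t-60 falls before the trace starts
        diary = _diary([20])
        matched, _ = match_protocol_to_diary(protocol, diary)
        annotated, counts = apply_exclusion_rules(matched, flat_series)
        assert annotated[0].exclusion == "cgm_unavailable"
        assert counts["cgm_unavailable"] == 1

    def test_report_table_shape(self):
        series, protocol, diary, _ = exclusion_fixture()
        matched, _ = match_protocol_to_diary(protocol, diary)
        annotated, _ = apply_exclusion_rules(matched, series)
        rep = exclusion_report(annotated)
        assert list(rep.columns) == ["patient_id", "meal_start", "status", "reason"]
        assert (rep.status == "excluded").sum() == 4


class TestReaders:
    def test_cgm_roundtrip_and_bad_rows(self, tmp_path):
        path = tmp_path / "cgm.csv"
        path.write_text(
            "patient_id,timestamp,glucose_mmol_l\n"
            "P0,2021-03-01T00:00:00,5.0\n"
            "P0,2021-03-01T00:05:00,5.5\n"
            "P0,2021-03-01T00:10:00,55.0\n"  # out of sensor band -> reported
            "P0,2021-03-01T00:15:00,6.0\n"
        )
        series, bad = read_cgm(path)
        assert len(series["P0"].glucose) == 3
        assert len(bad) == 1 and "line 4" in bad[0]

    def test_cgm_non_monotone_is_hard_error(self, tmp_path):
        path = tmp_path / "cgm.csv"
        path.write_text(
            "patient_id,timestamp,glucose_mmol_l\n"
            "P0,2021-03-01T00:05:00,5.0\n"
            "P0,2021-03-01T00:05:00,5.5\n"
        )
        with pytest.raises(ValueError, match="non-monotone"):
            read_cgm(path)

    def test_diary_rejects_zero_grams_and_unknown_meal_type(self, tmp_path):
        ok = tmp_path / "d1.csv"
        ok.write_text(
            "patient_id,timestamp,meal_type,food_name,grams\n"
            "P0,2021-03-01T08:00:00,breakfast,apple,120\n"
            "P0,2021-03-01T08:00:00,breakfast,milk,0\n"
        )
        records, bad = read_diary(ok)
        assert len(records) == 1 and len(records[0].items) == 1
        assert len(bad) == 1 and "line 3" in bad[0]

        nok = tmp_path / "d2.csv"
        nok.write_text(
            "patient_id,timestamp,meal_type,food_name,grams\n"
            "P0,2021-03-01T08:00:00,brunch,apple,120\n"
        )
        with pytest.raises(ValueError, match="brunch"):
            read_diary(nok)

    def test_protocol_reader_sorts_and_parses(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(
            "patient_id,timestamp,point_bg_mmol_l\n"
            "P0,2021-03-01T12:00:00,6.1\n"
            "P0,2021-03-01T08:00:00,\n"
        )
        entries = read_protocol(path)
        assert entries[0].meal_start.hour == 8
        assert entries[0].point_bg is None
        assert entries[1].point_bg == 6.1
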