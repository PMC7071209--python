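"""PPGR outcome extraction: AUC/iAUC against an independent integration
oracle, outcome invariants, and the misreporting/record filters."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from ppgr_pipeline.ppgr import (
    detect_misreporting,
    extract_ppgr,
    filter_records,
    incremental_auc,
    trapezoid_auc,
)
from ppgr_pipeline.cgm_io import CGMGapError, MealRecord

from conftest import START, make_series, piecewise_series


def oracle_auc(times, values, t0, t1, baseline=None):
    """Independent integral of the piecewise-linear trace over [t0, t1] in
    mmol/L·h.  Baseline crossings are located by root-finding (brentq) on the
    interpolant rather than by the closed-form used in the implementation."""
    f = lambda t: np.interp(t, times, values)
    knots = [t0] + [t for t in times if t0 < t < t1] + [t1]
    if baseline is not None:
        crossings = []
        g = lambda t: f(t) - baseline
        for a, b in zip(knots[:-1], knots[1:]):
            if g(a) * g(b) < 0:
                crossings.append(brentq(g, a, b, xtol=1e-12))
        knots = sorted(knots + crossings)
        y = np.maximum([g(t) for t in knots], 0.0)
    else:
        y = [f(t) for t in knots]
    return float(np.trapezoid(y, knots)) / 60.0


def random_trace(rng, span=200.0):
    steps = rng.uniform(3.0, 15.0, 40)
    t = np.concatenate([[0.0], np.cumsum(steps)])
    t = t[t <= span]
    if t[-1] < span:
        t = np.append(t, span)
    v = rng.uniform(3.5, 9.0, len(t))
    return make_series(t, v)


class TestAucOracle:
    def test_constant_trace_rectangle(self):
        s = make_series(np.arange(0, 125, 5.0), np.full(25, 5.0))
        assert trapezoid_auc(s, 0, 120) == pytest.approx(10.0, abs=1e-12)

    def test_linear_trace_trapezoid(self):
        t = np.arange(0, 125, 5.0)
        s = make_series(t, 5.0 + 2.0 * t / 120.0)
        assert trapezoid_auc(s, 0, 120) == pytest.approx(12.0, abs=1e-12)

    def test_constant_at_baseline_gives_zero_iauc(self):
        s = make_series(np.arange(0, 125, 5.0), np.full(25, 5.0))
        assert incremental_auc(s, 0, 120, baseline=5.0) == 0.0

    def test_triangular_excursion_area(self):
        # 0 -> 2 -> 0 mmol/L above baseline over 120 min: 0.5 * 2 h * 2 = 2.0
        s = piecewise_series([(0, 5.0), (60, 7.0), (120, 5.0)])
        assert incremental_auc(s, 0, 120, baseline=5.0) == pytest.approx(2.0, abs=1e-12)

    def test_below_baseline_hour_contributes_nothing(self):
        s = piecewise_series([(0, 5.0), (30, 7.0), (60, 5.0), (65, 4.0), (115, 4.0), (120, 5.0)])
        got = incremental_auc(s, 0, 120, baseline=5.0)
        want = oracle_auc(s.times_min, s.glucose, 0, 120, baseline=5.0)
        assert got == pytest.approx(want, abs=1e-9)
        assert got == pytest.approx(1.0, abs=1e-6)  # only the first-hour triangle

    def test_random_traces_match_bruteforce(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            s = random_trace(rng)
            t0 = float(rng.uniform(0, 20))
            t1 = t0 + float(rng.uniform(60, 150))
            baseline = float(rng.uniform(4.0, 8.0))
            assert trapezoid_auc(s, t0, t1) == pytest.approx(
                oracle_auc(s.times_min, s.glucose, t0, t1), abs=1e-9
            )
            assert incremental_auc(s, t0, t1, baseline) == pytest.approx(
                oracle_auc(s.times_min, s.glucose, t0, t1, baseline), abs=1e-9
            )

    def test_additive_over_adjacent_intervals(self):
        rng = np.random.default_rng(3)
        s = random_trace(rng)
        total = trapezoid_auc(s, 0, 180)
        assert trapezoid_auc(s, 0, 77.3) + trapezoid_auc(s, 77.3, 180) == pytest.approx(
            total, abs=1e-9
        )

    def test_iauc_nonincreasing_in_baseline(self):
        rng = np.random.default_rng(5)
        s = random_trace(rng)
        vals = [incremental_auc(s, 0, 180, b) for b in (3.0, 5.0, 7.0, 9.0)]
        assert all(a >= b - 1e-12 for a, b in zip(vals[:-1], vals[1:]))

    def test_iauc_zero_baseline_equals_auc_for_positive_trace(self):
        rng = np.random.default_rng(6)
        s = random_trace(rng)
        assert incremental_auc(s, 0, 180, 0.0) == pytest.approx(
            trapezoid_auc(s, 0, 180), abs=1e-9
        )

    def test_gap_inside_window_raises(self):
        s = make_series([0, 5, 40, 45, 200], [5, 5, 5, 5, 5])
        with pytest.raises(CGMGapError):
            trapezoid_auc(s, 0, 120)


class TestExtractPPGR:
    def test_flat_trace(self, flat_series):
        rec = extract_ppgr(flat_series, 300.0)
        assert rec.bg0 == rec.bg60 == rec.bgmax == 5.0
        assert rec.bgrise == 0.0
        assert rec.auc120 == pytest.approx(10.0)
        assert rec.iauc120 == 0.0

    def test_ramp_then_flat_closed_form(self):
        # rises 5 -> 7 over the first hour, flat at 7 afterwards:
        # iAUC60 = triangle = 0.5*1h*2 = 1.0; iAUC120 adds a 2 mmol/L hour
        s = piecewise_series([(0, 5.0), (300, 5.0), (360, 7.0), (540, 7.0)])
        rec = extract_ppgr(s, 300.0)
        assert rec.bgmax == pytest.approx(7.0)
        assert rec.bgrise == pytest.approx(2.0)
        assert rec.bg60 == pytest.approx(7.0)
        assert rec.iauc60 == pytest.approx(1.0, abs=1e-9)
        assert rec.iauc120 == pytest.approx(3.0, abs=1e-9)
        assert rec.auc120 == pytest.approx(3.0 + 2 * 5.0, abs=1e-9)

    def test_invariants_on_random_traces(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            s = random_trace(rng, span=260.0)
            rec = extract_ppgr(s, float(rng.uniform(0, 20)))
            assert rec.bgmax >= rec.bg60 - 1e-12
            assert rec.bgrise == pytest.approx(rec.bgmax - rec.bg0)
            assert rec.iauc60 <= rec.iauc120 + 1e-12
            assert rec.auc60 <= rec.auc120 + 1e-12
            assert rec.iauc120 <= rec.auc120 + 1e-12  # bg0 > 0 here
            assert min(rec.auc60, rec.auc120, rec.iauc60, rec.iauc120) >= 0

    def test_shift_equivariance(self):
        rng = np.random.default_rng(12)
        s = random_trace(rng, span=260.0)
        shifted = make_series(s.times_min, s.glucose + 1.5)
        a = extract_ppgr(s, 10.0)
        b = extract_ppgr(shifted, 10.0)
        assert b.bg0 == pytest.approx(a.bg0 + 1.5)
        assert b.bgmax == pytest.approx(a.bgmax + 1.5)
        assert b.bgrise == pytest.approx(a.bgrise, abs=1e-9)
        assert b.iauc120 == pytest.approx(a.iauc120, abs=1e-9)
        assert b.auc120 == pytest.approx(a.auc120 + 2 * 1.5, abs=1e-9)


def _meal(minute, items):
    return MealRecord("P0", START + pd.Timedelta(minutes=minute), "snack", tuple(items))


class TestMisreporting:
    def test_all_single_item_diary_flagged(self):
        diary = [_meal(60 * i, [("apple", 120.0)]) for i in range(10)]
        assert detect_misreporting(diary) == (True, "single_item")

    def test_six_rounded_meals_flagged(self):
        diary = [
            _meal(60 * i, [("apple", 100.0), ("bread", 200.0)]) for i in range(6)
        ] + [_meal(1000, [("apple", 113.0), ("bread", 47.0)])]
        assert detect_misreporting(diary) == (True, "rounded_portions")

    def test_five_rounded_meals_not_flagged(self):
        diary = [
            _meal(60 * i, [("apple", 100.0), ("bread", 200.0)]) for i in range(5)
        ] + [_meal(60 * i, [("apple", 113.0), ("bread", 47.0)]) for i in range(5, 20)]
        assert detect_misreporting(diary) == (False, None)


class TestRecordFilters:
    def _records(self):
        return pd.DataFrame(
            {
                "gi_defined": [True, False, True, True],
                "carbo": [30.0, 55.0, 50.0, 30.0],
                "iauc120": [1.5, 2.0, 0.4, 0.1],
            }
        )

    def test_filters_remove_exactly_the_flagged_records(self):
        kept, report = filter_records(self._records())
        # row 1: gi undefined; row 2: carbo 50 g with rate 0.2 mmol/L/h
        assert list(kept.index) == [0, 3]
        assert report == {"input": 4, "gi_undefined": 1, "small_ppgr": 1, "kept": 2}

    def test_small_response_with_low_carb_is_kept(self):
        kept, _ = filter_records(self._records())
        assert 3 in kept.index  # carbo 30 g, iauc 0.1: carb condition not met

    def test_counts_reconcile(self):
        kept, report = filter_records(self._records())
        assert report["input"] - report["kept"] == report["gi_undefined"] + report["small_ppgr"]
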