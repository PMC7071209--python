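"""Shared fixtures: glucose-trace builders, the hand-built exclusion-rule
fixture, and a small simulated cohort reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ppgr_pipeline.cgm_io import CGMSeries, MealRecord, ProtocolEntry
from ppgr_pipeline.foodlib import load_bundled_food_db
from ppgr_pipeline.pipeline import PipelineConfig, process_cohort
from ppgr_pipeline.synthetic_data import default_config, gen_cohort

START = pd.Timestamp("2021-03-01 00:00:00")


def make_series(times_min, glucose, patient_id="P0", start=START) -> CGMSeries:
    return CGMSeries(
        patient_id,
        pd.Timestamp(start),
        np.asarray(times_min, dtype=float),
        np.asarray(glucose, dtype=float),
    )


def piecewise_series(knots, patient_id="P0", step=5.0) -> CGMSeries:
    """Sample a piecewise-linear trace (knot minutes at multiples of `step`,
    so the sampled series reproduces it exactly) on a uniform grid."""
    kt = np.array([k[0] for k in knots], dtype=float)
    kv = np.array([k[1] for k in knots], dtype=float)
    t = np.arange(kt[0], kt[-1] + 1e-9, step)
    return make_series(t, np.interp(t, kt, kv), patient_id=patient_id)


@pytest.fixture(scope="session")
def food_db():
    return load_bundled_food_db()


@pytest.fixture
def flat_series():
    t = np.arange(0.0, 1441.0, 5.0)
    return make_series(t, np.full(len(t), 5.0))


def exclusion_fixture():
    """Twelve protocol meals on a crafted day-long trace: one triggers each
    of the four exclusion rules (late report on a rising peak at 500 min, a
    falling-edge report at 700 min, an interfering pair at 900/945 min) and
    eight are kept."""
    series = piecewise_series(
        [(0, 5.0), (440, 5.0), (500, 6.2), (560, 5.0),
         (610, 5.0), (670, 6.5), (730, 5.0), (1440, 5.0)]
    )
    minutes = [100, 200, 300, 400, 500, 600, 700, 800, 900, 945, 1100, 1200]
    protocol = [
        ProtocolEntry("P0", START + pd.Timedelta(minutes=m), None) for m in minutes
    ]
    diary = [
        MealRecord("P0", START + pd.Timedelta(minutes=m), "snack", (("apple", 100.0),))
        for m in minutes
    ]
    expected = {500: "late_report", 700: "falling_edge", 900: "subsequent_meal", 945: "prior_meal"}
    return series, protocol, diary, expected


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 12-patient cohort (3 days) with the default error rates."""
    cfg = default_config(seed=7, n_gdm=9, n_control=3, days=3)
    return gen_cohort(cfg)


@pytest.fixture(scope="session")
def small_result(small_cohort):
    return process_cohort(small_cohort, PipelineConfig(seed=7))
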