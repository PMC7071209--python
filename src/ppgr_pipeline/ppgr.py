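"""Postprandial glycemic response (PPGR) outcomes and data-quality filters.

For each kept meal the glucose trace yields eight outcomes: the pre-meal level
BG0, the level one hour later BG60, the peak BGMax within 3 h, the rise
BGRise = BGMax − BG0, total areas under the curve over 1 h and 2 h (AUC60,
AUC120) and the corresponding *incremental* areas (iAUC60, iAUC120) above the
BG0 baseline with the positive-increment convention: glucose excursions below
the baseline contribute nothing (standard GI methodology).  Areas are in
mmol/L·h; time is handled internally in minutes.

Two quality filters follow:

* patient-level misreporting — a diary consisting entirely of single-item
  meals, or with more than five meals whose every portion is a multiple of
  100 g, marks the patient as a misreporter and removes all their records;
* record-level — meals containing a GI-undefined item are removed, as are
  meals with more than 40 g of carbohydrate whose mean incremental response
  (iAUC120 over 2 h) is below 0.3 mmol/L/h, i.e. implausibly small responses
  to large carbohydrate loads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cgm_io import CGMSeries, MealRecord, bg_at, CGMGapError, OutOfRangeError

__all__ = [
    "PPGRRecord",
    "OUTCOME_COLUMNS",
    "trapezoid_auc",
    "incremental_auc",
    "extract_ppgr",
    "detect_misreporting",
    "filter_records",
    "SMALL_PPGR_RATE_THRESHOLD",
    "SMALL_PPGR_CARB_THRESHOLD",
]

#: Records with carbo above this (g) and mean incremental rate below
#: ``SMALL_PPGR_RATE_THRESHOLD`` (mmol/L/h) are treated as implausible.
SMALL_PPGR_CARB_THRESHOLD = 40.0
SMALL_PPGR_RATE_THRESHOLD = 0.3

#: BGMax search window after the meal start, minutes.
PEAK_WINDOW_MIN = 180.0

OUTCOME_COLUMNS = ("bg0", "bg60", "bgmax", "bgrise", "auc60", "auc120", "iauc60", "iauc120")


@dataclass(frozen=True)
class PPGRRecord:
    bg0: float
    bg60: float
    bgmax: float
    bgrise: float
    auc60: float
    auc120: float
    iauc60: float
    iauc120: float

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in OUTCOME_COLUMNS}


def _window_points(series: CGMSeries, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample times/values covering [t0, t1]: interior samples plus exactly
    interpolated endpoints.  Raises if the trace has a gap inside the window."""
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    v0 = bg_at(series, t0)
    v1 = bg_at(series, t1)
    inner = (series.times_min > t0) & (series.times_min < t1)
    t = np.concatenate(([t0], series.times_min[inner], [t1]))
    v = np.concatenate(([v0], series.glucose[inner], [v1]))
    gaps = np.diff(t)
    if len(gaps) and gaps.max() > 20.0 + 1e-9:
        raise CGMGapError(
            f"{series.patient_id}: {gaps.max():.0f}-min sensor gap in [{t0:.0f}, {t1:.0f}]"
        )
    return t, v


def trapezoid_auc(series: CGMSeries, t0: float, t1: float) -> float:
    """Trapezoidal area under the glucose trace over [t0, t1], mmol/L·h."""
    t, v = _window_points(series, t0, t1)
    return float(np.trapezoid(v, t)) / 60.0


def incremental_auc(series: CGMSeries, t0: float, t1: float, baseline: float) -> float:
    """Positive-increment area above ``baseline`` over [t0, t1], mmol/L·h.

    Baseline-crossing points of the piecewise-linear trace are inserted
    exactly before clipping, so the integral of max(BG − baseline, 0) is exact
    for the interpolated trace.
    """
    t, v = _window_points(series, t0, t1)
    d = v - baseline
    # exact linear crossings between samples of opposite sign
    sign_change = np.flatnonzero(d[:-1] * d[1:] < 0)
    if len(sign_change):
        frac = d[sign_change] / (d[sign_change] - d[sign_change + 1])
        t_cross = t[sign_change] + frac * (t[sign_change + 1] - t[sign_change])
        t = np.concatenate([t, t_cross])
        d = np.concatenate([d, np.zeros_like(t_cross)])
        order = np.argsort(t, kind="stable")
        t, d = t[order], d[order]
    return float(np.trapezoid(np.clip(d, 0.0, None), t)) / 60.0


def extract_ppgr(series: CGMSeries, meal_start_min: float) -> PPGRRecord:
    """All eight PPGR outcomes for a meal starting at ``meal_start_min``.

    BG0 and BG60 are interpolated values; BGMax is the maximum over raw
    samples in [start, start+180 min] together with the interpolated window
    edges.  Raises :class:`CGMGapError`/:class:`OutOfRangeError` when the
    trace cannot support the 3-h window; callers drop such records with a
    counted reason.
    """
    t = meal_start_min
    bg0 = bg_at(series, t)
    bg60 = bg_at(series, t + 60.0)
    tw, vw = _window_points(series, t, t + PEAK_WINDOW_MIN)
    bgmax = float(vw.max())
    return PPGRRecord(
        bg0=bg0,
        bg60=bg60,
        bgmax=bgmax,
        bgrise=bgmax - bg0,
        auc60=trapezoid_auc(series, t, t + 60.0),
        auc120=trapezoid_auc(series, t, t + 120.0),
        iauc60=incremental_auc(series, t, t + 60.0, baseline=bg0),
        iauc120=incremental_auc(series, t, t + 120.0, baseline=bg0),
    )


def detect_misreporting(
    patient_diary: Sequence[MealRecord], max_rounded_meals: int = 5
) -> tuple[bool, str | None]:
    """Flag a patient whose diary shows systematic misreporting.

    Fires when (a) every meal consists of a single item, or (b) strictly more
    than ``max_rounded_meals`` meals have every portion a multiple of 100 g.
    """
    if not patient_diary:
        raise ValueError("patient diary is empty")
    if all(len(m.items) == 1 for m in patient_diary):
        return True, "single_item"
    rounded = sum(
        1 for m in patient_diary if all(g % 100 == 0 for _, g in m.items)
    )
    if rounded > max_rounded_meals:
        return True, "rounded_portions"
    return False, None


def filter_records(
    records: pd.DataFrame,
    *,
    carb_threshold: float = SMALL_PPGR_CARB_THRESHOLD,
    rate_threshold: float = SMALL_PPGR_RATE_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Record-level filters on a table carrying meal composition and PPGR.

    Requires columns ``gi_defined``, ``carbo`` and ``iauc120``.  Removes
    (1) meals with a GI-undefined item, (2) meals with carbo > ``carb_threshold``
    grams whose mean incremental rate iauc120 / 2 h falls below
    ``rate_threshold`` mmol/L/h.  Returns the kept rows and per-reason counts.
    """
    for col in ("gi_defined", "carbo", "iauc120"):
        if col not in records.columns:
            raise ValueError(f"records table lacks column {col!r}")
    gi_undef = ~records["gi_defined"].astype(bool)
    small = (
        ~gi_undef
        & (records["carbo"] > carb_threshold)
        & (records["iauc120"] / 2.0 < rate_threshold)
    )
    kept = records.loc[~gi_undef & ~small].copy()
    report = {
        "input": int(len(records)),
        "gi_undefined": int(gi_undef.sum()),
        "small_ppgr": int(small.sum()),
        "kept": int(len(kept)),
    }
    return kept, report
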