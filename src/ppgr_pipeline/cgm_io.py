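"""CGM, meal-diary and meal-protocol I/O, trace interpolation, record linkage
and meal exclusion rules.

The study design pairs three record streams per patient: a continuous glucose
monitor (CGM) sampling interstitial glucose roughly every 5 minutes, an
electronic food diary (meal type, time, list of foods and grams), and a paper
protocol in which the patient wrote down the exact meal start times.  The
protocol start time is authoritative; each protocol entry is matched to the
nearest diary record, and matched meals whose start time is evidently
misreported, or which are interfered with by neighbouring meals, are excluded:

(a) *late_report* — glucose at the reported start is more than 1.0 mmol/L above
    the level one hour earlier (the report fell on the rising peak);
(b) *falling_edge* — the reported start sits on the falling edge of a peak
    (at least 0.5 mmol/L above the level 30 min later and at least 0.5 mmol/L
    below the level 30 min earlier);
(c) *prior_meal* — another meal started less than one hour before;
(d) *subsequent_meal* — another meal starts less than one hour after.

Rules are evaluated in this order and the first match labels the meal, so every
excluded meal carries exactly one reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MEAL_TYPES",
    "GLUCOSE_RANGE",
    "CGMSeries",
    "ProtocolEntry",
    "MealRecord",
    "MatchedMeal",
    "CGMGapError",
    "OutOfRangeError",
    "bg_at",
    "match_protocol_to_diary",
    "apply_exclusion_rules",
    "exclusion_report",
    "read_cgm",
    "read_diary",
    "read_protocol",
]

MEAL_TYPES = ("breakfast", "lunch", "dinner", "snack")
GLUCOSE_RANGE = (1.0, 30.0)  # mmol/L, sensor validity band

#: Interpolation across a sampling gap wider than this is refused.
MAX_INTERP_GAP_MIN = 20.0
#: Queries this far beyond the first/last sample are clamped to the edge value.
EDGE_TOLERANCE_MIN = 2.5


class CGMGapError(ValueError):
    """A required glucose value falls inside a sensor gap."""


class OutOfRangeError(ValueError):
    """A required time point lies outside the recorded CGM span."""


@dataclass
class CGMSeries:
    """One patient's glucose trace: minutes since ``start`` plus mmol/L values."""

    patient_id: str
    start: pd.Timestamp
    times_min: np.ndarray
    glucose: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times_min.shape != self.glucose.shape:
            raise ValueError("times and glucose must have equal length")
        if len(self.times_min) and np.any(np.diff(self.times_min) <= 0):
            raise ValueError(f"{self.patient_id}: CGM times not strictly increasing")

    def minutes(self, ts: pd.Timestamp) -> float:
        """Convert a timestamp to minutes since the series start."""
        return (pd.Timestamp(ts) - self.start).total_seconds() / 60.0

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times_min[0]), float(self.times_min[-1])


@dataclass(frozen=True)
class ProtocolEntry:
    patient_id: str
    meal_start: pd.Timestamp
    point_bg: float | None = None  # carried for provenance, unused computationally


@dataclass(frozen=True)
class MealRecord:
    patient_id: str
    diary_time: pd.Timestamp
    meal_type: str
    items: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.meal_type not in MEAL_TYPES:
            raise ValueError(f"unknown meal_type {self.meal_type!r}")
        if not self.items:
            raise ValueError("meal record needs at least one item")
        if any(g <= 0 for _, g in self.items):
            raise ValueError("item grams must be > 0")


@dataclass
class MatchedMeal:
    """A protocol entry paired with its diary record; ``meal_start`` is the
    protocol time.  ``exclusion`` is None for kept meals."""

    protocol_entry: ProtocolEntry
    meal_record: MealRecord
    meal_start: pd.Timestamp
    exclusion: str | None = None

    @property
    def patient_id(self) -> str:
        return self.protocol_entry.patient_id


def bg_at(series: CGMSeries, t_min: float, *, max_gap_min: float = MAX_INTERP_GAP_MIN) -> float:
    """Linearly interpolated glucose at ``t_min`` minutes into the series.

    Queries within ±2.5 min of the trace edges return the edge sample (protocol
    times can fall between the nominal 5-min samples); queries whose bracketing
    sample gap exceeds ``max_gap_min`` raise :class:`CGMGapError`; queries
    outside the span raise :class:`OutOfRangeError`.
    """
    t = series.times_min
    g = series.glucose
    lo, hi = series.span
    if t_min < lo or t_min > hi:
        if lo - EDGE_TOLERANCE_MIN <= t_min < lo:
            return float(g[0])
        if hi < t_min <= hi + EDGE_TOLERANCE_MIN:
            return float(g[-1])
        raise OutOfRangeError(
            f"{series.patient_id}: t={t_min:.1f} min outside CGM span [{lo:.1f}, {hi:.1f}]"
        )
    i = int(np.searchsorted(t, t_min))
    if i < len(t) and t[i] == t_min:
        return float(g[i])
    if t[i] - t[i - 1] > max_gap_min:
        raise CGMGapError(
            f"{series.patient_id}: {t[i] - t[i - 1]:.0f}-min sensor gap at t={t_min:.1f}"
        )
    w = (t_min - t[i - 1]) / (t[i] - t[i - 1])
    return float((1 - w) * g[i - 1] + w * g[i])


def match_protocol_to_diary(
    protocol: Sequence[ProtocolEntry],
    diary: Sequence[MealRecord],
    max_gap_min: float = 60.0,
) -> tuple[list[MatchedMeal], int]:
    """Pair each protocol entry with the nearest-in-time diary record.

    Greedy one-to-one assignment by ascending absolute time difference, capped
    at ``max_gap_min``; protocol entries with no diary record inside the cap
    are dropped.  Returns the matches (sorted by meal start) and the number of
    unmatched protocol entries.
    """
    candidates = []
    for ip, p in enumerate(protocol):
        for idx, d in enumerate(diary):
            if d.patient_id != p.patient_id:
                raise ValueError("matching requires records of a single patient")
            dt = abs((d.diary_time - p.meal_start).total_seconds()) / 60.0
            if dt <= max_gap_min:
                candidates.append((dt, ip, idx))
    candidates.sort()
    used_p: set[int] = set()
    used_d: set[int] = set()
    matches: list[MatchedMeal] = []
    for dt, ip, idx in candidates:
        if ip in used_p or idx in used_d:
            continue
        used_p.add(ip)
        used_d.add(idx)
        p = protocol[ip]
        matches.append(MatchedMeal(p, diary[idx], meal_start=p.meal_start))
    matches.sort(key=lambda m: m.meal_start)
    return matches, len(protocol) - len(used_p)


def apply_exclusion_rules(
    matched: Sequence[MatchedMeal],
    series: CGMSeries,
    *,
    late_threshold: float = 1.0,
    falling_threshold: float = 0.5,
    interference_window_min: float = 60.0,
) -> tuple[list[MatchedMeal], dict[str, int]]:
    """Annotate matched meals with the misreporting/interference exclusions.

    Rules (a)–(d) are checked in order; the first that fires is recorded.
    Rules (c)/(d) consider the protocol starts of *all* matched meals of the
    patient, including meals themselves excluded, with open interval endpoints.
    A meal for which any required glucose value is unavailable (sensor gap or
    outside the span) is excluded with reason ``cgm_unavailable``.
    """
    starts = [series.minutes(m.meal_start) for m in matched]
    counts = {
        "late_report": 0,
        "falling_edge": 0,
        "prior_meal": 0,
        "subsequent_meal": 0,
        "cgm_unavailable": 0,
        "kept": 0,
    }
    out: list[MatchedMeal] = []
    for i, meal in enumerate(matched):
        t = starts[i]
        reason = None
        try:
            bg_t = bg_at(series, t)
            bg_m60 = bg_at(series, t - 60.0)
            bg_m30 = bg_at(series, t - 30.0)
            bg_p30 = bg_at(series, t + 30.0)
        except (CGMGapError, OutOfRangeError):
            reason = "cgm_unavailable"
        if reason is None:
            if bg_t - bg_m60 > late_threshold:
                reason = "late_report"
            elif bg_t >= bg_p30 + falling_threshold and bg_t <= bg_m30 - falling_threshold:
                reason = "falling_edge"
            elif any(t - interference_window_min < s < t for j, s in enumerate(starts) if j != i):
                reason = "prior_meal"
            elif any(t < s < t + interference_window_min for j, s in enumerate(starts) if j != i):
                reason = "subsequent_meal"
        counts[reason or "kept"] += 1
        out.append(replace_exclusion(meal, reason))
    return out, counts


def replace_exclusion(meal: MatchedMeal, reason: str | None) -> MatchedMeal:
    return MatchedMeal(meal.protocol_entry, meal.meal_record, meal.meal_start, exclusion=reason)


def exclusion_report(matched: Iterable[MatchedMeal]) -> pd.DataFrame:
    """Per-meal status table (patient_id, meal_start, status, reason)."""
    rows = [
        {
            "patient_id": m.patient_id,
            "meal_start": m.meal_start,
            "status": "excluded" if m.exclusion else "kept",
            "reason": m.exclusion or "",
        }
        for m in matched
    ]
    return pd.DataFrame(rows, columns=["patient_id", "meal_start", "status", "reason"])


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")


def read_cgm(path: str | Path) -> tuple[dict[str, CGMSeries], list[str]]:
    """Read a CGM CSV (patient_id, timestamp, glucose_mmol_l).

    Returns one :class:`CGMSeries` per patient plus a list of human-readable
    reports for malformed rows (unparseable values, glucose outside the sensor
    band), which are skipped.  Duplicate or non-monotone timestamps within a
    patient are a hard error naming the offending line.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["patient_id", "timestamp", "glucose_mmol_l"], path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    glucose = pd.to_numeric(df["glucose_mmol_l"], errors="coerce")
    bad = []
    ok = np.ones(len(df), dtype=bool)
    for i in np.flatnonzero(ts.isna() | glucose.isna()):
        bad.append(f"line {i + 2}: unparseable timestamp or glucose")
        ok[i] = False
    out_of_band = (~glucose.isna()) & ((glucose < GLUCOSE_RANGE[0]) | (glucose > GLUCOSE_RANGE[1]))
    for i in np.flatnonzero(out_of_band):
        bad.append(f"line {i + 2}: glucose {glucose.iloc[i]} outside {GLUCOSE_RANGE} mmol/L")
        ok[i] = False
    df = df.loc[ok].assign(_ts=ts[ok], _g=glucose[ok])
    series: dict[str, CGMSeries] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        order = grp["_ts"].values
        if np.any(np.diff(order) <= np.timedelta64(0, "s")):
            j = int(np.flatnonzero(np.diff(order) <= np.timedelta64(0, "s"))[0])
            raise ValueError(
                f"{path}: non-monotone CGM timestamps for {pid} near line {grp.index[j + 1] + 2}"
            )
        start = grp["_ts"].iloc[0]
        tmin = (grp["_ts"] - start).dt.total_seconds().to_numpy() / 60.0
        series[str(pid)] = CGMSeries(str(pid), start, tmin, grp["_g"].to_numpy())
    return series, bad


def read_protocol(path: str | Path) -> list[ProtocolEntry]:
    """Read a protocol CSV (patient_id, timestamp, point_bg_mmol_l)."""
    df = pd.read_csv(path)
    _require_columns(df, ["patient_id", "timestamp", "point_bg_mmol_l"], path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        i = int(np.flatnonzero(ts.isna())[0])
        raise ValueError(f"{path}: unparseable timestamp at line {i + 2}")
    entries = [
        ProtocolEntry(
            str(r.patient_id),
            t,
            None if pd.isna(r.point_bg_mmol_l) else float(r.point_bg_mmol_l),
        )
        for r, t in zip(df.itertuples(), ts)
    ]
    entries.sort(key=lambda e: (e.patient_id, e.meal_start))
    return entries


def read_diary(path: str | Path) -> tuple[list[MealRecord], list[str]]:
    """Read a diary CSV (patient_id, timestamp, meal_type, food_name, grams;
    one row per item).  Rows with grams <= 0 are rejected and reported; an
    unknown meal_type is a hard error."""
    df = pd.read_csv(path)
    _require_columns(df, ["patient_id", "timestamp", "meal_type", "food_name", "grams"], path)
    unknown = ~df["meal_type"].isin(MEAL_TYPES)
    if unknown.any():
        i = int(np.flatnonzero(unknown)[0])
        raise ValueError(
            f"{path}: unknown meal_type {df['meal_type'].iloc[i]!r} at line {i + 2}"
        )
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        i = int(np.flatnonzero(ts.isna())[0])
        raise ValueError(f"{path}: unparseable timestamp at line {i + 2}")
    grams = pd.to_numeric(df["grams"], errors="coerce")
    bad = []
    ok = np.ones(len(df), dtype=bool)
    for i in np.flatnonzero(grams.isna() | (grams <= 0)):
        bad.append(f"line {i + 2}: non-positive or unparseable grams")
        ok[i] = False
    df = df.loc[ok].assign(_ts=ts[ok], _grams=grams[ok])
    records = []
    for (pid, t, mtype), grp in df.groupby(["patient_id", "_ts", "meal_type"], sort=True):
        items = tuple(zip(grp["food_name"].astype(str), grp["_grams"].astype(float)))
        records.append(MealRecord(str(pid), t, str(mtype), items))
    records.sort(key=lambda r: (r.patient_id, r.diary_time))
    return records, bad
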