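"""Synthetic cohort generator with known ground truth.

The pipeline's clinical inputs (CGM traces, food diaries, meal-start
protocols, a food table, patient profiles) are simulated so every downstream
stage can be validated against a planted signal:

* Each patient carries a basal glucose level (group-shifted: GDM above
  control), a circadian modulation, and a slow Ornstein–Uhlenbeck drift, so
  the pre-meal glucose BG0 varies both between and within patients.
* Each meal samples 1–6 items from the food table; its *true* incremental
  response is linear in the planted features:
  ``iAUC120 = β0 + β_carbo·carbo + β_gl·gl + β_bg0·BG0 + u_patient + ε``
  (clipped at zero), with u a patient random effect and ε meal-level noise.
* The glucose trace adds, per meal, a gamma-shaped response kernel peaking
  ~45 min after intake and normalized to unit iAUC120, so the planted value
  is recovered exactly by the outcome extractor on a noiseless trace.  AR(1)
  sensor noise (lag-5-min correlation 0.7) makes the trace realistically
  smooth rather than white.
* Reporting errors are injected at configurable rates: protocol times
  delayed onto the rising peak (late_report exclusions) or onto the falling
  edge, extra meals inserted within the hour (prior/subsequent exclusions),
  deleted diary records (unmatched protocol entries), and misreporting
  patients who log single-item or 100 g-rounded diaries.

``theoretical_r`` gives the Pearson-R ceiling any model predicting the
measured outcome from the planted features can reach under the generative
model; the default scenario is calibrated so this ceiling is ≈ 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cgm_io import CGMSeries, MealRecord, ProtocolEntry
from .foodlib import FoodDB, load_bundled_food_db, meal_composition

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "Cohort",
    "default_config",
    "gen_cohort",
    "gen_cgm_trace",
    "theoretical_r",
    "write_cohort",
]

#: Daily meal schedule, minutes after midnight (3 mains + 2 snacks, the
#: frequent small meals recommended in GDM dietary management).
MEAL_SCHEDULE = (480.0, 660.0, 810.0, 990.0, 1170.0)
MEAL_TYPE_OF_SLOT = ("breakfast", "snack", "lunch", "snack", "dinner")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Sizes echo the study design (more GDM than control patients, ~6 days of
    monitoring, 5 intakes/day); error rates echo the reported exclusion
    proportions.  ``beta`` is the planted linear signal in mmol/L·h per unit
    of each feature; ``noise_sd`` is meal-level outcome noise and
    ``random_effect_sd`` the patient-level effect, both in mmol/L·h.
    """

    n_gdm: int = 44
    n_control: int = 16
    days: int = 6
    meals_per_day: int = 5
    cgm_interval: float = 5.0
    # response kernel: peak time (min) and shape exponent of the gamma form
    kernel_peak_min: float = 45.0
    kernel_shape: float = 4.0
    # planted signal
    beta: tuple[tuple[str, float], ...] = (
        ("carbo", 0.012),
        ("gl", 0.045),
        ("bg0", -0.35),
    )
    intercept: float = 3.4
    noise_sd: float = 1.15
    random_effect_sd: float = 0.3
    # trace model
    sensor_noise_sd: float = 0.1
    sensor_ar1: float = 0.7
    basal_mean_gdm: float = 4.9
    basal_mean_control: float = 4.5
    basal_sd: float = 0.35
    circadian_amp: float = 0.5
    ou_sd: float = 0.3
    ou_tau_min: float = 180.0
    # reporting-error rates
    p_late: float = 0.045
    p_falling: float = 0.015
    p_cluster: float = 0.03
    p_missing_diary: float = 0.03
    misreporter_fraction: float = 0.10
    # diary noise
    diary_time_sd_min: float = 5.0
    items_per_meal: tuple[int, int] = (1, 6)
    profile_missing_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_late", "p_falling", "p_cluster", "p_missing_diary",
                     "misreporter_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.kernel_peak_min <= 0 or self.kernel_shape <= 0:
            raise ValueError("kernel parameters must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def beta_dict(self) -> dict[str, float]:
        return dict(self.beta)

    @property
    def n_patients(self) -> int:
        return self.n_gdm + self.n_control


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(seed=seed), **overrides)


@dataclass
class GroundTruth:
    """Per-meal planted values plus the generating parameters."""

    meals: pd.DataFrame  # patient_id, t_true_min, meal_start, signal, amplitude, carbo, gl, bg0, injected
    beta: dict[str, float]
    intercept: float
    random_effects: dict[str, float]

    @property
    def active_features(self) -> list[str]:
        return [k for k, v in self.beta.items() if v != 0.0]


@dataclass
class Cohort:
    """Everything the pipeline consumes, plus the ground truth."""

    config: GeneratorConfig
    food_db: FoodDB
    profiles: pd.DataFrame
    diary: list[MealRecord]
    protocol: list[ProtocolEntry]
    cgm: dict[str, CGMSeries]
    truth: GroundTruth
    misreporters: list[str]


# ---------------------------------------------------------------------------
# Response kernel
# ---------------------------------------------------------------------------

def _kernel(t_min: np.ndarray, peak: float, shape: float) -> np.ndarray:
    """Gamma-shaped unimodal response, value 1 at ``t = peak``, 0 for t <= 0."""
    t = np.clip(np.asarray(t_min, dtype=float), 0.0, None)
    u = t / peak
    with np.errstate(over="ignore"):
        k = u**shape * np.exp(shape * (1.0 - u))
    return np.where(t_min > 0, k, 0.0)


def _kernel_unit_area(peak: float, shape: float) -> float:
    """Integral of the kernel over the first 120 min, in hours — the constant
    that normalizes a unit-amplitude response to unit iAUC120."""
    t = np.linspace(0.0, 120.0, 4001)
    return float(np.trapezoid(_kernel(t, peak, shape), t)) / 60.0


# ---------------------------------------------------------------------------
# Patient profiles
# ---------------------------------------------------------------------------

def _gen_profiles(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Patient table following the bundled feature spec: numeric block with
    directional GDM shifts (higher BMI, OGTT glucose, triglycerides), binary
    history items, ordinal questionnaire items, plus sparse missingness in
    the numeric block."""
    n = cfg.n_patients
    ids = [f"P{i:03d}" for i in range(n)]
    gdm = np.array([1] * cfg.n_gdm + [0] * cfg.n_control)
    df = pd.DataFrame({"patient_id": ids, "group": np.where(gdm == 1, "GDM", "control")})
    norm = rng.normal
    df["age"] = np.round(norm(31.0, 4.5, n) + 0.5 * gdm, 1)
    df["bmi"] = np.round(norm(22.5, 3.5, n) + 3.0 * gdm, 1)
    df["weight"] = np.round(df["bmi"] * norm(2.72, 0.18, n), 1)  # ~height² factor
    df["gestational_age"] = np.round(np.clip(norm(27.0, 3.5, n), 19, 36), 1)
    df["bp_systolic"] = np.round(norm(116, 12, n) + 5 * gdm)
    df["bp_diastolic"] = np.round(norm(74, 9, n) + 3 * gdm)
    df["ogtt_fasting"] = np.round(norm(4.4, 0.35, n) + 0.8 * gdm, 2)
    df["ogtt_1h"] = np.round(norm(6.6, 1.3, n) + 3.0 * gdm, 2)
    df["ogtt_2h"] = np.round(norm(6.0, 1.1, n) + 2.5 * gdm, 2)
    df["fasting_insulin"] = np.round(norm(80, 35, n) + 14 * gdm, 1)
    df["hba1c"] = np.round(norm(5.0, 0.35, n) + 0.3 * gdm, 2)
    df["fructosamine"] = np.round(norm(230, 25, n), 1)
    df["leptin"] = np.round(np.clip(norm(34, 20, n), 2, None), 1)
    df["cholesterol"] = np.round(norm(6.1, 1.1, n) + 0.2 * gdm, 2)
    df["hdl"] = np.round(norm(2.05, 0.4, n), 2)
    df["ldl"] = np.round(norm(3.35, 0.9, n), 2)
    df["triglycerides"] = np.round(np.clip(norm(1.7, 0.7, n) + 0.4 * gdm, 0.4, None), 2)
    df["vldl"] = np.round(df["triglycerides"] / 2.2, 2)
    df["n_pregnancies"] = rng.poisson(1.8, n)
    df["n_deliveries"] = np.minimum(rng.poisson(0.8, n), df["n_pregnancies"])
    df["n_abortions"] = rng.poisson(0.3, n)
    df["n_miscarriages"] = rng.poisson(0.2, n)
    for col, p_gdm, p_ctrl in (
        ("gdm_history", 0.15, 0.02),
        ("pcos", 0.10, 0.05),
        ("igt_history", 0.12, 0.03),
        ("family_diabetes", 0.35, 0.20),
        ("hypertension", 0.10, 0.03),
        ("oc_pills", 0.30, 0.30),
        ("smoking", 0.12, 0.12),
    ):
        p = np.where(gdm == 1, p_gdm, p_ctrl)
        df[col] = (rng.random(n) < p).astype(int)
    df["group_gdm"] = gdm
    from .features import load_bundled_feature_spec

    spec = load_bundled_feature_spec()
    for var in spec.by_type("ordinal"):
        df[var.name] = rng.choice([0, 1, 2], size=n, p=[0.3, 0.45, 0.25]).astype(float)
    # sparse missingness in the numeric block only (as in the real data,
    # everything except patient characteristics is complete)
    numeric_cols = [v.name for v in spec.by_type("numeric")]
    for col in numeric_cols:
        miss = rng.random(n) < cfg.profile_missing_rate
        df.loc[miss, col] = np.nan
    return df


# ---------------------------------------------------------------------------
# Meals
# ---------------------------------------------------------------------------

def _sample_meal_items(
    food_names: list[str],
    weights: np.ndarray,
    portion_scale: np.ndarray,
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    snack: bool = False,
) -> tuple[tuple[str, float], ...]:
    lo, hi = cfg.items_per_meal
    sizes = np.arange(lo, hi + 1)
    # most intakes are 1-3 items; large composite meals are the minority
    probs = np.array([0.28, 0.30, 0.20, 0.12, 0.07, 0.03][: len(sizes)])
    n_items = 1 if snack and rng.random() < 0.5 else int(rng.choice(sizes, p=probs / probs.sum()))
    if snack:
        n_items = min(n_items, 2)
    idx = rng.choice(len(food_names), size=n_items, replace=False, p=weights)
    grams = np.clip(rng.lognormal(4.75, 0.28, n_items), 25, 300) * portion_scale[idx]
    if snack:
        grams = grams * 0.6
    grams = np.clip(np.round(grams / 5) * 5, 10, None)
    return tuple((food_names[i], float(g)) for i, g in zip(idx, grams))


def _food_sampling_weights(db: FoodDB) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Sampling weights and portion scales over the food table.

    Staples are eaten a bit more often than rare items; GI-undefined exotic
    items are rare (so a small share of meals hits the GI-undefined record
    filter, as in the curated database).  Concentrated carbohydrate sources
    (sugar, bread, dried fruit) come in smaller portions than watery dishes —
    without this, gram-level portion noise produces implausible 200 g sugar
    servings and a carbohydrate distribution far wider than real diaries.
    """
    names = []
    weights = []
    scales = []
    for item in db.items():
        if item.gi is None:
            w = 0.15
        elif item.carb_per100 >= 30:
            w = 1.3
        elif item.carb_per100 >= 10:
            w = 1.2
        else:
            w = 1.0
        if item.carb_per100 >= 60:
            s = 0.22
        elif item.carb_per100 >= 30:
            s = 0.5
        else:
            s = 1.0
        names.append(item.name)
        weights.append(w)
        scales.append(s)
    w = np.asarray(weights, dtype=float)
    return names, w / w.sum(), np.asarray(scales, dtype=float)


# ---------------------------------------------------------------------------
# CGM trace
# ---------------------------------------------------------------------------

def gen_cgm_trace(
    basal: float,
    circ_phase: float,
    meal_events: Sequence[tuple[float, float]],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    *,
    total_min: float,
    noiseless: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One patient's glucose trace on a uniform grid.

    ``meal_events`` is (start minute, amplitude in mmol/L·h) per meal.  The
    trace is basal + circadian + OU drift + Σ amplitude·kernel + AR(1) sensor
    noise, clipped to [2, 25] mmol/L.  Returns (times, glucose, baseline)
    where baseline excludes meal responses and sensor noise (used to plant
    BG0-dependent amplitudes consistently).
    """
    t = np.arange(0.0, total_min + 1e-9, cfg.cgm_interval)
    base = basal + cfg.circadian_amp * np.sin(2 * np.pi * (t - circ_phase) / 1440.0)
    if cfg.ou_sd > 0 and not noiseless:
        phi = float(np.exp(-cfg.cgm_interval / cfg.ou_tau_min))
        eta = rng.normal(0.0, cfg.ou_sd * np.sqrt(1 - phi**2), len(t))
        ou = np.empty(len(t))
        ou[0] = rng.normal(0.0, cfg.ou_sd)
        for i in range(1, len(t)):
            ou[i] = phi * ou[i - 1] + eta[i]
        base = base + ou
    unit_area = _kernel_unit_area(cfg.kernel_peak_min, cfg.kernel_shape)
    g = base.copy()
    for tm, amp in meal_events:
        g += (amp / unit_area) * _kernel(t - tm, cfg.kernel_peak_min, cfg.kernel_shape)
    if not noiseless and cfg.sensor_noise_sd > 0:
        rho = cfg.sensor_ar1
        eps = rng.normal(0.0, cfg.sensor_noise_sd * np.sqrt(1 - rho**2), len(t))
        noise = np.empty(len(t))
        noise[0] = rng.normal(0.0, cfg.sensor_noise_sd)
        for i in range(1, len(t)):
            noise[i] = rho * noise[i - 1] + eps[i]
        g = g + noise
    return t, np.clip(g, 2.0, 25.0), base


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def gen_cohort(cfg: GeneratorConfig, food_db: FoodDB | None = None) -> Cohort:
    """Generate the full cohort: profiles, diaries, protocols, CGM traces and
    ground truth, with reporting errors injected at the configured rates."""
    rng = np.random.default_rng(cfg.seed)
    db = food_db if food_db is not None else load_bundled_food_db()
    profiles = _gen_profiles(cfg, rng)
    food_names, food_weights, portion_scale = _food_sampling_weights(db)
    beta = cfg.beta_dict
    start_date = pd.Timestamp("2021-03-01 00:00:00")
    total_min = cfg.days * 1440.0

    diary: list[MealRecord] = []
    protocol: list[ProtocolEntry] = []
    cgm: dict[str, CGMSeries] = {}
    truth_rows = []
    random_effects: dict[str, float] = {}
    misreporters: list[str] = []

    n_mis = int(round(cfg.misreporter_fraction * cfg.n_patients))
    mis_ids = set(rng.choice(cfg.n_patients, size=n_mis, replace=False).tolist())

    for pi, row in profiles.iterrows():
        pid = row["patient_id"]
        p_start = start_date + pd.Timedelta(days=int(rng.integers(0, 60)))
        basal_mean = cfg.basal_mean_gdm if row["group"] == "GDM" else cfg.basal_mean_control
        basal = float(rng.normal(basal_mean, cfg.basal_sd))
        circ_phase = float(rng.uniform(0, 1440))
        u_p = float(rng.normal(0.0, cfg.random_effect_sd))
        random_effects[pid] = u_p
        is_mis = pi in mis_ids
        mis_mode = rng.choice(["single_item", "rounded_portions"]) if is_mis else None
        if is_mis:
            misreporters.append(pid)

        # true meal times
        slots = MEAL_SCHEDULE[: cfg.meals_per_day]
        types = MEAL_TYPE_OF_SLOT[: cfg.meals_per_day]
        meal_list = []  # (t_true, meal_type, items, injected)
        for day in range(cfg.days):
            for slot, mtype in zip(slots, types):
                t_true = day * 1440.0 + slot + float(rng.uniform(-20, 20))
                items = _sample_meal_items(food_names, food_weights, portion_scale,
                                           rng, cfg, snack=(mtype == "snack"))
                meal_list.append([t_true, mtype, items, "none"])
        # cluster injections: an extra unplanned snack shortly before a meal,
        # present in both protocol and diary, interfering with its neighbour
        for m in list(meal_list):
            if rng.random() < cfg.p_cluster:
                t_snack = m[0] - float(rng.uniform(25, 55))
                items = _sample_meal_items(food_names, food_weights, portion_scale,
                                           rng, cfg, snack=True)
                meal_list.append([t_snack, "snack", items, "cluster"])
        meal_list.sort(key=lambda m: m[0])

        # amplitudes need BG0, which needs the baseline trace; build baseline
        # first (no meals), then amplitudes, then the full trace
        _, _, baseline = gen_cgm_trace(
            basal, circ_phase, [], cfg, np.random.default_rng(rng.integers(2**31)),
            total_min=total_min, noiseless=True,
        )
        # regenerate the stochastic parts with a dedicated per-patient stream
        trace_rng = np.random.default_rng(rng.integers(2**31))
        t_grid = np.arange(0.0, total_min + 1e-9, cfg.cgm_interval)
        # OU drift belongs to the baseline the amplitudes see
        phi = float(np.exp(-cfg.cgm_interval / cfg.ou_tau_min))
        if cfg.ou_sd > 0:
            eta = trace_rng.normal(0.0, cfg.ou_sd * np.sqrt(1 - phi**2), len(t_grid))
            ou = np.empty(len(t_grid))
            ou[0] = trace_rng.normal(0.0, cfg.ou_sd)
            for i in range(1, len(t_grid)):
                ou[i] = phi * ou[i - 1] + eta[i]
        else:
            ou = np.zeros(len(t_grid))
        baseline = baseline + ou

        events = []
        for m in meal_list:
            t_true, mtype, items, injected = m
            comp = meal_composition(items, db)
            bg0_true = float(np.interp(t_true, t_grid, baseline))
            x = {"carbo": comp.carbo, "gl": comp.gl if comp.gi_defined else 0.0,
                 "bg0": bg0_true}
            signal = cfg.intercept + sum(beta.get(k, 0.0) * v for k, v in x.items())
            amp = max(signal + u_p + float(rng.normal(0.0, cfg.noise_sd)), 0.0)
            events.append((t_true, amp))
            m.append((comp, bg0_true, signal, amp))

        unit_area = _kernel_unit_area(cfg.kernel_peak_min, cfg.kernel_shape)
        g = baseline.copy()
        for tm, amp in events:
            g += (amp / unit_area) * _kernel(t_grid - tm, cfg.kernel_peak_min, cfg.kernel_shape)
        if cfg.sensor_noise_sd > 0:
            rho = cfg.sensor_ar1
            eps = trace_rng.normal(0.0, cfg.sensor_noise_sd * np.sqrt(1 - rho**2), len(t_grid))
            noise = np.empty(len(t_grid))
            noise[0] = trace_rng.normal(0.0, cfg.sensor_noise_sd)
            for i in range(1, len(t_grid)):
                noise[i] = rho * noise[i - 1] + eps[i]
            g = g + noise
        g = np.clip(g, 2.0, 25.0)
        cgm[pid] = CGMSeries(pid, p_start, t_grid, g)

        # diaries and protocols, with reporting errors
        for m in meal_list:
            t_true, mtype, items, injected, (comp, bg0_true, signal, amp) = m
            # misreported start times: the patient recorded the meal late, in
            # both the paper protocol and the app diary (so matching still
            # pairs them and the CGM-shape rules must catch the error)
            t_prot = t_true
            if injected == "none":
                r = rng.random()
                if r < cfg.p_late:
                    t_prot = t_true + float(rng.uniform(40, 55))
                    injected = "late"
                elif r < cfg.p_late + cfg.p_falling:
                    t_prot = t_true + cfg.kernel_peak_min + float(rng.uniform(30, 45))
                    injected = "falling"
            prot_ts = p_start + pd.Timedelta(minutes=t_prot)
            point_bg = float(np.interp(t_prot, t_grid, g)) + float(rng.normal(0, 0.15))
            protocol.append(ProtocolEntry(pid, prot_ts, round(point_bg, 1)))

            # diary record: small timing error; possibly deleted; misreporters
            # degrade their items
            if injected != "cluster" and rng.random() < cfg.p_missing_diary:
                truth_rows.append(
                    dict(patient_id=pid, t_true_min=t_true, meal_start=prot_ts,
                         carbo=comp.carbo, gl=x_gl(comp), bg0=bg0_true,
                         signal=signal, amplitude=amp, injected="missing_diary")
                )
                continue
            d_items = items
            if is_mis:
                if mis_mode == "single_item":
                    d_items = (max(items, key=lambda it: it[1]),)
                else:
                    d_items = tuple((nm, max(100.0, round(gr / 100) * 100)) for nm, gr in items)
            t_diary = t_prot + float(rng.normal(0, cfg.diary_time_sd_min))
            diary.append(
                MealRecord(pid, p_start + pd.Timedelta(minutes=round(t_diary)), mtype, d_items)
            )
            truth_rows.append(
                dict(patient_id=pid, t_true_min=t_true, meal_start=prot_ts,
                     carbo=comp.carbo, gl=x_gl(comp), bg0=bg0_true,
                     signal=signal, amplitude=amp, injected=injected)
            )

    truth = GroundTruth(
        meals=pd.DataFrame(truth_rows),
        beta=beta,
        intercept=cfg.intercept,
        random_effects=random_effects,
    )
    protocol.sort(key=lambda e: (e.patient_id, e.meal_start))
    diary.sort(key=lambda r: (r.patient_id, r.diary_time))
    return Cohort(cfg, db, profiles, diary, protocol, cgm, truth, misreporters)


def x_gl(comp) -> float:
    return comp.gl if comp.gi_defined else float("nan")


# ---------------------------------------------------------------------------
# Theoretical prediction ceiling
# ---------------------------------------------------------------------------

def iauc_measurement_sd(cfg: GeneratorConfig) -> float:
    """Closed-form sd of the iAUC120 estimate under AR(1) sensor noise.

    The trapezoidal iAUC with baseline subtraction is, to first order, a
    linear functional of the noise: Σ w_j δ_j − (Σ w_j) δ_0 with trapezoid
    weights w over the 2-h grid.  Positive-part clipping is ignored (the
    default scenario keeps excursions well above baseline over most of the
    window)."""
    n_pts = int(round(120.0 / cfg.cgm_interval)) + 1
    w = np.full(n_pts, cfg.cgm_interval / 60.0)
    w[0] = w[-1] = cfg.cgm_interval / 120.0
    v = w.copy()
    v[0] -= w.sum()
    idx = np.arange(n_pts)
    corr = cfg.sensor_ar1 ** np.abs(idx[:, None] - idx[None, :])
    var = cfg.sensor_noise_sd**2 * float(v @ corr @ v)
    return float(np.sqrt(max(var, 0.0)))


def _sample_meal_covariates(
    cfg: GeneratorConfig, rng: np.random.Generator, n_mc: int, db: FoodDB
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized draw of (carbo, gl) for ``n_mc`` meals from the generator's
    meal distribution.  Weighted sampling without replacement is done with the
    Gumbel top-k trick, which reproduces the successive-draw distribution of
    the per-meal sampler."""
    food_names, weights, portion_scale = _food_sampling_weights(db)
    items = db.items()
    carb100 = np.array([f.carb_per100 for f in items])
    gi = np.array([f.gi if f.gi is not None else np.nan for f in items])
    F = len(items)
    lo, hi = cfg.items_per_meal
    sizes = np.arange(lo, hi + 1)
    probs = np.array([0.28, 0.30, 0.20, 0.12, 0.07, 0.03][: len(sizes)])
    probs = probs / probs.sum()
    snack_slots = sum(1 for t in MEAL_TYPE_OF_SLOT[: cfg.meals_per_day] if t == "snack")
    p_snack = snack_slots / cfg.meals_per_day

    is_snack = rng.random(n_mc) < p_snack
    n_items = rng.choice(sizes, size=n_mc, p=probs)
    n_items = np.where(is_snack & (rng.random(n_mc) < 0.5), 1, n_items)
    n_items = np.where(is_snack, np.minimum(n_items, 2), n_items)

    keys = np.log(weights)[None, :] + rng.gumbel(size=(n_mc, F))
    order = np.argsort(-keys, axis=1)[:, : int(sizes.max())]
    slot = np.arange(order.shape[1])[None, :]
    active = slot < n_items[:, None]

    grams = np.clip(rng.lognormal(4.75, 0.28, order.shape), 25, 300)
    grams = grams * portion_scale[order]
    grams = np.where(is_snack[:, None], grams * 0.6, grams)
    grams = np.clip(np.round(grams / 5) * 5, 10, None) * active

    carbo_i = grams * carb100[order] / 100.0
    carbo = carbo_i.sum(axis=1)
    gi_sel = gi[order]
    undefined = ((carbo_i > 0) & np.isnan(gi_sel) & active).any(axis=1)
    gl = np.nansum(gi_sel * carbo_i, axis=1) / 100.0
    gl = np.where(undefined, 0.0, gl)
    return carbo, gl


def theoretical_r(cfg: GeneratorConfig, n_mc: int = 100_000) -> float:
    """Attainable Pearson R: corr(planted linear signal, measured outcome).

    Monte-Carlo evaluation of the generative model's covariate distribution
    (meal sampling, basal/circadian/OU glucose, random effect, outcome noise,
    amplitude clipping and the closed-form iAUC measurement noise).  This is
    a deterministic functional of the config — an expectation evaluated with
    a fixed internal stream — not a per-run simulation."""
    rng = np.random.default_rng(987_654_321)
    db = load_bundled_food_db()
    beta = cfg.beta_dict
    carbo, gl = _sample_meal_covariates(cfg, rng, n_mc, db)
    basal_mean = (
        cfg.n_gdm * cfg.basal_mean_gdm + cfg.n_control * cfg.basal_mean_control
    ) / cfg.n_patients
    bg0 = (
        rng.normal(basal_mean, cfg.basal_sd, n_mc)
        + cfg.circadian_amp * np.sin(rng.uniform(0, 2 * np.pi, n_mc))
        + rng.normal(0.0, cfg.ou_sd, n_mc)
    )
    signal = (
        cfg.intercept
        + beta.get("carbo", 0.0) * carbo
        + beta.get("gl", 0.0) * gl
        + beta.get("bg0", 0.0) * bg0
    )
    if cfg.noise_sd == 0 and cfg.random_effect_sd == 0 and cfg.sensor_noise_sd == 0:
        return 1.0
    y = np.clip(
        signal
        + rng.normal(0.0, cfg.random_effect_sd, n_mc)
        + rng.normal(0.0, cfg.noise_sd, n_mc),
        0.0,
        None,
    ) + rng.normal(0.0, iauc_measurement_sd(cfg), n_mc)
    return float(np.corrcoef(signal, y)[0, 1])


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the five pipeline inputs plus the ground-truth sidecar as CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = []
    for pid, s in cohort.cgm.items():
        ts = s.start + pd.to_timedelta(s.times_min, unit="m")
        rows.append(pd.DataFrame({
            "patient_id": pid,
            "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
            "glucose_mmol_l": np.round(s.glucose, 3),
        }))
    paths["cgm"] = outdir / "cgm.csv"
    pd.concat(rows, ignore_index=True).to_csv(paths["cgm"], index=False)

    paths["protocol"] = outdir / "protocol.csv"
    pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in cohort.protocol],
            "timestamp": [e.meal_start.strftime("%Y-%m-%dT%H:%M:%S") for e in cohort.protocol],
            "point_bg_mmol_l": [e.point_bg for e in cohort.protocol],
        }
    ).to_csv(paths["protocol"], index=False)

    diary_rows = []
    for r in cohort.diary:
        for name, grams in r.items:
            diary_rows.append(
                {
                    "patient_id": r.patient_id,
                    "timestamp": r.diary_time.strftime("%Y-%m-%dT%H:%M:%S"),
                    "meal_type": r.meal_type,
                    "food_name": name,
                    "grams": grams,
                }
            )
    paths["diary"] = outdir / "diary.csv"
    pd.DataFrame(diary_rows).to_csv(paths["diary"], index=False)

    paths["patients"] = outdir / "patients.csv"
    cohort.profiles.to_csv(paths["patients"], index=False)

    paths["food_table"] = outdir / "food_table.csv"
    cohort.food_db.to_frame().to_csv(paths["food_table"], index=False)

    paths["ground_truth"] = outdir / "ground_truth.csv"
    cohort.truth.meals.assign(
        meal_start=lambda d: d["meal_start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    ).to_csv(paths["ground_truth"], index=False)
    return paths
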