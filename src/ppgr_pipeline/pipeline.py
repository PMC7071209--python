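"""End-to-end orchestration of the PPGR prediction pipeline.

Two layers:

* an in-memory layer (:func:`process_cohort`, :func:`run_study`) used by the
  test-suite and the acceptance script — typed objects in, results out;
* a CSV-artifact layer (:func:`run_stage`) behind the command-line
  interface: each stage reads its predecessors' files from the working
  directory, writes its own artifacts plus a JSON log of counts and
  configuration, and fails with a clear message when a predecessor artifact
  is missing.  Stage-wise runs and a single ``all`` run produce identical
  artifacts.

Every reported count reconciles: matched = kept + Σ exclusions, and the
design matrix has exactly the rows the record filter kept.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cgm_io, foodlib, ppgr
from .cgm_io import CGMSeries, MatchedMeal, MealRecord, ProtocolEntry
from .features import (
    DesignMatrix,
    MEAL_FEATURES,
    assemble_design,
    impute_group_mean,
    load_bundled_feature_spec,
    load_feature_spec,
    one_hot,
    restrict_arm,
)
from .foodlib import FoodDB
from .models import (
    FittedModel,
    add_polynomial,
    grouped_split,
    run_comparison,
    stepwise_forward,
)
from .synthetic_data import Cohort, GeneratorConfig, gen_cohort, write_cohort

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "process_cohort",
    "run_study",
    "run_stage",
    "STAGES",
]

STAGES = ("simulate", "ingest", "match", "ppgr", "features", "fit", "evaluate", "report", "all")


@dataclass
class PipelineConfig:
    """Paths, thresholds and modeling settings; thresholds default to the
    study protocol's values and are all overridable."""

    workdir: str = "."
    cgm_path: str | None = None
    diary_path: str | None = None
    protocol_path: str | None = None
    food_table_path: str | None = None
    recipes_path: str | None = None
    patients_path: str | None = None
    feature_spec_path: str | None = None
    # matching / exclusion thresholds
    max_gap_min: float = 60.0
    late_threshold: float = 1.0          # mmol/L rise over the prior hour
    falling_threshold: float = 0.5       # mmol/L margins around the start
    interference_window_min: float = 60.0
    # record filters
    small_ppgr_rate: float = 0.3         # mmol/L/h
    carb_threshold: float = 40.0         # g
    # modeling
    arms: tuple[str, ...] = ("with_gigl", "without_gigl")
    methods: tuple[str, ...] = ("stepwise", "omp")
    outcomes: tuple[str, ...] = ("iauc120",)
    polynomial: bool = False
    split_fraction: float = 0.7
    k_folds: int = 10
    prefilter_threshold: float = 0.1
    alpha_enter: float = 0.05
    seed: int = 0
    simulate_seed: int = 0
    #: Overrides applied to GeneratorConfig by the simulate stage
    generator_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("arms", "methods", "outcomes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    _PATH_FIELDS = (
        "workdir", "cgm_path", "diary_path", "protocol_path", "food_table_path",
        "recipes_path", "patients_path", "feature_spec_path",
    )

    def hash(self) -> str:
        """Hash of the scientific settings (thresholds, seeds, model grid);
        file locations are excluded so relocated runs compare equal."""
        d = dataclasses.asdict(self)
        for k in self._PATH_FIELDS:
            d.pop(k, None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Products of the data-processing stages for one cohort."""

    matched: list[MatchedMeal]
    match_counts: dict
    exclusion_counts: dict
    misreporters: list[str]
    records: pd.DataFrame          # kept meals with composition + outcomes
    filter_report: dict
    design: DesignMatrix           # with_gigl arm; restrict for the other
    counts: dict


def _compose_and_extract(
    kept: Sequence[MatchedMeal],
    series_by_patient: dict[str, CGMSeries],
    db: FoodDB,
) -> tuple[pd.DataFrame, int]:
    """Meal composition + PPGR outcomes for kept matched meals.  Meals whose
    3-h window the trace cannot support are dropped and counted."""
    rows = []
    dropped = 0
    for m in kept:
        series = series_by_patient[m.patient_id]
        t = series.minutes(m.meal_start)
        comp = foodlib.meal_composition(list(m.meal_record.items), db)
        try:
            rec = ppgr.extract_ppgr(series, t)
        except (cgm_io.CGMGapError, cgm_io.OutOfRangeError):
            dropped += 1
            continue
        rows.append(
            {
                "patient_id": m.patient_id,
                "meal_start": m.meal_start,
                "meal_type": m.meal_record.meal_type,
                "gi": comp.gi,
                "gl": comp.gl,
                "carbo": comp.carbo,
                "prot": comp.prot,
                "fat": comp.fat,
                "kcal": comp.kcal,
                "water": comp.water,
                "starch": comp.starch,
                "fiber": comp.fiber,
                "gi_defined": comp.gi_defined,
                **rec.as_dict(),
            }
        )
    return pd.DataFrame(rows), dropped


def process_cohort(
    cohort: Cohort,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run matching, exclusion, misreporting and record filters, outcome
    extraction and design assembly on an in-memory cohort."""
    cfg = config or PipelineConfig()
    by_patient_diary: dict[str, list[MealRecord]] = {}
    for r in cohort.diary:
        by_patient_diary.setdefault(r.patient_id, []).append(r)
    by_patient_protocol: dict[str, list[ProtocolEntry]] = {}
    for e in cohort.protocol:
        by_patient_protocol.setdefault(e.patient_id, []).append(e)

    matched_all: list[MatchedMeal] = []
    unmatched = 0
    excl_counts: dict[str, int] = {}
    for pid, entries in by_patient_protocol.items():
        diary = by_patient_diary.get(pid, [])
        if not diary:
            unmatched += len(entries)
            continue
        matched, n_un = cgm_io.match_protocol_to_diary(entries, diary, cfg.max_gap_min)
        unmatched += n_un
        annotated, counts = cgm_io.apply_exclusion_rules(
            matched,
            cohort.cgm[pid],
            late_threshold=cfg.late_threshold,
            falling_threshold=cfg.falling_threshold,
            interference_window_min=cfg.interference_window_min,
        )
        matched_all.extend(annotated)
        for k, v in counts.items():
            excl_counts[k] = excl_counts.get(k, 0) + v

    misreporters = [
        pid
        for pid, diary in sorted(by_patient_diary.items())
        if ppgr.detect_misreporting(diary)[0]
    ]
    mis_set = set(misreporters)
    kept_meals = [m for m in matched_all if m.exclusion is None and m.patient_id not in mis_set]
    n_mis_records = sum(
        1 for m in matched_all if m.exclusion is None and m.patient_id in mis_set
    )

    records, n_trace_dropped = _compose_and_extract(kept_meals, cohort.cgm, cohort.food_db)
    records, filter_report = ppgr.filter_records(
        records,
        carb_threshold=cfg.carb_threshold,
        rate_threshold=cfg.small_ppgr_rate,
    )

    spec = (
        load_feature_spec(cfg.feature_spec_path)
        if cfg.feature_spec_path
        else load_bundled_feature_spec()
    )
    profiles = impute_group_mean(cohort.profiles, spec)
    encoded = one_hot(profiles, spec)
    design = assemble_design(records, encoded, arm="with_gigl")

    counts = {
        "protocol_entries": sum(len(v) for v in by_patient_protocol.values()),
        "unmatched_protocol": unmatched,
        "matched": len(matched_all),
        **{f"excluded_{k}": v for k, v in excl_counts.items() if k != "kept"},
        "kept_after_exclusions": excl_counts.get("kept", 0),
        "misreporter_patients": len(misreporters),
        "misreporter_records": n_mis_records,
        "trace_insufficient": n_trace_dropped,
        **{f"filtered_{k}": v for k, v in filter_report.items() if k not in ("input", "kept")},
        "final_records": len(records),
    }
    return PipelineResult(
        matched=matched_all,
        match_counts={"matched": len(matched_all), "unmatched": unmatched},
        exclusion_counts=excl_counts,
        misreporters=misreporters,
        records=records,
        filter_report=filter_report,
        design=design,
        counts=counts,
    )


def run_study(
    gen_config: GeneratorConfig,
    pipeline_config: PipelineConfig | None = None,
) -> tuple[PipelineResult, pd.DataFrame, dict[tuple, FittedModel]]:
    """Simulate a cohort, process it, and fit the configured model grid."""
    cfg = pipeline_config or PipelineConfig(seed=gen_config.seed)
    cohort = gen_cohort(gen_config)
    result = process_cohort(cohort, cfg)
    table, fitted = run_comparison(
        result.design,
        outcomes=cfg.outcomes,
        arms=cfg.arms,
        methods=cfg.methods,
        polynomial=cfg.polynomial,
        split_fraction=cfg.split_fraction,
        k=cfg.k_folds,
        seed=cfg.seed,
        alpha_enter=cfg.alpha_enter,
        prefilter_threshold=cfg.prefilter_threshold,
    )
    return result, table, fitted


# ---------------------------------------------------------------------------
# CSV-artifact stages (CLI layer)
# ---------------------------------------------------------------------------

def _need(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}; run the '{producer}' stage first"
        )
    return path


def _write_log(workdir: Path, stage: str, payload: dict, cfg: PipelineConfig) -> None:
    log = {"stage": stage, "config_hash": cfg.hash(), **payload}
    with open(workdir / f"log_{stage}.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=str)


def _load_inputs(cfg: PipelineConfig, workdir: Path):
    cgm_path = Path(cfg.cgm_path or _need(workdir / "cgm.csv", "simulate"))
    diary_path = Path(cfg.diary_path or _need(workdir / "diary.csv", "simulate"))
    protocol_path = Path(cfg.protocol_path or _need(workdir / "protocol.csv", "simulate"))
    food_path = Path(cfg.food_table_path or _need(workdir / "food_table.csv", "simulate"))
    patients_path = Path(cfg.patients_path or _need(workdir / "patients.csv", "simulate"))
    series, cgm_bad = cgm_io.read_cgm(cgm_path)
    diary, diary_bad = cgm_io.read_diary(diary_path)
    protocol = cgm_io.read_protocol(protocol_path)
    foods = foodlib.read_food_table(food_path)
    recipes = []
    recipes_path = Path(cfg.recipes_path) if cfg.recipes_path else workdir / "recipes.csv"
    db = FoodDB(foods)
    if recipes_path.exists():
        recipes = foodlib.read_recipes(recipes_path, db)
        db = FoodDB(foods, recipes)
    profiles = pd.read_csv(patients_path)
    return series, diary, protocol, db, profiles, {"cgm_bad_rows": len(cgm_bad), "diary_bad_rows": len(diary_bad)}


def run_stage(stage: str, cfg: PipelineConfig) -> dict:
    """Execute one pipeline stage (or ``all``) in ``cfg.workdir``."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    workdir = Path(cfg.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if stage == "all":
        out = {}
        for s in ("simulate", "ingest", "match", "ppgr", "features", "fit", "evaluate", "report"):
            out[s] = run_stage(s, cfg)
        return out

    if stage == "simulate":
        overrides = dict(cfg.generator_overrides)
        if isinstance(overrides.get("beta"), dict):
            overrides["beta"] = tuple(overrides["beta"].items())
        if isinstance(overrides.get("items_per_meal"), list):
            overrides["items_per_meal"] = tuple(overrides["items_per_meal"])
        gen_cfg = GeneratorConfig(seed=cfg.simulate_seed, **overrides)
        cohort = gen_cohort(gen_cfg)
        write_cohort(cohort, workdir)
        payload = {
            "patients": gen_cfg.n_patients,
            "diary_records": len(cohort.diary),
            "protocol_entries": len(cohort.protocol),
            "seed": gen_cfg.seed,
        }
        _write_log(workdir, stage, payload, cfg)
        return payload

    series, diary, protocol, db, profiles, io_counts = _load_inputs(cfg, workdir)
    cohort = Cohort(
        config=None, food_db=db, profiles=profiles, diary=diary,
        protocol=protocol, cgm=series, truth=None, misreporters=[],
    )

    if stage == "ingest":
        payload = {
            "patients_cgm": len(series),
            "diary_records": len(diary),
            "protocol_entries": len(protocol),
            "foods": len(db),
            **io_counts,
        }
        _write_log(workdir, stage, payload, cfg)
        return payload

    result = process_cohort(cohort, cfg)

    if stage == "match":
        report = cgm_io.exclusion_report(result.matched)
        report.to_csv(workdir / "exclusion_report.csv", index=False)
        payload = {**result.match_counts, **result.exclusion_counts}
        _write_log(workdir, stage, payload, cfg)
        return payload

    if stage == "ppgr":
        out = result.records.copy()
        out["meal_start"] = pd.to_datetime(out["meal_start"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(workdir / "records.csv", index=False, float_format="%.6g")
        payload = {k: v for k, v in result.counts.items()}
        _write_log(workdir, stage, payload, cfg)
        return payload

    if stage == "features":
        for arm in cfg.arms:
            dm = restrict_arm(result.design, arm)
            frame = dm.frame.copy()
            frame["meal_start"] = pd.to_datetime(frame["meal_start"]).dt.strftime(
                "%Y-%m-%dT%H:%M:%S"
            )
            frame.to_csv(workdir / f"design_{arm}.csv", index=False, float_format="%.8g")
            dm.column_metadata().to_csv(
                workdir / f"design_{arm}_columns.csv", index=False
            )
        payload = {
            "rows": len(result.design.frame),
            "features_with_gigl": len(result.design.feature_cols),
        }
        _write_log(workdir, stage, payload, cfg)
        return payload

    # fit / evaluate / report all need the comparison
    table, fitted = run_comparison(
        result.design,
        outcomes=cfg.outcomes,
        arms=cfg.arms,
        methods=cfg.methods,
        polynomial=cfg.polynomial,
        split_fraction=cfg.split_fraction,
        k=cfg.k_folds,
        seed=cfg.seed,
        alpha_enter=cfg.alpha_enter,
        prefilter_threshold=cfg.prefilter_threshold,
    )

    if stage == "fit":
        models_dir = workdir / "models"
        models_dir.mkdir(exist_ok=True)
        for (outcome, arm, method), model in fitted.items():
            name = f"{outcome}_{arm}_{method}{'_poly' if cfg.polynomial else ''}.json"
            (models_dir / name).write_text(model.to_text())
        payload = {"models": len(fitted)}
        _write_log(workdir, stage, payload, cfg)
        return payload

    if stage == "evaluate":
        table.to_csv(workdir / "evaluation.csv", index=False, float_format="%.6g")
        payload = {"rows": len(table)}
        _write_log(workdir, stage, payload, cfg)
        return payload

    if stage == "report":
        _write_report(workdir, cfg, result, table, fitted)
        payload = {"tables": 5}
        _write_log(workdir, stage, payload, cfg)
        return payload

    raise AssertionError("unreachable")


def _write_report(
    workdir: Path,
    cfg: PipelineConfig,
    result: PipelineResult,
    table: pd.DataFrame,
    fitted: dict[tuple, FittedModel],
) -> None:
    """Analysis-report tables: meal-feature/PPGR correlations, the stepwise
    trace, the final model comparison, test-set results, and the
    predicted-vs-observed scatter for the primary outcome."""
    design = result.design
    # correlations between meal features and the primary outcomes
    cols = [*MEAL_FEATURES, "iauc120", "bgrise"]
    corr = design.frame[cols].corr(method="pearson")
    corr.to_csv(workdir / "table_correlations.csv", float_format="%.3f")

    # stepwise trace for the primary outcome, with-GI/GL arm
    outcome = cfg.outcomes[0]
    trace, _ = stepwise_forward(
        design.X, design.y(outcome).to_numpy(), alpha_enter=cfg.alpha_enter
    )
    trace.to_frame().to_csv(workdir / "table_stepwise_trace.csv", index=False,
                            float_format="%.4g")

    table.to_csv(workdir / "table_model_comparison.csv", index=False, float_format="%.6g")

    # predicted-vs-observed scatter for the primary outcome on held-out patients
    key = next(
        (k for k in fitted if k[0] == outcome and k[2] != "stepwise"), None
    )
    if key is not None:
        model = fitted[key]
        dm = restrict_arm(design, key[1])
        if cfg.polynomial:
            dm = restrict_arm(add_polynomial(design), key[1])
        tr, te = grouped_split(dm.groups, fraction=cfg.split_fraction, seed=cfg.seed)
        X_te = dm.X.iloc[te]
        y_te = dm.y(outcome).iloc[te].to_numpy()
        pred = model.predict(X_te)
        pd.DataFrame(
            {
                "patient_id": dm.groups.iloc[te].to_numpy(),
                "observed": y_te,
                "predicted": pred,
                "abs_error_gt_1": (np.abs(y_te - pred) > 1.0).astype(int),
            }
        ).to_csv(workdir / "table_scatter.csv", index=False, float_format="%.4f")
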