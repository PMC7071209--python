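"""Per-meal design matrix assembly.

Each kept meal becomes one row: meal composition (including GI and GL), the
pre-meal glucose BG0 as a context feature, and the patient's profile —
anthropometrics, obstetric history, OGTT/biochemistry, and ordinal
lifestyle-questionnaire items (three levels 0/1/2, assessed before and during
pregnancy).  Missing patient values are imputed by the column mean within the
patient's group (GDM or control); non-ordered categorical and ordinal
questionnaire variables are dummy-encoded with columns named
``variable_value`` (e.g. ``fruits1_2``).

The feature roster is declared in a small YAML spec (name, block, type,
levels) rather than hard-coded, so cohorts with different questionnaires can
reuse the pipeline; a fixture spec emulating the study's structure ships with
the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ppgr import OUTCOME_COLUMNS

__all__ = [
    "FeatureVar",
    "FeatureSpec",
    "DesignMatrix",
    "MEAL_FEATURES",
    "GIGL_FEATURES",
    "PREDICTED_OUTCOMES",
    "load_feature_spec",
    "load_bundled_feature_spec",
    "impute_group_mean",
    "one_hot",
    "assemble_design",
    "restrict_arm",
]

#: Meal-composition regressors, in fixed column order.
MEAL_FEATURES = ("gi", "gl", "carbo", "prot", "fat", "kcal", "water", "starch", "fiber")
#: The pair removed in the "without GI/GL" modeling arm.
GIGL_FEATURES = ("gi", "gl")
#: The seven predicted PPGR outcomes (bg0 is a regressor, not an outcome).
PREDICTED_OUTCOMES = tuple(c for c in OUTCOME_COLUMNS if c != "bg0")

VAR_TYPES = ("numeric", "ordinal", "binary", "categorical")


@dataclass(frozen=True)
class FeatureVar:
    name: str
    block: str
    type: str
    levels: tuple | None = None

    def __post_init__(self) -> None:
        if self.type not in VAR_TYPES:
            raise ValueError(f"{self.name}: unknown type {self.type!r}")
        if self.type in ("ordinal", "categorical") and not self.levels:
            raise ValueError(f"{self.name}: {self.type} variable needs declared levels")


@dataclass(frozen=True)
class FeatureSpec:
    variables: tuple[FeatureVar, ...]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def by_type(self, *types: str) -> list[FeatureVar]:
        return [v for v in self.variables if v.type in types]

    def __len__(self) -> int:
        return len(self.variables)


def load_feature_spec(path: str | Path) -> FeatureSpec:
    """Read a feature-spec YAML: a list of {name, block, type, levels} entries."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    variables = tuple(
        FeatureVar(
            name=str(e["name"]),
            block=str(e.get("block", "patient")),
            type=str(e["type"]),
            levels=tuple(e["levels"]) if e.get("levels") is not None else None,
        )
        for e in raw["variables"]
    )
    names = [v.name for v in variables]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable names in feature spec")
    return FeatureSpec(variables)


def load_bundled_feature_spec() -> FeatureSpec:
    from importlib.resources import files

    return load_feature_spec(str(files("ppgr_pipeline") / "data" / "feature_spec.yaml"))


def impute_group_mean(profiles: pd.DataFrame, spec: FeatureSpec) -> pd.DataFrame:
    """Replace missing numeric/ordinal values by the within-group column mean.

    ``profiles`` must carry a non-missing ``group`` column.  A column that is
    entirely missing within one group falls back to the overall column mean
    (with a warning).  Imputed ordinal values are rounded to the nearest
    declared level so they remain encodable.  Input is returned unchanged
    (copy) when nothing is missing.
    """
    if "group" not in profiles.columns or profiles["group"].isna().any():
        raise ValueError("profiles need a complete 'group' column")
    out = profiles.copy()
    for var in spec.by_type("numeric", "ordinal"):
        col = var.name
        if col not in out.columns or not out[col].isna().any():
            continue
        group_means = out.groupby("group")[col].transform("mean")
        if group_means.isna().any():
            warnings.warn(
                f"{col}: all values missing within a group; falling back to overall mean"
            )
            group_means = group_means.fillna(out[col].mean())
        filled = out[col].fillna(group_means)
        if var.type == "ordinal":
            levels = np.asarray(var.levels, dtype=float)
            missing = out[col].isna()
            snapped = levels[
                np.abs(filled[missing].to_numpy()[:, None] - levels[None, :]).argmin(axis=1)
            ]
            filled.loc[missing] = snapped
        out[col] = filled
    return out


def one_hot(profiles: pd.DataFrame, spec: FeatureSpec) -> pd.DataFrame:
    """Dummy-encode ordinal and categorical variables as 0/1 ``variable_value``
    columns (one per observed level); numeric and binary variables pass
    through.  A value outside the declared level set is an error naming the
    variable and the value.
    """
    encode = {v.name: v for v in spec.by_type("ordinal", "categorical")}
    missing = [name for name in encode if name not in profiles.columns]
    if missing:
        raise ValueError(f"profiles lack declared variables {missing}")
    pieces: dict[str, pd.Series] = {}
    for col in profiles.columns:
        if col not in encode:
            pieces[col] = profiles[col]
            continue
        var = encode[col]
        values = profiles[col]
        declared = set(var.levels)
        bad = values.dropna().loc[~values.dropna().isin(declared)]
        if len(bad):
            raise ValueError(
                f"{col}: value {bad.iloc[0]!r} outside declared levels {sorted(declared)}"
            )
        for lev in sorted(values.dropna().unique().tolist()):
            pieces[_dummy_name(col, lev)] = (values == lev).astype(int)
    return pd.DataFrame(pieces, index=profiles.index)


def _dummy_name(var: str, level) -> str:
    if isinstance(level, float) and level.is_integer():
        level = int(level)
    return f"{var}_{level}"


@dataclass
class DesignMatrix:
    """One row per kept meal: named feature columns, the seven PPGR outcome
    columns, and ``patient_id`` for grouped splitting."""

    frame: pd.DataFrame
    feature_cols: list[str]
    outcome_cols: list[str]
    meal_cols: list[str]
    arm: str = "with_gigl"

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate column names in design matrix")
        missing = [c for c in [*self.feature_cols, *self.outcome_cols] if c not in cols]
        if missing:
            raise ValueError(f"design frame lacks columns {missing}")
        if self.frame[self.feature_cols].isna().any().any():
            raise ValueError("design features contain missing values after imputation")

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[self.feature_cols]

    def y(self, outcome: str) -> pd.Series:
        return self.frame[outcome]

    @property
    def groups(self) -> pd.Series:
        return self.frame["patient_id"]

    def column_metadata(self) -> pd.DataFrame:
        role = {c: "feature" for c in self.feature_cols}
        role.update({c: "outcome" for c in self.outcome_cols})
        rows = [
            {
                "column": c,
                "role": role.get(c, "key"),
                "block": "meal" if c in self.meal_cols else "",
            }
            for c in self.frame.columns
        ]
        return pd.DataFrame(rows)


def assemble_design(
    records: pd.DataFrame,
    encoded_profiles: pd.DataFrame,
    *,
    arm: str = "with_gigl",
) -> DesignMatrix:
    """Join kept meal records with encoded patient profiles.

    ``records`` carries ``patient_id``, ``meal_start``, the meal composition
    columns, and the eight extracted outcomes (bg0 becomes the pre-meal
    context feature).  ``encoded_profiles`` is the imputed, dummy-encoded
    patient table indexed by ``patient_id``; a meal whose patient has no
    profile is a hard error.  ``arm`` is ``with_gigl`` or ``without_gigl``.
    """
    prof = encoded_profiles.copy()
    if "patient_id" in prof.columns:
        prof = prof.set_index("patient_id")
    prof = prof.drop(columns=[c for c in ("group",) if c in prof.columns])
    orphans = set(records["patient_id"]) - set(prof.index)
    if orphans:
        raise ValueError(f"meals reference patients without profiles: {sorted(orphans)[:5]}")
    joined = records.merge(
        prof, left_on="patient_id", right_index=True, how="left", validate="many_to_one"
    )
    patient_cols = [c for c in prof.columns]
    feature_cols = [*MEAL_FEATURES, "bg0", *patient_cols]
    outcome_cols = list(PREDICTED_OUTCOMES)
    keys = ["patient_id", "meal_start"]
    frame = joined[[*keys, *feature_cols, *outcome_cols]].reset_index(drop=True)
    design = DesignMatrix(
        frame=frame,
        feature_cols=feature_cols,
        outcome_cols=outcome_cols,
        meal_cols=list(MEAL_FEATURES),
        arm="with_gigl",
    )
    if arm == "without_gigl":
        design = restrict_arm(design, "without_gigl")
    elif arm != "with_gigl":
        raise ValueError(f"unknown arm {arm!r}")
    return design


def _is_gigl_derived(col: str) -> bool:
    """True for gi/gl and their polynomial children ('gi^2', 'carbo × gl', ...)."""
    base = col[:-2] if col.endswith("^2") else col
    parts = base.split(" × ")
    return any(p in GIGL_FEATURES for p in parts)


def restrict_arm(design: DesignMatrix, arm: str) -> DesignMatrix:
    """The 'without GI/GL' arm: identical design minus gi, gl and any
    polynomial features derived from them."""
    if arm == "with_gigl":
        return design
    if arm != "without_gigl":
        raise ValueError(f"unknown arm {arm!r}")
    dropped = [c for c in design.feature_cols if _is_gigl_derived(c)]
    return DesignMatrix(
        frame=design.frame.drop(columns=dropped),
        feature_cols=[c for c in design.feature_cols if c not in dropped],
        outcome_cols=list(design.outcome_cols),
        meal_cols=[c for c in design.meal_cols if c not in dropped],
        arm="without_gigl",
    )
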