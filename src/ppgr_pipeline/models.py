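"""PPGR prediction models.

Two modeling tracks:

1. **Forward stepwise linear regression** fitted on the complete record set —
   the descriptive track.  At each step the variable giving the largest gain
   in R² enters; entry stops when the entering variable's partial-F p-value
   exceeds ``alpha_enter``.  The trace records R, R², adjusted R² and the
   standard error of the estimate at every step.

2. **Regularized regression evaluated on held-out patients** — the predictive
   track.  Features are prefiltered by Spearman correlation with the outcome
   (|r| > 0.1 on the training data only), columns are normalized by
   subtracting the mean and dividing by the l2 norm of the centered column,
   and a sparse/penalized linear model (orthogonal matching pursuit,
   LARS-lasso, lasso, ridge or elastic-net) is selected by exhaustive grid
   search under grouped k-fold cross-validation scored by the coefficient of
   determination.  All splits are grouped by patient so no patient ever
   appears on both sides of a split.

Prediction quality is summarized by the Pearson correlation R between
predicted and observed responses, the mean absolute error, and r².
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import (
    ElasticNet,
    Lasso,
    LassoLars,
    OrthogonalMatchingPursuit,
    Ridge,
)

from .features import DesignMatrix

__all__ = [
    "METHODS",
    "StepwiseStep",
    "StepwiseTrace",
    "FittedModel",
    "EvalReport",
    "stepwise_forward",
    "spearman_prefilter",
    "normalize_columns",
    "apply_normalization",
    "grouped_split",
    "grouped_kfold",
    "default_grid",
    "fit_regularized",
    "add_polynomial",
    "evaluate",
    "run_comparison",
]

METHODS = ("stepwise", "omp", "lars_lasso", "lasso", "ridge", "elastic_net")


# ---------------------------------------------------------------------------
# Stepwise track
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepwiseStep:
    variable: str
    r: float
    r2: float
    adj_r2: float
    se: float


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"step": i + 1, "variable": s.variable, "r": s.r, "r2": s.r2,
                 "adj_r2": s.adj_r2, "se": s.se}
                for i, s in enumerate(self.steps)
            ]
        )

    @property
    def entered(self) -> list[str]:
        return [s.variable for s in self.steps]


def stepwise_forward(
    X: pd.DataFrame,
    y: Sequence[float],
    *,
    alpha_enter: float = 0.05,
    max_steps: int | None = None,
) -> tuple[StepwiseTrace, "FittedModel"]:
    """Greedy forward variable selection for ordinary least squares.

    Each step enters the candidate maximizing R² (ties broken by column
    order); entry stops when the best candidate's partial-F p-value exceeds
    ``alpha_enter`` or no candidate remains.  Rank-deficient candidates are
    skipped with a warning.  Computed via Gram matrices, so the trace is
    invariant under row permutations.
    """
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n < 3:
        raise ValueError("need at least 3 rows")
    cols = list(X.columns)
    Z = np.column_stack([np.ones(n), Xv])  # intercept first
    G = Z.T @ Z
    b = Z.T @ yv
    yy = float(yv @ yv)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss == 0:
        raise ValueError("outcome is constant")

    def rss_of(active: list[int]) -> tuple[float, np.ndarray] | None:
        Gs = G[np.ix_(active, active)]
        bs = b[active]
        try:
            coef = np.linalg.solve(Gs, bs)
        except np.linalg.LinAlgError:
            return None
        rss = yy - float(bs @ coef)
        return max(rss, 0.0), coef

    active = [0]
    remaining = list(range(1, p + 1))
    rss_cur, coef_cur = rss_of(active)
    steps: list[StepwiseStep] = []
    limit = max_steps if max_steps is not None else p
    while remaining and len(steps) < limit and len(active) + 1 < n:
        best = None
        for j in remaining:
            res = rss_of(active + [j])
            if res is None:
                continue
            rss_j, coef_j = res
            if best is None or rss_j < best[0] - 1e-12:
                best = (rss_j, j, coef_j)
        if best is None:
            warnings.warn("all remaining candidates are rank-deficient")
            break
        rss_new, j, coef_new = best
        k_new = len(active)  # number of slope terms after entry
        dof = n - k_new - 1
        if dof <= 0:
            break
        if rss_new <= 0:
            p_value = 0.0
        else:
            f_stat = (rss_cur - rss_new) / (rss_new / dof)
            p_value = float(stats.f.sf(max(f_stat, 0.0), 1, dof))
        if p_value > alpha_enter:
            break
        active.append(j)
        remaining.remove(j)
        rss_cur, coef_cur = rss_new, coef_new
        r2 = 1.0 - rss_cur / tss
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k_new - 1)
        se = float(np.sqrt(rss_cur / (n - k_new - 1)))
        steps.append(
            StepwiseStep(cols[j - 1], r=float(np.sqrt(max(r2, 0.0))), r2=r2, adj_r2=adj, se=se)
        )
    selected = [cols[j - 1] for j in active[1:]]
    model = FittedModel(
        outcome="",
        arm="",
        method="stepwise",
        columns=selected,
        coef={c: float(v) for c, v in zip(selected, coef_cur[1:])},
        intercept=float(coef_cur[0]),
        normalization=None,
        hyperparameters={"alpha_enter": alpha_enter},
        polynomial=False,
    )
    return StepwiseTrace(steps), model


# ---------------------------------------------------------------------------
# Regularized track building blocks
# ---------------------------------------------------------------------------

def spearman_prefilter(
    X: pd.DataFrame, y: Sequence[float], threshold: float = 0.1
) -> list[str]:
    """Columns whose |Spearman r| with the outcome exceeds ``threshold``.

    Computed on whatever rows are passed in — callers must pass training data
    only.  Constant columns are dropped regardless of threshold.
    """
    yv = np.asarray(y, dtype=float)
    ry = stats.rankdata(yv)
    ry = ry - ry.mean()
    ny = np.sqrt(float(ry @ ry))
    keep = []
    for col in X.columns:
        xv = X[col].to_numpy(dtype=float)
        if np.all(xv == xv[0]):
            continue
        rx = stats.rankdata(xv)
        rx = rx - rx.mean()
        r = float(rx @ ry) / (np.sqrt(float(rx @ rx)) * ny)
        if abs(r) > threshold:
            keep.append(col)
    return keep


def normalize_columns(
    X: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]], list[str]]:
    """Center each column by its mean and divide by the centered l2 norm.

    Returns the normalized frame, the per-column (mean, norm) constants to be
    reapplied verbatim to validation/test data, and the names of zero-norm
    (constant) columns, which are dropped with a warning.
    """
    constants: dict[str, tuple[float, float]] = {}
    dropped: list[str] = []
    data = {}
    for col in X.columns:
        xv = X[col].to_numpy(dtype=float)
        mean = float(xv.mean())
        centered = xv - mean
        norm = float(np.sqrt(centered @ centered))
        if norm == 0.0:
            dropped.append(col)
            continue
        constants[col] = (mean, norm)
        data[col] = centered / norm
    if dropped:
        warnings.warn(f"dropping constant columns: {dropped[:5]}")
    return pd.DataFrame(data, index=X.index), constants, dropped


def apply_normalization(
    X: pd.DataFrame, constants: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    """Apply stored (mean, norm) constants to new data, column order fixed by
    ``constants``."""
    data = {
        col: (X[col].to_numpy(dtype=float) - mean) / norm
        for col, (mean, norm) in constants.items()
    }
    return pd.DataFrame(data, index=X.index)


def grouped_split(
    groups: Sequence, fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level train/test partition holding ≈ ``fraction`` of rows in
    the training side.  Whole patients go to one side only; deterministic
    given ``seed``.  Returns positional row indices (train, test)."""
    g = np.asarray(groups)
    patients = pd.unique(g)
    if len(patients) < 2:
        raise ValueError("cannot split a single patient across train and test")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    target = fraction * len(g)
    counts = pd.Series(g).value_counts()
    train_patients: list = []
    total = 0
    for idx in order:
        pid = patients[idx]
        c = int(counts[pid])
        if total >= target:
            break
        # include the boundary patient only if that lands closer to target
        if total + c - target > target - total and total > 0:
            break
        train_patients.append(pid)
        total += c
    if len(train_patients) == len(patients):
        train_patients = train_patients[:-1]
    train_set = set(train_patients)
    mask = np.fromiter((x in train_set for x in g), dtype=bool, count=len(g))
    return np.flatnonzero(mask), np.flatnonzero(~mask)


def grouped_kfold(
    groups: Sequence, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k folds partitioning patients (not rows); each validation fold contains
    only patients absent from its training folds.  Patients are shuffled by
    ``seed`` and assigned to the currently smallest fold (by row count) for
    balance."""
    g = np.asarray(groups)
    patients = pd.unique(g)
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients for {k}-fold grouped CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    counts = pd.Series(g).value_counts()
    fold_of: dict = {}
    fold_sizes = np.zeros(k, dtype=int)
    for idx in order:
        pid = patients[idx]
        f = int(np.argmin(fold_sizes))
        fold_of[pid] = f
        fold_sizes[f] += int(counts[pid])
    assignment = np.fromiter((fold_of[x] for x in g), dtype=int, count=len(g))
    folds = []
    for f in range(k):
        val = np.flatnonzero(assignment == f)
        train = np.flatnonzero(assignment != f)
        folds.append((train, val))
    return folds


def default_grid(method: str) -> list:
    """Hyperparameter grids: support size 1–30 for OMP, a 20-point log-spaced
    alpha grid 1e-4…1e1 for the penalized methods (× three l1 ratios for
    elastic-net)."""
    if method == "omp":
        return list(range(1, 31))
    alphas = np.logspace(-4, 1, 20)
    if method == "elastic_net":
        return [(float(a), l1) for a in alphas for l1 in (0.1, 0.5, 0.9)]
    return [float(a) for a in alphas]


def _make_estimator(method: str, param):
    if method == "omp":
        return OrthogonalMatchingPursuit(n_nonzero_coefs=int(param))
    if method == "lars_lasso":
        return LassoLars(alpha=float(param))
    if method == "lasso":
        return Lasso(alpha=float(param), max_iter=5000)
    if method == "ridge":
        return Ridge(alpha=float(param))
    if method == "elastic_net":
        alpha, l1 = param
        return ElasticNet(alpha=alpha, l1_ratio=l1, max_iter=5000)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Fitted model container
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A trained linear PPGR model with everything needed for prediction-time
    reuse: selected columns, coefficients on the normalized scale, and the
    (mean, l2-norm) normalization constants per column."""

    outcome: str
    arm: str
    method: str
    columns: list[str]          # columns with nonzero coefficients
    coef: dict[str, float]      # on the normalized scale when normalization set
    intercept: float
    normalization: dict[str, tuple[float, float]] | None
    hyperparameters: dict
    polynomial: bool = False
    seed: int | None = None
    cv_score: float | None = None

    @property
    def n_coefficients(self) -> int:
        return len(self.columns)

    def coef_original_scale(self) -> dict[str, float]:
        """Coefficients on the raw feature scale (undo the l2 normalization)."""
        if self.normalization is None:
            return dict(self.coef)
        return {c: self.coef[c] / self.normalization[c][1] for c in self.columns}

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        yhat = np.full(len(X), self.intercept, dtype=float)
        for c in self.columns:
            xv = X[c].to_numpy(dtype=float)
            if self.normalization is not None:
                mean, norm = self.normalization[c]
                xv = (xv - mean) / norm
            yhat += self.coef[c] * xv
        return yhat

    def to_text(self) -> str:
        payload = {
            "outcome": self.outcome,
            "arm": self.arm,
            "method": self.method,
            "columns": self.columns,
            "coef": {c: self.coef[c] for c in self.columns},
            "intercept": self.intercept,
            "normalization": (
                None
                if self.normalization is None
                else {c: list(v) for c, v in self.normalization.items()}
            ),
            "hyperparameters": self.hyperparameters,
            "polynomial": self.polynomial,
            "seed": self.seed,
            "cv_score": self.cv_score,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_text(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        norm = d["normalization"]
        if norm is not None:
            norm = {c: (float(m), float(s)) for c, (m, s) in norm.items()}
        hp = d["hyperparameters"]
        return cls(
            outcome=d["outcome"],
            arm=d["arm"],
            method=d["method"],
            columns=list(d["columns"]),
            coef={c: float(v) for c, v in d["coef"].items()},
            intercept=float(d["intercept"]),
            normalization=norm,
            hyperparameters=hp,
            polynomial=bool(d["polynomial"]),
            seed=d["seed"],
            cv_score=d["cv_score"],
        )


def _r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def fit_regularized(
    X: pd.DataFrame,
    y: Sequence[float],
    groups: Sequence,
    *,
    method: str = "omp",
    grid: Sequence | None = None,
    k: int = 10,
    seed: int = 0,
    prefilter_threshold: float = 0.1,
    outcome: str = "",
    arm: str = "",
    polynomial: bool = False,
) -> FittedModel:
    """Grid-searched regularized fit with grouped k-fold cross-validation.

    The Spearman prefilter and the column normalization are refit inside each
    training fold (no information from validation patients leaks into feature
    selection or scaling).  The grid point with the largest mean validation r²
    wins; the final model refits on the full training data.  If every grid
    point scores negative the best is still returned, with a warning.
    """
    if grid is None:
        grid = default_grid(method)
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    yv = np.asarray(y, dtype=float)
    folds = grouped_kfold(groups, k=k, seed=seed)
    scores = np.zeros((len(grid), len(folds)))
    for fi, (tr, va) in enumerate(folds):
        Xtr, ytr = X.iloc[tr], yv[tr]
        Xva, yva = X.iloc[va], yv[va]
        cols = spearman_prefilter(Xtr, ytr, threshold=prefilter_threshold)
        if not cols:
            scores[:, fi] = np.nan
            continue
        Xn, constants, _ = normalize_columns(Xtr[cols])
        Xvn = apply_normalization(Xva, constants)
        p_avail = Xn.shape[1]
        for gi_, param in enumerate(grid):
            eff = min(int(param), p_avail) if method == "omp" else param
            est = _make_estimator(method, eff)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xn.to_numpy(), ytr)
                pred = est.predict(Xvn.to_numpy())
            scores[gi_, fi] = _r2_score(yva, pred)
    mean_scores = np.nanmean(scores, axis=1)
    if np.all(np.isnan(mean_scores)):
        raise ValueError("cross-validation produced no valid scores")
    best_idx = int(np.nanargmax(mean_scores))
    best_param = grid[best_idx]
    best_score = float(mean_scores[best_idx])
    if best_score < 0:
        warnings.warn(f"best CV r² is negative ({best_score:.3f}); returning it anyway")
    cols = spearman_prefilter(X, yv, threshold=prefilter_threshold)
    Xn, constants, _ = normalize_columns(X[cols])
    eff = min(int(best_param), Xn.shape[1]) if method == "omp" else best_param
    est = _make_estimator(method, eff)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Xn.to_numpy(), yv)
    coefs = np.asarray(est.coef_, dtype=float)
    nz = np.flatnonzero(coefs != 0.0)
    sel_cols = [Xn.columns[i] for i in nz]
    return FittedModel(
        outcome=outcome,
        arm=arm,
        method=method,
        columns=sel_cols,
        coef={c: float(coefs[i]) for c, i in zip(sel_cols, nz)},
        intercept=float(est.intercept_),
        normalization={c: constants[c] for c in sel_cols},
        hyperparameters={
            "param": best_param if not isinstance(best_param, tuple) else list(best_param),
            "k": k,
            "prefilter_threshold": prefilter_threshold,
        },
        polynomial=polynomial,
        seed=seed,
        cv_score=best_score,
    )


def add_polynomial(design: DesignMatrix, meal_features: Sequence[str] | None = None) -> DesignMatrix:
    """Degree-2 expansion (squares and pairwise products) of the
    meal-composition block only; new columns named ``a^2`` and ``a × b``."""
    meal = list(meal_features) if meal_features is not None else list(design.meal_cols)
    unknown = [c for c in meal if c not in design.feature_cols]
    if unknown:
        raise ValueError(f"meal features not in design: {unknown}")
    frame = design.frame.copy()
    new_cols = []
    for c in meal:
        name = f"{c}^2"
        frame[name] = frame[c] ** 2
        new_cols.append(name)
    for a, b_ in combinations(meal, 2):
        name = f"{a} × {b_}"
        frame[name] = frame[a] * frame[b_]
        new_cols.append(name)
    return DesignMatrix(
        frame=frame,
        feature_cols=[*design.feature_cols, *new_cols],
        outcome_cols=list(design.outcome_cols),
        meal_cols=list(design.meal_cols),
        arm=design.arm,
    )


@dataclass(frozen=True)
class EvalReport:
    pearson_r: float
    mae: float
    r2: float
    n_test: int
    n_coefficients: int
    frac_abs_error_gt_threshold: float | None = None

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "mae": self.mae,
            "r2": self.r2,
            "n_test": self.n_test,
            "n_coefficients": self.n_coefficients,
            "frac_abs_error_gt_threshold": self.frac_abs_error_gt_threshold,
        }


def evaluate(
    model: FittedModel,
    X: pd.DataFrame,
    y: Sequence[float],
    *,
    abs_error_threshold: float | None = None,
) -> EvalReport:
    """Test-set accuracy: Pearson R, MAE, r², and optionally the fraction of
    predictions off by more than ``abs_error_threshold`` (used with
    1.0 mmol/L·h for iAUC120).  Zero-variance predictions give R = NaN."""
    yv = np.asarray(y, dtype=float)
    pred = model.predict(X)
    if np.std(pred) == 0 or np.std(yv) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(yv, pred).statistic)
    err = np.abs(yv - pred)
    frac = None
    if abs_error_threshold is not None:
        frac = float(np.mean(err > abs_error_threshold))
    return EvalReport(
        pearson_r=r,
        mae=float(err.mean()),
        r2=_r2_score(yv, pred),
        n_test=len(yv),
        n_coefficients=model.n_coefficients,
        frac_abs_error_gt_threshold=frac,
    )


def run_comparison(
    design: DesignMatrix,
    *,
    outcomes: Sequence[str] | None = None,
    arms: Sequence[str] = ("with_gigl", "without_gigl"),
    methods: Sequence[str] = ("stepwise", "omp"),
    polynomial: bool = False,
    split_fraction: float = 0.7,
    k: int = 10,
    seed: int = 0,
    alpha_enter: float = 0.05,
    prefilter_threshold: float = 0.1,
) -> tuple[pd.DataFrame, dict[tuple, FittedModel]]:
    """Fit every outcome × arm × method combination and tabulate accuracy.

    Stepwise models are fitted and scored on the full record set (the
    descriptive track); regularized models are fitted on a grouped 70/30
    training split and scored on the held-out patients.  Returns the table
    and the fitted models keyed by (outcome, arm, method).
    """
    from .features import restrict_arm

    if outcomes is None:
        outcomes = list(design.outcome_cols)
    base = add_polynomial(design) if polynomial else design
    tr_idx, te_idx = grouped_split(base.groups, fraction=split_fraction, seed=seed)
    rows = []
    fitted: dict[tuple, FittedModel] = {}
    for arm in arms:
        dm = restrict_arm(base, arm)
        for outcome in outcomes:
            yv = dm.y(outcome).to_numpy(dtype=float)
            for method in methods:
                if method == "stepwise":
                    trace, model = stepwise_forward(
                        dm.X, yv, alpha_enter=alpha_enter
                    )
                    model.outcome, model.arm, model.polynomial = outcome, arm, polynomial
                    rep = evaluate(model, dm.X, yv)
                    row_eval = {"r": rep.pearson_r, "mae": float("nan"), "n_eval": rep.n_test}
                else:
                    model = fit_regularized(
                        dm.X.iloc[tr_idx],
                        yv[tr_idx],
                        dm.groups.iloc[tr_idx],
                        method=method,
                        k=k,
                        seed=seed,
                        prefilter_threshold=prefilter_threshold,
                        outcome=outcome,
                        arm=arm,
                        polynomial=polynomial,
                    )
                    thresh = 1.0 if outcome == "iauc120" else None
                    rep = evaluate(
                        model,
                        dm.X.iloc[te_idx],
                        yv[te_idx],
                        abs_error_threshold=thresh,
                    )
                    row_eval = {"r": rep.pearson_r, "mae": rep.mae, "n_eval": rep.n_test}
                fitted[(outcome, arm, method)] = model
                rows.append(
                    {
                        "outcome": outcome,
                        "arm": arm,
                        "method": method,
                        "polynomial": polynomial,
                        "n_coefficients": model.n_coefficients,
                        **row_eval,
                        "includes_gigl": any(
                            c in ("gi", "gl") or "gi ×" in c or "× gl" in c
                            or c in ("gi^2", "gl^2")
                            for c in model.columns
                        ),
                    }
                )
    return pd.DataFrame(rows), fitted
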