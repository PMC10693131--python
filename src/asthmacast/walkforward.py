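"""Walk-forward expanding-window cross-validation and model selection.

Fold k trains on calendar years years[0..k+1] and tests on years[k+2]; with
2015-2019 this gives the three splits 2015-16/2017, 2015-17/2018,
2015-18/2019. Within each fold the min-max scaler is fitted on the training
rows only, networks regress on the scaled target, and predictions are
inverse-transformed to counts before scoring. Test windows may draw their
4-week history from the tail of the training period (history is covariates
only, never future information); a leakage audit asserts that no target week
appears in both a fold's training and test sets.

R² is the unclipped 1 - SSE/SST definition (negative when a model does worse
than the evaluated-set mean). Pooled metrics concatenate all folds' test
(resp. training) predictions; per-fold values are also reported.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import fit_gam, fit_glm, fit_tree_ensembles, make_flat_design
from .columns import INPUT_COLUMNS, TARGET_COLUMNS
from .nets import HyperConfig, TrainSpec, build_model, predict as net_predict, train
from .preprocess import ScalerState, make_windows, minmax_apply, minmax_fit, minmax_invert

log = logging.getLogger(__name__)

__all__ = [
    "Fold", "make_folds", "r_squared", "EvalMetrics", "evaluate_network",
    "evaluate_baseline", "grid_search", "select_final", "default_hyper_grid",
    "smoke_hyper_grid", "WalkForwardPredictor",
]

BASELINE_NAMES = ("glm", "gam", "rf", "gbm")
TIME_STEPS = 5


@dataclass(frozen=True)
class Fold:
    train_years: tuple[int, ...]
    test_year: int


def make_folds(years: list[int]) -> list[Fold]:
    """Expanding-window folds: train on years[0..k+1], test on years[k+2]."""
    years = sorted(int(y) for y in years)
    if len(years) < 3:
        raise ValueError("walk-forward validation needs at least 3 years")
    return [
        Fold(train_years=tuple(years[: k + 2]), test_year=years[k + 2])
        for k in range(len(years) - 2)
    ]


def r_squared(observed, predicted) -> float:
    """Unclipped coefficient of determination, 1 - SSE/SST.

    SST uses the mean of the evaluated observed values; the result can be
    negative and is exactly 0 for the constant mean predictor.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-d arrays")
    if len(o) < 2:
        raise ValueError("need at least 2 observations")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    return 1.0 - float(np.sum((o - p) ** 2)) / sst


# ---------------------------------------------------------------------------
# per-fold machinery
# ---------------------------------------------------------------------------


@dataclass
class FoldArtifacts:
    fold: Fold
    scaler: ScalerState
    model: object  # TrainedModel | CountRegression | TreeEnsembles
    train_obs: np.ndarray
    train_pred: np.ndarray
    test_obs: np.ndarray
    test_pred: np.ndarray
    test_week_ids: tuple


@dataclass
class EvalMetrics:
    """Per-fold and pooled train/test MSE and R² for one target."""

    target: str
    per_fold: pd.DataFrame
    pooled: dict
    folds: list[FoldArtifacts] = field(repr=False, default_factory=list)


def _audit_leakage(train_ids: set, test_ids: set, fold: Fold) -> None:
    overlap = train_ids & test_ids
    if overlap:
        raise AssertionError(f"leakage in fold {fold}: overlapping weeks {sorted(overlap)[:5]}")


def _fold_frames(table: pd.DataFrame, fold: Fold, target: str,
                 scale_target: bool):
    """Scale per-fold and carve out training rows and the test segment
    (test year plus its 4-week covariate history from the training tail)."""
    ids = [(int(r.year), int(r.week_of_year))
           for r in table[["year", "week_of_year"]].itertuples()]
    train_mask = table["year"].isin(fold.train_years).to_numpy()
    test_mask = (table["year"] == fold.test_year).to_numpy()
    if not train_mask.any() or not test_mask.any():
        raise ValueError(f"table does not cover fold {fold}")
    train_pos = np.flatnonzero(train_mask)
    test_pos = np.flatnonzero(test_mask)

    scale_cols = list(INPUT_COLUMNS) + ([target] if scale_target else [])
    scaler = minmax_fit(table.iloc[train_pos], columns=scale_cols)
    scaled = minmax_apply(scaler, table)

    train_ids = [ids[i] for i in train_pos]
    seg_lo = max(test_pos[0] - (TIME_STEPS - 1), 0)
    seg_pos = np.arange(seg_lo, test_pos[-1] + 1)
    seg_ids = [ids[i] for i in seg_pos]
    _audit_leakage(set(train_ids), {ids[i] for i in test_pos}, fold)
    return scaler, scaled, train_pos, seg_pos, train_ids, seg_ids


def _metrics_frame(target: str, folds: list[FoldArtifacts]) -> EvalMetrics:
    rows = []
    for fa in folds:
        rows.append({
            "train_years": f"{fa.fold.train_years[0]}-{fa.fold.train_years[-1]}",
            "test_year": fa.fold.test_year,
            "train_mse": float(np.mean((fa.train_obs - fa.train_pred) ** 2)),
            "test_mse": float(np.mean((fa.test_obs - fa.test_pred) ** 2)),
            "train_r2": r_squared(fa.train_obs, fa.train_pred),
            "test_r2": r_squared(fa.test_obs, fa.test_pred),
        })
    per_fold = pd.DataFrame(rows)
    tr_o = np.concatenate([fa.train_obs for fa in folds])
    tr_p = np.concatenate([fa.train_pred for fa in folds])
    te_o = np.concatenate([fa.test_obs for fa in folds])
    te_p = np.concatenate([fa.test_pred for fa in folds])
    pooled = {
        "train_mse": float(np.mean((tr_o - tr_p) ** 2)),
        "test_mse": float(np.mean((te_o - te_p) ** 2)),
        "train_r2": r_squared(tr_o, tr_p),
        "test_r2": r_squared(te_o, te_p),
    }
    pooled["r2_gap"] = pooled["train_r2"] - pooled["test_r2"]
    return EvalMetrics(target=target, per_fold=per_fold, pooled=pooled, folds=folds)


def evaluate_network(
    table: pd.DataFrame,
    target: str,
    config: HyperConfig,
    plan: list[Fold] | None = None,
    train_spec: TrainSpec | None = None,
    seed: int = 0,
) -> EvalMetrics:
    """Walk-forward evaluation of one recurrent configuration on one target."""
    if target not in TARGET_COLUMNS:
        raise ValueError(f"unknown target {target!r}")
    plan = plan if plan is not None else make_folds(sorted(table["year"].unique()))
    spec = train_spec if train_spec is not None else TrainSpec(seed=seed)
    folds = []
    for fold in plan:
        scaler, scaled, train_pos, seg_pos, train_ids, seg_ids = _fold_frames(
            table, fold, target, scale_target=True)
        wtr = make_windows(scaled.iloc[train_pos], target_column=target, ids=train_ids)
        wte = make_windows(scaled.iloc[seg_pos], target_column=target, ids=seg_ids)
        if spec.monitor == "validation_tail":
            n_tail = max(int(0.2 * len(wtr)), 1)
            from .preprocess import WindowSet
            monitor = WindowSet(wtr.X[-n_tail:], wtr.y[-n_tail:], wtr.week_ids[-n_tail:])
        else:
            monitor = wte
        model = build_model(config, n_features=len(INPUT_COLUMNS), seed=spec.seed)
        trained = train(model, wtr, monitor, spec)
        trained.scaler, trained.target = scaler, target
        raw = table[target].to_numpy(dtype=float)
        folds.append(FoldArtifacts(
            fold=fold, scaler=scaler, model=trained,
            train_obs=raw[train_pos][TIME_STEPS - 1:],
            train_pred=net_predict(trained, wtr),
            test_obs=raw[seg_pos][TIME_STEPS - 1:],
            test_pred=net_predict(trained, wte),
            test_week_ids=wte.week_ids,
        ))
    return _metrics_frame(target, folds)


def evaluate_baseline(
    table: pd.DataFrame,
    target: str,
    model_name: str,
    plan: list[Fold] | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> EvalMetrics:
    """Walk-forward evaluation of one classical baseline on one target.

    Baselines receive the min-max-scaled inputs flattened to 110 (feature,
    lag) columns and regress on the raw counts (log link for GLM/GAM).
    """
    if model_name not in BASELINE_NAMES:
        raise ValueError(f"unknown baseline {model_name!r}")
    plan = plan if plan is not None else make_folds(sorted(table["year"].unique()))
    folds = []
    for fold in plan:
        scaler, scaled, train_pos, seg_pos, train_ids, seg_ids = _fold_frames(
            table, fold, target, scale_target=False)
        dtr = make_flat_design(scaled.iloc[train_pos], ids=train_ids)
        dte = make_flat_design(scaled.iloc[seg_pos], ids=seg_ids)
        ytr = table[target].to_numpy(dtype=float)[train_pos][TIME_STEPS - 1:]
        yte = table[target].to_numpy(dtype=float)[seg_pos][TIME_STEPS - 1:]
        if model_name == "glm":
            fit = fit_glm(dtr, ytr, **fit_kwargs)
            tr_p, te_p = fit.predict(dtr.X), fit.predict(dte.X)
        elif model_name == "gam":
            fit = fit_gam(dtr, ytr, **fit_kwargs)
            tr_p, te_p = fit.predict(dtr.X), fit.predict(dte.X)
        else:
            fit = fit_tree_ensembles(dtr, ytr, seed=seed, **fit_kwargs)
            tr_p, te_p = fit.predict(model_name, dtr.X), fit.predict(model_name, dte.X)
        folds.append(FoldArtifacts(
            fold=fold, scaler=scaler, model=fit,
            train_obs=ytr, train_pred=np.asarray(tr_p),
            test_obs=yte, test_pred=np.asarray(te_p),
            test_week_ids=dte.week_ids,
        ))
    return _metrics_frame(target, folds)


class WalkForwardPredictor:
    """Pooled-test predictor over the fitted fold models of one evaluation.

    Calling it with a (possibly feature-perturbed) copy of the weekly table
    re-runs each fold's scaler, window construction and trained model on its
    test segment and returns (observed, predicted) concatenated over folds —
    the evaluation surface permutation importance operates on.
    """

    def __init__(self, metrics: EvalMetrics, table: pd.DataFrame):
        self.metrics = metrics
        self.table = table
        self.target = metrics.target

    def __call__(self, table: pd.DataFrame | None = None):
        table = table if table is not None else self.table
        obs_all, pred_all = [], []
        for fa in self.metrics.folds:
            fold = fa.fold
            ids = [(int(r.year), int(r.week_of_year))
                   for r in table[["year", "week_of_year"]].itertuples()]
            test_pos = np.flatnonzero((table["year"] == fold.test_year).to_numpy())
            seg_lo = max(test_pos[0] - (TIME_STEPS - 1), 0)
            seg_pos = np.arange(seg_lo, test_pos[-1] + 1)
            scaled = minmax_apply(fa.scaler, table)
            wte = make_windows(scaled.iloc[seg_pos], target_column=self.target,
                               ids=[ids[i] for i in seg_pos])
            pred_all.append(net_predict(fa.model, wte))
            obs_all.append(self.table[self.target].to_numpy(dtype=float)[seg_pos][TIME_STEPS - 1:])
        return np.concatenate(obs_all), np.concatenate(pred_all)


# ---------------------------------------------------------------------------
# hyperparameter grids, search, final selection
# ---------------------------------------------------------------------------

_UNITS = (8, 16, 32, 64, 96, 128)
_HIDDEN_PAIRS = ((8, 4), (16, 8), (32, 16), (64, 32), (96, 48), (128, 64))
_DROPOUTS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def default_hyper_grid() -> list[HyperConfig]:
    """216 configurations per architecture: 6 recurrent sizes x 6 hidden
    layouts x 6 uniform dropout rates."""
    grid = []
    for u, (h1, h2), d in itertools.product(_UNITS, _HIDDEN_PAIRS, _DROPOUTS):
        grid.append(HyperConfig("lstm", u, h1, h2, (d, d, d, d)))
    return grid


def smoke_hyper_grid() -> list[HyperConfig]:
    """8-point smoke grid for fast end-to-end runs."""
    grid = []
    for u, (h1, h2), d in itertools.product((16, 32), ((16, 8), (32, 16)), (0.0, 0.2)):
        grid.append(HyperConfig("lstm", u, h1, h2, (d, d, d, d)))
    return grid


def _with_cell(config: HyperConfig, cell: str) -> HyperConfig:
    return HyperConfig(cell, config.recurrent_units, config.hidden1_units,
                       config.hidden2_units, config.dropout_rates)


def grid_search(
    architectures: list[str],
    grid: list[HyperConfig],
    table: pd.DataFrame,
    plan: list[Fold] | None = None,
    seed: int = 0,
    train_spec: TrainSpec | None = None,
    targets: tuple[str, ...] = ("outpatient", "er"),
) -> pd.DataFrame:
    """Evaluate every architecture x configuration on both targets.

    Returns a leaderboard with one row per attempted model; individual
    failures are recorded in the ``error`` column rather than aborting.
    """
    rows = []
    for arch in architectures:
        for config in grid:
            cfg = _with_cell(config, arch)
            row = {
                "architecture": arch,
                "recurrent_units": cfg.recurrent_units,
                "hidden1_units": cfg.hidden1_units,
                "hidden2_units": cfg.hidden2_units,
                "dropout": cfg.dropout_rates[0],
                "n_params": cfg.dense_param_count,
                "error": "",
            }
            try:
                for tgt in targets:
                    m = evaluate_network(table, tgt, cfg, plan=plan,
                                         train_spec=train_spec, seed=seed)
                    row[f"train_r2_{tgt}"] = m.pooled["train_r2"]
                    row[f"test_r2_{tgt}"] = m.pooled["test_r2"]
                vals = [row[f"test_r2_{t}"] for t in targets]
                row["mean_test_r2"] = float(np.mean(vals))
            except Exception as exc:  # individual failures are data, not fatal
                log.warning("model %s failed: %s", cfg, exc)
                row["error"] = str(exc)
                row["mean_test_r2"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def select_final(leaderboard: pd.DataFrame) -> pd.Series:
    """The final-model rule: restrict to models in the top decile of test R²
    for both targets (inclusive 90th-percentile thresholds), then take the
    best mean of the two test R² values; ties break toward fewer parameters,
    then lexicographic configuration order. If the top-decile intersection is
    empty, fall back to the global best mean with a warning."""
    lb = leaderboard[leaderboard["error"] == ""].dropna(subset=["mean_test_r2"])
    if len(lb) == 0:
        raise ValueError("no successful models on the leaderboard")
    sort_keys = ["architecture", "recurrent_units", "hidden1_units",
                 "hidden2_units", "dropout"]

    def _pick(frame: pd.DataFrame) -> pd.Series:
        best = frame[frame["mean_test_r2"] == frame["mean_test_r2"].max()]
        best = best.sort_values(["n_params"] + sort_keys)
        return best.iloc[0]

    thr_out = np.quantile(lb["test_r2_outpatient"], 0.9)
    thr_er = np.quantile(lb["test_r2_er"], 0.9)
    area1 = lb[(lb["test_r2_outpatient"] >= thr_out) & (lb["test_r2_er"] >= thr_er)]
    if len(area1) == 0:
        log.warning("top-decile intersection empty; falling back to global best mean")
        return _pick(lb)
    return _pick(area1)
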