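"""Classical comparison models on the flattened 5-week lag design.

The networks see a (5 weeks x 22 features) window per sample; to give the
non-sequence models identical information content, each sample is flattened
into 110 columns named ``<feature>_lag<0..4>``. GLM and GAM are log-link
count regressions (Poisson likelihood point estimates with a free Pearson
dispersion, i.e. quasi-Poisson); RF and GBM are scikit-learn ensembles with
hyperparameters chosen by time-ordered inner cross-validation on the
training rows only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, TimeSeriesSplit
from statsmodels.gam.api import BSplines, GLMGam

from .columns import INPUT_COLUMNS

log = logging.getLogger(__name__)

__all__ = ["FlatDesign", "make_flat_design", "fit_glm", "fit_gam",
           "fit_tree_ensembles", "DEFAULT_RF_GRID", "DEFAULT_GBM_GRID"]

DEFAULT_RF_GRID = {"n_estimators": [100, 300, 500], "max_depth": [3, 5, 10, None]}
DEFAULT_GBM_GRID = {
    "n_estimators": [100, 300, 500],
    "max_depth": [3, 5, 10],
    "learning_rate": [0.01, 0.05, 0.1],
}


@dataclass(frozen=True)
class FlatDesign:
    """Per-week predictor matrix: 22 features at lags 0-4, aligned to the
    same target weeks as the recurrent models' windows."""

    X: pd.DataFrame  # columns "<feature>_lag<l>"
    week_ids: tuple[tuple[int, int], ...]


def make_flat_design(
    table: pd.DataFrame,
    feature_columns: list[str] | None = None,
    time_steps: int = 5,
    ids: list[tuple[int, int]] | None = None,
) -> FlatDesign:
    """Flatten each 5-week window into one row of (feature, lag) columns.

    Lag 0 is the target week itself; lag l is l weeks earlier. Row count is
    n_rows - time_steps + 1, identical to the windowed sample count.
    """
    cols = feature_columns if feature_columns is not None else INPUT_COLUMNS
    n = len(table)
    if n < time_steps:
        raise ValueError(f"need at least {time_steps} rows, got {n}")
    if ids is None:
        ids = [
            (int(r.year), int(r.week_of_year))
            for r in table[["year", "week_of_year"]].itertuples()
        ]
    F = table[cols].to_numpy(dtype=float)
    blocks = {}
    for lag in range(time_steps):
        sub = F[time_steps - 1 - lag : n - lag]
        for j, c in enumerate(cols):
            blocks[f"{c}_lag{lag}"] = sub[:, j]
    X = pd.DataFrame(blocks)
    return FlatDesign(X=X, week_ids=tuple(ids[time_steps - 1 :]))


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Remove linearly dependent columns (pivoted-QR rank check)."""
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return X, names
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    if rank < X.shape[1]:
        dropped = [names[i] for i in sorted(piv[rank:])]
        log.warning("dropping %d aliased design columns: %s",
                    len(dropped), ", ".join(dropped[:8]))
    return X[:, keep], [names[i] for i in keep]


@dataclass
class CountRegression:
    """A fitted log-link count model (GLM or GAM) with its design recipe."""

    kind: str
    result: object
    columns: list[str]
    dispersion: float
    smooth_columns: list[str] | None = None
    smoother: object | None = None
    smooth_bounds: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.result.params)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.kind == "glm":
            mat = sm.add_constant(X[self.columns].to_numpy(dtype=float),
                                  has_constant="add")
            return np.asarray(self.result.predict(mat))
        exog = sm.add_constant(X[self.columns].to_numpy(dtype=float),
                               has_constant="add")
        # spline bases are only defined on the fitted range; clamp test-range
        # extrapolation to the boundary knots
        smooth_x = X[self.smooth_columns].to_numpy(dtype=float)
        lo, hi = self.smooth_bounds
        smooth_x = np.clip(smooth_x, lo, hi)
        exog_smooth = self.smoother.transform(smooth_x)
        return np.asarray(self.result.predict(exog, exog_smooth=exog_smooth,
                                              transform=False))

    def summary_dict(self) -> dict:
        return {
            "kind": self.kind,
            "dispersion": self.dispersion,
            "coefficients": {str(k): float(v) for k, v in self.coefficients.items()},
        }


def _pearson_dispersion(result, y: np.ndarray) -> float:
    mu = np.asarray(result.fittedvalues)
    dof = max(len(y) - result.df_model - 1, 1)
    return float(np.sum((y - mu) ** 2 / np.maximum(mu, 1e-12)) / dof)


def fit_glm(design: FlatDesign, targets: np.ndarray) -> CountRegression:
    """Quasi-Poisson log-linear model: Poisson ML point estimates plus a
    Pearson dispersion estimate. Aliased columns are dropped with a warning."""
    y = np.asarray(targets, dtype=float)
    if np.all(y == 0):
        raise ValueError("targets are constant zero")
    names = list(design.X.columns)
    X, kept = _drop_aliased(design.X.to_numpy(dtype=float), names)
    mat = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, mat, family=sm.families.Poisson()).fit()
    return CountRegression(kind="glm", result=res, columns=kept,
                           dispersion=_pearson_dispersion(res, y))


def fit_gam(
    design: FlatDesign,
    targets: np.ndarray,
    smooth_columns: list[str] | None = None,
    df: int = 5,
    alpha: float = 1.0,
) -> CountRegression:
    """Quasi-Poisson additive model: penalized B-spline smooths on the lag-0
    feature columns, linear terms on the lagged copies (smoothing all 110
    columns would be statistically untenable at ~100-250 weekly samples)."""
    y = np.asarray(targets, dtype=float)
    if np.all(y == 0):
        raise ValueError("targets are constant zero")
    if smooth_columns is None:
        smooth_columns = [c for c in design.X.columns if c.endswith("_lag0")]
    # constant columns cannot carry a spline basis
    smooth_columns = [c for c in smooth_columns if design.X[c].nunique() > df]
    linear_cols = [c for c in design.X.columns if c not in smooth_columns]
    Xlin, kept = _drop_aliased(design.X[linear_cols].to_numpy(dtype=float),
                               linear_cols)
    exog = sm.add_constant(Xlin, has_constant="add")
    smooth_train = design.X[smooth_columns].to_numpy(dtype=float)
    smoother = BSplines(smooth_train,
                        df=[df] * len(smooth_columns),
                        degree=[3] * len(smooth_columns))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = GLMGam(y, exog=exog, smoother=smoother,
                     alpha=[alpha] * len(smooth_columns),
                     family=sm.families.Poisson()).fit()
    return CountRegression(kind="gam", result=res, columns=kept,
                           dispersion=_pearson_dispersion(res, y),
                           smooth_columns=smooth_columns, smoother=smoother,
                           smooth_bounds=(smooth_train.min(axis=0),
                                          smooth_train.max(axis=0)))


@dataclass
class TreeEnsembles:
    """Grid-searched RF and GBM regressors refit on the full training rows."""

    rf: RandomForestRegressor
    gbm: GradientBoostingRegressor
    rf_params: dict
    gbm_params: dict

    def predict(self, which: str, X: pd.DataFrame) -> np.ndarray:
        model = {"rf": self.rf, "gbm": self.gbm}[which]
        return model.predict(X.to_numpy(dtype=float))

    def summary_dict(self) -> dict:
        return {"rf_params": self.rf_params, "gbm_params": self.gbm_params}


def fit_tree_ensembles(
    design: FlatDesign,
    targets: np.ndarray,
    rf_grid: dict | None = None,
    gbm_grid: dict | None = None,
    inner_cv_splits: int = 3,
    seed: int = 0,
) -> TreeEnsembles:
    """Select RF/GBM hyperparameters by inner time-ordered CV on the training
    rows only (the test year is never seen), then refit on all training rows."""
    X = design.X.to_numpy(dtype=float)
    y = np.asarray(targets, dtype=float)
    cv = TimeSeriesSplit(n_splits=inner_cv_splits)
    searches = {}
    for name, est, grid in (
        ("rf", RandomForestRegressor(random_state=seed), rf_grid or DEFAULT_RF_GRID),
        ("gbm", GradientBoostingRegressor(random_state=seed), gbm_grid or DEFAULT_GBM_GRID),
    ):
        gs = GridSearchCV(est, grid, cv=cv, scoring="neg_mean_squared_error",
                          n_jobs=1, refit=True)
        gs.fit(X, y)
        searches[name] = gs
    return TreeEnsembles(
        rf=searches["rf"].best_estimator_,
        gbm=searches["gbm"].best_estimator_,
        rf_params=searches["rf"].best_params_,
        gbm_params=searches["gbm"].best_params_,
    )
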