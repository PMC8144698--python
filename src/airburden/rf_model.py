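"""Random-forest estimation of surface concentrations with dual cross-validation.

A per-pollutant random-forest regressor maps the covariate row of a
station-day (satellite column, meteorology, geography, day-of-window index)
to the observed surface concentration. Model skill is reported with three
metrics on pooled held-out predictions — the coefficient of determination
R^2 = 1 - SS_res/SS_tot, RMSE and MAE — under two schemes:

* sample-based 10-fold cross-validation (random row partition), and
* by-year (leave-one-year-out) cross-validation, which probes temporal
  transferability: trees cannot extrapolate beyond the training target range,
  so a year whose levels fall outside the other years' range scores lower.

Defaults: 500 trees, covariate subsampling at the classical regression
default of one third of the predictors, unlimited depth. All are exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from . import features
from .grid import GridSpec

logger = logging.getLogger(__name__)


@dataclass
class RFHyperparams:
    n_estimators: int = 500
    max_features: float = 1.0 / 3.0
    max_depth: int | None = None
    min_samples_leaf: int = 1

    def make_estimator(self, seed: int) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=int(seed) % (2**31),
            n_jobs=1,
        )


@dataclass
class Metrics:
    r2: float
    rmse: float
    mae: float
    r2_defined: bool = True


@dataclass
class FittedModel:
    estimator: RandomForestRegressor
    predictors: list[str]
    pollutant: str | None = None

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(table[self.predictors].to_numpy())


@dataclass
class CVResult:
    """Pooled and per-fold skill of one cross-validation run.

    ``predictions`` has one row per input row with columns y_true, y_pred and
    fold; every row is predicted exactly once across folds.
    """
    scheme: str
    predictions: pd.DataFrame
    r2: float
    rmse: float
    mae: float
    r2_defined: bool
    per_fold: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> dict:
        return {"scheme": self.scheme, "R2": self.r2, "RMSE": self.rmse,
                "MAE": self.mae, "R2_defined": self.r2_defined,
                "n": int(len(self.predictions))}


def metrics(pred: np.ndarray, truth: np.ndarray) -> Metrics:
    """R^2 (1 - SS_res/SS_tot), RMSE and MAE on pooled prediction pairs.

    A zero-variance truth makes SS_tot = 0; R^2 is then flagged undefined
    (NaN) rather than raised, since degenerate targets occur in toy fixtures.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length 1-D arrays")
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    resid = truth - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        return Metrics(r2=float("nan"), rmse=rmse, mae=mae, r2_defined=False)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return Metrics(r2=r2, rmse=rmse, mae=mae)


def _predictors(table: pd.DataFrame, predictors: list[str] | None) -> list[str]:
    cols = predictors if predictors is not None else [
        c for c in features.PREDICTOR_COLUMNS if c in table.columns]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"predictor columns missing from table: {missing}")
    return cols


def fit(table: pd.DataFrame, hyperparams: RFHyperparams | None = None,
        seed: int = 0, predictors: list[str] | None = None,
        pollutant: str | None = None) -> FittedModel:
    """Fit a random-forest regressor on a feature table.

    The target is the ``value`` column; predictors default to the documented
    covariate set. All-constant covariates are tolerated with a warning.
    """
    if table.empty:
        raise ValueError("cannot fit on an empty table")
    if "value" not in table.columns:
        raise ValueError("table lacks the target column 'value'")
    hp = hyperparams or RFHyperparams()
    cols = _predictors(table, predictors)
    X = table[cols].to_numpy()
    constant = [c for c, col in zip(cols, X.T) if np.all(col == col[0])]
    if constant:
        logger.warning("all-constant covariates in training table: %s", constant)
    est = hp.make_estimator(seed)
    est.fit(X, table["value"].to_numpy())
    return FittedModel(estimator=est, predictors=cols, pollutant=pollutant)


def _pooled_result(scheme: str, rows: pd.DataFrame,
                   per_fold_rows: list[dict]) -> CVResult:
    m = metrics(rows["y_pred"].to_numpy(), rows["y_true"].to_numpy())
    return CVResult(scheme=scheme, predictions=rows, r2=m.r2, rmse=m.rmse,
                    mae=m.mae, r2_defined=m.r2_defined,
                    per_fold=pd.DataFrame(per_fold_rows))


def cross_validate_10fold(table: pd.DataFrame,
                          hyperparams: RFHyperparams | None = None,
                          seed: int = 0, n_folds: int = 10,
                          predictors: list[str] | None = None) -> CVResult:
    """Sample-based K-fold cross-validation (default 10 folds).

    Rows are randomly partitioned into folds of sizes differing by at most
    one; each fold is predicted by a model trained on the others and metrics
    are computed on the pooled held-out predictions.
    """
    if len(table) < n_folds:
        raise ValueError(f"need at least {n_folds} rows, got {len(table)}")
    hp = hyperparams or RFHyperparams()
    cols = _predictors(table, predictors)
    table = table.reset_index(drop=True)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**31))
    y_pred = np.full(len(table), np.nan)
    fold_of = np.full(len(table), -1)
    per_fold = []
    y = table["value"].to_numpy()
    X = table[cols].to_numpy()
    for k, (tr, te) in enumerate(kf.split(X)):
        est = hp.make_estimator(seed + k + 1)
        est.fit(X[tr], y[tr])
        y_pred[te] = est.predict(X[te])
        fold_of[te] = k
        m = metrics(y_pred[te], y[te])
        per_fold.append({"fold": k, "n": len(te), "R2": m.r2,
                         "RMSE": m.rmse, "MAE": m.mae})
    rows = pd.DataFrame({"y_true": y, "y_pred": y_pred, "fold": fold_of})
    return _pooled_result("tenfold_sample", rows, per_fold)


def cross_validate_by_year(table: pd.DataFrame,
                           hyperparams: RFHyperparams | None = None,
                           seed: int = 0,
                           predictors: list[str] | None = None) -> CVResult:
    """Leave-one-year-out cross-validation over the ``year`` label."""
    years = np.sort(table["year"].unique())
    if len(years) < 2:
        raise ValueError("by-year cross-validation needs at least two distinct years")
    hp = hyperparams or RFHyperparams()
    cols = _predictors(table, predictors)
    table = table.reset_index(drop=True)
    y = table["value"].to_numpy()
    X = table[cols].to_numpy()
    year_col = table["year"].to_numpy()
    y_pred = np.full(len(table), np.nan)
    fold_of = np.full(len(table), -1)
    per_fold = []
    for k, held_out in enumerate(years):
        te = np.flatnonzero(year_col == held_out)
        tr = np.flatnonzero(year_col != held_out)
        est = hp.make_estimator(seed + k + 1)
        est.fit(X[tr], y[tr])
        y_pred[te] = est.predict(X[te])
        fold_of[te] = k
        m = metrics(y_pred[te], y[te])
        per_fold.append({"fold": k, "year": int(held_out), "n": len(te),
                         "R2": m.r2, "RMSE": m.rmse, "MAE": m.mae})
    rows = pd.DataFrame({"y_true": y, "y_pred": y_pred, "fold": fold_of,
                         "year": year_col})
    return _pooled_result("by_year", rows, per_fold)


def predict_grid_series(model: FittedModel, satellite: xr.DataArray,
                        meteorology: xr.Dataset, static: xr.Dataset,
                        grid: GridSpec,
                        window_start: tuple[int, int] = (1, 23)) -> xr.DataArray:
    """Predict daily concentration grids for every covariate day."""
    cells = features.build_cell_table(satellite, meteorology, static, grid,
                                      window_start=window_start)
    pred = model.predict(cells)
    n_t = len(satellite.time)
    cube = pred.reshape(n_t, *grid.shape)
    return xr.DataArray(cube, coords={"time": satellite.time.values,
                                      "lat": grid.lat_centers,
                                      "lon": grid.lon_centers},
                        dims=("time", "lat", "lon"))
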