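"""Bare-ground index regression: partitioning, repeated CV, selection, prediction.

Candidate algorithms are random forest (RF), nu-support-vector regression
with an RBF kernel (SVR) and gradient boosting trees (GBT). The response is
percent bare ground transformed as log(x + 1); models are compared by
repeated random cross-validation within the training partition and by a
single untouched holdout partition, and the winner is refit on all plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.svm import NuSVR

from ._util import substream

logger = logging.getLogger(__name__)

__all__ = [
    "ALGORITHMS",
    "DEFAULT_PARAMS",
    "BareGroundSeries",
    "split_holdout",
    "transform_response",
    "back_transform_response",
    "make_model",
    "repeated_cv",
    "evaluate_candidates",
    "select_model",
    "predict_series",
]

ALGORITHMS = ("RF", "SVR", "GBT")

# Fixed default hyperparameters per algorithm (kept deliberately small; the
# comparison protocol, not the grid, is the object of interest here).
DEFAULT_PARAMS: dict[str, dict] = {
    "RF": {"n_estimators": 300, "min_samples_leaf": 2},
    "SVR": {"kernel": "rbf", "nu": 0.5, "C": 2.0, "gamma": "scale"},
    "GBT": {"n_estimators": 200, "learning_rate": 0.05, "max_depth": 2},
}


def make_model(algorithm, seed: int = 0, params: dict | None = None):
    """Instantiate a candidate regressor.

    ``algorithm`` is one of the named candidates, or a callable
    ``factory(seed) -> estimator`` (useful for oracle models in tests).
    """
    if callable(algorithm):
        return algorithm(seed)
    p = dict(DEFAULT_PARAMS[algorithm])
    if params:
        p.update(params)
    if algorithm == "RF":
        return RandomForestRegressor(random_state=seed, **p)
    if algorithm == "SVR":
        return NuSVR(**p)
    if algorithm == "GBT":
        return GradientBoostingRegressor(random_state=seed, **p)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def split_holdout(plots: pd.DataFrame, fraction: float = 0.25, seed: int = 0):
    """Random, reproducible split into (train, holdout) partitions.

    The holdout receives round(n * fraction) plots and is never used during
    tuning or model comparison.
    """
    if not 0 < fraction < 1:
        raise ValueError("holdout fraction must lie in (0, 1)")
    n = len(plots)
    if n < 8:
        raise ValueError("need at least 8 plots to split")
    rng = substream(seed, "holdout-split")
    perm = rng.permutation(n)
    n_hold = int(round(n * fraction))
    hold_idx = np.sort(perm[:n_hold])
    train_idx = np.sort(perm[n_hold:])
    return plots.iloc[train_idx].copy(), plots.iloc[hold_idx].copy()


def transform_response(bare_percent):
    """log(x + 1) of percent bare ground; the response is zero-skewed."""
    x = np.asarray(bare_percent, dtype=float)
    if np.any(x < 0):
        raise ValueError("bare ground percent must be non-negative")
    return np.log1p(x)


def back_transform_response(y):
    """Inverse of the response transform: exp(y) - 1."""
    return np.expm1(np.asarray(y, dtype=float))


def repeated_cv(
    algorithm: str,
    X: np.ndarray,
    y: np.ndarray,
    repeats: int = 10,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> dict:
    """Repeated random cross-validation of one algorithm.

    Each repeat draws a fresh random train_fraction/(1-train_fraction) split
    of the training partition, fits the model, and scores RMSE and the
    coefficient of determination R^2 on the validation subset, all in the
    transformed response space. Repeats with a constant validation response
    have undefined R^2; those repeats are recorded as NaN and excluded from
    the mean with a log entry.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    alg_name = algorithm if isinstance(algorithm, str) else getattr(algorithm, "__name__", "custom")
    rmses, r2s = [], []
    for r in range(repeats):
        rng = substream(seed, f"cv/{alg_name}/{r}")
        perm = rng.permutation(n)
        n_train = int(round(n * train_fraction))
        tr, va = perm[:n_train], perm[n_train:]
        model = make_model(algorithm, seed=int(rng.integers(2**31)))
        model.fit(X[tr], y[tr])
        pred = model.predict(X[va])
        rmses.append(float(np.sqrt(mean_squared_error(y[va], pred))))
        if np.ptp(y[va]) == 0:
            logger.warning("repeat %d: constant validation response, R^2 undefined", r)
            r2s.append(np.nan)
        else:
            r2s.append(float(r2_score(y[va], pred)))
    rmses = np.array(rmses)
    r2s = np.array(r2s)
    return {
        "algorithm": alg_name,
        "rmse_mean": float(np.mean(rmses)),
        "rmse_sd": float(np.std(rmses, ddof=1)),
        "r2_mean": float(np.nanmean(r2s)),
        "r2_sd": float(np.nanstd(r2s, ddof=1)),
        "rmse_repeats": rmses,
        "r2_repeats": r2s,
    }


def evaluate_candidates(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_holdout: np.ndarray,
    y_holdout: np.ndarray,
    algorithms=ALGORITHMS,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV report for every candidate: repeated-CV summaries plus holdout
    RMSE/R^2 of the model refit on the full training partition."""
    rows = []
    for alg in algorithms:
        row = repeated_cv(alg, X_train, y_train, repeats=repeats, seed=seed)
        model = make_model(alg, seed=seed)
        model.fit(X_train, y_train)
        pred = model.predict(X_holdout)
        row["holdout_rmse"] = float(np.sqrt(mean_squared_error(y_holdout, pred)))
        row["holdout_r2"] = float(r2_score(y_holdout, pred))
        # Squared Pearson correlation reported alongside for comparability.
        if np.ptp(pred) > 0:
            row["holdout_r2_pearson"] = float(np.corrcoef(y_holdout, pred)[0, 1] ** 2)
        else:
            row["holdout_r2_pearson"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("algorithm")


def select_model(report: pd.DataFrame) -> str:
    """Choose the final algorithm: best (lowest) holdout RMSE; ties broken by
    higher holdout R^2, then lower CV mean RMSE."""
    if len(report) == 0:
        raise ValueError("no candidate algorithms to select from")
    order = report.sort_values(
        by=["holdout_rmse", "holdout_r2", "rmse_mean"],
        ascending=[True, False, True],
    )
    chosen = str(order.index[0])
    logger.info("select_model: chose %s (holdout RMSE %.4f)", chosen, order.iloc[0]["holdout_rmse"])
    return chosen


@dataclass
class BareGroundSeries:
    """Predicted bare-ground score maps per year, on three linked scales.

    raw: back-transformed percent bare ground; scaled: z-scored by the
    reference year's (2016) spatial mean and standard deviation; normalized:
    min-max over all pixel-years of the scaled layer, in [0, 1]. Within any
    year the three layers are monotone transforms of one another.
    """

    years: np.ndarray
    raw: np.ndarray  # (Y, rows, cols)
    scaled: np.ndarray
    normalized: np.ndarray

    def for_year(self, year: int, layer: str = "normalized") -> np.ndarray:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not predicted")
        return getattr(self, layer)[int(idx[0])]


def predict_series(
    model,
    features_by_year: dict[int, np.ndarray],
    shape: tuple[int, int],
    reference_year: int = 2016,
) -> BareGroundSeries:
    """Predict yearly bare-ground maps and place them on the three scales.

    ``features_by_year`` maps each year to its standardized predictor matrix
    (one row per pixel, NaN rows allowed and propagated). Predictions are
    back-transformed from the log scale, z-scored by the reference year's
    spatial mean/sd, then min-max normalized over the whole series.
    """
    years = np.array(sorted(features_by_year), dtype=int)
    if reference_year not in years:
        raise ValueError(f"reference year {reference_year} absent from predictions")
    raw = np.full((years.size,) + tuple(shape), np.nan)
    for i, year in enumerate(years):
        X = np.asarray(features_by_year[int(year)], dtype=float)
        ok = np.isfinite(X).all(axis=1)
        pred = np.full(X.shape[0], np.nan)
        if ok.any():
            pred[ok] = model.predict(X[ok])
        raw[i] = back_transform_response(pred).reshape(shape)
    ref = raw[years == reference_year][0]
    mu = float(np.nanmean(ref))
    sd = float(np.nanstd(ref, ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("reference-year predictions have zero spatial variance")
    scaled = (raw - mu) / sd
    lo, hi = np.nanmin(scaled), np.nanmax(scaled)
    normalized = (scaled - lo) / (hi - lo) if hi > lo else np.zeros_like(scaled)
    return BareGroundSeries(years, raw, scaled, normalized)
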