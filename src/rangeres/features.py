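"""Predictor assembly: annual index means, harmonic phenology, windowed rainfall.

The per pixel-year feature set is the 10-predictor table used to calibrate
the bare-ground index: {EVI, BSI, MSAVI} x {seasonal mean, harmonic
magnitude, harmonic phase} plus annual rainfall accumulated May (previous
year) through April (focal year).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import IndexSeries, annual_composite, composite_window
from .synthetic import RainfallSeries, WorldConfig, _cell_of_pixel

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonicFit",
    "harmonic_fit",
    "annual_rainfall",
    "standardize",
    "apply_standardization",
    "build_feature_table",
    "PREDICTOR_COLUMNS",
]

PREDICTOR_COLUMNS = [
    "evi_mean",
    "bsi_mean",
    "msavi_mean",
    "evi_magnitude",
    "evi_phase",
    "bsi_magnitude",
    "bsi_phase",
    "msavi_magnitude",
    "msavi_phase",
    "annual_rainfall_mm",
]


@dataclass
class HarmonicFit:
    """Per-pixel single-harmonic fit y(t) = a0 + a1 cos(2*pi*t) + b1 sin(2*pi*t).

    magnitude = sqrt(a1^2 + b1^2); phase = atan2(b1, a1) in (-pi, pi], i.e.
    the curve peaks at t = phase / (2*pi) fraction of the year. Pixels with
    fewer than the minimum number of valid scenes are NaN.
    """

    a0: np.ndarray
    a1: np.ndarray
    b1: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.a1, self.b1)

    @property
    def phase(self) -> np.ndarray:
        return np.arctan2(self.b1, self.a1)


def harmonic_fit(series: IndexSeries, focal_year: int, min_scenes: int = 3) -> HarmonicFit:
    """Least-squares annual harmonic per pixel over the focal seasonal window.

    Ordinary least squares on the design [1, cos(2*pi*t), sin(2*pi*t)] with
    t the fraction of year, using only valid scenes inside the Nov-Oct
    compositing window; pixels with fewer than ``min_scenes`` valid scenes
    (or a singular design) are masked.
    """
    lo, hi = composite_window(focal_year)
    sel = (series.dates >= lo) & (series.dates < hi)
    if not np.any(sel):
        raise ValueError(f"no scenes inside the composite window for {focal_year}")
    dates = series.dates[sel]
    vals = series.values[sel].reshape(sel.sum(), -1)  # (T, N)
    t = np.mod(dates, 1.0)
    X = np.column_stack([np.ones_like(t), np.cos(2 * np.pi * t), np.sin(2 * np.pi * t)])

    w = np.isfinite(vals)  # (T, N)
    y = np.where(w, vals, 0.0)
    # Batched weighted normal equations: one 3x3 solve per pixel.
    A = np.einsum("ti,tj,tn->nij", X, X, w.astype(float))
    b = np.einsum("ti,tn->ni", X, y)
    counts = w.sum(axis=0)
    ok = counts >= min_scenes
    dets = np.linalg.det(A)
    ok &= np.abs(dets) > 1e-12
    coef = np.full((vals.shape[1], 3), np.nan)
    if np.any(ok):
        coef[ok] = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
    shape = series.values.shape[1:]
    return HarmonicFit(
        a0=coef[:, 0].reshape(shape),
        a1=coef[:, 1].reshape(shape),
        b1=coef[:, 2].reshape(shape),
    )


def annual_rainfall(rainfall: RainfallSeries, focal_year: int) -> np.ndarray:
    """Total rainfall (mm) per cell from May of the previous calendar year
    through the end of April of the focal year."""
    prev = rainfall.year_index(focal_year - 1)
    focal = rainfall.year_index(focal_year)
    # months are 1-based in the calendar, axis index is month-1
    return rainfall.monthly[prev, 4:12].sum(axis=0) + rainfall.monthly[focal, 0:4].sum(axis=0)


def standardize(table: pd.DataFrame, reference_rows=None, columns=None):
    """Z-score predictors against reference (training) rows.

    Returns ``(standardized_table, stats)`` where ``stats`` maps each column
    to its reference mean and sample (n-1) standard deviation, for reuse at
    prediction time. Raises if a predictor has zero variance in the
    reference, naming the column.
    """
    columns = list(columns) if columns is not None else [c for c in PREDICTOR_COLUMNS if c in table.columns]
    ref = table if reference_rows is None else table.loc[reference_rows]
    stats = {}
    out = table.copy()
    for col in columns:
        mean = float(ref[col].mean())
        sd = float(ref[col].std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"predictor {col!r} has zero variance in the reference rows")
        stats[col] = {"mean": mean, "sd": sd}
        out[col] = (table[col] - mean) / sd
    return out, stats


def apply_standardization(table: pd.DataFrame, stats: dict) -> pd.DataFrame:
    """Standardize new data with previously stored reference statistics."""
    out = table.copy()
    for col, s in stats.items():
        out[col] = (table[col] - s["mean"]) / s["sd"]
    return out


def build_feature_table(
    index_series: dict[str, IndexSeries],
    rainfall: RainfallSeries,
    years,
    config: WorldConfig | None = None,
    min_scenes: int = 3,
) -> pd.DataFrame:
    """Assemble the 10-predictor table for every pixel-year.

    ``index_series`` must contain gap-filled series named 'evi', 'bsi' and
    'msavi'. Rows missing any predictor are dropped with a logged count.
    Rainfall cells are broadcast to fine pixels through the pixel->cell map
    of ``config`` (identity mapping if omitted and grids agree).
    """
    needed = ("evi", "bsi", "msavi")
    for name in needed:
        if name not in index_series:
            raise KeyError(f"missing index series {name!r}")
    shape = index_series["evi"].values.shape[1:]
    n_pix = int(np.prod(shape))
    frames = []
    for year in [int(y) for y in years]:
        cols = {"pixel_id": np.arange(n_pix), "year": year}
        for name in needed:
            comp = annual_composite(index_series[name], year)
            fit = harmonic_fit(index_series[name], year, min_scenes=min_scenes)
            cols[f"{name}_mean"] = comp.values.ravel()
            cols[f"{name}_magnitude"] = fit.magnitude.ravel()
            cols[f"{name}_phase"] = fit.phase.ravel()
        rain = annual_rainfall(rainfall, year)
        if config is not None:
            prow, pcol = _cell_of_pixel(config)
            rain_fine = rain[prow[:, None], pcol[None, :]]
        elif rain.shape == shape:
            rain_fine = rain
        else:
            rain_fine = np.full(shape, float(rain.mean()))
        cols["annual_rainfall_mm"] = rain_fine.ravel()
        frames.append(pd.DataFrame(cols))
    table = pd.concat(frames, ignore_index=True)
    complete = table[PREDICTOR_COLUMNS].notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("build_feature_table: dropped %d incomplete pixel-year rows", dropped)
    return table.loc[complete].reset_index(drop=True)
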