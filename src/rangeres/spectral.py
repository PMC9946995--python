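"""Spectral indices, quality masking, gap filling and seasonal composites.

Missing or masked values are carried as NaN throughout; a pixel is "valid" in
a scene iff its ``valid`` flag is set and the index arithmetic is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import DAYS_PER_YEAR, date_value

__all__ = [
    "Scene",
    "IndexSeries",
    "AnnualComposite",
    "compute_ndvi",
    "compute_evi",
    "compute_bsi",
    "compute_msavi",
    "mask_low_quality",
    "fill_gaps",
    "annual_composite",
    "composite_window",
]


@dataclass
class Scene:
    """One acquisition date's reflectance grid.

    Bands are surface reflectance in [0, 1]; ``date`` is a fractional-year
    instant (e.g. 2016.5); ``valid`` marks cloud-free, usable pixels.
    """

    date: float
    blue: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    swir: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.blue = np.asarray(self.blue, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        self.nir = np.asarray(self.nir, dtype=float)
        self.swir = np.asarray(self.swir, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.blue.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        for b in (self.red, self.nir, self.swir, self.valid):
            if b.shape != self.blue.shape:
                raise ValueError("bands and valid mask must share one shape")
        for name in ("blue", "red", "nir", "swir"):
            band = getattr(self, name)
            ok = band[self.valid]
            if ok.size and (np.nanmin(ok) < 0 or np.nanmax(ok) > 1):
                raise ValueError(f"{name} reflectance outside [0, 1] at valid pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape


@dataclass
class IndexSeries:
    """A stack of per-scene index grids; NaN marks missing values."""

    name: str
    dates: np.ndarray  # (T,), strictly increasing fractional years
    values: np.ndarray  # (T, rows, cols)

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.dates.ndim != 1 or self.values.shape[0] != self.dates.size:
            raise ValueError("dates and values leading dimension must agree")
        if self.dates.size > 1 and not np.all(np.diff(self.dates) > 0):
            raise ValueError("dates must be strictly increasing")


@dataclass
class AnnualComposite:
    """Per-pixel seasonal-window mean of an index for one focal year."""

    index: str
    year: int
    values: np.ndarray
    window: tuple[float, float]
    n_scenes: np.ndarray  # valid scenes per pixel


def _masked(scene: Scene, values: np.ndarray, defined: np.ndarray) -> np.ndarray:
    out = np.where(scene.valid & defined, values, np.nan)
    return out


def compute_ndvi(scene: Scene) -> np.ndarray:
    """(NIR − Red) / (NIR + Red); NaN where masked or the denominator is 0."""
    denom = scene.nir + scene.red
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (scene.nir - scene.red) / denom
    return _masked(scene, v, denom != 0)


def compute_evi(scene: Scene) -> np.ndarray:
    """Enhanced vegetation index, 2.5·(NIR − Red)/(NIR + 6·Red − 7.5·Blue + 1)."""
    denom = scene.nir + 6.0 * scene.red - 7.5 * scene.blue + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        v = 2.5 * (scene.nir - scene.red) / denom
    return _masked(scene, v, denom != 0)


def compute_bsi(scene: Scene) -> np.ndarray:
    """Bare soil index: ((SWIR + Red) − (NIR + Blue)) / ((SWIR + Red) + (NIR + Blue)).

    Contrasts the soil-bright SWIR/Red bands against the vegetation-bright
    NIR (and Blue); higher values mean barer ground.
    """
    a = scene.swir + scene.red
    b = scene.nir + scene.blue
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (a - b) / denom
    return _masked(scene, v, denom != 0)


def compute_msavi(scene: Scene) -> np.ndarray:
    """Modified soil-adjusted vegetation index.

    (2·NIR + 1 − sqrt((2·NIR + 1)² − 8·(NIR − Red))) / 2; NaN where the
    radicand is negative.
    """
    s = 2.0 * scene.nir + 1.0
    radicand = s * s - 8.0 * (scene.nir - scene.red)
    with np.errstate(invalid="ignore"):
        v = (s - np.sqrt(radicand)) / 2.0
    return _masked(scene, v, radicand >= 0)


def mask_low_quality(scene: Scene, cloud_score: np.ndarray, threshold: float = 10.0) -> Scene:
    """Drop pixels whose per-pixel cloud score (percent) is >= threshold.

    The comparison is strict: a pixel is kept only with *less than*
    ``threshold`` percent cloud cover.
    """
    cloud_score = np.asarray(cloud_score, dtype=float)
    if cloud_score.shape != scene.shape:
        raise ValueError("cloud score grid must match the scene shape")
    if np.nanmin(cloud_score) < 0 or np.nanmax(cloud_score) > 100:
        raise ValueError("cloud scores must lie in [0, 100]")
    keep = cloud_score < threshold
    return Scene(
        date=scene.date,
        blue=scene.blue,
        red=scene.red,
        nir=scene.nir,
        swir=scene.swir,
        valid=scene.valid & keep,
    )


def fill_gaps(series: IndexSeries, max_run: int = 3) -> IndexSeries:
    """Fill short temporal gaps per pixel by linear interpolation in date.

    Runs of 1..max_run consecutive missing scenes flanked by valid values are
    interpolated; longer runs and runs touching either end of the series stay
    missing. Originally valid values are never altered, so the operation is
    idempotent.
    """
    vals = series.values
    T = vals.shape[0]
    flat = vals.reshape(T, -1)
    valid = np.isfinite(flat)
    idx = np.arange(T)[:, None]

    prev = np.where(valid, idx, -1)
    np.maximum.accumulate(prev, axis=0, out=prev)
    nxt = np.where(valid[::-1], idx, -1)
    np.maximum.accumulate(nxt, axis=0, out=nxt)
    nxt = (T - 1) - nxt[::-1]  # -1 sentinel becomes T

    fillable = (~valid) & (prev >= 0) & (nxt <= T - 1) & ((nxt - prev - 1) <= max_run)
    if np.any(fillable):
        p = np.clip(prev, 0, T - 1)
        n = np.clip(nxt, 0, T - 1)
        vp = np.take_along_axis(flat, p, axis=0)
        vn = np.take_along_axis(flat, n, axis=0)
        dp = series.dates[p]
        dn = series.dates[n]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = (series.dates[:, None] - dp) / (dn - dp)
            interp = vp + (vn - vp) * frac
        flat = np.where(fillable, interp, flat)
    return IndexSeries(series.name, series.dates.copy(), flat.reshape(vals.shape))


def composite_window(focal_year: int) -> tuple[float, float]:
    """Seasonal compositing window: 1 Nov of the previous year up to (but
    excluding) 1 Nov of the focal year — i.e. through 31 October."""
    return date_value(focal_year - 1, 11, 1), date_value(focal_year, 11, 1)


def annual_composite(series: IndexSeries, focal_year: int, statistic: str = "mean") -> AnnualComposite:
    """Per-pixel seasonal-window statistic of an index for one focal year."""
    if statistic != "mean":
        raise ValueError("only the mean composite statistic is supported")
    lo, hi = composite_window(focal_year)
    if hi <= series.dates[0] or lo > series.dates[-1]:
        raise ValueError(f"composite window for {focal_year} lies outside the series span")
    sel = (series.dates >= lo) & (series.dates < hi)
    window_vals = series.values[sel]
    n_valid = np.isfinite(window_vals).sum(axis=0)
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(window_vals, axis=0) if window_vals.size else np.full(series.values.shape[1:], np.nan)
    mean = np.where(n_valid > 0, mean, np.nan)
    return AnnualComposite(series.name, focal_year, mean, (lo, hi), n_valid)
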