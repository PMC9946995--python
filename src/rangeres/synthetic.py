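"""Synthetic savanna landscape with controllable resistance and recovery.

The generator produces everything the downstream stages consume — gridded
rainfall with drought years, static anthropogenic covariates, latent
bare-ground dynamics, rendered multi-band reflectance scenes with cloud
dropouts, and point-intercept survey plots — together with the ground truth
needed to test whether the analysis recovers it.

The latent bare-ground fraction b of pixel i evolves annually as

    b[i, t] = clip01( b[i, t-1]
                      + delta_i * max(0, -A_t)                       # shock response
                      - rho_i * (b[i, t-1] - beta_i) * max(0, A_t)   # recovery pull
                      + gamma * (w_h h_i + w_l l_i + w_d[d_i])       # chronic pressure
                      + eps_it )                                      # process noise

where A_t is the pixel's standardized annual rainfall anomaly, beta_i the
undisturbed baseline cover, delta_i the susceptibility (inverse resistance)
and rho_i the fractional recovery rate. Dry shocks (A_t < 0) push cover up by
delta_i per unit anomaly; wet years pull it back towards baseline at rate
rho_i. The two scenario presets hold one of delta/rho spatially constant and
let the other vary, so "loss of resistance" and "loss of recovery" worlds are
distinguishable only through the dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from ._util import substream
from .spectral import Scene

__all__ = [
    "DESIGNATIONS",
    "WorldConfig",
    "PixelTruth",
    "RainfallSeries",
    "CoverSeries",
    "make_truth",
    "simulate_rainfall",
    "cover_step",
    "simulate_cover_dynamics",
    "render_year",
    "render_scenes",
    "stratify_sites",
    "sample_survey_plots",
    "generate_world",
]

#: Land-use designations in increasing order of grazing restriction; NONE is
#: the regression baseline.
DESIGNATIONS = ("NONE", "CCRO", "WMA", "NP")

# Fraction of annual rain falling in each calendar month (bimodal: short
# rains Nov-Jan, long rains Mar-May), summing to 1.
MONTHLY_RAIN_PROFILE = np.array(
    [0.12, 0.06, 0.13, 0.15, 0.10, 0.02, 0.01, 0.01, 0.02, 0.04, 0.16, 0.18]
)


@dataclass
class WorldConfig:
    """Defaults are the package's reference study conditions: a 21-year
    series (2000-2020) with four ~50% rainfall-deficit drought years, monthly
    scene sampling, and 10% independent cloud dropout."""

    grid_rows: int = 168
    grid_cols: int = 168
    years: tuple[int, ...] = tuple(range(2000, 2021))
    scenes_per_year: int = 12
    seed: int = 0
    shock_years: tuple[int, ...] = (2003, 2009, 2011, 2019)
    rain_mean_mm: float = 600.0
    rain_sd_mm: float = 20.0
    rain_gradient_sd_mm: float = 80.0
    rain_cell_sd_mm: float = 10.0
    shock_deficit: float = 0.5
    rain_rows: int = 4
    rain_cols: int = 4
    cloud_prob: float = 0.10
    reflectance_sd: float = 0.01
    dynamics_sd: float = 0.01
    pressure_scale: float = 0.001  # gamma, cover units per year
    w_human: float = 1.0
    w_livestock: float = 1.0
    w_designation: dict = field(
        default_factory=lambda: {"NONE": 0.5, "CCRO": 0.25, "WMA": 0.0, "NP": -0.5}
    )
    soil_endmember: tuple[float, float, float, float] = (0.12, 0.22, 0.28, 0.34)
    veg_endmember: tuple[float, float, float, float] = (0.04, 0.05, 0.45, 0.20)

    def __post_init__(self):
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if not self.years:
            raise ValueError("years must be non-empty")
        if not set(self.shock_years) <= set(self.years):
            raise ValueError("shock_years must be a subset of years")
        if not 0 <= self.cloud_prob <= 1:
            raise ValueError("cloud_prob must lie in [0, 1]")
        for name in ("rain_sd_mm", "rain_gradient_sd_mm", "rain_cell_sd_mm", "reflectance_sd", "dynamics_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for em in (self.soil_endmember, self.veg_endmember):
            if min(em) < 0 or max(em) > 1:
                raise ValueError("endmember reflectances must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid_rows, self.grid_cols


@dataclass
class PixelTruth:
    """Per-pixel latent parameters and static covariates (grid-of-arrays)."""

    baseline: np.ndarray  # beta, undisturbed bare-ground fraction in [0, 1]
    susceptibility: np.ndarray  # delta >= 0, cover gained per unit dry anomaly
    recovery_rate: np.ndarray  # rho in [0, 1], excess removed per unit wet anomaly
    phase: np.ndarray  # phenology peak as fraction of year, [0, 1)
    human_density: np.ndarray  # relative density, >= 0
    livestock_density: np.ndarray  # TLU-style relative density, >= 0
    designation: np.ndarray  # integer codes into DESIGNATIONS

    def __post_init__(self):
        if np.any(self.recovery_rate < 0) or np.any(self.recovery_rate > 1):
            raise ValueError("recovery_rate must lie in [0, 1]")
        if np.any(self.susceptibility < 0):
            raise ValueError("susceptibility must be non-negative")

    @property
    def designation_names(self) -> np.ndarray:
        return np.asarray(DESIGNATIONS)[self.designation]


@dataclass
class RainfallSeries:
    """Monthly rainfall (mm) on a coarse cell grid.

    Covers one year before the study period so previous-year accumulation
    windows are always computable.
    """

    years: np.ndarray  # (Y,) calendar years, ascending
    monthly: np.ndarray  # (Y, 12, rain_rows, rain_cols), mm

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.monthly = np.asarray(self.monthly, dtype=float)
        if np.any(self.monthly < 0):
            raise ValueError("rainfall must be non-negative")

    def annual_totals(self) -> np.ndarray:
        """Calendar-year totals, (Y, rain_rows, rain_cols)."""
        return self.monthly.sum(axis=1)

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not covered by the rainfall series")
        return int(idx[0])

    def anomalies(self, study_years) -> np.ndarray:
        """Per-cell standardized annual anomalies over the study years."""
        study_years = np.asarray(list(study_years), dtype=int)
        totals = self.annual_totals()
        sel = np.array([self.year_index(y) for y in study_years])
        t = totals[sel]
        mean = t.mean(axis=0)
        sd = t.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        return (t - mean) / sd

    def to_frame(self) -> pd.DataFrame:
        Y, M, R, C = self.monthly.shape
        yy, mm, rr, cc = np.meshgrid(
            self.years, np.arange(1, 13), np.arange(R), np.arange(C), indexing="ij"
        )
        return pd.DataFrame(
            {
                "year": yy.ravel(),
                "month": mm.ravel(),
                "cell_row": rr.ravel(),
                "cell_col": cc.ravel(),
                "rain_mm": self.monthly.ravel(),
            }
        )


@dataclass
class CoverSeries:
    """True bare-ground fraction per pixel and year."""

    years: np.ndarray  # (Y,)
    cover: np.ndarray  # (Y, rows, cols) in [0, 1]

    def for_year(self, year: int) -> np.ndarray:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not simulated")
        return self.cover[int(idx[0])]


def _smooth_field(rng: np.random.Generator, shape, sigma=None) -> np.ndarray:
    """Spatially smooth standard-normal field (unit variance, zero mean)."""
    if sigma is None:
        sigma = max(shape) / 12
    white = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    sd = sm.std()
    return (sm - sm.mean()) / (sd if sd > 0 else 1.0)


def make_truth(config: WorldConfig, scenario: str = "loss_of_resistance") -> PixelTruth:
    """Draw the latent pixel parameters for one of the two scenario presets.

    ``loss_of_resistance``: susceptibility delta varies smoothly across the
    landscape (0.02-0.12 per unit anomaly) while the recovery rate is a
    constant 0.5. ``loss_of_recovery``: delta is a constant 0.07 while rho
    varies smoothly (0.15-0.90). Baseline cover, phenology, covariates and
    designation patches are drawn identically in both.
    """
    if scenario not in ("loss_of_resistance", "loss_of_recovery"):
        raise ValueError(f"unknown scenario preset: {scenario!r}")
    rng = substream(config.seed, "truth")
    shape = config.shape
    beta = np.clip(0.28 + 0.08 * _smooth_field(rng, shape), 0.05, 0.5)
    u = stats.norm.cdf(_smooth_field(rng, shape))  # smooth uniform in (0, 1)
    if scenario == "loss_of_resistance":
        delta = 0.02 + 0.10 * u
        rho = np.full(shape, 0.5)
    else:
        delta = np.full(shape, 0.07)
        rho = 0.15 + 0.75 * u
    phase = np.mod(0.35 + 0.03 * _smooth_field(rng, shape), 1.0)
    human = np.exp(0.5 * _smooth_field(rng, shape) - 0.125)
    livestock = np.exp(0.5 * _smooth_field(rng, shape) - 0.125)
    dfield = _smooth_field(rng, shape)
    q = np.quantile(dfield, [0.15, 0.35, 0.50])
    designation = np.full(shape, DESIGNATIONS.index("NONE"), dtype=int)
    designation[dfield < q[2]] = DESIGNATIONS.index("CCRO")
    designation[dfield < q[1]] = DESIGNATIONS.index("WMA")
    designation[dfield < q[0]] = DESIGNATIONS.index("NP")
    return PixelTruth(beta, delta, rho, phase, human, livestock, designation)


def simulate_rainfall(config: WorldConfig, deficit: float | None = None) -> RainfallSeries:
    """Monthly rainfall with shock years at a ~``deficit`` fractional deficit.

    Annual totals combine a static spatial gradient (cell means around
    rain_mean_mm with sd rain_gradient_sd_mm), a landscape-wide interannual
    term (sd rain_sd_mm) — droughts are regionally coherent, so year-to-year
    variation is shared across cells — and small independent cell-year noise
    (sd rain_cell_sd_mm). Shock-year totals are reduced by a coherent
    shortfall of ``deficit * rain_mean_mm``. Totals are spread over
    months with a fixed bimodal profile. Covers years[0]-1 through
    years[-1]; the pre-study year is never a shock year.
    """
    if not config.years:
        raise ValueError("years must be non-empty")
    if deficit is None:
        deficit = config.shock_deficit
    rng = substream(config.seed, "rainfall")
    all_years = np.arange(min(config.years) - 1, max(config.years) + 1)
    shock = np.isin(all_years, list(config.shock_years))
    cell_shape = (config.rain_rows, config.rain_cols)
    gradient = config.rain_gradient_sd_mm * _smooth_field(rng, cell_shape, sigma=1.0) if config.rain_gradient_sd_mm > 0 else np.zeros(cell_shape)
    cell_mean = config.rain_mean_mm + gradient
    year_dev = config.rain_sd_mm * rng.standard_normal(all_years.size)
    # Drought deficit as a landscape-wide absolute shortfall: regional
    # droughts remove a coherent amount of moisture, so shock severity does
    # not scale with the static wet/dry gradient.
    shortfall = deficit * config.rain_mean_mm * shock.astype(float)
    totals = cell_mean[None, :, :] + (year_dev - shortfall)[:, None, None]
    if config.rain_cell_sd_mm > 0:
        totals = totals + config.rain_cell_sd_mm * rng.standard_normal((all_years.size,) + cell_shape)
    totals = np.clip(totals, 0.0, None)
    monthly = totals[:, None, :, :] * MONTHLY_RAIN_PROFILE[None, :, None, None]
    return RainfallSeries(all_years, monthly)


def _cell_of_pixel(config: WorldConfig) -> tuple[np.ndarray, np.ndarray]:
    rows = np.arange(config.grid_rows) * config.rain_rows // config.grid_rows
    cols = np.arange(config.grid_cols) * config.rain_cols // config.grid_cols
    return rows, cols


def cover_step(b_prev, anomaly, susceptibility, recovery_rate, baseline, pressure=0.0, noise=0.0):
    """One annual update of the bare-ground fraction (before the next year).

    b_next = clip01(b_prev + delta*max(0, -A) - rho*(b_prev - beta)*max(0, A)
                    + pressure + noise). A dry anomaly (A < 0) adds
    susceptibility-scaled bare ground; a wet anomaly pulls the excess over
    baseline back at the recovery rate. With A = +1 and rho = 1 the excess
    is removed completely in a single year.
    """
    a = np.asarray(anomaly, dtype=float)
    shock_push = np.asarray(susceptibility) * np.maximum(0.0, -a)
    recovery_pull = np.asarray(recovery_rate) * (np.asarray(b_prev) - np.asarray(baseline)) * np.maximum(0.0, a)
    return np.clip(b_prev + shock_push - recovery_pull + pressure + noise, 0.0, 1.0)


def simulate_cover_dynamics(
    truth: PixelTruth, rainfall: RainfallSeries, config: WorldConfig
) -> CoverSeries:
    """Iterate the bare-ground update rule over the study years.

    The initial state (year before the series) is the baseline cover. The
    rainfall anomaly of each pixel is that of its coarse rainfall cell,
    standardized per cell over the study period.
    """
    years = np.asarray(config.years, dtype=int)
    if not set(years) <= set(rainfall.years.tolist()):
        raise ValueError("rainfall series does not cover all study years")
    anom = rainfall.anomalies(years)  # (Y, rain_rows, rain_cols)
    prow, pcol = _cell_of_pixel(config)
    A = anom[:, prow[:, None], pcol[None, :]]  # (Y, rows, cols)
    w_d = np.array([config.w_designation[d] for d in DESIGNATIONS])
    pressure = config.pressure_scale * (
        config.w_human * truth.human_density
        + config.w_livestock * truth.livestock_density
        + w_d[truth.designation]
    )
    rng = substream(config.seed, "dynamics")
    b = truth.baseline.copy()
    cover = np.empty((years.size,) + config.shape)
    for t in range(years.size):
        eps = (
            config.dynamics_sd * rng.standard_normal(config.shape)
            if config.dynamics_sd > 0
            else 0.0
        )
        b = cover_step(b, A[t], truth.susceptibility, truth.recovery_rate, truth.baseline, pressure, eps)
        cover[t] = b
    return CoverSeries(years, cover)


def render_year(
    cover: CoverSeries, truth: PixelTruth, config: WorldConfig, year: int
) -> list[Scene]:
    """Render one year's scenes by linear soil/vegetation mixing.

    Per pixel, reflectance = b*soil + (1-b)*g(t)*veg + noise with seasonal
    greenness g(t) = 0.5*(1 + cos(2*pi*(t - phase))). Pixels go invalid
    (cloud) independently with probability cloud_prob.
    """
    b = cover.for_year(year)
    rng = substream(config.seed, f"scenes/{year}")
    soil = np.asarray(config.soil_endmember)
    veg = np.asarray(config.veg_endmember)
    scenes = []
    for j in range(config.scenes_per_year):
        frac = (j + 0.5) / config.scenes_per_year
        g = 0.5 * (1.0 + np.cos(2 * np.pi * (frac - truth.phase)))
        bands = []
        for k in range(4):
            refl = b * soil[k] + (1.0 - b) * g * veg[k]
            if config.reflectance_sd > 0:
                refl = refl + config.reflectance_sd * rng.standard_normal(b.shape)
            bands.append(np.clip(refl, 0.0, 1.0))
        valid = rng.random(b.shape) >= config.cloud_prob
        scenes.append(
            Scene(date=year + frac, blue=bands[0], red=bands[1], nir=bands[2], swir=bands[3], valid=valid)
        )
    return scenes


def render_scenes(cover: CoverSeries, truth: PixelTruth, config: WorldConfig) -> list[Scene]:
    """Render the full scene series (all study years)."""
    scenes: list[Scene] = []
    for year in cover.years:
        scenes.extend(render_year(cover, truth, config, int(year)))
    return scenes


def _quantile_bins(layer: np.ndarray, n_bins: int, name: str) -> np.ndarray:
    if np.ptp(layer) == 0:
        warnings.warn(f"{name} layer is constant; using a single stratification bin")
        return np.zeros(layer.shape, dtype=int)
    edges = np.quantile(layer, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.digitize(layer, edges)


def stratify_sites(
    rainfall_mean: np.ndarray,
    greenness_mean: np.ndarray,
    landcover: np.ndarray,
    n_rain_bins: int = 2,
    n_green_bins: int = 2,
) -> np.ndarray:
    """Stratum label per cell: the cross of quantile-binned mean rainfall,
    quantile-binned mean greenness, and the landcover class."""
    rainfall_mean = np.asarray(rainfall_mean, dtype=float)
    if rainfall_mean.shape != np.shape(greenness_mean) or rainfall_mean.shape != np.shape(landcover):
        raise ValueError("stratification layers must share the sampling grid")
    rbin = _quantile_bins(rainfall_mean, n_rain_bins, "rainfall")
    gbin = _quantile_bins(np.asarray(greenness_mean, float), n_green_bins, "greenness")
    land = np.asarray(landcover)
    land_classes, land_idx = np.unique(land, return_inverse=True)
    land_idx = land_idx.reshape(land.shape)
    return (rbin * n_green_bins + gbin) * land_classes.size + land_idx


def sample_survey_plots(
    cover: CoverSeries,
    strata: np.ndarray,
    n_plots: int,
    years,
    seed: int,
    cell_size: int = 7,
    n_points: int = 100,
) -> pd.DataFrame:
    """Point-intercept survey plots allocated evenly across strata.

    ``strata`` labels the survey-cell grid (each cell covering
    ``cell_size`` x ``cell_size`` fine pixels); a plot sits at its cell's
    centre pixel. No two plots occupy adjacent (8-neighbour) cells. Each
    plot records bare ground at ``n_points`` points: bare_points ~
    Binomial(n_points, true cover at the plot pixel in the plot year).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5EED]))
    strata = np.asarray(strata)
    years = [int(y) for y in np.atleast_1d(years)]
    labels = np.unique(strata)
    base, rem = divmod(int(n_plots), labels.size)
    quotas = {lab: base + (1 if i < rem else 0) for i, lab in enumerate(labels)}

    selected: list[tuple[int, int, int]] = []  # (cell_row, cell_col, stratum)
    taken = np.zeros(strata.shape, dtype=bool)
    for lab in labels:
        cand = np.argwhere(strata == lab)
        rng.shuffle(cand)
        got = 0
        for r, c in cand:
            if got == quotas[lab]:
                break
            r0, r1 = max(r - 1, 0), min(r + 2, strata.shape[0])
            c0, c1 = max(c - 1, 0), min(c + 2, strata.shape[1])
            if taken[r0:r1, c0:c1].any():
                continue
            taken[r, c] = True
            selected.append((int(r), int(c), int(lab)))
            got += 1
        if got < quotas[lab]:
            raise ValueError(
                f"stratum {lab}: only {got} non-adjacent cells available, {quotas[lab]} requested"
            )

    half = cell_size // 2
    rows = []
    for r, c, lab in selected:
        year = int(rng.choice(years))
        pr = min(r * cell_size + half, cover.cover.shape[1] - 1)
        pc = min(c * cell_size + half, cover.cover.shape[2] - 1)
        p = float(cover.for_year(year)[pr, pc])
        bare = int(rng.binomial(n_points, p))
        rows.append(
            {
                "cell_row": r,
                "cell_col": c,
                "row": pr,
                "col": pc,
                "year": year,
                "stratum": lab,
                "n_points": n_points,
                "bare_points": bare,
                "bare_fraction": bare / n_points,
                "b_true": p,
            }
        )
    return pd.DataFrame(rows)


def generate_world(config: WorldConfig, scenario: str = "loss_of_resistance") -> dict:
    """Convenience bundle: truth, rainfall and cover dynamics for a preset."""
    truth = make_truth(config, scenario)
    rainfall = simulate_rainfall(config)
    cover = simulate_cover_dynamics(truth, rainfall, config)
    return {"config": config, "scenario": scenario, "truth": truth, "rainfall": rainfall, "cover": cover}
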