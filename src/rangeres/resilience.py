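"""Resistance and recovery analysis of a bare-ground score series.

Pixels are aggregated to a coarse grid, classed into most/medium/least
degraded tertiles from the final three years, and shock years are detected
as the steepest landscape-wide increases in the median score. Resistance is
the per-pixel score increase in a shock year (larger increase = lower
resistance); recovery is the decrease in the following year, measured in
absolute units or relative to the shock-year increase. Class contrasts use
two-way ANOVA with Tukey-adjusted pairwise comparisons, and the per-year
contrasts feed a mechanism verdict: loss of resistance, loss of recovery,
mixed, or indeterminate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._util import substream

__all__ = [
    "CLASS_NAMES",
    "ClassMap",
    "ShockSet",
    "aggregate_to_coarse",
    "classify_tertiles",
    "detect_shock_years",
    "relative_recovery",
    "resistance_by_class",
    "recovery_by_class",
    "compare_classes",
    "tukey_by_year",
    "mechanism_verdict",
    "analyze_resilience",
]

CLASS_NAMES = ("least", "medium", "most")

#: Relative recovery is undefined when the shock-year increase is this small
#: (normalized-score units); the ratio blows up on near-zero shocks.
RELATIVE_RECOVERY_GUARD = 0.01


def aggregate_to_coarse(values: np.ndarray, block: int = 7, statistic: str = "median") -> np.ndarray:
    """Non-overlapping block aggregation (origin-anchored) with NaN handling.

    ``values`` may be (rows, cols) or (years, rows, cols). Each coarse pixel
    is the median (or mean) of its block's finite fine pixels; an all-masked
    block is NaN. Incomplete edge blocks are discarded.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    arr = np.asarray(values, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    Y, R, C = arr.shape
    r, c = R // block, C // block
    trimmed = arr[:, : r * block, : c * block].reshape(Y, r, block, c, block)
    stat = {"median": np.nanmedian, "mean": np.nanmean}[statistic]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        out = stat(trimmed.transpose(0, 1, 3, 2, 4).reshape(Y, r, c, block * block), axis=-1)
    return out[0] if squeeze else out


@dataclass
class ClassMap:
    """Degradation tertile labels per coarse pixel.

    labels: -1 for masked pixels, otherwise an index into CLASS_NAMES
    ('least' < 'medium' < 'most' degraded). The basis statistic is the
    per-pixel median normalized score over the final years.
    """

    labels: np.ndarray
    basis: np.ndarray
    final_years: tuple[int, ...]

    def mask(self, name: str) -> np.ndarray:
        return self.labels == CLASS_NAMES.index(name)


def classify_tertiles(years, normalized: np.ndarray, final_years=None) -> ClassMap:
    """Split pixels into even-sized most/medium/least degraded classes.

    The basis is the per-pixel median normalized score over the final three
    years (default: the last three of ``years``). Labels are assigned by
    rank, so class sizes are balanced to within one pixel; ties are broken
    by pixel index (row-major, stable sort).
    """
    years = np.asarray(years, dtype=int)
    if final_years is None:
        final_years = tuple(int(y) for y in years[-3:])
    final_years = tuple(int(y) for y in final_years)
    sel = np.isin(years, final_years)
    if sel.sum() != len(final_years):
        raise ValueError(f"final years {final_years} not all present in the series")
    basis = np.nanmedian(normalized[sel], axis=0)
    flat = basis.ravel()
    ok = np.isfinite(flat)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 valid pixels to form tertiles")
    order = np.argsort(flat[ok], kind="stable")
    labels = np.full(flat.shape, -1, dtype=int)
    thirds = np.array_split(np.flatnonzero(ok)[order], 3)
    for k, idx in enumerate(thirds):
        labels[idx] = k
    return ClassMap(labels.reshape(basis.shape), basis, final_years)


@dataclass
class ShockSet:
    """The k years with the largest landscape-median score increase."""

    years: np.ndarray  # shock years, ascending
    increases: np.ndarray  # median score increase of each shock year
    weak: np.ndarray  # True where the "increase" was actually <= 0
    median_series: pd.Series = field(repr=False, default=None)  # type: ignore[assignment]


def detect_shock_years(years, normalized: np.ndarray, k: int = 4) -> ShockSet:
    """Detect shock years from year-over-year jumps of the landscape median.

    The landscape median of the normalized score is differenced; the k most
    positive differences mark shock years (labelled by the later year of
    each pair). Non-positive selected differences are flagged weak.
    """
    years = np.asarray(years, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.array([np.nanmedian(normalized[i]) for i in range(len(years))])
    diffs = np.diff(med)
    if k >= diffs.size or k < 1:
        raise ValueError(f"k={k} incompatible with {diffs.size} year-over-year differences")
    top = np.argsort(diffs, kind="stable")[::-1][:k]
    top = np.sort(top)
    return ShockSet(
        years=years[top + 1],
        increases=diffs[top],
        weak=diffs[top] <= 0,
        median_series=pd.Series(med, index=years),
    )


def relative_recovery(delta_shock, delta_rec, guard: float = RELATIVE_RECOVERY_GUARD):
    """Proportion of the shock-year decline that returns in the recovery year.

    1 = total recovery, 0 = no recovery, < 0 = continued decline, > 1 = net
    improvement beyond the pre-shock state. NaN where |delta_shock| < guard.
    """
    delta_shock = np.asarray(delta_shock, dtype=float)
    delta_rec = np.asarray(delta_rec, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = -delta_rec / delta_shock
    return np.where(np.abs(delta_shock) >= guard, rel, np.nan)


def _bootstrap_median_ci(values: np.ndarray, rng, n_boot: int = 1000, level: float = 0.95):
    values = values[np.isfinite(values)]
    if values.size == 0:
        return np.nan, np.nan, np.nan
    med = float(np.median(values))
    boots = np.median(
        values[rng.integers(0, values.size, size=(n_boot, values.size))], axis=1
    )
    alpha = (1 - level) / 2
    return med, float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha))


def _group_summary(per_class: dict[str, np.ndarray], seed: int, n_boot: int) -> pd.DataFrame:
    rows = []
    rng = substream(seed, "bootstrap-ci")
    for name in CLASS_NAMES:
        vals = per_class[name]
        med, lo, hi = _bootstrap_median_ci(vals, rng, n_boot=n_boot)
        rows.append(
            {
                "class": name,
                "median": med,
                "ci_lo": lo,
                "ci_hi": hi,
                "n": int(np.isfinite(vals).sum()),
            }
        )
    return pd.DataFrame(rows)


def _deltas(years, normalized, shock_year):
    years = np.asarray(years, dtype=int)
    idx = np.flatnonzero(years == int(shock_year))
    if idx.size == 0:
        raise ValueError(f"shock year {shock_year} not in the series")
    s = int(idx[0])
    if s == 0:
        raise ValueError(f"shock year {shock_year} has no preceding year")
    d_shock = normalized[s] - normalized[s - 1]
    d_rec = None
    if s + 1 < len(years):
        d_rec = normalized[s + 1] - normalized[s]
    return d_shock, d_rec


def resistance_by_class(years, normalized, class_map: ClassMap, shock_year: int, seed: int = 0, n_boot: int = 1000):
    """Shock-year score increases grouped by degradation class.

    Larger increases mean lower resistance. Returns per-class pixel values
    and a bootstrap median-CI summary.
    """
    d_shock, _ = _deltas(years, normalized, shock_year)
    per_class = {}
    for k, name in enumerate(CLASS_NAMES):
        m = class_map.labels == k
        if not m.any():
            raise ValueError(f"class {name!r} is empty")
        per_class[name] = d_shock[m]
    summary = _group_summary(per_class, seed, n_boot)
    summary.insert(0, "year", int(shock_year))
    summary.insert(1, "metric", "delta_shock")
    return {"values": per_class, "summary": summary}


def recovery_by_class(
    years,
    normalized,
    class_map: ClassMap,
    shock_year: int,
    mode: str = "absolute",
    seed: int = 0,
    n_boot: int = 1000,
):
    """Post-shock recovery grouped by degradation class.

    absolute mode: -(score[s+1] - score[s]), units recovered; relative mode:
    the proportion of the shock-year increase recovered (guarded against
    near-zero shocks).
    """
    if mode not in ("absolute", "relative"):
        raise ValueError("mode must be 'absolute' or 'relative'")
    d_shock, d_rec = _deltas(years, normalized, shock_year)
    if d_rec is None:
        raise ValueError(f"shock year {shock_year} is the final year; no recovery year exists")
    value = -d_rec if mode == "absolute" else relative_recovery(d_shock, d_rec)
    per_class = {}
    for k, name in enumerate(CLASS_NAMES):
        m = class_map.labels == k
        if not m.any():
            raise ValueError(f"class {name!r} is empty")
        per_class[name] = value[m]
    summary = _group_summary(per_class, seed, n_boot)
    summary.insert(0, "year", int(shock_year))
    summary.insert(1, "metric", f"{mode}_recovery")
    return {"values": per_class, "summary": summary}


def compare_classes(values, class_labels, year_labels, alpha: float = 0.05) -> dict:
    """Two-way ANOVA (class x year) with marginal means and Tukey contrasts.

    Returns the ANOVA table, per-class estimated marginal means (mean of
    cell means, robust to mild imbalance), Tukey-adjusted pairwise class
    comparisons flagged at ``alpha``, and a degeneracy flag for a constant
    response. Raises on an empty design cell, naming it.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "cls": np.asarray(class_labels).astype(str),
            "year": np.asarray(year_labels).astype(str),
        }
    ).dropna(subset=["value"])
    counts = df.groupby(["cls", "year"], sort=True).size()
    full = pd.MultiIndex.from_product([df["cls"].unique(), df["year"].unique()])
    missing = [cell for cell in full if cell not in counts.index]
    if missing:
        raise ValueError(f"empty design cell (class, year): {missing[0]}")
    degenerate = bool(np.ptp(df["value"].to_numpy()) == 0)
    if degenerate:
        anova = None
        tukey = None
    else:
        fit = smf.ols("value ~ C(cls) * C(year)", data=df).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        tk = pairwise_tukeyhsd(df["value"], df["cls"], alpha=alpha)
        tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    cell_means = df.groupby(["cls", "year"], sort=True)["value"].mean()
    marginal = cell_means.groupby(level="cls").mean().rename("emmean")
    return {"anova": anova, "marginal_means": marginal, "tukey": tukey, "degenerate": degenerate, "alpha": alpha}


def tukey_by_year(per_class_values: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise class comparisons for a single year's values."""
    vals, labs = [], []
    for name, v in per_class_values.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        vals.append(v)
        labs.extend([name] * v.size)
    allv = np.concatenate(vals)
    if np.ptp(allv) == 0:
        return pd.DataFrame(columns=["group1", "group2", "meandiff", "p-adj", "reject"])
    tk = pairwise_tukeyhsd(allv, np.array(labs), alpha=alpha)
    return pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])


def _most_vs_least(tukey: pd.DataFrame):
    """(mean(most) - mean(least), reject flag) from a Tukey table."""
    for _, row in tukey.iterrows():
        pair = {row["group1"], row["group2"]}
        if pair == {"most", "least"}:
            diff = float(row["meandiff"])
            if row["group1"] == "most":  # meandiff = mean(group2) - mean(group1)
                diff = -diff
            return diff, bool(row["reject"])
    return np.nan, False


def mechanism_verdict(
    resistance_results: list[dict],
    recovery_results: list[dict],
    alpha: float = 0.05,
    min_effect: float = 0.005,
) -> dict:
    """Decide the degradation mechanism from per-shock-year class contrasts.

    loss_of_resistance: the most-degraded class shows a larger shock-year
    increase in a majority of shock years, while its absolute recovery is
    *not* smaller in a majority of recovery years. loss_of_recovery: the
    mirror pattern. Both majorities -> mixed; neither -> indeterminate.

    A year counts only if the most-vs-least contrast is both Tukey
    significant at ``alpha`` *and* at least ``min_effect`` normalized-score
    units in the right direction: with hundreds of pixels per class,
    significance alone is nearly inevitable, so an effect-size floor keeps
    ecologically negligible contrasts from driving the verdict.
    """
    if len(resistance_results) < 2:
        raise ValueError("need at least 2 analyzed shock years")
    res_flags, rec_flags, detail = [], [], []
    for res in resistance_results:
        diff, sig = _most_vs_least(tukey_by_year(res["values"], alpha=alpha))
        res_flags.append(bool(sig and diff > min_effect))
        detail.append({"year": int(res["summary"]["year"].iloc[0]), "metric": "delta_shock", "most_minus_least": diff, "significant": sig})
    for rec in recovery_results:
        diff, sig = _most_vs_least(tukey_by_year(rec["values"], alpha=alpha))
        rec_flags.append(bool(sig and diff < -min_effect))
        detail.append({"year": int(rec["summary"]["year"].iloc[0]), "metric": "absolute_recovery", "most_minus_least": diff, "significant": sig})
    res_majority = sum(res_flags) > len(res_flags) / 2
    rec_majority = sum(rec_flags) > len(rec_flags) / 2
    if res_majority and rec_majority:
        verdict = "mixed"
    elif res_majority:
        verdict = "loss_of_resistance"
    elif rec_majority:
        verdict = "loss_of_recovery"
    else:
        verdict = "indeterminate"
    return {
        "verdict": verdict,
        "resistance_years_significant": int(sum(res_flags)),
        "recovery_years_significant": int(sum(rec_flags)),
        "n_shock_years": len(res_flags),
        "n_recovery_years": len(rec_flags),
        "detail": detail,
        "alpha": alpha,
    }


def analyze_resilience(
    years,
    normalized_coarse: np.ndarray,
    k_shocks: int = 4,
    final_years=None,
    alpha: float = 0.05,
    seed: int = 0,
    n_boot: int = 200,
) -> dict:
    """Full resilience stage on a coarse normalized score series.

    Classifies tertiles, detects shock years, computes per-class resistance
    and absolute/relative recovery with bootstrap CIs, and returns the
    mechanism verdict. Shock years without a following year in the series
    are dropped from the recovery side.
    """
    years = np.asarray(years, dtype=int)
    class_map = classify_tertiles(years, normalized_coarse, final_years=final_years)
    shocks = detect_shock_years(years, normalized_coarse, k=k_shocks)
    resistance, recovery_abs, recovery_rel = [], [], []
    for sy in shocks.years:
        resistance.append(resistance_by_class(years, normalized_coarse, class_map, int(sy), seed=seed, n_boot=n_boot))
        if int(sy) < years[-1]:
            recovery_abs.append(recovery_by_class(years, normalized_coarse, class_map, int(sy), "absolute", seed=seed, n_boot=n_boot))
            recovery_rel.append(recovery_by_class(years, normalized_coarse, class_map, int(sy), "relative", seed=seed, n_boot=n_boot))
    verdict = mechanism_verdict(resistance, recovery_abs, alpha=alpha)
    summary = pd.concat(
        [r["summary"] for r in resistance + recovery_abs + recovery_rel], ignore_index=True
    )
    return {
        "class_map": class_map,
        "shocks": shocks,
        "resistance": resistance,
        "recovery_absolute": recovery_abs,
        "recovery_relative": recovery_rel,
        "summary": summary,
        "verdict": verdict,
    }
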