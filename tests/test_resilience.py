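"""Aggregation, tertile classes, shock detection, recovery statistics, ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rangeres.resilience import (
    CLASS_NAMES,
    aggregate_to_coarse,
    classify_tertiles,
    compare_classes,
    detect_shock_years,
    mechanism_verdict,
    recovery_by_class,
    relative_recovery,
    resistance_by_class,
)


class TestAggregateToCoarse:
    def test_constant_block(self):
        out = aggregate_to_coarse(np.full((14, 14), 0.7), block=7)
        assert out.shape == (2, 2) and np.allclose(out, 0.7)

    def test_median_robust_to_single_outlier(self):
        block = np.zeros((7, 7))
        block[3, 3] = 1.0
        assert aggregate_to_coarse(block, block=7).item() == 0.0

    def test_matches_sort_and_middle_oracle(self):
        rng = np.random.default_rng(8)
        grid = rng.normal(size=(21, 21))
        out = aggregate_to_coarse(grid, block=7)
        for i in range(3):
            for j in range(3):
                vals = np.sort(grid[7 * i : 7 * i + 7, 7 * j : 7 * j + 7].ravel())
                assert out[i, j] == pytest.approx(np.median(vals))

    def test_all_masked_block_is_nan(self):
        grid = np.full((7, 14), np.nan)
        grid[:, 7:] = 1.0
        out = aggregate_to_coarse(grid, block=7)
        assert np.isnan(out[0, 0]) and out[0, 1] == 1.0

    def test_edge_remainder_discarded(self):
        out = aggregate_to_coarse(np.ones((16, 9)), block=7)
        assert out.shape == (2, 1)


class TestClassifyTertiles:
    def _series(self, basis):
        basis = np.asarray(basis, dtype=float)
        vals = np.broadcast_to(basis, (3,) + basis.shape).copy()
        return np.array([2018, 2019, 2020]), vals

    def test_ranks_1_to_9(self):
        years, vals = self._series(np.arange(1.0, 10.0).reshape(3, 3))
        cm = classify_tertiles(years, vals)
        flat = cm.labels.ravel()
        assert [CLASS_NAMES[k] for k in flat[:3]] == ["least"] * 3
        assert [CLASS_NAMES[k] for k in flat[3:6]] == ["medium"] * 3
        assert [CLASS_NAMES[k] for k in flat[6:]] == ["most"] * 3

    def test_ties_still_balanced(self):
        years, vals = self._series(np.zeros((4, 3)))
        cm = classify_tertiles(years, vals)
        sizes = [(cm.labels == k).sum() for k in range(3)]
        assert max(sizes) - min(sizes) <= 1

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        basis = rng.normal(size=(5, 4))
        years, vals = self._series(basis)
        base = classify_tertiles(years, vals).labels
        for f in (np.exp, lambda x: 3 * x + 1, lambda x: x**3):
            _, tv = self._series(f(basis))
            np.testing.assert_array_equal(classify_tertiles(years, tv).labels, base)

    def test_reversed_presentation_gives_identical_labels(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(6, 6))
        years, vals = self._series(basis)
        a = classify_tertiles(years, vals).labels
        b = classify_tertiles(years, vals[:, ::-1, ::-1]).labels[::-1, ::-1]
        np.testing.assert_array_equal(a, b)

    def test_too_few_pixels_rejected(self):
        years, vals = self._series(np.zeros((1, 2)))
        with pytest.raises(ValueError, match="at least 3"):
            classify_tertiles(years, vals)


class TestDetectShockYears:
    def _series(self, medians, start=2000):
        years = np.arange(start, start + len(medians))
        vals = np.asarray(medians)[:, None, None] * np.ones((1, 2, 2))
        return years, vals

    def test_largest_step_detected(self):
        years, vals = self._series([0.2, 0.5, 0.4, 0.6])
        shocks = detect_shock_years(years, vals, k=1)
        assert shocks.years.tolist() == [2001]
        assert shocks.increases[0] == pytest.approx(0.3)
        assert not shocks.weak[0]

    def test_monotone_decline_flags_weak_shock(self):
        years, vals = self._series([0.9, 0.7, 0.6, 0.2])
        shocks = detect_shock_years(years, vals, k=1)
        assert shocks.years.tolist() == [2002]  # least negative step
        assert shocks.weak[0]

    def test_k_too_large_rejected(self):
        years, vals = self._series([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="k="):
            detect_shock_years(years, vals, k=2)


class TestRelativeRecovery:
    """The four caption identities: 1 total, 0 none, <0 continued decline,
    >1 net improvement; plus the near-zero-shock guard."""

    @pytest.mark.parametrize(
        "d_shock,d_rec,expected",
        [
            (0.2, -0.2, 1.0),
            (0.2, 0.0, 0.0),
            (0.2, 0.1, -0.5),
            (0.2, -0.3, 1.5),
        ],
    )
    def test_caption_identities(self, d_shock, d_rec, expected):
        assert relative_recovery(d_shock, d_rec).item() == pytest.approx(expected, abs=1e-15)

    def test_near_zero_shock_masked(self):
        assert np.isnan(relative_recovery(0.005, -0.002))
        assert np.isfinite(relative_recovery(0.011, -0.002))


class TestByClassSummaries:
    def _setup(self):
        years = np.arange(2000, 2004)
        rng = np.random.default_rng(0)
        vals = rng.random((4, 6, 6))
        cm = classify_tertiles(years[-3:], vals[-3:], final_years=years[-3:].tolist())
        return years, vals, cm

    def test_identical_pixels_identical_class_medians(self):
        years = np.arange(2000, 2004)
        vals = np.tile(np.array([0.1, 0.4, 0.3, 0.35])[:, None, None], (1, 6, 6))
        cm = classify_tertiles(years[-3:], vals[-3:], final_years=years[-3:].tolist())
        out = resistance_by_class(years, vals, cm, 2001)
        meds = out["summary"]["median"]
        assert meds.nunique() == 1

    def test_recovery_final_year_rejected(self):
        years, vals, cm = self._setup()
        with pytest.raises(ValueError, match="final year"):
            recovery_by_class(years, vals, cm, 2003)

    def test_summary_schema(self):
        years, vals, cm = self._setup()
        out = recovery_by_class(years, vals, cm, 2001, mode="relative", n_boot=50)
        assert set(out["summary"].columns) == {"year", "metric", "class", "median", "ci_lo", "ci_hi", "n"}
        assert (out["summary"]["metric"] == "relative_recovery").all()


def _anova_oracle_F(values, cls, year):
    """Brute-force balanced two-way ANOVA F for the class factor."""
    values = np.asarray(values, dtype=float)
    classes, years = np.unique(cls), np.unique(year)
    grand = values.mean()
    n_per_class = [np.sum(cls == c) for c in classes]
    ss_class = sum(n * (values[cls == c].mean() - grand) ** 2 for c, n in zip(classes, n_per_class))
    df_class = len(classes) - 1
    ss_err, df_err = 0.0, 0
    for c in classes:
        for y in years:
            cell = values[(cls == c) & (year == y)]
            ss_err += ((cell - cell.mean()) ** 2).sum()
            df_err += len(cell) - 1
    return (ss_class / df_class) / (ss_err / df_err)


class TestCompareClasses:
    def _planted(self, seed=0, effect=1.0, sd=0.1, n=50):
        rng = np.random.default_rng(seed)
        rows = []
        for c, shift in (("a", 0.0), ("b", effect)):
            for y in ("y1", "y2"):
                for v in shift + sd * rng.standard_normal(n):
                    rows.append((v, c, y))
        vals, cls, yr = map(np.array, zip(*rows))
        return vals, cls, yr

    def test_class_F_matches_sum_of_squares_oracle(self):
        vals, cls, yr = self._planted()
        out = compare_classes(vals, cls, yr)
        got = float(out["anova"].loc["C(cls)", "F"])
        assert got == pytest.approx(_anova_oracle_F(vals, cls, yr), rel=1e-8)

    def test_marginal_means_recover_planted_effect(self):
        vals, cls, yr = self._planted()
        mm = compare_classes(vals, cls, yr)["marginal_means"]
        assert mm["b"] - mm["a"] == pytest.approx(1.0, abs=0.05)

    def test_constant_response_flagged_degenerate(self):
        vals = np.zeros(40)
        cls = np.repeat(["a", "b"], 20)
        yr = np.tile(np.repeat(["y1", "y2"], 10), 2)
        out = compare_classes(vals, cls, yr)
        assert out["degenerate"] and out["anova"] is None

    def test_empty_cell_named_in_error(self):
        vals, cls, yr = self._planted()
        keep = ~((cls == "b") & (yr == "y2"))
        with pytest.raises(ValueError, match=r"\('b', 'y2'\)"):
            compare_classes(vals[keep], cls[keep], yr[keep])

    def test_permuting_labels_destroys_significance(self):
        vals, cls, yr = self._planted(effect=1.0)
        rng = np.random.default_rng(11)
        insignificant = 0
        for _ in range(20):
            out = compare_classes(vals, rng.permutation(cls), yr)
            insignificant += float(out["anova"].loc["C(cls)", "PR(>F)"]) > 0.05
        assert insignificant >= 18


class TestMechanismVerdict:
    def test_requires_two_shock_years(self):
        with pytest.raises(ValueError, match="2"):
            mechanism_verdict([{}], [])

    def test_shuffled_classes_indeterminate(self):
        # strong per-class structure destroyed by shuffling the labels
        rng = np.random.default_rng(4)
        years = np.arange(2000, 2006)
        ramp = np.linspace(0, 1, 64).reshape(8, 8)
        vals = np.stack([ramp * (0.3 + 0.1 * t) + 0.01 * rng.random((8, 8)) for t in range(6)])
        cm = classify_tertiles(years[-3:], vals[-3:], final_years=years[-3:].tolist())
        cm.labels = rng.permutation(cm.labels.ravel()).reshape(cm.labels.shape)
        res = [resistance_by_class(years, vals, cm, y, n_boot=20) for y in (2002, 2004)]
        rec = [recovery_by_class(years, vals, cm, y, n_boot=20) for y in (2002, 2004)]
        out = mechanism_verdict(res, rec)
        assert out["verdict"] == "indeterminate"
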