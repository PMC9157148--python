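"""Equivalent-ellipse morphometry and the strain-level statistics."""

import numpy as np
import pytest
from scipy import stats
from skimage import draw

from yeastburden import (
    bonferroni_adjust,
    dead_cell_fraction,
    elongation_property_correlation,
    extract_shapes,
    levene_test,
    sample_cells,
    strain_summary,
)
from yeastburden.morphology import StrainMorphology


def disk_mask(radius=20, pad=10):
    size = 2 * (radius + pad)
    mask = np.zeros((size, size), dtype=np.int32)
    rr, cc = draw.disk((size // 2, size // 2), radius)
    mask[rr, cc] = 1
    return mask


def ellipse_mask(a=40, b=10, rotation=0.0, pad=12):
    # generic (subpixel) center: integer-aligned axis-parallel ellipses are a
    # measure-zero worst case of pixel-center digitization
    size = 2 * int(a + pad)
    mask = np.zeros((size, size), dtype=np.int32)
    rr, cc = draw.ellipse(size / 2 + 0.5, size / 2 + 0.3, a, b, rotation=rotation)
    mask[rr, cc] = 1
    return mask


def brute_force_levene(groups, center=np.mean):
    """Direct evaluation of the W formula, independent of the library path."""
    z = [np.abs(np.asarray(g, float) - center(g)) for g in groups]
    k = len(z)
    N = sum(len(zi) for zi in z)
    zbar = np.concatenate(z).mean()
    num = sum(len(zi) * (zi.mean() - zbar) ** 2 for zi in z)
    den = sum(((zi - zi.mean()) ** 2).sum() for zi in z)
    W = (N - k) / (k - 1) * num / den
    p = stats.f.sf(W, k - 1, N - k)
    return W, p


class TestExtractShapes:
    def test_digitized_disk(self):
        shapes = extract_shapes(disk_mask(radius=20))
        assert len(shapes) == 1
        s = shapes[0]
        assert 1.0 <= s.axis_ratio <= 1.02
        assert s.major_axis_length == pytest.approx(40.0, rel=0.02)

    @pytest.mark.parametrize("rotation", [0.0, 0.4, np.pi / 4, 1.2])
    def test_digitized_ellipse_ratio(self, rotation):
        shapes = extract_shapes(ellipse_mask(40, 10, rotation))
        assert len(shapes) == 1
        assert shapes[0].axis_ratio == pytest.approx(4.0, rel=0.02)

    def test_rotation_by_90_degrees_is_exact(self):
        mask = ellipse_mask(40, 10, rotation=0.3)
        r0 = extract_shapes(mask)[0]
        r90 = extract_shapes(np.ascontiguousarray(np.rot90(mask)))[0]
        assert r90.axis_ratio == pytest.approx(r0.axis_ratio, rel=1e-12)

    def test_min_area_filter(self):
        mask = disk_mask(radius=20)
        mask[2:4, 2:4] = 2  # 4-pixel speck
        with pytest.warns(UserWarning, match="dropped 1"):
            shapes = extract_shapes(mask, min_area=50)
        assert [s.label for s in shapes] == [1]

    def test_border_exclusion(self):
        mask = np.zeros((60, 60), dtype=np.int32)
        rr, cc = draw.disk((0, 30), 12, shape=mask.shape)
        mask[rr, cc] = 1  # touches top edge
        rr, cc = draw.disk((35, 30), 10)
        mask[rr, cc] = 2
        with pytest.warns(UserWarning):
            shapes = extract_shapes(mask, exclude_border=True)
        assert [s.label for s in shapes] == [2]
        both = extract_shapes(mask, exclude_border=False)
        assert sorted(s.label for s in both) == [1, 2]

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="no regions"):
            assert extract_shapes(np.zeros((20, 20), dtype=np.int32)) == []

    def test_non_integer_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_shapes(np.zeros((5, 5), dtype=float))


class TestSampleCells:
    def make_shapes(self, n):
        return extract_shapes(disk_mask()) * n  # n copies of one disk shape

    def test_reproducible_and_subset(self):
        shapes = self.make_shapes(250)
        a = sample_cells(shapes, n=100, seed=3)
        b = sample_cells(shapes, n=100, seed=3)
        assert len(a) == 100 and a == b
        assert all(s in shapes for s in a)

    def test_shortfall_returns_all_with_warning(self):
        shapes = self.make_shapes(80)
        with pytest.warns(UserWarning, match="only 80"):
            out = sample_cells(shapes, n=100, seed=0)
        assert len(out) == 80


class TestLeveneTest:
    def test_identical_groups_give_zero_statistic(self):
        W, p = levene_test([[1, 2, 3], [1, 2, 3]])
        assert W == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("center", ["mean", "median"])
    def test_matches_brute_force_formula(self, center):
        groups = [[1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0]]
        fn = np.mean if center == "mean" else np.median
        W, p = levene_test(groups, center=center)
        W0, p0 = brute_force_levene(groups, center=fn)
        assert W == pytest.approx(W0, rel=1e-12)
        assert p == pytest.approx(p0, rel=1e-12)

    def test_matches_brute_force_on_random_groups(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            groups = [rng.normal(0, s, rng.integers(3, 30)) for s in (1.0, 2.5, 0.5)]
            W, p = levene_test(groups)
            W0, p0 = brute_force_levene(groups)
            assert W == pytest.approx(W0, rel=1e-9)
            assert p == pytest.approx(p0, rel=1e-9)

    def test_degenerate_deviations_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            levene_test([[1.0, 3.0], [2.0, 4.0]])

    def test_power_distinguishes_dispersion(self):
        """Vector-like (sd 0.1) vs elongated (sd 0.5) axis ratios, n=300."""
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            ctrl = 1.3 + rng.normal(0, 0.1, 300)
            elong = 1.3 + rng.normal(0, 0.5, 300)
            _, p = levene_test([elong, ctrl])
            rejections += p < 0.05
        assert rejections >= 0.99 * 200


class TestBonferroni:
    def test_examples(self):
        assert bonferroni_adjust([0.01], m=5)[0] == pytest.approx(0.05)
        assert bonferroni_adjust([0.5], m=3)[0] == 1.0
        assert bonferroni_adjust([0.2], m=1)[0] == pytest.approx(0.2)

    def test_adjusted_at_least_raw_and_monotone_in_m(self):
        p = np.array([0.001, 0.04, 0.2, 1.0])
        for m in (1, 2, 5, 20):
            adj = bonferroni_adjust(p, m=m)
            assert (adj >= p).all()
            if m > 1:
                assert (adj >= bonferroni_adjust(p, m=m - 1)).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5])


class TestStrainSummary:
    def shapes_with_ratios(self, rng, mean, sd, n):
        from yeastburden.morphology import CellShape

        ratios = np.maximum(1.0, rng.normal(mean, sd, n))
        return [
            CellShape(i + 1, 500, (0.0, 0.0), 20.0 * r, 20.0, 0.0, float(r), False)
            for i, r in enumerate(ratios)
        ]

    def test_identical_control_normalizes_to_one(self):
        rng = np.random.default_rng(0)
        reps = [self.shapes_with_ratios(rng, 1.3, 0.1, 120) for _ in range(3)]
        ctrl = strain_summary("ctrl", reps, seed=1)
        same = strain_summary("same", reps, control=ctrl, seed=1)
        assert same.mean_size_normalized == pytest.approx(1.0)
        assert same.n_cells == 300

    def test_recovers_generating_means(self):
        rng = np.random.default_rng(2)
        ctrl_reps = [self.shapes_with_ratios(rng, 1.3, 0.1, 150) for _ in range(3)]
        strain_reps = [self.shapes_with_ratios(rng, 1.8, 0.3, 150) for _ in range(3)]
        ctrl = strain_summary("ctrl", ctrl_reps, seed=3)
        strain = strain_summary("egfp", strain_reps, control=ctrl, seed=3, family_size=5)
        assert ctrl.mean_axis_ratio == pytest.approx(1.3, abs=0.05)
        assert strain.mean_axis_ratio == pytest.approx(1.8, abs=0.05)
        assert strain.p_adjusted <= 1.0 and strain.p_adjusted >= strain.p_raw
        assert strain.p_adjusted < 0.05  # broader dispersion detected

    def test_null_calibration(self):
        """A strain drawn from the control's own distribution should rarely
        be called significantly different after Bonferroni."""
        false_calls = 0
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            ctrl_reps = [self.shapes_with_ratios(rng, 1.3, 0.15, 120) for _ in range(3)]
            reps = [self.shapes_with_ratios(rng, 1.3, 0.15, 120) for _ in range(3)]
            ctrl = strain_summary("ctrl", ctrl_reps, seed=seed)
            strain = strain_summary("null", reps, control=ctrl, seed=seed, family_size=3)
            false_calls += strain.p_adjusted < 0.05
        assert false_calls <= 0.10 * 200

    def test_missing_control_cells_rejected(self):
        with pytest.raises(ValueError):
            strain_summary("x", [[]])


class TestCorrelationAndDeadCells:
    def test_colinear_points(self):
        x = np.arange(5, dtype=float)
        r, p = elongation_property_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = elongation_property_correlation(x, -3 * x + 2)
        assert r == pytest.approx(-1.0)

    def test_p_value_matches_t_transform(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=15)
        y = 0.5 * x + rng.normal(size=15)
        r, p = elongation_property_correlation(x, y)
        t = r * np.sqrt(13) / np.sqrt(1 - r**2)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 13), rel=1e-9)

    def test_recovers_generating_correlation(self):
        """Linear ratio-cysteine link plus noise across 15-strain panels."""
        rho = 0.8
        slope = 0.1
        rs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            cys = rng.uniform(0, 6, 15)
            signal_sd = slope * cys.std()
            noise_sd = signal_sd * np.sqrt(1 / rho**2 - 1)
            ratio = 1.2 + slope * cys + rng.normal(0, noise_sd, 15)
            r, _ = elongation_property_correlation(ratio, cys)
            rs.append(r)
        assert abs(np.mean(rs) - rho) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            elongation_property_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_dead_cell_fraction(self):
        flags = [True] * 30 + [False] * 270
        assert dead_cell_fraction(flags) == pytest.approx(10.0)
        assert dead_cell_fraction([False] * 300) == 0.0
        with pytest.warns(UserWarning, match="299"):
            dead_cell_fraction([False] * 299)
        with pytest.raises(ValueError):
            dead_cell_fraction([])
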