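"""Gradient mapping, line profiles, AP-line counting, volumes, heat maps."""

import numpy as np
import pytest

from follipulse import spatialmap as sp
from follipulse.errors import InputError


class TestMetricVsDistance:
    def test_constant_metric_flat_profile_zero_amplitude(self):
        rng = np.random.default_rng(0)
        cents = rng.uniform(0, 100, (60, 2))
        prof = sp.metric_vs_distance(
            np.full(60, 3.0), cents, (0, 50), bin_width_um=10
        )
        assert np.allclose(prof.bins.metric_mean, 3.0)
        assert prof.fit["amplitude_at_pole"] == pytest.approx(0.0, abs=1e-6)

    def test_metric_equal_to_distance_gives_bin_centers(self):
        rng = np.random.default_rng(1)
        cents = rng.uniform(0, 100, (500, 2))
        pole = (50.0, 50.0)
        d = np.hypot(cents[:, 0] - 50, cents[:, 1] - 50)
        prof = sp.metric_vs_distance(d, cents, pole, bin_width_um=10, fit=False)
        for row in prof.bins.itertuples():
            assert abs(row.metric_mean - row.bin_center_um) <= 5.0

    def test_bin_means_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        cents = rng.uniform(0, 80, (100, 2))
        vals = rng.random(100)
        p1 = sp.metric_vs_distance(vals, cents, (0, 0), fit=False)
        perm = rng.permutation(100)
        p2 = sp.metric_vs_distance(vals[perm], cents[perm], (0, 0), fit=False)
        assert np.allclose(p1.bins.metric_mean, p2.bins.metric_mean)

    @pytest.mark.parametrize("lam", [15.0, 30.0, 60.0])
    def test_exponential_fit_recovery_noise_free(self, lam):
        """Known gradient sampled at random positions: lambda within 15%."""
        rng = np.random.default_rng(int(lam))
        cents = rng.uniform(0, 4 * lam, (800, 2))
        d = np.hypot(cents[:, 0], cents[:, 1])
        metric = 0.1 + 0.3 * np.exp(-d / lam)
        prof = sp.metric_vs_distance(metric, cents, (0, 0), bin_width_um=lam / 3)
        assert prof.fit["decay_length_um"] == pytest.approx(lam, rel=0.15)
        assert prof.fit["amplitude_at_pole"] == pytest.approx(0.3, rel=0.15)

    def test_single_bin_skips_fit_with_warning(self):
        cents = np.array([[1.0, 1.0], [2.0, 2.0]])
        with pytest.warns(UserWarning):
            prof = sp.metric_vs_distance([1.0, 2.0], cents, (0, 0),
                                         bin_width_um=100)
        assert prof.fit is None

    def test_no_cells_rejected(self):
        with pytest.raises(InputError):
            sp.metric_vs_distance([], np.empty((0, 2)), (0, 0))


class TestRelativeApicalSurface:
    def test_smallest_cell_is_one(self):
        cents = np.array([[0, 0], [10, 0], [20, 0]], float)
        prof = sp.relative_apical_surface([2, 4, 8], cents, (0, 0),
                                          bin_width_um=5, fit=False,
                                          min_bin_n=1)
        vals = prof.bins.metric_mean.to_numpy()
        assert vals[0] == pytest.approx(1.0)
        assert vals[-1] == pytest.approx(4.0)

    def test_equal_areas_all_one(self):
        rng = np.random.default_rng(4)
        cents = rng.uniform(0, 50, (30, 2))
        prof = sp.relative_apical_surface(np.full(30, 7.0), cents, (0, 0),
                                          fit=False)
        assert np.allclose(prof.bins.metric_mean, 1.0)

    def test_small_polar_cells_give_increasing_profile(self):
        rng = np.random.default_rng(5)
        cents = rng.uniform(0, 100, (200, 2))
        d = np.hypot(cents[:, 0], cents[:, 1])
        areas = 20.0 - 8.0 * np.exp(-d / 25.0) + rng.normal(0, 0.2, 200)
        prof = sp.relative_apical_surface(areas, cents, (0, 0),
                                          bin_width_um=20, fit=False)
        means = prof.bins.metric_mean.to_numpy()
        assert means[-1] > means[0]

    def test_nonpositive_area_rejected(self):
        with pytest.raises(InputError):
            sp.relative_apical_surface([1.0, 0.0], np.zeros((2, 2)), (0, 0))


class TestLineProfile:
    def test_uniform_image_profile_is_one(self):
        img = np.full((50, 80), 4.2)
        prof = sp.line_profile(img, [(5, 25), (75, 25)])
        assert np.allclose(prof, 1.0)

    def test_normalization_identity_any_image(self):
        rng = np.random.default_rng(6)
        img = rng.random((60, 60)) + 0.5
        prof = sp.line_profile(img, [(5, 10), (50, 40)])
        assert prof.mean() == pytest.approx(1.0, abs=1e-9)

    def test_two_pole_field_has_high_ends_low_middle(self):
        xs = np.arange(120)
        field = np.exp(-xs / 20.0) + np.exp(-(119 - xs) / 20.0) + 0.05
        img = np.tile(field, (40, 1))
        prof = sp.line_profile(img, [(2, 20), (117, 20)])
        third = len(prof) // 3
        assert prof[:third].mean() > prof[third: 2 * third].mean()
        assert prof[-third:].mean() > prof[third: 2 * third].mean()

    def test_path_leaving_image_clipped_with_warning(self):
        img = np.ones((20, 20))
        with pytest.warns(UserWarning):
            sp.line_profile(img, [(0, 1), (19, 1)], width_px=15)

    def test_band_width_one_samples_centerline(self):
        img = np.zeros((21, 40))
        img[10] = 5.0
        prof = sp.line_profile(img, [(2, 10), (37, 10)], width_px=1)
        assert np.allclose(prof, 1.0)


class TestCountCells:
    def _row_of_squares(self, n=7, size=10):
        lab = np.zeros((size, n * size), int)
        for i in range(n):
            lab[:, i * size : (i + 1) * size] = i + 1
        return lab

    def test_row_of_seven_squares(self):
        lab = self._row_of_squares()
        n = sp.count_cells_on_ap_line(lab, (0, 5), (69, 5))
        assert n == 7

    def test_exclusion_of_polar_cell_labels(self):
        lab = self._row_of_squares()
        n = sp.count_cells_on_ap_line(lab, (0, 5), (69, 5), exclude_labels=[1, 7])
        assert n == 5

    def test_symmetry_in_pole_order(self):
        lab = self._row_of_squares()
        a = sp.count_cells_on_ap_line(lab, (0, 5), (69, 5))
        b = sp.count_cells_on_ap_line(lab, (69, 5), (0, 5))
        assert a == b

    def test_matches_rasterization_oracle_on_synthetic(self, pipeline_lag2):
        from skimage.draw import line as draw_line

        labels = pipeline_lag2.truth.label_stack[0]
        h, w = labels.shape
        pa, pb = (0, h // 2), (w - 1, h // 2)
        rr, cc = draw_line(pa[1], pa[0], pb[1], pb[0])
        expect = len({int(v) for v in labels[rr, cc] if v > 0})
        assert sp.count_cells_on_ap_line(labels, pa, pb) == expect

    def test_background_only_returns_zero_with_warning(self):
        lab = np.zeros((10, 10), int)
        lab[0, 0] = 1
        with pytest.warns(UserWarning):
            assert sp.count_cells_on_ap_line(lab, (0, 9), (9, 9)) == 0

    def test_pole_outside_bounds_rejected(self):
        with pytest.raises(InputError):
            sp.count_cells_on_ap_line(np.ones((5, 5), int), (0, 0), (10, 0))


class TestCellVolume:
    def test_product(self):
        assert sp.cell_volume(10.0, 5.0) == 50.0

    def test_linearity_in_surface(self):
        assert sp.cell_volume(20.0, 5.0) == 2 * sp.cell_volume(10.0, 5.0)

    def test_elementwise_table_matches_oracle(self):
        rng = np.random.default_rng(8)
        surf = rng.uniform(5, 40, 50)
        height = rng.uniform(2, 12, 50)
        got = [sp.cell_volume(s, h) for s, h in zip(surf, height)]
        assert np.allclose(got, surf * height)

    def test_nonpositive_rejected(self):
        with pytest.raises(InputError):
            sp.cell_volume(0.0, 5.0)


class TestHeatmap:
    def test_two_cells_at_colormap_ends(self):
        lab = np.zeros((10, 20), int)
        lab[:, :10] = 1
        lab[:, 10:] = 2
        rgb, meta = sp.heatmap_export(lab, {1: 0.0, 2: 1.0}, "viridis")
        assert meta["vmin"] == 0.0 and meta["vmax"] == 1.0
        assert not np.allclose(rgb[0, 0], rgb[0, 15])
        # uniform fill inside each cell
        assert np.allclose(rgb[:, :10], rgb[0, 0])

    def test_constant_metric_single_color(self):
        lab = np.zeros((10, 10), int)
        lab[:5] = 1
        lab[5:] = 2
        rgb, _ = sp.heatmap_export(lab, {1: 2.0, 2: 2.0})
        assert np.allclose(rgb[0, 0], rgb[9, 9])

    def test_background_is_black(self):
        lab = np.zeros((5, 5), int)
        lab[2, 2] = 1
        rgb, _ = sp.heatmap_export(lab, {1: 1.0})
        assert np.allclose(rgb[0, 0], 0.0)

    def test_rank_order_of_colors_matches_metric(self):
        lab = np.zeros((10, 30), int)
        lab[:, :10] = 1
        lab[:, 10:20] = 2
        lab[:, 20:] = 3
        rgb, _ = sp.heatmap_export(lab, {1: 0.1, 2: 0.5, 3: 0.9}, "gray")
        g = [rgb[5, 5, 0], rgb[5, 15, 0], rgb[5, 25, 0]]
        assert g[0] < g[1] < g[2]

    def test_missing_label_warned_and_neutral(self):
        lab = np.zeros((5, 10), int)
        lab[:, :5] = 1
        lab[:, 5:] = 2
        with pytest.warns(UserWarning):
            rgb, _ = sp.heatmap_export(lab, {1: 1.0})
        assert np.allclose(rgb[0, 7], 0.5)
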