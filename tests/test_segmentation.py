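import numpy as np
import pytest

import seedfrost as sf
from seedfrost.errors import DegenerateInputError, EmptyMaskError

from conftest import make_cube
from oracles import otsu_between_class_variance, otsu_brute_force


class TestToGray:
    def test_exact_match(self, tiny_grid, rng):
        cube = sf.HyperCube(rng.random((4, 4, 3)), tiny_grid)
        np.testing.assert_array_equal(
            sf.to_gray(cube, 700), cube.values[:, :, 1]
        )

    def test_nearest_neighbor_rule(self, tiny_grid, rng):
        cube = sf.HyperCube(rng.random((4, 4, 3)), tiny_grid)
        np.testing.assert_array_equal(
            sf.to_gray(cube, 690), cube.values[:, :, 1]
        )

    def test_out_of_range_raises(self, tiny_grid, rng):
        cube = sf.HyperCube(rng.random((4, 4, 3)), tiny_grid)
        with pytest.raises(ValueError):
            sf.to_gray(cube, 1100)


class TestEnhance:
    def test_full_span_unchanged(self):
        img = np.array([[0.0, 0.5], [0.25, 1.0]])
        np.testing.assert_allclose(sf.enhance(img, 0, 100), img)

    def test_two_values_stretch_to_unit(self):
        img = np.array([[0.2, 0.4], [0.2, 0.4]])
        np.testing.assert_allclose(
            sf.enhance(img, 0, 100), np.array([[0.0, 1.0], [0.0, 1.0]])
        )

    def test_constant_image_warns_and_passes_through(self):
        img = np.full((3, 3), 0.7)
        with pytest.warns(UserWarning):
            out = sf.enhance(img)
        np.testing.assert_array_equal(out, img)

    def test_preserves_rank_order(self, rng):
        img = rng.random((20, 20))
        out = sf.enhance(img, 1, 99)
        # strictly monotone inside the clip range, non-decreasing overall
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= 0)


class TestOtsu:
    def test_perfectly_bimodal(self):
        img = np.array([0.1] * 50 + [0.8] * 50).reshape(10, 10)
        t = sf.otsu_threshold(img)
        assert 0.1 < t < 0.8
        assert np.array_equal(img > t, img == 0.8)

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            sf.otsu_threshold(np.full((5, 5), 0.3))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_search(self, seed):
        """Otsu's partition equals the exhaustive 256-threshold search.

        Thresholds can differ inside an empty histogram gap between the
        modes (any value there splits the histogram identically), so the
        check compares the achieved between-class variance, which must be
        maximal for both.
        """
        rng = np.random.default_rng(seed)
        img = np.concatenate(
            [rng.normal(0.25, 0.05, 300), rng.normal(0.7, 0.08, 200)]
        ).reshape(25, 20)
        t_impl = sf.otsu_threshold(img)
        t_oracle = otsu_brute_force(img)
        v_impl = otsu_between_class_variance(img, t_impl)
        v_oracle = otsu_between_class_variance(img, t_oracle)
        assert v_impl == pytest.approx(v_oracle, rel=1e-6)


class TestLabelSeeds:
    def test_two_blobs(self):
        mask = np.zeros((20, 20), bool)
        mask[2:7, 2:4] = True   # 10 px
        mask[12:17, 12:14] = True
        seeds = sf.label_seeds(mask, min_area=5)
        assert seeds.seed_count == 2
        assert sorted(seeds.areas.tolist()) == [10, 10]

    def test_small_blob_filtered_to_empty(self):
        mask = np.zeros((10, 10), bool)
        mask[3, 3:6] = True  # 3 px
        with pytest.raises(EmptyMaskError):
            sf.label_seeds(mask, min_area=5)

    def test_raster_order_labels(self):
        mask = np.zeros((30, 30), bool)
        mask[20:25, 2:7] = True   # lower-left
        mask[2:7, 20:25] = True   # upper-right: must get label 1
        seeds = sf.label_seeds(mask, min_area=5)
        assert seeds.labels[3, 22] == 1
        assert seeds.labels[22, 3] == 2


class TestMeanSpectra:
    def _calibrated(self, values, grid=None):
        cube = make_cube(values, grid)
        cube.calibrated = True
        return cube

    def test_single_pixel_seed(self, rng):
        cube = self._calibrated(rng.random((4, 4, 5)))
        labels_img = np.zeros((4, 4), int)
        labels_img[1:3, 1:3] = 0
        labels_img[2, 2] = 1
        mask = sf.SeedMask(labels_img, np.array([1]))
        table = sf.mean_spectra(cube, mask, np.array([2]))
        np.testing.assert_allclose(table.spectra[0], cube.values[2, 2])
        assert table.labels[0] == 2

    def test_two_pixel_average(self, rng):
        cube = self._calibrated(rng.random((4, 4, 5)))
        labels_img = np.zeros((4, 4), int)
        labels_img[0, 0] = labels_img[3, 3] = 1
        mask = sf.SeedMask(labels_img, np.array([2]))
        table = sf.mean_spectra(cube, mask, np.array([1]))
        np.testing.assert_allclose(
            table.spectra[0], (cube.values[0, 0] + cube.values[3, 3]) / 2
        )

    def test_uncalibrated_cube_rejected(self, rng):
        cube = make_cube(rng.random((4, 4, 5)))
        mask = sf.SeedMask(np.ones((4, 4), int), np.array([16]))
        with pytest.raises(ValueError, match="calibrated"):
            sf.mean_spectra(cube, mask, np.array([1]))

    def test_invariant_to_pixel_enumeration(self, rng):
        """Means are identical after any spatial permutation of seed pixels."""
        cube = self._calibrated(rng.random((6, 6, 4)))
        labels_img = (rng.random((6, 6)) < 0.5).astype(int)
        mask = sf.SeedMask(labels_img, np.array([labels_img.sum()]))
        t1 = sf.mean_spectra(cube, mask, np.array([1]))
        perm = rng.permutation(36)
        shuffled = sf.HyperCube(
            cube.values.reshape(36, 4)[perm].reshape(6, 6, 4),
            cube.grid,
            calibrated=True,
        )
        mask2 = sf.SeedMask(
            labels_img.reshape(36)[perm].reshape(6, 6), mask.areas
        )
        t2 = sf.mean_spectra(shuffled, mask2, np.array([1]))
        np.testing.assert_allclose(t1.spectra, t2.spectra)


class TestPipelineOnGeneratedCube:
    def test_noiseless_cube_segments_pixel_exactly(self):
        """Calibrate -> enhance -> Otsu -> label recovers the painted truth."""
        from dataclasses import replace

        cfg = sf.default_config("endosperm", seed=5, class_sizes=(2, 2, 2), n_bands=16)
        cfg = replace(
            cfg, noise_sd=0.0, scatter_gain=(1.0, 1.0),
            baseline_range=(0.0, 0.0), severity_jitter=0.0,
        )
        layout = sf.grid_layout(2, 3, (1, 2, 3, 1, 2, 3), cell=24, radius=(7, 6))
        raw, dark, white, truth_mask = sf.gen_cube(cfg, layout)
        cube = sf.calibrate(raw, dark, white)
        mask = sf.segment_cube(cube, gray_nm=700, min_area=20)
        np.testing.assert_array_equal(mask.labels, truth_mask.labels)
        # and per-seed means match the class mean curves exactly
        table = sf.mean_spectra(cube, mask, np.array(layout.classes))
        from seedfrost.synthetic import class_mean_curves

        means = class_mean_curves(cfg)
        for row, cls in enumerate(layout.classes):
            np.testing.assert_allclose(
                table.spectra[row], means[cls - 1], atol=1e-10
            )


def test_spectra_table_csv_round_trip(tmp_path, small_table):
    table, _ = small_table
    path = tmp_path / "spectra.csv"
    table.to_csv(path)
    back = sf.SpectraTable.from_csv(path)
    np.testing.assert_allclose(back.spectra, table.spectra)
    np.testing.assert_array_equal(back.labels, table.labels)
    assert back.side == table.side
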