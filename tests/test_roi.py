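"""Calyx ROI acquisition: segmentation, morphology, geometry, extraction."""

import numpy as np
import pytest

from calyxscan import (Hypercube, SceneConfig, acquire_roi, calyx_centroid,
                       circular_roi, erode, extract_pixel_spectra,
                       generate_scene, mean_spectrum, rect_roi, segment_scene)
from calyxscan.calibration import calibrate
from calyxscan.errors import (EmptyMaskError, NoCalyxError, ParameterError,
                              SegmentationError)
from calyxscan.roi import mask_to_rle, rle_to_mask

WL3 = np.array([900.0, 1084.0, 1700.0])


def _one_band_cube(img):
    data = np.repeat(np.asarray(img, float)[:, :, None], 3, axis=2)
    return Hypercube(data, WL3)


class TestSegmentScene:
    def test_fixed_threshold_separable(self):
        img = np.full((10, 10), 0.1)
        img[2:8, 2:8] = 0.8          # fruit
        img[4:6, 4:6] = 0.2          # calyx
        mask = segment_scene(_one_band_cube(img), 1084, method="fixed",
                             threshold=0.5)
        np.testing.assert_array_equal(mask, img == 0.8)

    def test_constant_image_fails(self):
        with pytest.raises(SegmentationError):
            segment_scene(_one_band_cube(np.full((8, 8), 0.5)), 1084)

    def test_otsu_threshold_in_intermode_valley(self, rng):
        """Automatic threshold agrees with an exhaustive 256-level
        between-class-variance scan and falls between the two modes."""
        values = np.concatenate([rng.normal(0.2, 0.02, 600),
                                 rng.normal(0.8, 0.02, 400)])
        img = values.reshape(25, 40)
        mask = segment_scene(_one_band_cube(img), 1084)

        hist, edges = np.histogram(img, bins=256)
        w = hist / hist.sum()
        centers = (edges[:-1] + edges[1:]) / 2
        best_sb, best_t = -1.0, None
        for k in range(1, 256):
            w0, w1 = w[:k].sum(), w[k:].sum()
            if w0 == 0 or w1 == 0:
                continue
            mu0 = (w[:k] * centers[:k]).sum() / w0
            mu1 = (w[k:] * centers[k:]).sum() / w1
            sb = w0 * w1 * (mu0 - mu1) ** 2
            if sb > best_sb:
                best_sb, best_t = sb, centers[k - 1]
        # the threshold must lie in the empty valley between the two modes
        # (any value there yields the same mask; ties go to the gap entrance)
        assert values[:600].max() <= best_t < values[600:].min()
        np.testing.assert_array_equal(mask, img > best_t)


class TestErode:
    def test_radius_zero_identity(self, rng):
        mask = rng.uniform(size=(6, 6)) > 0.5
        np.testing.assert_array_equal(erode(mask, 0), mask)

    def test_all_true_shrinks_to_interior(self):
        out = erode(np.ones((5, 5), bool), 1)
        expect = np.zeros((5, 5), bool)
        expect[1:4, 1:4] = True
        np.testing.assert_array_equal(out, expect)

    def test_matches_double_loop_oracle(self, rng):
        from skimage.morphology import disk

        mask = rng.uniform(size=(16, 16)) > 0.4
        selem = disk(1)
        off = 1
        oracle = np.zeros_like(mask)
        for i in range(16):
            for j in range(16):
                keep = True
                for di in range(-off, off + 1):
                    for dj in range(-off, off + 1):
                        if not selem[di + off, dj + off]:
                            continue
                        ii, jj = i + di, j + dj
                        inside = 0 <= ii < 16 and 0 <= jj < 16
                        if not (inside and mask[ii, jj]):
                            keep = False
                oracle[i, j] = keep
        np.testing.assert_array_equal(erode(mask, 1), oracle)

    def test_composition_on_convex_masks(self, rng):
        """Iterated disk erosion brackets single-shot erosion: the Minkowski
        sum of rasterized disks B2⊕B1 is a subset of B3, so eroding twice
        removes no pixel that eroding once by the summed radius keeps, and
        the two differ only in a thin boundary ring."""
        for _ in range(5):
            r0, c0 = rng.integers(12, 20, size=2)
            rad = int(rng.integers(6, 10))
            mask = circular_roi((r0, c0), 2 * rad, (32, 32))
            single = erode(mask, 3)
            iterated = erode(erode(mask, 2), 1)
            assert not (single & ~iterated).any()
            boundary = iterated & ~erode(iterated, 1)
            assert not ((iterated & ~single) & ~boundary).any()


class TestCentroid:
    def test_single_pixel(self):
        mask = np.zeros((10, 10), bool)
        mask[7, 3] = True
        assert calyx_centroid(mask) == (7.0, 3.0)

    def test_symmetric_block(self):
        mask = np.zeros((20, 20), bool)
        mask[9:12, 9:12] = True
        assert calyx_centroid(mask) == (10.0, 10.0)

    def test_largest_component_wins_flood_fill_oracle(self):
        mask = np.zeros((12, 12), bool)
        mask[1:4, 1:5] = True     # 12 pixels
        mask[8:10, 8:10] = True   # 4 pixels
        # flood-fill from every true pixel to enumerate components
        seen, comps = set(), []
        for seed in zip(*np.nonzero(mask)):
            if seed in seen:
                continue
            stack, comp = [seed], []
            while stack:
                p = stack.pop()
                if p in seen or not mask[p]:
                    continue
                seen.add(p)
                comp.append(p)
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        q = (p[0] + di, p[1] + dj)
                        if 0 <= q[0] < 12 and 0 <= q[1] < 12:
                            stack.append(q)
            comps.append(comp)
        biggest = max(comps, key=len)
        expect = (np.mean([p[0] for p in biggest]),
                  np.mean([p[1] for p in biggest]))
        assert calyx_centroid(mask) == expect

    def test_empty_mask(self):
        with pytest.raises(NoCalyxError):
            calyx_centroid(np.zeros((5, 5), bool))


class TestCircularRoi:
    def test_diameter_one_single_pixel(self):
        mask = circular_roi((5, 5), 1, (11, 11))
        assert mask.sum() == 1 and mask[5, 5]

    def test_covering_circle_is_all_true(self):
        assert circular_roi((5, 5), 100, (11, 11)).all()

    def test_lattice_point_enumeration_oracle(self):
        mask = circular_roi((100, 100), 50, (200, 200))
        count = sum(
            (i - 100) ** 2 + (j - 100) ** 2 <= 25.0 ** 2
            for i in range(200) for j in range(200)
        )
        assert mask.sum() == count
        assert count <= np.pi * (25 + 0.5) ** 2

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            circular_roi((5, 5), 0, (11, 11))
        with pytest.raises(ParameterError):
            circular_roi((50, 5), 3, (11, 11))


class TestRectRoi:
    def test_single_pixel(self):
        mask = rect_roi((4, 4), 1, 1, (9, 9))
        assert mask.sum() == 1 and mask[4, 4]

    def test_interior_10x10_has_100_pixels(self):
        assert rect_roi((50, 50), 10, 10, (100, 100)).sum() == 100

    def test_border_clipping_count(self):
        mask = rect_roi((1, 1), 10, 10, (100, 100))
        # rows -3..6 clipped to 0..6 (7), cols likewise
        assert mask.sum() == 7 * 7

    def test_bad_size(self):
        with pytest.raises(ParameterError):
            rect_roi((4, 4), 0, 5, (9, 9))


class TestAcquireRoi:
    def test_centroid_recovery_and_pixel_count(self, calibrated_scene):
        cfg, cal, truth = calibrated_scene
        result = acquire_roi(cal)
        assert abs(result.centroid[0] - truth.calyx_center[0]) <= 1.0
        assert abs(result.centroid[1] - truth.calyx_center[1]) <= 1.0
        oracle = circular_roi(result.centroid, 50, cal.data.shape[:2]).sum()
        assert result.n_pixels == oracle
        assert result.n_pixels <= np.pi * (25 + 0.5) ** 2

    def test_deterministic(self, calibrated_scene):
        _, cal, _ = calibrated_scene
        a, b = acquire_roi(cal), acquire_roi(cal)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.centroid == b.centroid

    def test_uniform_fruit_disk_has_no_calyx(self):
        cfg = SceneConfig(seed=5, calyx_darkening=1.0, label="healthy")
        raw, refs, _ = generate_scene(cfg)
        with pytest.raises(NoCalyxError):
            acquire_roi(calibrate(raw, refs))

    def test_rotation_equivariance(self, calibrated_scene):
        """Rotating the scene 90° rotates the ROI mask with it."""
        _, cal, _ = calibrated_scene
        rot = Hypercube(np.rot90(cal.data, axes=(0, 1)).copy(),
                        cal.wavelengths)
        base = acquire_roi(cal)
        rotated = acquire_roi(rot)
        np.testing.assert_array_equal(rotated.mask,
                                      np.rot90(base.mask, axes=(0, 1)))


class TestExtraction:
    def test_values_match_direct_indexing(self, small_cube):
        mask = np.zeros((8, 8), bool)
        mask[[1, 3, 6], [2, 5, 0]] = True
        table = extract_pixel_spectra(small_cube, mask, "healthy",
                                      sample_id="s1")
        assert table.n == 3
        pix = list(zip(*np.nonzero(mask)))
        for k, (r, c) in enumerate(pix):
            np.testing.assert_array_equal(table.spectra[k],
                                          small_cube.data[r, c, :])
            assert (table.provenance.loc[k, "row"],
                    table.provenance.loc[k, "col"]) == (r, c)

    def test_empty_mask_error(self, small_cube):
        with pytest.raises(EmptyMaskError):
            extract_pixel_spectra(small_cube, np.zeros((8, 8), bool), "healthy")

    def test_mean_spectrum(self, rng):
        data = rng.normal(size=(4, 4, 5))
        cube = Hypercube(data, np.linspace(900, 1700, 5))
        one = np.zeros((4, 4), bool)
        one[2, 2] = True
        np.testing.assert_array_equal(mean_spectrum(cube, one), data[2, 2])

        sym = Hypercube(np.stack([data[0, 0], -data[0, 0]])[None].reshape(1, 2, 5),
                        np.linspace(900, 1700, 5))
        np.testing.assert_allclose(
            mean_spectrum(sym, np.ones((1, 2), bool)), 0.0, atol=1e-12)

        mask = rng.uniform(size=(4, 4)) > 0.4
        loop = np.zeros(5)
        for r, c in zip(*np.nonzero(mask)):
            loop += data[r, c]
        loop /= mask.sum()
        np.testing.assert_allclose(mean_spectrum(cube, mask), loop)


def test_rle_roundtrip(rng):
    mask = rng.uniform(size=(9, 13)) > 0.5
    np.testing.assert_array_equal(rle_to_mask(mask_to_rle(mask)), mask)
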