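"""Bead detection, optical-flow tracking, drift correction, gridding."""

import numpy as np
import pytest
from scipy.spatial import Delaunay, cKDTree

from conftest import render_spots, scattered_positions
from tfmkit.beads import (BeadImagePair, DetectionParams, TrackingParams,
                          detect_beads, dog_filter, drift_correct,
                          grid_displacements, track_displacements)
from tfmkit.fields import ScatteredDisplacementField
from tfmkit.synthetic import SceneConfig, generate_scene


class TestDogFilter:
    def test_constant_image_maps_to_zero(self):
        out = dog_filter(np.full((64, 64), 37.0))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_impulse_response_matches_analytic_kernel(self):
        img = np.zeros((101, 101))
        img[50, 50] = 1.0
        out = dog_filter(img, 1.5, 2.0)
        expected = 1 / (2 * np.pi * 1.5 ** 2) - 1 / (2 * np.pi * 2.0 ** 2)
        assert out[50, 50] == pytest.approx(expected, rel=0.01)

    def test_gaussian_spot_peak_stays_at_center(self):
        img = render_spots([(40.0, 25.0)], (64, 64), sigma=1.5)
        out = dog_filter(img)
        r, c = np.unravel_index(np.argmax(out), out.shape)
        assert (c, r) == (40, 25)

    def test_invalid_sigmas_rejected(self):
        with pytest.raises(ValueError):
            dog_filter(np.zeros((8, 8)), -1.0, 2.0)
        with pytest.raises(ValueError):
            dog_filter(np.zeros((8, 8)), 2.0, 1.5)


class TestDetectBeads:
    def test_blank_image_gives_empty_list(self):
        assert len(detect_beads(np.full((64, 64), 9.0))) == 0

    def test_well_separated_spots_found_to_subpixel(self):
        rng = np.random.default_rng(5)
        true = np.column_stack([
            20 + 90 * (np.arange(10) % 5 / 5) + rng.uniform(-3, 3, 10),
            20 + 90 * (np.arange(10) // 5 / 2) + rng.uniform(-3, 3, 10),
        ])
        img = render_spots(true, (160, 160), sigma=1.5)
        img = np.clip(img + rng.normal(0, 50, img.shape), 0, None)  # SNR 20
        found = detect_beads(img)
        assert len(found) == 10
        dist, _ = cKDTree(true).query(found)
        assert dist.max() < 0.5

    def test_nonmax_suppression_merges_close_spots(self):
        img = render_spots([(30.0, 30.0), (32.0, 30.0)], (64, 64), sigma=1.5)
        found = detect_beads(img, DetectionParams(min_distance=5))
        assert len(found) == 1

    def test_count_monotone_in_quality_level(self):
        rng = np.random.default_rng(8)
        img = render_spots(scattered_positions(40, (128, 128), 8, rng),
                           (128, 128))
        img = np.clip(img + rng.normal(0, 30, img.shape), 0, None)
        counts = [len(detect_beads(img, DetectionParams(quality_level=q)))
                  for q in (0.02, 0.05, 0.1, 0.3, 0.6)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(dog_sigma_small=2.5)  # >= large
        with pytest.raises(ValueError):
            DetectionParams(quality_level=1.5)


class TestTracking:
    def test_identical_pair_gives_zero_vectors(self):
        rng = np.random.default_rng(2)
        img = render_spots(scattered_positions(60, (128, 128), 8, rng), (128, 128))
        pair = BeadImagePair(img, img)
        field = track_displacements(pair, detect_beads(img))
        assert field.n_tracked > 0
        assert np.allclose(field.tracked_vectors, 0.0)

    def test_integer_shift_recovered(self):
        # margin covers the tracking window so no window sees the wrap seam
        rng = np.random.default_rng(4)
        img = render_spots(scattered_positions(200, (256, 256), 32, rng), (256, 256))
        loaded = np.roll(img, (-2, 3), axis=(0, 1))  # (dx, dy) = (3, -2)
        field = track_displacements(BeadImagePair(loaded, img), detect_beads(img))
        err = np.abs(field.tracked_vectors - [3.0, -2.0])
        assert field.n_tracked >= 0.8 * len(field)
        assert err.max() < 0.05

    def test_smooth_warp_tracked_below_tenth_pixel(self):
        """Forward-model warp (≤ 2 px), SNR 20 camera noise: RMS < 0.1 px."""
        cfg = SceneConfig(seed=21, noise_gaussian_sigma=50.0,
                          noise_poisson_scale=0.0)
        scene = generate_scene(cfg)
        pair = BeadImagePair(scene.loaded, scene.relaxed)
        field = track_displacements(pair, detect_beads(scene.relaxed))
        truth = scene.bead_positions_loaded - scene.bead_positions_relaxed
        _, idx = cKDTree(scene.bead_positions_relaxed).query(field.tracked_anchors)
        err = field.tracked_vectors - truth[idx]
        assert np.sqrt((err ** 2).mean()) < 0.1

    def test_error_decreases_with_snr(self):
        """Sampled property: tracking error monotone over SNR ∈ {5, 10, 20}."""
        rms = {}
        for snr in (5, 10, 20):
            cfg = SceneConfig(seed=33, noise_gaussian_sigma=1000.0 / snr,
                              noise_poisson_scale=0.0)
            scene = generate_scene(cfg)
            field = track_displacements(BeadImagePair(scene.loaded, scene.relaxed),
                                        detect_beads(scene.relaxed))
            truth = scene.bead_positions_loaded - scene.bead_positions_relaxed
            _, idx = cKDTree(scene.bead_positions_relaxed).query(field.tracked_anchors)
            err = field.tracked_vectors - truth[idx]
            rms[snr] = np.sqrt((err ** 2).mean())
        assert rms[5] > rms[10] > rms[20]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            BeadImagePair(np.zeros((32, 32)), np.zeros((16, 16)))

    def test_no_anchors_rejected(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError):
            track_displacements(BeadImagePair(img, img), np.empty((0, 2)))

    def test_window_must_be_odd(self):
        with pytest.raises(ValueError):
            TrackingParams(window=60)


class TestDriftCorrect:
    def _field(self, vectors, n=None, rng_seed=0):
        vectors = np.atleast_2d(vectors)
        n = len(vectors)
        rng = np.random.default_rng(rng_seed)
        anchors = scattered_positions(n, (128, 128), 5, rng)
        return ScatteredDisplacementField(anchors, vectors,
                                          np.ones(n, bool), (128, 128))

    def test_uniform_offset_removed(self):
        field = self._field(np.ones((20, 2)))
        out = drift_correct(field)
        assert np.allclose(out.tracked_vectors, 0.0)

    def test_offset_on_structured_field_removed(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 0.02, (40, 2))
        field = self._field(base + [0.7, -0.3])
        out = drift_correct(field)
        resid = out.tracked_vectors - base
        assert np.abs(np.median(resid, axis=0)).max() < 0.05

    def test_too_few_reference_beads_leaves_field_unchanged(self):
        field = self._field(np.ones((4, 2)))
        with pytest.warns(UserWarning):
            out = drift_correct(field)
        assert np.allclose(out.tracked_vectors, field.tracked_vectors)

    def test_mask_excludes_cell_beads_from_reference(self):
        rng = np.random.default_rng(9)
        anchors = scattered_positions(60, (128, 128), 5, rng)
        inside = anchors[:, 0] < 64
        vectors = np.where(inside[:, None], [2.0, 2.0], [0.5, -0.5])
        field = ScatteredDisplacementField(anchors, vectors,
                                           np.ones(60, bool), (128, 128))
        mask = np.zeros((128, 128))
        mask[:, :64] = 1
        out = drift_correct(field, mask)
        # outside-mask median (0.5, -0.5) subtracted everywhere
        assert np.allclose(out.tracked_vectors[~inside], 0.0, atol=1e-12)


class TestGridding:
    def test_constant_field_on_nodes(self):
        xs, ys = np.meshgrid(np.arange(0, 128, 8.0), np.arange(0, 128, 8.0))
        anchors = np.column_stack([xs.ravel(), ys.ravel()])
        v = np.tile([1.25, -0.5], (len(anchors), 1))
        field = ScatteredDisplacementField(anchors, v, np.ones(len(anchors), bool),
                                           (128, 128))
        g = grid_displacements(field, 8.0)
        assert np.allclose(g.u_x, 1.25) and np.allclose(g.u_y, -0.5)

    def test_affine_field_reproduced_exactly_inside_hull(self):
        rng = np.random.default_rng(10)
        anchors = scattered_positions(200, (256, 256), 2, rng)
        a, b = 0.01, -0.004
        v = np.column_stack([a * anchors[:, 0], b * anchors[:, 1]])
        field = ScatteredDisplacementField(anchors, v, np.ones(200, bool),
                                           (256, 256))
        g = grid_displacements(field, 8.0)
        X, Y = g.node_positions_px()
        hull = Delaunay(anchors)
        inside = hull.find_simplex(np.column_stack([X.ravel(), Y.ravel()])) >= 0
        inside = inside.reshape(X.shape)
        assert np.abs(g.u_x - a * X)[inside].max() < 1e-6
        assert np.abs(g.u_y - b * Y)[inside].max() < 1e-6

    def test_empty_field_rejected(self):
        field = ScatteredDisplacementField(np.empty((0, 2)), np.empty((0, 2)),
                                           np.empty(0, bool), (64, 64))
        with pytest.raises(ValueError):
            grid_displacements(field, 8.0)

    def test_collinear_beads_rejected(self):
        anchors = np.column_stack([np.arange(10.0) * 5, np.arange(10.0) * 5])
        field = ScatteredDisplacementField(anchors, np.ones((10, 2)),
                                           np.ones(10, bool), (64, 64))
        with pytest.raises(ValueError):
            grid_displacements(field, 8.0)
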