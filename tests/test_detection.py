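"""Segmentation, weighted centroids, and the detection pipeline."""

import numpy as np
import pytest

from iscatrack import DetectionConfig, absolute_contrast, segment, weighted_centroid
from iscatrack.detection import (
    close_mask,
    detect_frame,
    robust_threshold,
    split_region_peaks,
)
from iscatrack.errors import DegenerateRegionError, InvalidParameterError


def bare_cfg(**kwargs):
    """Plain connected-component segmentation: no smoothing/closing/splitting."""
    base = dict(
        threshold=0.5,
        min_area_px=1,
        smooth_sigma_px=0.0,
        close_radius_px=0,
        peak_min_distance_px=0,
        edge_margin_px=0,
    )
    base.update(kwargs)
    return DetectionConfig(**base)


def flood_fill_oracle(mask, connectivity):
    """Iterative flood-fill labelling, independent of scipy."""
    H, W = mask.shape
    labels = np.zeros((H, W), dtype=int)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    nxt = 0
    for si in range(H):
        for sj in range(W):
            if mask[si, sj] and labels[si, sj] == 0:
                nxt += 1
                stack = [(si, sj)]
                labels[si, sj] = nxt
                while stack:
                    i, j = stack.pop()
                    for di, dj in nbrs:
                        a, b = i + di, j + dj
                        if 0 <= a < H and 0 <= b < W and mask[a, b] and labels[a, b] == 0:
                            labels[a, b] = nxt
                            stack.append((a, b))
    return labels


def same_partition(a, b):
    """Two labelings agree up to label permutation."""
    fa, fb = a.ravel(), b.ravel()
    if np.any((fa > 0) != (fb > 0)):
        return False
    pairs = set(zip(fa[fa > 0], fb[fa > 0]))
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


class TestAbsoluteContrast:
    def test_negative_contrast_folds_positive(self):
        assert absolute_contrast(np.array([[-0.02]]))[0, 0] == 0.02
        assert absolute_contrast(np.array([[0.0]]))[0, 0] == 0.0

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidParameterError):
            absolute_contrast(np.array([[np.nan]]))

    def test_dipole_lobes_form_one_region_when_contiguous(self):
        """Adjacent bright/dark lobes survive |.| and merge into one blob."""
        img = np.zeros((9, 9))
        img[4, 2:4] = 0.9   # bright lobe
        img[4, 4:6] = -0.9  # dark lobe, contiguous after abs
        labels = segment(absolute_contrast(img), bare_cfg())
        oracle = flood_fill_oracle(np.abs(img) >= 0.5, 8)
        assert labels.max() == 1
        assert same_partition(labels, oracle)


class TestSegment:
    def test_all_below_threshold_yields_nothing(self):
        labels = segment(np.zeros((5, 5)), bare_cfg())
        assert labels.max() == 0

    def test_subthreshold_gap_disconnects(self):
        img = np.zeros((3, 7))
        img[1, 1] = img[1, 5] = 1.0
        labels = segment(img, bare_cfg(connectivity=4))
        assert labels.max() == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_fields(self, rng, connectivity):
        for _ in range(10):
            mask = rng.random((16, 16)) < 0.4
            labels = segment(mask.astype(float), bare_cfg(connectivity=connectivity))
            assert same_partition(labels, flood_fill_oracle(mask, connectivity))

    def test_min_area_filter(self):
        img = np.zeros((8, 8))
        img[1, 1] = 1.0          # area 1: dropped
        img[4:6, 4:6] = 1.0      # area 4: kept
        labels = segment(img, bare_cfg(min_area_px=4))
        assert labels.max() == 1
        assert labels[1, 1] == 0

    def test_region_mode_drops_border_touching_regions(self):
        img = np.zeros((8, 8))
        img[0:3, 3] = 1.0
        img[4:6, 4:6] = 1.0
        cfg = bare_cfg(edge_margin_px=1, edge_margin_mode="region")
        labels = segment(img, cfg)
        assert labels.max() == 1
        assert np.all(labels[0:3, 3] == 0)


class TestWeightedCentroid:
    def test_symmetric_blob_centroid_at_pixel_centre(self):
        rows = np.array([4, 5, 6, 5])
        cols = np.array([5, 4, 5, 6])
        w = np.ones(4)
        loc = weighted_centroid(rows, cols, w, pixel_nm=33.0)
        assert loc.x_px == pytest.approx(5.0)
        assert loc.y_px == pytest.approx(5.0)
        assert loc.x_nm == pytest.approx(5.5 * 33.0)

    def test_weighted_pair(self):
        loc = weighted_centroid(
            np.array([0, 0]), np.array([0, 2]), np.array([1.0, 3.0]), pixel_nm=1.0
        )
        assert loc.x_px == pytest.approx(1.5)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(2, 12)
            rows = rng.integers(0, 30, n)
            cols = rng.integers(0, 30, n)
            w = rng.uniform(0.01, 1.0, n)
            loc = weighted_centroid(rows, cols, w, pixel_nm=33.0)
            # independent accumulation
            sx = sy = sw = 0.0
            for r, c, wi in zip(rows, cols, w):
                sx += c * wi
                sy += r * wi
                sw += wi
            assert loc.x_px == pytest.approx(sx / sw, rel=1e-12)
            assert loc.y_px == pytest.approx(sy / sw, rel=1e-12)

    def test_zero_weight_region_rejected(self):
        with pytest.raises(DegenerateRegionError):
            weighted_centroid(np.array([1]), np.array([1]), np.array([0.0]), 33.0)

    def test_translation_equivariance(self, rng):
        rows = rng.integers(5, 15, 6)
        cols = rng.integers(5, 15, 6)
        w = rng.uniform(0.1, 1.0, 6)
        a = weighted_centroid(rows, cols, w, 33.0)
        b = weighted_centroid(rows + 3, cols + 7, w, 33.0)
        assert b.x_px == pytest.approx(a.x_px + 7)
        assert b.y_px == pytest.approx(a.y_px + 3)


class TestMorphology:
    def test_closing_bridges_small_gaps(self):
        mask = np.zeros((9, 15), dtype=bool)
        mask[4, 2:6] = mask[4, 9:13] = True  # 3-px gap
        closed = close_mask(mask, 2)
        labels = segment(mask.astype(float), bare_cfg(), closed_mask=closed)
        assert labels.max() == 1

    def test_split_by_distant_peaks(self):
        img = np.zeros((20, 60))
        img[10, 10] = 1.0
        img[10, 45] = 0.8
        from scipy import ndimage

        smooth = ndimage.gaussian_filter(img, 3.0)
        labels = (smooth > 1e-4).astype(int)  # one connected region
        out = split_region_peaks(labels, smooth, min_distance_px=10, threshold=1e-3)
        assert out.max() == 2

    def test_nearby_peaks_left_intact(self):
        img = np.zeros((20, 40))
        img[10, 16] = 1.0
        img[10, 22] = 0.8
        from scipy import ndimage

        smooth = ndimage.gaussian_filter(img, 2.0)
        labels = (smooth > 1e-4).astype(int)
        out = split_region_peaks(labels, smooth, min_distance_px=10, threshold=1e-3)
        assert out.max() == 1


def test_robust_threshold_tracks_noise_scale(rng):
    noise = rng.normal(0.0, 0.01, size=(50, 50))
    thr = robust_threshold(noise, k_sigma=4.0)
    assert thr == pytest.approx(0.04, rel=0.15)


def test_detect_frame_localizes_an_isolated_gaussian_spot():
    y, x = np.mgrid[0:41, 0:41]
    img = 0.05 * np.exp(-(((x - 20.3) ** 2 + (y - 17.8) ** 2) / (2 * 3.0**2)))
    cfg = DetectionConfig(threshold=0.005, min_area_px=4, close_radius_px=0,
                          peak_min_distance_px=0)
    locs = detect_frame(img, cfg, pixel_nm=33.0)
    assert len(locs) == 1
    assert locs[0].x_px == pytest.approx(20.3, abs=0.2)
    assert locs[0].y_px == pytest.approx(17.8, abs=0.2)


def test_localization_error_shrinks_as_snr_grows():
    """RMSE of matched localizations decreases along a 3-point SNR ladder."""
    from iscatrack import SimulationConfig, score_detections, simulate_movie, track_movie
    from iscatrack import uniform_surface

    rmses = []
    for noise_sigma in (0.316, 0.158, 0.079):  # amplitude/noise = 5, 10, 20
        cfg = SimulationConfig(n_frames=300, arrival_rate=0.08,
                               noise_sigma=noise_sigma, seed=5)
        surf = uniform_surface((cfg.n_px, cfg.n_px), interior_margin_px=16)
        movie, truth = simulate_movie(cfg, surf)
        res = track_movie(movie, window=100, stride=10)
        s = score_detections(truth, res.localizations, 3 * cfg.pixel_nm,
                             frame_offset=100)
        rmses.append(s.rmse_nm)
    assert rmses[1] <= rmses[0] * 1.05
    assert rmses[2] <= rmses[1] * 1.05
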