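"""Static-count stage: Otsu thresholding, morphology, impurity removal, counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spermtrack.count import (binarize, count_sperm, fill_holes, morph_close, morph_open,
                              otsu_threshold, remove_small, scaled_min_area)
from spermtrack.synthetic import SceneConfig, simulate_video


def otsu_bruteforce(gray: np.ndarray) -> float:
    """Independent oracle: exhaustive search over all 256 thresholds."""
    hist, _ = np.histogram(gray, bins=256, range=(-0.5, 255.5))
    p = hist / hist.sum()
    best, best_ts = -1.0, []
    for t in range(256):
        w0 = p[: t + 1].sum()
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (np.arange(t + 1) * p[: t + 1]).sum() / w0
        m1 = (np.arange(t + 1, 256) * p[t + 1 :]).sum() / w1
        sb = w0 * w1 * (m0 - m1) ** 2
        if sb > best + 1e-12:
            best, best_ts = sb, [t]
        elif abs(sb - best) <= 1e-12:
            best_ts.append(t)
    return (best_ts[0] + best_ts[-1]) / 2 / 255.0


class TestOtsu:
    def test_half_and_half_plateau_midpoint(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[5:] = 255
        assert otsu_threshold(img) == pytest.approx(127 / 255)

    def test_constant_image_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            otsu_threshold(np.full((8, 8), 42, dtype=np.uint8))

    def test_matches_bruteforce_on_random_images(self, rng):
        for _ in range(100):
            img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
            assert otsu_threshold(img) == pytest.approx(otsu_bruteforce(img))

    def test_matches_bruteforce_on_bimodal_images(self, rng):
        for _ in range(20):
            img = np.clip(np.concatenate([
                rng.normal(60, 5, 200), rng.normal(190, 10, 56),
            ]).reshape(16, 16), 0, 255).astype(np.uint8)
            assert otsu_threshold(img) == pytest.approx(otsu_bruteforce(img))


class TestBinarize:
    def test_all_zero_stays_empty(self):
        assert not binarize(np.zeros((4, 4), dtype=np.uint8), 0.5).any()

    def test_checkerboard_selects_bright(self):
        board = np.indices((6, 6)).sum(axis=0) % 2 * 255
        mask = binarize(board.astype(np.uint8), 0.5)
        assert np.array_equal(mask, board == 255)

    def test_ramp_threshold_is_strict_greater(self):
        ramp = np.tile(np.arange(256, dtype=np.uint8), (2, 1))
        mask = binarize(ramp, 0.6235)  # 0.6235·255 = 158.9925
        assert np.array_equal(mask[0], np.arange(256) > 158.9925)
        assert mask[0].sum() == 97  # intensities 159..255


class TestMorphology:
    def test_fill_holes_closes_interior(self):
        sq = np.zeros((9, 9), dtype=bool)
        sq[2:7, 2:7] = True
        sq[4, 4] = False
        assert fill_holes(sq)[4, 4]

    def test_opening_severs_one_px_bridge(self):
        from skimage.measure import label

        m = np.zeros((11, 25), dtype=bool)
        m[1:10, 1:10] = True
        m[1:10, 15:24] = True
        m[5, 10:15] = True  # 1-px-wide bridge joining the squares
        assert label(m, connectivity=2).max() == 1
        assert label(morph_open(m, 1), connectivity=2).max() == 2

    def test_open_and_close_on_empty_mask(self):
        empty = np.zeros((5, 5), dtype=bool)
        assert not morph_open(empty, 1).any()
        assert not morph_close(empty, 1).any()

    def test_close_bridges_gap_opening_cannot(self):
        m = np.zeros((7, 12), dtype=bool)
        m[2:5, 1:5] = True
        m[2:5, 7:11] = True
        from skimage.measure import label

        assert label(morph_close(m, 2), connectivity=2).max() == 1


class TestRemoveSmall:
    def test_keeps_large_drops_small(self):
        m = np.zeros((40, 40), dtype=bool)
        m[1:21, 1:11] = True   # 200 px
        m[30:35, 30:36] = True  # 30 px
        out = remove_small(m, 70)
        assert out[5, 5] and not out[32, 32]

    def test_zero_threshold_is_identity(self, rng):
        m = rng.random((20, 20)) > 0.7
        assert np.array_equal(remove_small(m, 0), m)

    def test_all_below_threshold_gives_empty(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2, 2] = m[7, 7] = True
        assert not remove_small(m, 5).any()

    @given(st.integers(min_value=0, max_value=120))
    @settings(max_examples=20, deadline=None)
    def test_survivor_count_monotone_in_threshold(self, thr):
        from skimage.measure import label

        rng = np.random.default_rng(99)
        m = rng.random((50, 50)) > 0.6
        n_small = label(remove_small(m, thr), connectivity=2).max()
        n_smaller = label(remove_small(m, max(0, thr - 10)), connectivity=2).max()
        assert n_small <= n_smaller


class TestCountSperm:
    def test_counts_sperm_not_debris(self):
        cfg = SceneConfig(n_progressive=6, n_nonprogressive=3, n_immotile=3, n_debris=5,
                          n_frames=1, noise_sigma=0.0, seed=3)
        seq, truth = simulate_video(cfg)
        res = count_sperm(seq[0], min_area=scaled_min_area(0.5))
        assert res.count == truth.count_per_frame[0] == 12
        assert len(res.detections) == res.count

    def test_blank_noise_frame_counts_zero(self, rng):
        # fixed level: sensor noise sits far below any sensible threshold
        frame = np.clip(rng.normal(60, 3, (64, 64)), 0, 255).astype(np.uint8)
        res = count_sperm(frame, min_area=70, level=0.5)
        assert res.count == 0

    def test_count_monotone_in_min_area(self):
        cfg = SceneConfig(n_frames=1, seed=4)
        seq, _ = simulate_video(cfg)
        counts = [count_sperm(seq[0], min_area=a).count for a in (4, 40, 120, 400)]
        assert counts == sorted(counts, reverse=True)

    def test_error_rate_under_5pct_over_sequence(self):
        cfg = SceneConfig(n_frames=20, seed=5)
        seq, truth = simulate_video(cfg)
        ma = scaled_min_area(0.5)
        errs = [abs(count_sperm(seq[i], min_area=ma, frame_index=i).count - truth.count_per_frame[i])
                / truth.count_per_frame[i] for i in range(20)]
        assert np.mean(errs) * 100 < 5.0

    def test_declump_splits_adhered_pair(self):
        from spermtrack.count import declump_detections

        # nine isolated cells fix the median area; one blob is a merged pair
        mask = np.zeros((120, 120), dtype=bool)
        for i in range(3):
            for j in range(3):
                mask[10 + 35 * i:16 + 35 * i, 10 + 35 * j:20 + 35 * j] = True  # 60 px each
        mask[100:106, 10:30] = True  # 120 px: two adhered cells
        dets = declump_detections(mask)
        assert len(dets) == 11
        pair = [d for d in dets if d.centroid[0] > 90]
        assert len(pair) == 2
        assert abs(pair[0].centroid[1] - pair[1].centroid[1]) > 5

    def test_dark_polarity_inverts(self):
        img = np.full((32, 32), 220, dtype=np.uint8)
        img[10:20, 10:20] = 30  # dark object on bright field
        res = count_sperm(img, min_area=20, polarity="dark")
        assert res.count == 1
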