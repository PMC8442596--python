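"""Saliency model: feature maps, max-norm, map geometry, signal, filter."""

import numpy as np
import pytest

from tvcentrality import (
    BlobEvent,
    SaliencySignal,
    SyntheticMovieSpec,
    ValidationError,
    compute_feature_maps,
    compute_saliency_map,
    generate_synthetic_movie,
    lowpass_filter,
    mean_saliency_signal,
    normalize_map,
)


def bruteforce_max_norm(m):
    """Direct re-implementation of the max-norm operator: explicit
    neighbourhood scan for strict 3x3 local maxima."""
    m = np.asarray(m, dtype=float)
    lo, hi = m.min(), m.max()
    if hi == lo:
        return m - lo
    r = (m - lo) / (hi - lo)
    h, w = r.shape
    maxima = []
    for i in range(h):
        for j in range(w):
            v = r[i, j]
            neigh = [r[a, b]
                     for a in range(max(0, i - 1), min(h, i + 2))
                     for b in range(max(0, j - 1), min(w, j + 2))
                     if (a, b) != (i, j)]
            if all(v > x for x in neigh) and v < 1.0:
                maxima.append(v)
    mbar = np.mean(maxima) if maxima else 0.0
    return r * (1.0 - mbar) ** 2


class TestFeatureMaps:
    def test_uniform_gray_frame_gives_zero_contrast(self):
        frame = np.full((256, 256, 3), 120, np.uint8)
        maps = compute_feature_maps(frame)
        assert len(maps["intensity"]) == 6
        assert len(maps["color"]) == 12
        assert len(maps["orientation"]) == 24
        for ch in maps.values():
            for m in ch:
                assert np.abs(m).max() < 1e-9

    def test_pure_red_field_has_no_color_contrast(self):
        frame = np.zeros((256, 256, 3), np.uint8)
        frame[..., 0] = 210
        maps = compute_feature_maps(frame)
        for m in maps["color"]:
            assert np.abs(m).max() < 1e-9

    def test_white_disk_on_black_peaks_on_disk(self):
        frame = np.zeros((256, 256, 3), np.uint8)
        yy, xx = np.mgrid[0:256, 0:256]
        disk = (xx - 128) ** 2 + (yy - 128) ** 2 <= 40**2
        frame[disk] = 255
        maps = compute_feature_maps(frame)
        total = np.sum(maps["intensity"], axis=0)
        iy, ix = np.unravel_index(np.argmax(total), total.shape)
        # argmax within the disk region (level-4 coordinates)
        assert disk[min(255, iy * 16 + 8), min(255, ix * 16 + 8)]
        # far field (frame corner) carries no intensity contrast
        assert total[0, 0] < 0.05 * total.max()

    def test_frame_too_small_rejected_with_minimum(self):
        with pytest.raises(ValidationError, match="256"):
            compute_feature_maps(np.zeros((128, 128, 3), np.uint8))


class TestNormalizeMap:
    def test_single_dominant_peak_keeps_weight(self):
        m = np.zeros((30, 30))
        m[15, 15] = 10.0
        out = normalize_map(m)
        assert out.max() == pytest.approx(1.0, abs=1e-12)  # (M - 0)^2 * 1

    def test_many_equal_peaks_suppressed(self):
        m = np.zeros((32, 32))
        m[4::8, 4::8] = 5.0  # grid of identical peaks, all at the max
        m[4, 4] = 5.5  # one barely-dominant global max
        out = normalize_map(m)
        assert out.max() < 0.02  # (1 - ~0.9)^2

    def test_matches_bruteforce_local_maxima_oracle(self, rng):
        for _ in range(5):
            m = rng.random((20, 25))
            np.testing.assert_allclose(
                normalize_map(m), bruteforce_max_norm(m), atol=1e-12)

    def test_all_zero_map_passes_through(self):
        m = np.zeros((10, 10))
        np.testing.assert_array_equal(normalize_map(m), m)


class TestSaliencyMap:
    def test_hd_frame_yields_64_by_45_map(self, rng):
        frame = rng.integers(0, 256, (720, 1024, 3), dtype=np.uint8)
        sm = compute_saliency_map(frame)
        assert sm.values.shape == (45, 64)
        assert sm.scale_factor == 16
        assert np.all(sm.values >= 0)

    def test_uniform_frame_gives_zero_map(self):
        sm = compute_saliency_map(np.full((256, 256, 3), 77, np.uint8))
        assert sm.values.max() < 1e-6

    def test_blob_is_global_argmax(self):
        ev = BlobEvent(0.0, 0.5, 310, 170, 40, 1.0, (255, 255, 255))
        spec = SyntheticMovieSpec(width=512, height=288, duration_s=0.5,
                                  blob_events=(ev,), background_level=30)
        frames, gt = generate_synthetic_movie(spec)
        sm = compute_saliency_map(frames[0])
        iy, ix = np.unravel_index(np.argmax(sm.values), sm.values.shape)
        assert gt.frame_masks[0][iy * 16 + 8, ix * 16 + 8]

    def test_invariant_to_global_brightness_shift(self, rng):
        base = rng.integers(100, 200, (256, 256, 3))
        a = compute_saliency_map(base.astype(np.uint8))
        b = compute_saliency_map((base + 20).astype(np.uint8))
        np.testing.assert_allclose(a.values, b.values, atol=1e-6)

    def test_downscale_contract_ceiling_division(self, rng):
        frame = rng.integers(0, 256, (260, 300, 3), dtype=np.uint8)
        sm = compute_saliency_map(frame)
        assert sm.values.shape == (int(np.ceil(260 / 16)),
                                   int(np.ceil(300 / 16)))


class TestMeanSaliencySignal:
    def test_identical_frames_give_constant_signal(self):
        maps = [np.full((4, 5), 0.3)] * 48
        sig = mean_saliency_signal(maps, fps=24, tr_seconds=1.0)
        np.testing.assert_allclose(sig.values, 0.3, atol=1e-15)
        assert sig.values.size == 2

    def test_toy_stack_matches_hand_computed_grand_mean(self):
        maps = [np.array([[0.0, 1.0], [2.0, 3.0]]),
                np.array([[1.0, 1.0], [1.0, 1.0]]),
                np.array([[4.0, 0.0], [0.0, 0.0]])]
        sig = mean_saliency_signal(maps, fps=3, tr_seconds=1.0)
        assert sig.values.tolist() == [pytest.approx((1.5 + 1.0 + 1.0) / 3)]

    def test_trailing_partial_bin_dropped(self):
        maps = [np.full((2, 2), float(i)) for i in range(50)]
        sig = mean_saliency_signal(maps, fps=24, tr_seconds=1.0)
        assert sig.values.size == 2

    def test_scaling_maps_scales_signal_linearly(self, rng):
        maps = [rng.random((3, 4)) for _ in range(24)]
        a = mean_saliency_signal(maps, fps=24, tr_seconds=1.0)
        b = mean_saliency_signal([3.5 * m for m in maps], fps=24,
                                 tr_seconds=1.0)
        np.testing.assert_allclose(b.values, 3.5 * a.values, rtol=1e-12)

    def test_non_integral_frames_per_tr_rejected(self):
        with pytest.raises(ValidationError):
            mean_saliency_signal([np.zeros((2, 2))] * 10, fps=24,
                                 tr_seconds=0.72)


class TestLowpassFilter:
    def test_constant_signal_unchanged(self):
        sig = SaliencySignal(values=np.full(200, 1.7), tr_seconds=1.0)
        out = lowpass_filter(sig, 0.1)
        np.testing.assert_allclose(out.values, 1.7, atol=1e-9)
        assert out.filtered and out.cutoff_hz == 0.1

    def test_slow_sinusoid_preserved(self):
        t = np.arange(2000)
        sig = SaliencySignal(values=np.sin(2 * np.pi * 0.01 * t),
                             tr_seconds=1.0)
        out = lowpass_filter(sig, 0.1)
        ratio = out.values.std() / sig.values.std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_fast_sinusoid_attenuated_20db(self):
        t = np.arange(2000)
        sig = SaliencySignal(values=np.sin(2 * np.pi * 0.4 * t),
                             tr_seconds=1.0)
        out = lowpass_filter(sig, 0.1)
        atten_db = 20 * np.log10(sig.values.std() / out.values.std())
        assert atten_db > 20

    def test_cutoff_at_or_above_nyquist_rejected(self):
        sig = SaliencySignal(values=np.zeros(100), tr_seconds=1.0)
        with pytest.raises(ValidationError):
            lowpass_filter(sig, 0.5)

    def test_short_signal_rejected(self):
        sig = SaliencySignal(values=np.zeros(20), tr_seconds=1.0)
        with pytest.raises(ValidationError):
            lowpass_filter(sig, 0.1)
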