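"""Foreground extraction: statistics, thresholding rules, annotation maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import scalar_fe1 as _scalar_fe1
from _oracles import scalar_stats as _scalar_stats

from antdet.foreground import (EPS_SCALE, MedianExtractor,
                               PixelStatsExtractor, annotate_sequence,
                               compute_pixel_statistics,
                               extract_foreground_fe1,
                               extract_foreground_median,
                               make_pseudo_annotation)


class TestPixelStatistics:
    def test_constant_video(self):
        frames = np.full((5, 4, 4), 0.7)
        stats = compute_pixel_statistics(frames)
        assert np.allclose(stats.mean, 0.7)
        assert np.allclose(stats.std, 0.0)

    def test_three_values_known_answer(self):
        frames = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        stats = compute_pixel_statistics(frames)
        assert stats.mean[0, 0] == pytest.approx(2.0)
        assert stats.std[0, 0] == pytest.approx(1.0)  # N-1 denominator

    def test_matches_scalar_oracle(self, rng):
        frames = rng.random((6, 4, 4))
        stats = compute_pixel_statistics(frames)
        mean, std = _scalar_stats(frames)
        np.testing.assert_allclose(stats.mean, mean)
        np.testing.assert_allclose(stats.std, std)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            compute_pixel_statistics(np.zeros((1, 4, 4)))


class TestFE1:
    def test_constant_video_all_background(self):
        frames = np.full((6, 3, 3), 0.5)
        for T in (0.5, 2.5, 10.0):
            assert not extract_foreground_fe1(frames, T=T).any()

    def test_single_outlier_hand_evaluation(self):
        """Nine zeros and one 100: mean 10, std sqrt(1000); only the
        outlier frame exceeds 2.5 sigma."""
        vals = np.array([0.0] * 9 + [100.0])
        frames = vals.reshape(10, 1, 1)
        masks = extract_foreground_fe1(frames, T=2.5)
        assert masks[9, 0, 0]
        assert not masks[:9].any()

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(5):
            frames = rng.random((6, 8, 8))
            got = extract_foreground_fe1(frames, T=2.5)
            want = _scalar_fe1(frames, 2.5)
            assert np.array_equal(got, want)

    def test_affine_invariance(self, rng):
        frames = rng.random((6, 8, 8))
        base = extract_foreground_fe1(frames, T=2.5)
        transformed = extract_foreground_fe1(3.0 * frames + 0.25, T=2.5)
        assert np.array_equal(base, transformed)

    def test_monotone_in_threshold(self, rng):
        frames = rng.random((8, 8, 8))
        prev = None
        for T in (1.0, 1.5, 2.0, 2.5, 3.0):
            mask = extract_foreground_fe1(frames, T=T)
            if prev is not None:
                assert not (mask & ~prev).any()  # raising T adds nothing
            prev = mask

    def test_shape_mismatch_error(self, rng):
        frames = rng.random((6, 8, 8))
        stats = compute_pixel_statistics(rng.random((6, 4, 4)))
        with pytest.raises(ValueError):
            extract_foreground_fe1(frames, stats, T=2.5)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 10.0),
           st.floats(-5.0, 5.0))
    def test_affine_invariance_property(self, seed, a, b):
        rng = np.random.default_rng(seed)
        frames = rng.random((5, 6, 6))
        assert np.array_equal(
            extract_foreground_fe1(frames, T=2.5),
            extract_foreground_fe1(a * frames + b, T=2.5))


class TestMedianExtractor:
    def test_constant_video_all_background(self):
        frames = np.full((5, 3, 3), 0.4)
        assert not extract_foreground_median(frames).any()

    def test_outlier_with_scale_floor(self):
        """MAD is zero, so the floored scale applies: only the gross
        outlier frame is foreground."""
        frames = np.array([0.0, 0.0, 0.0, 0.0, 100.0]).reshape(5, 1, 1)
        masks = extract_foreground_median(frames, k_mad=3.0)
        assert masks[4, 0, 0]
        assert not masks[:4].any()
        assert EPS_SCALE == pytest.approx(1e-6)

    def test_needs_three_frames(self):
        with pytest.raises(ValueError):
            extract_foreground_median(np.zeros((2, 3, 3)))

    def test_diverges_from_fe1_on_wind_frames(self, small_video):
        """The two extractors must disagree somewhere (source diversity)."""
        fe1 = extract_foreground_fe1(small_video.frames, T=2.5)
        med = extract_foreground_median(small_video.frames, k_mad=3.0)
        assert (fe1 != med).any()


class TestPseudoAnnotation:
    def test_empty_mask(self):
        assert (make_pseudo_annotation(np.zeros((8, 8), bool)) == 0).all()

    def test_single_pixel_boundary_is_4_neighbors(self):
        mask = np.zeros((7, 7), bool)
        mask[3, 3] = True
        lm = make_pseudo_annotation(mask, min_area=1, boundary_radius=1)
        assert lm[3, 3] == 1
        ring = {(2, 3), (4, 3), (3, 2), (3, 4)}
        assert {tuple(p) for p in np.argwhere(lm == 2)} == ring

    def test_small_components_removed(self):
        mask = np.zeros((10, 10), bool)
        mask[1, 1] = True                 # area 1 < min_area
        mask[5:8, 5:8] = True             # area 9 survives
        lm = make_pseudo_annotation(mask, min_area=5, boundary_radius=0)
        assert lm[1, 1] == 0
        assert (lm[5:8, 5:8] == 1).all()

    def test_gap_between_close_blobs_is_boundary(self):
        """Two blobs one pixel apart: the ring claims the gap, keeping the
        two body components separated."""
        mask = np.zeros((9, 12), bool)
        mask[3:6, 2:5] = True
        mask[3:6, 6:9] = True             # gap at column 5
        lm = make_pseudo_annotation(mask, min_area=1, boundary_radius=1)
        assert (lm[3:6, 5] == 2).all()
        assert lm[4, 3] == 1 and lm[4, 7] == 1

    def test_partition_property(self, small_video):
        masks = extract_foreground_fe1(small_video.frames, T=2.5)
        lms = annotate_sequence(masks, min_area=5, boundary_radius=2)
        assert set(np.unique(lms)) <= {0, 1, 2}

    def test_zero_boundary_radius(self):
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        lm = make_pseudo_annotation(mask, min_area=1, boundary_radius=0)
        assert not (lm == 2).any()


def test_per_channel_mode_catches_single_channel_motion(rng):
    """A deviation confined to one color channel triggers the per-channel
    mode; luma mixing can dilute it below threshold."""
    frames = np.full((10, 4, 4, 3), 0.5)
    frames += 0.001 * rng.standard_normal(frames.shape)
    frames[9, 2, 2, 2] = 1.0  # strong outlier in the blue channel only
    per_ch = extract_foreground_fe1(frames, color_mode="per_channel")
    assert per_ch[9, 2, 2]
    assert per_ch.shape == (10, 4, 4)


class TestTransformers:
    def test_pixel_stats_extractor_roundtrip(self, small_video):
        tr = PixelStatsExtractor(T=2.5).fit(small_video.frames)
        lm = tr.transform(small_video.frames)
        direct = annotate_sequence(
            extract_foreground_fe1(small_video.frames, T=2.5),
            min_area=5, boundary_radius=2)
        assert np.array_equal(lm, direct)

    def test_median_extractor_sklearn_params(self):
        tr = MedianExtractor(k_mad=2.0)
        assert tr.get_params()["k_mad"] == 2.0
        tr.set_params(k_mad=4.0)
        assert tr.k_mad == 4.0
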