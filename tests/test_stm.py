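"""Spike-triggered masks: response windows, weighted averaging, the shuffle
significance test, and the mask metrics."""

import numpy as np
import pandas as pd
import pytest

from bubblestm import (
    EmptyResponseError,
    InsufficientDataError,
    InvalidConfigurationError,
    SessionLog,
    SpikeTriggeredMask,
    compute_frame_responses,
    intermask_comparison,
    make_bubble_mask,
    mask_metrics,
    raw_stm,
    significance,
    similarity_analysis,
)
from bubblestm.receptive_field import SpatialRF


def simple_session(spikes, n_frames=3, duration=240.0):
    frames = pd.DataFrame(
        {
            "frame_id": np.arange(n_frames),
            "kind": "bubble",
            "onset_ms": np.arange(n_frames) * duration,
            "duration_ms": duration,
            "base_image_id": "img0",
            "orientation_deg": np.nan,
            "sf_cpd": np.nan,
            "phase_deg": np.nan,
            "probe_x_deg": np.nan,
            "probe_y_deg": np.nan,
            "eye_x_deg": 0.0,
            "eye_y_deg": 0.0,
        }
    )
    return SessionLog(frames=frames, spikes=np.sort(spikes), meta={"size_px": 64})


def mask_ensemble(n, size=64, n_windows=8, sigma=4.0, seed=0):
    rng = np.random.default_rng(seed)
    return np.stack(
        [make_bubble_mask(size, n_windows, sigma, rng).transparency for _ in range(n)]
    ).astype(np.float32)


def make_stm(weights, labels):
    return SpikeTriggeredMask(
        base_image_id="img0",
        weights=np.asarray(weights, float),
        labels=np.asarray(labels, np.int8),
        n_frames=100,
        alpha=0.01,
        n_shuffles=200,
    )


class TestFrameResponses:
    def test_three_spikes_in_window_give_30_hz(self):
        log = simple_session([60.0, 100.0, 149.0], n_frames=1)
        out = compute_frame_responses(log)
        assert out["rate_hz"].iloc[0] == pytest.approx(30.0)

    def test_no_spikes_gives_zero(self):
        log = simple_session([], n_frames=2)
        assert (compute_frame_responses(log)["rate_hz"] == 0).all()

    def test_window_is_half_open(self):
        """A spike exactly at onset + 150 ms belongs to no window."""
        log = simple_session([150.0], n_frames=1)
        assert compute_frame_responses(log)["rate_hz"].iloc[0] == 0.0
        log = simple_session([149.999], n_frames=1)
        assert compute_frame_responses(log)["rate_hz"].iloc[0] == 10.0

    def test_overlapping_windows_rejected(self):
        log = simple_session([60.0], n_frames=3, duration=80.0)
        with pytest.raises(InvalidConfigurationError):
            compute_frame_responses(log)


class TestRawSTM:
    def test_constant_responses_center_near_zero(self):
        T = mask_ensemble(300)
        m = raw_stm(T, np.full(300, 5.0))
        assert np.abs(m).max() < 1e-6

    def test_rate_equals_transparency_at_pixel_peaks_there(self):
        T = mask_ensemble(2000, seed=3)
        p = (20, 44)  # (y, x)
        m = raw_stm(T, T[:, p[0], p[1]].astype(float))
        py, px = np.unravel_index(np.argmax(m), m.shape)
        assert np.hypot(px - p[1], py - p[0]) <= 4.0

    def test_joint_permutation_invariance(self):
        T = mask_ensemble(200)
        w = np.random.default_rng(0).uniform(0, 10, 200)
        perm = np.random.default_rng(1).permutation(200)
        # float32 mask stacks: summation order shifts the last bits
        assert np.allclose(raw_stm(T, w), raw_stm(T[perm], w[perm]), atol=1e-6)

    def test_all_zero_responses_rejected(self):
        with pytest.raises(EmptyResponseError):
            raw_stm(mask_ensemble(60), np.zeros(60))


class TestSignificance:
    def test_alpha_one_marks_nearly_everything(self):
        T = mask_ensemble(100)
        w = np.random.default_rng(0).uniform(0, 10, 100)
        s = significance(T, w, n_shuffles=200, alpha=1.0, rng=np.random.default_rng(1))
        assert s.area > 0.9 * s.labels.size

    def test_scale_equivariance_of_significant_set(self):
        T = mask_ensemble(200, seed=5)
        w = T[:, 30, 30].astype(float) * 10
        a = significance(T, w, n_shuffles=300, rng=np.random.default_rng(2))
        b = significance(T, 3.0 * w, n_shuffles=300, rng=np.random.default_rng(2))
        assert np.array_equal(a.labels, b.labels)

    def test_null_inputs_stay_near_nominal_rate(self):
        """Responses shuffled before the test: significant-pixel fraction
        stays within a factor ~3 of alpha."""
        T = mask_ensemble(600, seed=7)
        rng = np.random.default_rng(8)
        w = rng.uniform(0, 10, 600)  # independent of the masks
        s = significance(T, w, n_shuffles=500, alpha=0.01, rng=rng)
        assert s.area / s.labels.size < 0.05

    def test_labels_follow_weight_sign(self):
        T = mask_ensemble(400, seed=9)
        w = 5 + 20 * T[:, 30, 30].astype(float) - 20 * T[:, 10, 50].astype(float)
        s = significance(T, np.clip(w, 0, None), n_shuffles=300,
                         rng=np.random.default_rng(3))
        assert s.labels[30, 30] == 1 and s.weights[30, 30] > 0
        assert s.labels[10, 50] == -1 and s.weights[10, 50] < 0

    def test_configuration_errors(self):
        T = mask_ensemble(60)
        w = np.ones(60)
        with pytest.raises(InvalidConfigurationError):
            significance(T, w, n_shuffles=100)
        with pytest.raises(InvalidConfigurationError):
            significance(T, w, n_shuffles=200, alpha=0.001)
        with pytest.raises(InsufficientDataError):
            significance(T[:20], w[:20], n_shuffles=200)


class TestMaskMetrics:
    def rf(self, radius_deg=0.5):
        return SpatialRF(
            response_map=np.ones((3, 3)),
            grid_x_deg=np.arange(3.0),
            grid_y_deg=np.arange(3.0),
            center_deg=(0.0, 0.0),
            radius_deg=radius_deg,
        )

    def test_hand_built_fraction(self):
        labels = np.zeros((128, 128), np.int8)
        labels[:10, :10] = 1  # 100 px
        s = make_stm(np.where(labels, 1.0, 0.0), labels)
        out = mask_metrics(s, self.rf(0.5), deg_per_px=0.025)  # radius 20 px
        assert out["area_fraction_of_crf"] == pytest.approx(100 / (np.pi * 400))
        assert out["crf_outside_flag"]  # corner block is far from the center

    def test_empty_mask(self):
        s = make_stm(np.zeros((64, 64)), np.zeros((64, 64), np.int8))
        out = mask_metrics(s, self.rf(), deg_per_px=0.025)
        assert out["area_px"] == 0 and out["centroid_px"] is None
        assert not out["crf_outside_flag"]

    def test_mask_inside_crf_not_flagged(self):
        labels = np.zeros((128, 128), np.int8)
        labels[62:66, 62:66] = 1  # at raster center = CRF center
        s = make_stm(np.where(labels, 1.0, 0.0), labels)
        out = mask_metrics(s, self.rf(0.5), deg_per_px=0.025)
        assert not out["crf_outside_flag"]


class TestSimilarity:
    def test_zero_stm_gives_zero_similarity(self):
        T = mask_ensemble(120)
        s = make_stm(np.zeros((64, 64)), np.zeros((64, 64), np.int8))
        out = similarity_analysis(s, T, np.ones(120))
        assert np.all(out["similarity"] == 0)

    def test_nested_masks_order_similarity(self):
        s = make_stm(np.full((64, 64), 0.5), np.ones((64, 64), np.int8))
        big = np.full((1, 64, 64), 0.8, dtype=np.float32)
        small = np.full((1, 64, 64), 0.3, dtype=np.float32)
        T = np.concatenate([big, small])
        out = similarity_analysis(s, T, np.array([1.0, 2.0]))
        assert out["similarity"][0] > out["similarity"][1]

    def test_top_percentile_mean_rate(self):
        T = mask_ensemble(200, seed=11)
        s = make_stm(np.ones((64, 64)), np.ones((64, 64), np.int8))
        w = np.arange(200.0)
        out = similarity_analysis(s, T, w, unmasked_rate=50.0, q=90)
        assert out["unmasked_mean_rate"] == 50.0
        assert np.isfinite(out["top_mean_rate"])


class TestIntermask:
    def test_identical_masks(self):
        labels = np.zeros((64, 64), np.int8)
        labels[10:20, 10:20] = 1
        s = make_stm(np.where(labels, 1.0, 0.0), labels)
        out = intermask_comparison([s, s])
        assert out["overlap_pct"].iloc[0] == 100.0
        assert out["size_diff_pct"].iloc[0] == 0.0

    def test_disjoint_equal_masks(self):
        a = np.zeros((64, 64), np.int8)
        a[:8, :8] = 1
        b = np.zeros((64, 64), np.int8)
        b[40:48, 40:48] = 1
        out = intermask_comparison(
            [make_stm(a.astype(float), a), make_stm(b.astype(float), b)]
        )
        assert out["overlap_pct"].iloc[0] == 0.0
        assert out["size_diff_pct"].iloc[0] == 0.0

    def test_nested_masks_arithmetic(self):
        a = np.zeros((64, 64), np.int8)
        a[:10, :20] = 1  # 200 px
        b = np.zeros((64, 64), np.int8)
        b[:10, :10] = 1  # 100 px inside a
        out = intermask_comparison(
            [make_stm(a.astype(float), a), make_stm(b.astype(float), b)]
        )
        assert out["overlap_pct"].iloc[0] == 50.0
        assert out["size_diff_pct"].iloc[0] == 50.0

    def test_fewer_than_two_masks_rejected(self):
        s = make_stm(np.ones((8, 8)), np.ones((8, 8), np.int8))
        with pytest.raises(InsufficientDataError):
            intermask_comparison([s])
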