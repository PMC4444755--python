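"""Amplitude-only SRF filtering: spectral identities, area-matched
thresholding, prediction scoring and orientation-power analyses."""

import numpy as np
import pytest

from bubblestm import (
    GratingStim,
    InvalidConfigurationError,
    SpikeTriggeredMask,
    build_filter,
    filter_image,
    make_grating,
    predict_masks,
    score_prediction,
)
from bubblestm.linear_model import _top_k_mask, image_mask_osi, orientation_power
from bubblestm.receptive_field import SRF
from bubblestm.synthetic import default_grating_grids, gaussian_srf


def make_srf(R):
    og, fg, pg = default_grating_grids()
    R = np.asarray(R, dtype=float)
    return SRF(
        orientations_deg=og,
        spatial_freqs_cpd=fg,
        phases_deg=pg,
        response=R,
        per_phase=np.repeat(R[..., None], 4, axis=2),
        counts=np.full((8, 6, 4), 9),
    )


def all_pass_gain(size):
    g = np.ones((size, size))
    g[0, 0] = 0.0
    return g


class TestFilterImage:
    def test_all_pass_filter_returns_squared_contrast(self, small_image):
        out = filter_image(small_image.pixels, all_pass_gain(64))
        expected = (small_image.pixels - small_image.pixels.mean()) ** 2
        assert np.allclose(out, expected, atol=1e-12)

    def test_zero_filter_returns_zero(self, small_image):
        out = filter_image(small_image.pixels, np.zeros((64, 64)))
        assert np.allclose(out, 0.0)

    def test_parseval_identity(self, small_image):
        """Sum of the squared filtered raster equals the spectral-domain sum."""
        rng = np.random.default_rng(0)
        gain = rng.uniform(0, 1, (64, 64))
        gain[0, 0] = 0.0
        # enforce conjugate symmetry so the filtered raster is real
        gain = 0.5 * (gain + np.roll(np.flip(gain), 1, axis=(0, 1)))
        out = filter_image(small_image.pixels, gain)
        img = small_image.pixels - small_image.pixels.mean()
        spec = np.abs(np.fft.fft2(img) * gain) ** 2
        assert np.sum(out) == pytest.approx(spec.sum() / 64**2, rel=1e-9)

    def test_shape_mismatch_rejected(self, small_image):
        with pytest.raises(InvalidConfigurationError):
            filter_image(small_image.pixels, np.zeros((32, 32)))


class TestBuildFilter:
    def test_optimal_grating_squared_response_is_unity(self):
        og, fg, _ = default_grating_grids()
        srf = make_srf(gaussian_srf(og, fg, 67.5, 1.5) * 40.0)
        filt = build_filter(srf, 128, 0.025)
        g = make_grating(
            GratingStim(
                filt.opt_orientation_deg,
                filt.opt_sf_cpd,
                0.0,
                inner_radius_deg=np.inf,
                outer_radius_deg=np.inf,
            ),
            128,
            0.025,
        )
        assert filter_image(g, filt.gain).max() == pytest.approx(1.0, rel=0.01)

    def test_constant_srf_gives_flat_gain(self):
        srf = make_srf(np.full((8, 6), 5.0))
        filt = build_filter(srf, 64, 0.025)
        inband = filt.gain[filt.gain > 0]
        assert inband.std() / inband.mean() < 1e-9
        assert filt.gain[0, 0] == 0.0

    def test_delta_srf_concentrates_gain_symmetrically(self):
        R = np.zeros((8, 6))
        R[3, 2] = 10.0  # orientation 67.5 deg, sf ~1.15 c/deg
        filt = build_filter(make_srf(R), 128, 0.025)
        g = filt.gain
        ky, kx = np.unravel_index(np.argmax(g), g.shape)
        # conjugate-symmetric partner bin carries the same gain
        assert g[(-ky) % 128, (-kx) % 128] == pytest.approx(g[ky, kx])
        # gain is concentrated: top bins carry most of the mass
        flat = np.sort(g.ravel())[::-1]
        assert flat[:200].sum() > 0.8 * g.sum()

    def test_passband_vs_stopband_gain_ratio(self):
        """Gratings inside vs outside the passband differ by ~the squared
        gain ratio after filtering."""
        og, fg, _ = default_grating_grids()
        srf = make_srf(gaussian_srf(og, fg, 90.0, 1.5, orientation_bw_deg=25.0))
        filt = build_filter(srf, 128, 0.025)
        def peak_response(theta):
            g = make_grating(
                GratingStim(theta, 1.5, 0.0, inner_radius_deg=np.inf,
                            outer_radius_deg=np.inf),
                128, 0.025,
            )
            return filter_image(g, filt.gain).max()
        assert peak_response(90.0) > 10 * peak_response(0.0)


class TestPredictMasks:
    def test_all_pass_srf_selects_largest_contrast_pixels(self, small_image):
        srf = make_srf(np.full((8, 6), 3.0))
        k = 40
        pred = predict_masks(small_image, srf, k)
        contrast = (small_image.pixels - small_image.pixels.mean()) ** 2
        # filtered map with a flat passband ~ band-passed contrast; exact
        # equality holds for the scaled all-pass case
        filt = build_filter(srf, 64, small_image.deg_per_px)
        expected, _ = _top_k_mask(filter_image(small_image.pixels, filt.gain), k)
        assert np.array_equal(pred.excitatory, expected)
        assert pred.excitatory.sum() == k
        del contrast

    def test_unity_srf_gives_empty_suppressive_set(self, small_image):
        srf = make_srf(np.full((8, 6), 1.0))
        pred = predict_masks(small_image, srf, 30)
        assert pred.suppressive.sum() == 0

    def test_grating_patch_prediction_confined_to_patch(self):
        og, fg, _ = default_grating_grids()
        srf = make_srf(gaussian_srf(og, fg, 45.0, 2.0))
        bg = np.full((128, 128), 0.5)
        patch = make_grating(GratingStim(45.0, 2.0, 0.0), 48, 0.025)
        raster = bg.copy()
        raster[40:88, 40:88] = patch
        pred = predict_masks(raster, build_filter(srf, 128, 0.025), 300)
        ys, xs = np.nonzero(pred.excitatory)
        inside = (ys >= 34) & (ys < 94) & (xs >= 34) & (xs < 94)
        assert inside.mean() > 0.95

    def test_area_matching_is_exact(self, small_image):
        srf = make_srf(np.full((8, 6), 1.0))
        for k in (1, 17, 256):
            pred = predict_masks(small_image, srf, k)
            assert int(pred.excitatory.sum()) == k

    def test_target_area_bounds(self, small_image):
        srf = make_srf(np.full((8, 6), 1.0))
        with pytest.raises(InvalidConfigurationError):
            predict_masks(small_image, srf, 0)
        with pytest.raises(InvalidConfigurationError):
            predict_masks(small_image, srf, 64 * 64 + 1)

    def test_tie_break_deterministic_row_major(self):
        vals = np.zeros((4, 4))
        vals[1, :] = 5.0  # four tied pixels
        mask, thr = _top_k_mask(vals, 2)
        assert thr == 5.0
        assert np.array_equal(np.nonzero(mask.ravel())[0], [4, 5])


class TestScorePrediction:
    def make(self, exc, sup=None):
        exc = np.asarray(exc, bool)
        sup = np.zeros_like(exc) if sup is None else np.asarray(sup, bool)
        labels = np.zeros(exc.shape, np.int8)
        labels[exc] = 1
        labels[sup] = -1
        stm = SpikeTriggeredMask(
            base_image_id="img0",
            weights=np.where(exc, 1.0, np.where(sup, -1.0, 0.0)),
            labels=labels,
            n_frames=100,
            alpha=0.01,
            n_shuffles=200,
        )
        from bubblestm.linear_model import PredictedMask

        pred = PredictedMask(
            base_image_id="img0", excitatory=exc, suppressive=sup, threshold=1.0
        )
        return pred, stm

    def test_identical_masks_score_100(self):
        exc = np.zeros((32, 32), bool)
        exc[5:10, 5:10] = True
        pred, stm = self.make(exc)
        out = score_prediction(pred, stm)
        assert out["excitatory_overlap_pct"] == 100.0
        assert out["excitatory_size_diff_pct"] == 0.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((32, 32), bool)
        a[:4, :4] = True
        b = np.zeros((32, 32), bool)
        b[20:24, 20:24] = True
        pred, _ = self.make(a)
        _, stm = self.make(b)
        assert score_prediction(pred, stm)["excitatory_overlap_pct"] == 0.0

    def test_partial_overlap_arithmetic(self):
        """|P| = 80, |M| = 100, |P & M| = 40 -> overlap 40%."""
        p = np.zeros((32, 32), bool)
        p.ravel()[:80] = True
        m = np.zeros((32, 32), bool)
        m.ravel()[40:140] = True
        pred, _ = self.make(p)
        _, stm = self.make(m)
        out = score_prediction(pred, stm)
        assert out["excitatory_overlap_pct"] == pytest.approx(40.0)
        assert out["excitatory_size_diff_pct"] == pytest.approx(20.0)

    def test_empty_component_pair_is_nan(self):
        exc = np.zeros((32, 32), bool)
        exc[:3, :3] = True
        pred, stm = self.make(exc)
        assert np.isnan(score_prediction(pred, stm)["suppressive_overlap_pct"])


class TestOrientationPower:
    og = np.arange(0.0, 180.0, 22.5)

    def grating_raster(self, theta):
        return make_grating(GratingStim(theta, 2.0, 0.0), 128, 0.025)

    def test_pure_grating_region_peaks_at_its_orientation(self):
        raster = self.grating_raster(67.5)
        pset = np.zeros((128, 128), bool)
        pset[34:94, 34:94] = True
        og, power = orientation_power(raster, pset, self.og, (0.5, 4.0), 0.025)
        assert og[np.argmax(power)] == 67.5

    def test_rotation_by_90_shifts_the_peak(self):
        raster = self.grating_raster(45.0)
        pset = np.zeros((128, 128), bool)
        pset[34:94, 34:94] = True
        _, p0 = orientation_power(raster, pset, self.og, (0.5, 4.0), 0.025)
        _, p90 = orientation_power(
            np.rot90(raster), np.rot90(pset), self.og, (0.5, 4.0), 0.025
        )
        assert (self.og[np.argmax(p90)] - self.og[np.argmax(p0)]) % 180 == 90.0

    def test_isotropic_noise_is_roughly_flat(self):
        """White noise in the set: no orientation bin dominates.  A wide
        frequency band keeps the per-bin sampling error manageable."""
        rng = np.random.default_rng(5)
        raster = rng.uniform(size=(128, 128))
        pset = np.zeros((128, 128), bool)
        pset[30:98, 30:98] = True
        _, power = orientation_power(raster, pset, self.og, (0.5, 15.0), 0.025)
        assert power.max() / power.min() < 2.0

    def test_empty_set_rejected(self, small_image):
        with pytest.raises(InvalidConfigurationError):
            orientation_power(
                small_image, np.zeros((64, 64), bool), self.og, (0.5, 4.0)
            )


class TestImageMaskOSI:
    def test_grating_region_yields_high_osi(self):
        raster = make_grating(GratingStim(90.0, 2.0, 0.0), 128, 0.025)
        labels = np.zeros((128, 128), np.int8)
        labels[44:84, 44:84] = 1
        stm = SpikeTriggeredMask(
            base_image_id=None,
            weights=np.where(labels == 1, 1.0, 0.0),
            labels=labels,
            n_frames=100,
            alpha=0.01,
            n_shuffles=200,
        )
        og = np.arange(0.0, 180.0, 22.5)
        val = image_mask_osi(
            raster, stm, og, np.array([1.0, 2.0]), np.array([0.0, 90.0]), 0.025
        )
        assert val > 1.0

    def test_empty_mask_flagged_nan(self, small_image):
        labels = np.zeros((64, 64), np.int8)
        stm = SpikeTriggeredMask(
            base_image_id=None,
            weights=np.zeros((64, 64)),
            labels=labels,
            n_frames=100,
            alpha=0.01,
            n_shuffles=200,
        )
        og = np.arange(0.0, 180.0, 22.5)
        with pytest.warns(UserWarning):
            val = image_mask_osi(
                small_image, stm, og, np.array([2.0]), np.array([0.0])
            )
        assert np.isnan(val)
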