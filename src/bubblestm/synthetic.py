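"""Ground-truth model neurons, fixational eye traces and simulated sessions.

The forward model combines three mechanism classes reported for V4:

* a quasi-linear spectral channel ``L`` — dot product of the stimulus
  amplitude spectrum with an (orientation x spatial-frequency) gain
  surface, normalized to 1 for the neuron's optimal full-contrast grating
  (phase-invariant by construction);
* a localized feature-template channel ``F`` — rectified normalized
  correlation of an image patch template at its patch location;
* a spatially tuned suppressive channel ``S`` of the same form with
  negative weight, which may overlap the excitatory passband spectrally
  ("hidden" suppressive tuning).

Firing rate: ``rate = max(0, baseline + gain * (max(0, L + F - threshold) - S))``.
Suppression subtracts after the excitatory threshold, so a suppressive
feature shown alone pulls the rate below baseline (floored at zero), while
a blank screen yields exactly the baseline rate.

A position-coding parameter ``v`` in [0, 1] interpolates the template
location between retinal (v = 0: the driving patch follows gaze across the
image) and head/image-centered coordinates (v = 1: gaze-independent).
Spiking is inhomogeneous Poisson with lognormal latency jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import session as sess
from . import stimuli
from ._spectral import amplitude_spectrum, polar_gain
from .exceptions import InvalidConfigurationError

RESPONSE_WINDOW_MS = 100.0  # integration window the analyses assume


@dataclass
class FeaturePatch:
    """A localized feature channel: (x, y) patch center plus a zero-mean,
    unit-norm template raster; weight < 0 marks a suppressive patch.

    ``kind='template'`` responds to the normalized correlation with the
    template (a rigid fragment matcher); ``kind='energy'`` responds to the
    RMS contrast revealed at the patch (any content), normalized by
    ``energy_ref`` so full visibility of the home fragment gives ~1.  The
    energy form is what a translation-sensitive neuron needs: a fragment
    matcher falls silent once gaze moves its preferred fragment away.
    """

    center_px: tuple[float, float]
    template: np.ndarray
    weight: float
    kind: str = "template"
    energy_ref: float = 1.0

    def __post_init__(self):
        if self.kind not in ("template", "energy"):
            raise InvalidConfigurationError("patch kind must be template|energy")
        t = np.asarray(self.template, dtype=float)
        t = t - t.mean()
        norm = np.linalg.norm(t)
        if self.kind == "energy" and self.energy_ref == 1.0 and norm > 0:
            self.energy_ref = norm
        if norm > 0:
            t = t / norm
        self.template = t


@dataclass
class ModelNeuron:
    """Generative description of a simulated V4-like neuron."""

    neuron_id: str
    orientations_deg: np.ndarray | None = None
    spatial_freqs_cpd: np.ndarray | None = None
    srf_gain: np.ndarray | None = None  # (n_orient, n_sf), >= 0
    srf_weight: float = 1.0  # weight of the spectral channel in the drive sum
    features: dict = field(default_factory=dict)  # base_image_id -> list[FeaturePatch]
    position_coding: float = 0.0  # 0 = retinotopic, 1 = head-centered
    threshold: float = 0.0
    gain: float = 50.0
    baseline: float = 5.0
    latency_ms: float = 100.0
    latency_jitter_ms: float = 10.0
    deg_per_px: float = stimuli.DEFAULT_DEG_PER_PX
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not 0.0 <= self.position_coding <= 1.0:
            raise InvalidConfigurationError("position_coding must lie in [0, 1]")
        if self.gain < 0:
            raise InvalidConfigurationError("gain must be non-negative")
        if self.srf_gain is not None:
            self.srf_gain = np.asarray(self.srf_gain, dtype=float)
            if np.any(self.srf_gain < 0):
                raise InvalidConfigurationError("srf_gain must be non-negative")

    # -- spectral channel -------------------------------------------------
    def _spectral_gain(self, size: int):
        """Fourier gain grid + normalization (response to optimal grating)."""
        key = ("gain", size)
        if key not in self._cache:
            g = polar_gain(
                self.orientations_deg,
                self.spatial_freqs_cpd,
                self.srf_gain,
                size,
                self.deg_per_px,
            )
            i, j = np.unravel_index(np.argmax(self.srf_gain), self.srf_gain.shape)
            opt = stimuli.GratingStim(
                self.orientations_deg[i],
                self.spatial_freqs_cpd[j],
                0.0,
                contrast=1.0,
                inner_radius_deg=np.inf,
                outer_radius_deg=np.inf,
            )
            a_opt = amplitude_spectrum(
                stimuli.make_grating(opt, size, self.deg_per_px)
            )
            norm = float((g * a_opt).sum())
            self._cache[key] = (g, norm if norm > 0 else 1.0)
        return self._cache[key]


def _crop(raster: np.ndarray, center_px, shape, background: float) -> np.ndarray:
    """Crop ``shape`` around a (x, y) center, padding with background."""
    h, w = shape
    cx, cy = center_px
    y0 = int(round(cy)) - h // 2
    x0 = int(round(cx)) - w // 2
    out = np.full(shape, background)
    ys0, ys1 = max(y0, 0), min(y0 + h, raster.shape[0])
    xs0, xs1 = max(x0, 0), min(x0 + w, raster.shape[1])
    if ys1 > ys0 and xs1 > xs0:
        out[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0] = raster[ys0:ys1, xs0:xs1]
    return out


def _template_response(
    raster: np.ndarray, patch: FeaturePatch, shift_px, background: float
) -> float:
    """Rectified response of one patch channel at its (shifted) location."""
    cx, cy = patch.center_px
    crop = _crop(
        raster, (cx + shift_px[0], cy + shift_px[1]), patch.template.shape, background
    )
    crop = crop - crop.mean()
    norm = np.linalg.norm(crop)
    if norm == 0:
        return 0.0
    if patch.kind == "energy":
        return min(float(norm / patch.energy_ref), 1.5)
    return max(0.0, float(np.dot(crop.ravel(), patch.template.ravel()) / norm))


def drive(
    neuron: ModelNeuron,
    raster: np.ndarray,
    eye_offset_deg=(0.0, 0.0),
    base_image_id: str | None = None,
    amp: np.ndarray | None = None,
    background: float = stimuli.BACKGROUND,
) -> float:
    """Instantaneous firing rate (spikes/s) for one stimulus frame."""
    L = 0.0
    if neuron.srf_gain is not None and np.any(neuron.srf_gain):
        g, norm = neuron._spectral_gain(raster.shape[0])
        a = amp if amp is not None else amplitude_spectrum(raster)
        L = float((g * a).sum() / norm)

    F = 0.0
    S = 0.0
    patches = neuron.features.get(base_image_id, [])
    if patches:
        shift = (1.0 - neuron.position_coding) * np.asarray(eye_offset_deg) / (
            neuron.deg_per_px
        )
        for patch in patches:
            r = _template_response(raster, patch, shift, background)
            if patch.weight >= 0:
                F += patch.weight * r
            else:
                S += -patch.weight * r

    rate = neuron.baseline + neuron.gain * (
        max(0.0, neuron.srf_weight * L + F - neuron.threshold) - S
    )
    return max(0.0, rate)


# ---------------------------------------------------------------------------
# Neuron constructors
# ---------------------------------------------------------------------------


def default_grating_grids():
    """Grating parameter grids: 8 orientations x 6 spatial freqs x 4 phases."""
    orientations = np.arange(0.0, 180.0, 22.5)
    sfs = np.geomspace(0.5, 4.0, 6)
    phases = np.arange(0.0, 360.0, 90.0)
    return orientations, sfs, phases


def gaussian_srf(
    orientations_deg,
    sfs_cpd,
    pref_orientation_deg: float,
    pref_sf_cpd: float,
    orientation_bw_deg: float = 30.0,
    sf_bw_oct: float = 1.0,
    peak: float = 1.0,
) -> np.ndarray:
    """Separable von Mises (orientation) x log-Gaussian (frequency) gain."""
    og = np.asarray(orientations_deg, float)
    fg = np.asarray(sfs_cpd, float)
    dth = np.radians(2.0 * (og - pref_orientation_deg))  # period-180 angle
    kappa = (180.0 / (np.pi * orientation_bw_deg)) ** 2
    tune_th = np.exp(kappa * (np.cos(dth) - 1.0))
    doct = np.log2(fg / pref_sf_cpd)
    tune_f = np.exp(-0.5 * (doct / sf_bw_oct) ** 2)
    return peak * np.outer(tune_th, tune_f)


def linear_neuron(
    neuron_id: str,
    pref_orientation_deg: float,
    pref_sf_cpd: float,
    *,
    orientation_bw_deg: float = 30.0,
    gain: float = 250.0,
    baseline: float = 5.0,
    threshold: float = 0.0,
    deg_per_px: float = stimuli.DEFAULT_DEG_PER_PX,
) -> ModelNeuron:
    """Quasi-linear neuron driven only by the spectral (SRF) channel."""
    og, fg, _ = default_grating_grids()
    return ModelNeuron(
        neuron_id=neuron_id,
        orientations_deg=og,
        spatial_freqs_cpd=fg,
        srf_gain=gaussian_srf(
            og, fg, pref_orientation_deg, pref_sf_cpd, orientation_bw_deg
        ),
        gain=gain,
        baseline=baseline,
        threshold=threshold,
        deg_per_px=deg_per_px,
    )


def circular_patch_template(
    image: stimuli.BaseImage, center_px, radius_px: float
) -> np.ndarray:
    """Extract a circular image fragment (background outside the disk)."""
    d = int(np.ceil(2 * radius_px)) + 1
    crop = _crop(image.pixels, center_px, (d, d), stimuli.BACKGROUND)
    yy, xx = np.mgrid[:d, :d] - (d - 1) / 2.0
    disk = np.hypot(xx, yy) <= radius_px
    out = np.full((d, d), stimuli.BACKGROUND)
    out[disk] = crop[disk]
    return out


def feature_neuron(
    neuron_id: str,
    image: stimuli.BaseImage,
    excitatory_center_px,
    *,
    suppressive_center_px=None,
    patch_radius_px: float = 10.0,
    excitatory_weight: float = 1.0,
    suppressive_weight: float = -0.8,
    position_coding: float = 0.0,
    gain: float = 60.0,
    baseline: float = 20.0,
    srf_gain: np.ndarray | None = None,
    srf_weight: float = 0.4,
    orientations_deg=None,
    spatial_freqs_cpd=None,
    feature_kind: str = "template",
) -> ModelNeuron:
    """Feature-conjunction neuron: image-fragment template(s), optional
    spatially separate suppression, optional weak spectral channel."""
    patches = [
        FeaturePatch(
            tuple(excitatory_center_px),
            circular_patch_template(image, excitatory_center_px, patch_radius_px),
            excitatory_weight,
            kind=feature_kind,
        )
    ]
    if suppressive_center_px is not None:
        if suppressive_weight > 0:
            raise InvalidConfigurationError("suppressive weight must be <= 0")
        patches.append(
            FeaturePatch(
                tuple(suppressive_center_px),
                circular_patch_template(image, suppressive_center_px, patch_radius_px),
                suppressive_weight,
                kind=feature_kind,
            )
        )
    if srf_gain is not None and orientations_deg is None:
        orientations_deg, spatial_freqs_cpd, _ = default_grating_grids()
    return ModelNeuron(
        neuron_id=neuron_id,
        orientations_deg=orientations_deg,
        spatial_freqs_cpd=spatial_freqs_cpd,
        srf_gain=srf_gain,
        srf_weight=srf_weight,
        features={image.id: patches},
        position_coding=position_coding,
        gain=gain,
        baseline=baseline,
        threshold=0.0,
        deg_per_px=image.deg_per_px,
    )


# ---------------------------------------------------------------------------
# Eye traces
# ---------------------------------------------------------------------------


@dataclass
class EyeTrace:
    """Per-frame modal gaze offsets (deg) plus a raw sample series.

    Offsets are expressed in image coordinates: a positive vertical offset
    displaces the neuron's retinal sampling window downward in the image.
    """

    frame_offsets_deg: np.ndarray  # (n_frames, 2) as (x, y)
    samples: pd.DataFrame  # t_ms, x_deg, y_deg


def gen_eye_trace(
    n_frames: int,
    sd_deg: float = 0.15,
    rng=None,
    *,
    frame_duration_ms: float = 240.0,
    sample_rate_hz: float = 500.0,
    tremor_sd_deg: float = 0.01,
    max_deg: float = 1.0,
) -> EyeTrace:
    """Fixational eye offsets: truncated-normal vertical offsets on
    [-1, 1] deg, horizontal spread one third of the vertical."""
    if sd_deg > 0.5:
        raise InvalidConfigurationError("sd_deg must be <= 0.5 (fixation window)")
    rng = stimuli._as_rng(rng)

    def trunc(scale, n):
        if scale == 0:
            return np.zeros(n)
        a, b = -max_deg / scale, max_deg / scale
        return stats.truncnorm.rvs(a, b, scale=scale, size=n, random_state=rng)

    y = trunc(sd_deg, n_frames)
    x = trunc(sd_deg / 3.0, n_frames)
    offsets = np.column_stack([x, y])

    n_per = max(int(frame_duration_ms * sample_rate_hz / 1000.0), 1)
    t = (
        np.arange(n_frames * n_per) * (1000.0 / sample_rate_hz)
    )
    rep = np.repeat(offsets, n_per, axis=0)
    noise = rng.normal(0.0, tremor_sd_deg, size=rep.shape) if tremor_sd_deg else 0.0
    samp = rep + noise
    samples = pd.DataFrame(
        {"t_ms": t, "x_deg": samp[:, 0], "y_deg": samp[:, 1]}
    )
    return EyeTrace(frame_offsets_deg=offsets, samples=samples)


def modal_offset(samples_deg: np.ndarray, bin_deg: float = 0.05) -> float:
    """Mode of an eye-position sample set, via histogram binning."""
    s = np.asarray(samples_deg, dtype=float)
    edges = np.arange(s.min() - bin_deg, s.max() + 2 * bin_deg, bin_deg)
    counts, edges = np.histogram(s, bins=edges)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


# ---------------------------------------------------------------------------
# Spiking simulation
# ---------------------------------------------------------------------------


def simulate_session(
    neuron: ModelNeuron,
    frames: list[sess.FrameSpec],
    eye: EyeTrace | None = None,
    rng=None,
    *,
    background: float = stimuli.BACKGROUND,
) -> sess.SessionLog:
    """Simulate Poisson spiking to a frame stream and log the session.

    Per frame the expected spike count is ``drive * 100 ms``; each spike is
    placed at ``onset + latency * exp(N(0, jitter/latency))`` (lognormal
    latency jitter), so the fixed 50-150 ms analysis window captures the
    bulk of the response for the default 100 ms latency.
    """
    rng = stimuli._as_rng(rng)
    n = len(frames)
    if eye is not None and len(eye.frame_offsets_deg) != n:
        raise InvalidConfigurationError("eye trace and frame stream lengths differ")
    offsets = (
        eye.frame_offsets_deg if eye is not None else np.zeros((n, 2))
    )
    sigma_log = neuron.latency_jitter_ms / neuron.latency_ms
    spike_times = []
    for fr, off in zip(frames, offsets):
        rate = drive(
            neuron,
            fr.raster,
            eye_offset_deg=off,
            base_image_id=fr.base_image_id,
            amp=fr.amp,
            background=background,
        )
        count = rng.poisson(rate * RESPONSE_WINDOW_MS / 1000.0)
        if count:
            lat = neuron.latency_ms * np.exp(rng.normal(0.0, sigma_log, size=count))
            spike_times.append(fr.onset_ms + lat)
    spikes = (
        np.sort(np.concatenate(spike_times)) if spike_times else np.empty(0)
    )
    frames_df = sess.frames_table(frames, offsets)
    masks_df = sess.masks_table(frames)
    size = frames[0].raster.shape[0]
    sigma = frames[0].mask.sigma if frames[0].mask is not None else np.nan
    rate_hz = 1000.0 / frames[0].duration_ms
    meta = {
        "neuron_id": neuron.neuron_id,
        "size_px": size,
        "deg_per_px": neuron.deg_per_px,
        "sigma_px": sigma,
        "frame_rate_hz": rate_hz,
        "background": background,
    }
    return sess.SessionLog(frames=frames_df, spikes=spikes, masks=masks_df, meta=meta)
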