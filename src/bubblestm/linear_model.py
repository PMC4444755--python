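"""Quasi-linear (amplitude-only Fourier filter) prediction of driving
features from the SRF, and spectral analyses of measured masks.

The SRF, normalized to [0, 1] by its maximum, becomes a Fourier-domain
amplitude gain (no phase selectivity).  Filtering a base image and squaring
the result highlights regions whose local spectral content falls inside the
neuron's passband; thresholding at the value that matches the measured STM
area yields the predicted excitatory mask.  The predicted suppressive mask
filters with ``1 - SRF`` on the same scale and applies the same threshold.
The excitatory filter is scaled so the squared response to the neuron's
optimal full-contrast grating peaks at exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import stimuli
from ._spectral import fft_polar_coords, polar_gain
from .exceptions import InvalidConfigurationError
from .receptive_field import SRF, osi
from .stm import SpikeTriggeredMask, _overlap_pct


@dataclass
class SRFFilter:
    """Fourier-domain amplitude gain pair derived from one SRF."""

    gain: np.ndarray  # excitatory gain, unshifted FFT layout
    suppressive_gain: np.ndarray  # from 1 - normalized SRF, same scale
    size: int
    deg_per_px: float
    opt_orientation_deg: float
    opt_sf_cpd: float
    scale: float  # applied so the optimal grating's squared response peaks at 1


@dataclass
class PredictedMask:
    """SRF-predicted excitatory / suppressive pixel sets."""

    base_image_id: str | None
    excitatory: np.ndarray  # boolean (H, W)
    suppressive: np.ndarray
    threshold: float  # in squared-filtered-luminance units


def _normalized_srf(srf: SRF) -> np.ndarray:
    r = np.nan_to_num(srf.response, nan=0.0)
    r = np.clip(r, 0.0, None)
    peak = r.max()
    if peak <= 0:
        raise InvalidConfigurationError("SRF has no positive response to normalize")
    return r / peak


def _filter_raw(image: np.ndarray, gain: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    spec = np.fft.fft2(img - img.mean())
    return np.fft.ifft2(spec * gain).real


def build_filter(srf: SRF, size: int, deg_per_px: float) -> SRFFilter:
    """Construct the amplitude-only filter pair from a (phase-collapsed) SRF."""
    rn = _normalized_srf(srf)
    gain_e = polar_gain(
        srf.orientations_deg, srf.spatial_freqs_cpd, rn, size, deg_per_px
    )
    i, j = np.unravel_index(np.argmax(rn), rn.shape)
    opt = stimuli.GratingStim(
        srf.orientations_deg[i],
        srf.spatial_freqs_cpd[j],
        0.0,
        contrast=1.0,
        inner_radius_deg=np.inf,
        outer_radius_deg=np.inf,
    )
    grating = stimuli.make_grating(opt, size, deg_per_px)
    peak_sq = (_filter_raw(grating, gain_e) ** 2).max()
    if peak_sq <= 0:
        raise InvalidConfigurationError(
            "filter passes no energy of the optimal grating; "
            "SRF grids may not cover the raster's frequency range"
        )
    scale = 1.0 / np.sqrt(peak_sq)
    gain_s = polar_gain(
        srf.orientations_deg, srf.spatial_freqs_cpd, 1.0 - rn, size, deg_per_px
    )
    return SRFFilter(
        gain=gain_e * scale,
        suppressive_gain=gain_s * scale,
        size=size,
        deg_per_px=deg_per_px,
        opt_orientation_deg=float(srf.orientations_deg[i]),
        opt_sf_cpd=float(srf.spatial_freqs_cpd[j]),
        scale=float(scale),
    )


def filter_image(image: np.ndarray, filt) -> np.ndarray:
    """Squared, amplitude-filtered image (phase preserved, mean removed)."""
    gain = filt.gain if isinstance(filt, SRFFilter) else np.asarray(filt, float)
    img = np.asarray(image, dtype=float)
    if img.shape != gain.shape:
        raise InvalidConfigurationError("image and filter shapes differ")
    return _filter_raw(img, gain) ** 2


def _top_k_mask(values: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Boolean mask of the k largest pixels; ties broken by descending
    value then row-major index (stable sort)."""
    flat = values.ravel()
    order = np.argsort(-flat, kind="stable")
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(values.shape), float(flat[order[k - 1]])


def predict_masks(
    image, srf_or_filter, target_area: int, base_image_id: str | None = None
) -> PredictedMask:
    """Predict excitatory/suppressive driving features for one base image.

    ``target_area`` (px) is taken from the measured spike-triggered mask;
    the threshold equating the excitatory above-threshold count with it is
    then reused verbatim for the suppressive (1 - SRF) prediction.
    """
    pixels = image.pixels if isinstance(image, stimuli.BaseImage) else np.asarray(image)
    if isinstance(srf_or_filter, SRFFilter):
        filt = srf_or_filter
    else:
        dpp = image.deg_per_px if isinstance(image, stimuli.BaseImage) else (
            stimuli.DEFAULT_DEG_PER_PX
        )
        filt = build_filter(srf_or_filter, pixels.shape[0], dpp)
    if not 1 <= target_area <= pixels.size:
        raise InvalidConfigurationError("target_area must be in [1, raster size]")
    exc_map = filter_image(pixels, filt.gain)
    excitatory, threshold = _top_k_mask(exc_map, int(target_area))
    sup_map = filter_image(pixels, filt.suppressive_gain)
    suppressive = sup_map >= threshold if threshold > 0 else sup_map > 0
    return PredictedMask(
        base_image_id=base_image_id,
        excitatory=excitatory,
        suppressive=suppressive,
        threshold=threshold,
    )


def score_prediction(predicted: PredictedMask, measured: SpikeTriggeredMask) -> dict:
    """Component-wise overlap and size difference (%), relative to the
    larger set of each pair; empty pairs score NaN and are excluded from
    averages by the caller."""
    if predicted.excitatory.shape != measured.labels.shape:
        raise InvalidConfigurationError("prediction and measurement rasters differ")
    out = {}
    for name, p, m in (
        ("excitatory", predicted.excitatory, measured.excitatory),
        ("suppressive", predicted.suppressive, measured.suppressive),
    ):
        np_, nm = int(p.sum()), int(m.sum())
        big = max(np_, nm)
        out[f"{name}_overlap_pct"] = _overlap_pct(p, m)
        out[f"{name}_size_diff_pct"] = (
            100.0 * (big - min(np_, nm)) / big if big else np.nan
        )
    return out


# ---------------------------------------------------------------------------
# Spectral content of measured masks
# ---------------------------------------------------------------------------


def orientation_power(
    image,
    pixel_set: np.ndarray,
    orientations_deg: np.ndarray,
    sf_range_cpd: tuple[float, float],
    deg_per_px: float | None = None,
    taper_px: float = 3.0,
):
    """Orientation-binned Fourier power of the image content inside a mask.

    The image is zeroed outside the set, mean-subtracted over the set and
    cosine-tapered at the set boundary before the FFT; power is summed over
    spatial frequency within orientation bins centered on the given grid.
    Returns ``(orientations_deg, power)``.
    """
    pixels = image.pixels if isinstance(image, stimuli.BaseImage) else np.asarray(image)
    if deg_per_px is None:
        deg_per_px = (
            image.deg_per_px
            if isinstance(image, stimuli.BaseImage)
            else stimuli.DEFAULT_DEG_PER_PX
        )
    pset = np.asarray(pixel_set, dtype=bool)
    if not pset.any():
        raise InvalidConfigurationError("pixel set is empty")
    d = ndimage.distance_transform_edt(pset)
    taper = np.where(
        d >= taper_px, 1.0, 0.5 * (1.0 - np.cos(np.pi * np.minimum(d, taper_px) / taper_px))
    )
    masked = (pixels - pixels[pset].mean()) * taper
    power = np.abs(np.fft.fft2(masked)) ** 2
    theta, f = fft_polar_coords(pixels.shape[0], deg_per_px)

    og = np.asarray(orientations_deg, dtype=float)
    in_band = (f >= sf_range_cpd[0]) & (f <= sf_range_cpd[1])
    # assign each bin to the nearest orientation grid point, with 180 wrap
    dth = np.abs(theta[..., None] - og[None, None, :])
    dth = np.minimum(dth, 180.0 - dth)
    nearest = np.argmin(dth, axis=-1)
    out = np.zeros(og.size)
    np.add.at(out, nearest[in_band], power[in_band])
    return og, out


def image_mask_osi(
    image,
    stm: SpikeTriggeredMask,
    orientations_deg: np.ndarray,
    sfs_cpd: np.ndarray,
    phases_deg: np.ndarray,
    deg_per_px: float | None = None,
) -> float:
    """OSI of the masked image content, probed with the grating set.

    The base image (mean-subtracted) is windowed by the excitatory STM
    weights; the pseudo-response to each grating is the absolute dot
    product, collapsed over phase by maximum (phase invariance) and over
    spatial frequency by mean, then summarized with the standard OSI.
    Returns NaN (with a warning) for an empty excitatory component.
    """
    pixels = image.pixels if isinstance(image, stimuli.BaseImage) else np.asarray(image)
    if deg_per_px is None:
        deg_per_px = (
            image.deg_per_px
            if isinstance(image, stimuli.BaseImage)
            else stimuli.DEFAULT_DEG_PER_PX
        )
    window = stm.weights * stm.excitatory
    if not np.any(window):
        warnings.warn("empty excitatory component; image+mask OSI undefined")
        return float("nan")
    masked = (pixels - pixels.mean()) * window
    size = pixels.shape[0]
    curve = np.zeros(len(orientations_deg))
    for i, th in enumerate(orientations_deg):
        per_f = []
        for sf in sfs_cpd:
            best = 0.0
            for ph in phases_deg:
                g = stimuli.make_grating(
                    stimuli.GratingStim(th, sf, ph), size, deg_per_px
                )
                resp = abs(float(np.sum(masked * (g - stimuli.BACKGROUND))))
                best = max(best, resp)
            per_f.append(best)
        curve[i] = np.mean(per_f)
    return osi(np.asarray(orientations_deg, float), curve)
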