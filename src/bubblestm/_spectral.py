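"""Shared Fourier-domain helpers: polar (orientation, frequency) bin mapping."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .exceptions import InvalidConfigurationError


def fft_polar_coords(size: int, deg_per_px: float):
    """Orientation (deg, [0, 180)) and radial frequency (c/deg) of each FFT bin.

    Uses numpy's unshifted fft2 layout.  A grating with bar orientation
    theta has wave vector ``(kx, ky) = f*(sin theta, cos theta)``, so the
    bin orientation is ``atan2(fx, fy) mod 180``.
    """
    fr = np.fft.fftfreq(size, d=deg_per_px)
    FY, FX = np.meshgrid(fr, fr, indexing="ij")
    f = np.hypot(FX, FY)
    theta = np.degrees(np.arctan2(FX, FY)) % 180.0
    return theta, f


def polar_gain(
    orientations_deg: np.ndarray,
    sfs_cpd: np.ndarray,
    values: np.ndarray,
    size: int,
    deg_per_px: float,
) -> np.ndarray:
    """Map an (orientation x spatial-frequency) table onto the FFT grid.

    Bilinear interpolation with 180 deg orientation wrap-around; bins whose
    radial frequency falls outside the tabulated range (and the DC bin) get
    gain 0.  Raises if the table does not reach into the resolvable range.
    """
    og = np.asarray(orientations_deg, dtype=float)
    fg = np.asarray(sfs_cpd, dtype=float)
    vals = np.asarray(values, dtype=float)
    vals = np.nan_to_num(vals, nan=0.0)
    if vals.shape != (og.size, fg.size):
        raise InvalidConfigurationError("values shape must be (n_orient, n_sf)")
    nyquist = 1.0 / (2.0 * deg_per_px)
    if fg.min() >= nyquist:
        raise InvalidConfigurationError(
            "spatial-frequency grid lies entirely above the raster's Nyquist limit"
        )
    # wrap-extend the orientation axis on both sides
    og_ext = np.concatenate([[og[-1] - 180.0], og, [og[0] + 180.0]])
    vals_ext = np.vstack([vals[-1:], vals, vals[:1]])
    interp = RegularGridInterpolator(
        (og_ext, fg), vals_ext, method="linear", bounds_error=False, fill_value=0.0
    )
    theta, f = fft_polar_coords(size, deg_per_px)
    gain = interp(np.stack([theta.ravel(), f.ravel()], axis=1)).reshape(size, size)
    gain[0, 0] = 0.0
    return gain


def amplitude_spectrum(raster: np.ndarray) -> np.ndarray:
    """|FFT| of the mean-subtracted raster (unshifted layout)."""
    r = np.asarray(raster, dtype=float)
    return np.abs(np.fft.fft2(r - r.mean()))
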