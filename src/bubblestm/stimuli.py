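"""Stimulus construction: 1/f base images, Gaussian bubble masks, gratings.

Conventions used throughout the package
---------------------------------------
* Rasters are square float arrays indexed ``[row, col] = [y, x]`` with
  luminance in ``[0, 1]`` and a mid-gray background of 0.5.  The y axis
  increases downward (image convention).
* Positions are ``(x, y)`` pixel coordinates; the image center maps to
  0 deg of visual angle, so ``deg = (px - (size - 1) / 2) * deg_per_px``.
* Grating orientation is the angle of the iso-luminance bars in degrees,
  0 deg = horizontal bars (luminance modulated along the vertical axis),
  period 180 deg.

Bubble masks are opaque overlays perforated by transparent unit-peak
Gaussian windows.  Overlapping windows combine by the independent-occlusion
rule ``T = 1 - prod_i(1 - g_i)``, which keeps transparency in [0, 1].
Windows wrap around the raster edge (Gaussian profiles are evaluated on
circular pixel distance), so the expected coverage is uniform across the
raster and matches the closed form ``1 - (1 - 2*pi*sigma^2 / N^2)**n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .exceptions import InvalidConfigurationError

DEFAULT_DEG_PER_PX = 0.025
"""Degrees of visual angle per pixel: a 128 px raster spans 3.2 deg,
comfortably covering a ~1 deg-radius V4 classical receptive field."""

BACKGROUND = 0.5


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Base images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaseImage:
    """A square grayscale raster standing in for a natural photograph."""

    id: str
    pixels: np.ndarray
    deg_per_px: float = DEFAULT_DEG_PER_PX

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise InvalidConfigurationError("base image must be square")
        if px.shape[0] < 32:
            raise InvalidConfigurationError("base image must be at least 32 px")
        if not np.all(np.isfinite(px)) or px.min() < 0 or px.max() > 1:
            raise InvalidConfigurationError("pixel values must be finite and in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def generate_base_image(
    size: int,
    spectral_exponent: float = 1.0,
    seed=None,
    *,
    deg_per_px: float = DEFAULT_DEG_PER_PX,
    image_id: str | None = None,
) -> BaseImage:
    """Generate a grayscale noise image with a ``f**(-exponent)`` spectrum.

    ``spectral_exponent = 1`` emulates the 1/f amplitude statistics of
    natural scenes; 0 gives white noise.  The raster is rescaled to [0, 1].
    """
    if size <= 0:
        raise InvalidConfigurationError("size must be positive")
    rng = _as_rng(seed)
    noise = rng.standard_normal((size, size))
    spec = np.fft.fft2(noise)
    fy = np.fft.fftfreq(size)
    f = np.hypot(*np.meshgrid(fy, fy, indexing="ij"))
    scale = np.zeros_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-spectral_exponent)
    img = np.fft.ifft2(spec * scale).real
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.full_like(img, BACKGROUND)
    if image_id is None:
        image_id = f"synth-{spectral_exponent:g}"
    return BaseImage(id=image_id, pixels=img, deg_per_px=deg_per_px)


def radial_amplitude_spectrum(pixels: np.ndarray, n_bins: int = 16):
    """Radially averaged amplitude spectrum, for spectral-slope checks.

    Returns ``(freq, amplitude)`` with frequency in cycles/px.
    """
    px = np.asarray(pixels, dtype=float)
    n = px.shape[0]
    amp = np.abs(np.fft.fft2(px - px.mean()))
    fy = np.fft.fftfreq(n)
    f = np.hypot(*np.meshgrid(fy, fy, indexing="ij")).ravel()
    a = amp.ravel()
    keep = (f > 0) & (f <= 0.5)
    edges = np.geomspace(f[keep].min(), 0.5, n_bins + 1)
    idx = np.clip(np.digitize(f[keep], edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=a[keep], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    centers = np.sqrt(edges[:-1] * edges[1:])
    ok = counts > 0
    return centers[ok], sums[ok] / counts[ok]


# ---------------------------------------------------------------------------
# Bubble masks
# ---------------------------------------------------------------------------


@dataclass
class BubbleMask:
    """Transparent Gaussian windows on an otherwise opaque overlay.

    ``centers`` is an ``(n, 2)`` array of (x, y) pixel positions; the
    transparency field is recomputed deterministically from the centers,
    so only centers + sigma need to be serialized.
    """

    centers: np.ndarray
    sigma: float
    size: int

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            self.centers = np.empty((0, 2))
        if self.sigma <= 0:
            raise InvalidConfigurationError("sigma must be positive")

    @cached_property
    def transparency(self) -> np.ndarray:
        return bubble_transparency(self.centers, self.sigma, self.size)


def _axis_profiles(centers_1d: np.ndarray, sigma: float, size: int) -> np.ndarray:
    """Unit-peak Gaussian profile per window along one axis, wrapped."""
    coords = np.arange(size, dtype=float)
    d = np.abs(coords[None, :] - centers_1d[:, None])
    d = np.minimum(d, size - d)
    return np.exp(-0.5 * (d / sigma) ** 2)


def bubble_transparency(centers: np.ndarray, sigma: float, size: int) -> np.ndarray:
    """Per-pixel transparency ``T = 1 - prod_i(1 - g_i)`` in [0, 1]."""
    if sigma <= 0:
        raise InvalidConfigurationError("sigma must be positive")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        return np.zeros((size, size))
    gx = _axis_profiles(centers[:, 0], sigma, size)
    gy = _axis_profiles(centers[:, 1], sigma, size)
    opaque = np.ones((size, size))
    for i in range(centers.shape[0]):
        opaque *= 1.0 - gy[i][:, None] * gx[i][None, :]
    return 1.0 - opaque


def make_bubble_mask(
    size: int, n_windows: int = 20, sigma: float = 7.0, rng=None
) -> BubbleMask:
    """Draw window centers i.i.d. uniform over the raster."""
    if sigma <= 0:
        raise InvalidConfigurationError("sigma must be positive")
    if n_windows < 0:
        raise InvalidConfigurationError("n_windows must be non-negative")
    rng = _as_rng(rng)
    centers = rng.uniform(0.0, size, size=(n_windows, 2))
    return BubbleMask(centers=centers, sigma=sigma, size=size)


def apply_mask(image, mask: BubbleMask, background: float = BACKGROUND) -> np.ndarray:
    """Blend the image through the mask: ``T*image + (1 - T)*background``."""
    pixels = image.pixels if isinstance(image, BaseImage) else np.asarray(image, float)
    T = mask.transparency if isinstance(mask, BubbleMask) else np.asarray(mask, float)
    if pixels.shape != T.shape:
        raise InvalidConfigurationError(
            f"image shape {pixels.shape} != mask shape {T.shape}"
        )
    return T * pixels + (1.0 - T) * background


def visible_fraction(mask: BubbleMask) -> float:
    """Mean transparency: the fraction of the underlying image visible."""
    return float(mask.transparency.mean())


def mean_visible_fraction_closed_form(
    size: int, n_windows: int = 20, sigma: float = 7.0
) -> float:
    """Expected visible fraction of a random mask.

    Each unit-peak wrapped Gaussian window has mean transparency
    ``2*pi*sigma^2 / size^2`` at any pixel (center uniform over the raster);
    with independent centers the occlusion factors multiply.
    """
    per_window = 2.0 * np.pi * sigma**2 / size**2
    return float(1.0 - (1.0 - per_window) ** n_windows)


# ---------------------------------------------------------------------------
# Gratings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GratingStim:
    """Sinusoidal grating, alpha-blended into the background.

    The trapezoidal envelope is 1 inside ``inner_radius_deg``, 0 outside
    ``outer_radius_deg`` and linear in between.  ``None`` radii default to
    the raster half-extent (outer) and 70% of it (inner); pass ``inf`` for
    a full-field, unwindowed grating.
    """

    orientation_deg: float
    sf_cpd: float
    phase_deg: float = 0.0
    contrast: float = 1.0
    inner_radius_deg: float | None = None
    outer_radius_deg: float | None = None

    def __post_init__(self):
        # orientation kept mod 360: theta and theta+180 render identically
        # only jointly with a phase flip (phi -> 360 - phi), except at phase 0
        object.__setattr__(self, "orientation_deg", float(self.orientation_deg) % 360.0)
        object.__setattr__(self, "phase_deg", float(self.phase_deg) % 360.0)


def make_grating(
    stim: GratingStim,
    size: int,
    deg_per_px: float = DEFAULT_DEG_PER_PX,
    background: float = BACKGROUND,
) -> np.ndarray:
    """Render a grating raster in [0, 1] on the uniform gray background."""
    nyquist = 1.0 / (2.0 * deg_per_px)
    if stim.sf_cpd >= nyquist:
        raise InvalidConfigurationError(
            f"spatial frequency {stim.sf_cpd} c/deg at or above Nyquist {nyquist}"
        )
    c = (size - 1) / 2.0
    ax = (np.arange(size) - c) * deg_per_px
    X, Y = np.meshgrid(ax, ax)  # X varies along columns, Y along rows
    th = np.radians(stim.orientation_deg)
    ph = np.radians(stim.phase_deg)
    carrier = np.cos(2.0 * np.pi * stim.sf_cpd * (X * np.sin(th) + Y * np.cos(th)) + ph)

    outer = stim.outer_radius_deg
    if outer is None:
        outer = size / 2.0 * deg_per_px
    inner = stim.inner_radius_deg
    if inner is None:
        inner = 0.7 * outer
    if np.isinf(outer):
        alpha = np.ones_like(carrier)
    else:
        r = np.hypot(X, Y)
        alpha = np.clip((outer - r) / max(outer - inner, 1e-12), 0.0, 1.0)
    raster = background + 0.5 * stim.contrast * alpha * carrier
    return np.clip(raster, 0.0, 1.0)
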