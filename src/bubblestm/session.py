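"""Session logs: the interchange object between simulation and analysis.

A :class:`SessionLog` records everything needed to re-render every stimulus
frame bit-exactly (stimulus descriptors, bubble-window centers), plus spike
times and per-frame modal eye position.  Frame streams are built here; the
spiking simulation lives in :mod:`bubblestm.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stimuli
from ._spectral import amplitude_spectrum
from .exceptions import InvalidConfigurationError

FRAME_COLUMNS = [
    "frame_id",
    "kind",
    "onset_ms",
    "duration_ms",
    "base_image_id",
    "orientation_deg",
    "sf_cpd",
    "phase_deg",
    "probe_x_deg",
    "probe_y_deg",
    "eye_x_deg",
    "eye_y_deg",
]


@dataclass
class FrameSpec:
    """One stimulus frame with its rendered raster (simulation side only)."""

    frame_id: int
    kind: str  # "bubble" | "grating" | "image" | "probe"
    onset_ms: float
    duration_ms: float
    base_image_id: str | None = None
    mask: stimuli.BubbleMask | None = None
    grating: stimuli.GratingStim | None = None
    probe_xy_deg: tuple[float, float] | None = None
    raster: np.ndarray | None = None
    amp: np.ndarray | None = None  # cached |FFT| of the mean-subtracted raster


@dataclass
class SessionLog:
    """Ordered stimulus frames, spike times (ms) and metadata.

    ``frames`` uses :data:`FRAME_COLUMNS`; ``masks`` is a long table
    (frame_id, window_index, x_px, y_px) from which bubble transparencies
    are recomputed bit-exactly (sigma and raster size live in ``meta``).
    """

    frames: pd.DataFrame
    spikes: np.ndarray
    masks: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spikes = np.asarray(self.spikes, dtype=float)
        onsets = self.frames["onset_ms"].to_numpy()
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise InvalidConfigurationError("frame onsets must be strictly increasing")
        if self.spikes.size and (
            np.any(np.diff(self.spikes) < 0) or self.spikes.min() < 0
        ):
            raise InvalidConfigurationError("spike times must be sorted, non-negative")

    @property
    def size_px(self) -> int:
        return int(self.meta["size_px"])

    @property
    def deg_per_px(self) -> float:
        return float(self.meta["deg_per_px"])


def frame_rates(
    frames: pd.DataFrame,
    spikes: np.ndarray,
    latency_ms: float = 50.0,
    window_ms: float = 100.0,
) -> np.ndarray:
    """Mean firing rate (spikes/s) per frame in the half-open response window
    ``[onset + latency, onset + latency + window)``."""
    starts = frames["onset_ms"].to_numpy(dtype=float) + latency_ms
    if starts.size > 1 and np.any(np.diff(starts) < window_ms):
        raise InvalidConfigurationError(
            "response windows of consecutive frames overlap; "
            "shorten window_ms or use a slower frame stream"
        )
    spikes = np.asarray(spikes, dtype=float)
    lo = np.searchsorted(spikes, starts, side="left")
    hi = np.searchsorted(spikes, starts + window_ms, side="left")
    return (hi - lo) / (window_ms / 1000.0)


def mask_stack(
    session: SessionLog, base_image_id: str | None = None, dtype=np.float32
):
    """Recompute bubble transparencies for (a subset of) the session frames.

    Returns ``(frame_index, stack)`` where ``frame_index`` indexes rows of
    ``session.frames`` (bubble frames, optionally restricted to one base
    image) and ``stack`` is an ``(n, size, size)`` transparency array.
    """
    if session.masks is None:
        raise InvalidConfigurationError("session has no bubble-mask table")
    frames = session.frames
    sel = frames["kind"] == "bubble"
    if base_image_id is not None:
        sel &= frames["base_image_id"] == base_image_id
    idx = np.flatnonzero(sel.to_numpy())
    fids = frames["frame_id"].to_numpy()[idx]
    size = session.size_px
    sigma = float(session.meta["sigma_px"])
    m = session.masks.sort_values(["frame_id", "window_index"])
    grouped = {fid: g[["x_px", "y_px"]].to_numpy() for fid, g in m.groupby("frame_id")}
    stack = np.empty((idx.size, size, size), dtype=dtype)
    for k, fid in enumerate(fids):
        stack[k] = stimuli.bubble_transparency(grouped[fid], sigma, size)
    return idx, stack


# ---------------------------------------------------------------------------
# Frame-stream builders
# ---------------------------------------------------------------------------


def bubble_frame_stream(
    images: list[stimuli.BaseImage],
    n_frames: int,
    rng: np.random.Generator,
    *,
    n_windows: int = 20,
    sigma: float = 7.0,
    rate_hz: float = 4.25,
    background: float = stimuli.BACKGROUND,
    compute_amps: bool = False,
) -> list[FrameSpec]:
    """Bubble-masked image stream; base images randomly interleaved."""
    duration = 1000.0 / rate_hz
    size = images[0].size
    frames = []
    for i in range(n_frames):
        img = images[rng.integers(len(images))]
        mask = stimuli.make_bubble_mask(size, n_windows, sigma, rng)
        raster = stimuli.apply_mask(img, mask, background)
        fr = FrameSpec(
            frame_id=i,
            kind="bubble",
            onset_ms=i * duration,
            duration_ms=duration,
            base_image_id=img.id,
            mask=mask,
            raster=raster,
        )
        if compute_amps:
            fr.amp = amplitude_spectrum(raster)
        frames.append(fr)
    return frames


def grating_frame_stream(
    n_frames: int,
    rng: np.random.Generator,
    *,
    orientations_deg: np.ndarray,
    sfs_cpd: np.ndarray,
    phases_deg: np.ndarray,
    size: int,
    deg_per_px: float = stimuli.DEFAULT_DEG_PER_PX,
    rate_hz: float = 10.0,
    contrast: float = 1.0,
    compute_amps: bool = False,
) -> list[FrameSpec]:
    """Dynamic grating stream: parameters drawn uniformly each frame."""
    duration = 1000.0 / rate_hz
    frames = []
    # render each distinct grating once; streams reuse a modest parameter grid
    cache: dict[tuple, tuple[np.ndarray, np.ndarray | None]] = {}
    for i in range(n_frames):
        th = float(orientations_deg[rng.integers(len(orientations_deg))])
        sf = float(sfs_cpd[rng.integers(len(sfs_cpd))])
        ph = float(phases_deg[rng.integers(len(phases_deg))])
        key = (th, sf, ph)
        if key not in cache:
            g = stimuli.GratingStim(th, sf, ph, contrast=contrast)
            raster = stimuli.make_grating(g, size, deg_per_px)
            amp = amplitude_spectrum(raster) if compute_amps else None
            cache[key] = (raster, amp)
        raster, amp = cache[key]
        frames.append(
            FrameSpec(
                frame_id=i,
                kind="grating",
                onset_ms=i * duration,
                duration_ms=duration,
                grating=stimuli.GratingStim(th, sf, ph, contrast=contrast),
                raster=raster,
                amp=amp,
            )
        )
    return frames


def image_frame_stream(
    images: list[stimuli.BaseImage],
    n_frames: int,
    rng: np.random.Generator,
    *,
    rate_hz: float = 4.25,
    compute_amps: bool = False,
) -> list[FrameSpec]:
    """Unmasked base-image stream (for image selection / unmasked rates)."""
    duration = 1000.0 / rate_hz
    frames = []
    for i in range(n_frames):
        img = images[rng.integers(len(images))]
        fr = FrameSpec(
            frame_id=i,
            kind="image",
            onset_ms=i * duration,
            duration_ms=duration,
            base_image_id=img.id,
            raster=img.pixels,
        )
        if compute_amps:
            fr.amp = amplitude_spectrum(img.pixels)
        frames.append(fr)
    return frames


def probe_frame_stream(
    grid_x_deg: np.ndarray,
    grid_y_deg: np.ndarray,
    repeats: int,
    rng: np.random.Generator,
    *,
    size: int,
    deg_per_px: float = stimuli.DEFAULT_DEG_PER_PX,
    rate_hz: float = 8.0,
    probe_size_deg: float = 0.2,
    background: float = stimuli.BACKGROUND,
) -> list[FrameSpec]:
    """Flashed bright probes on an invisible grid, randomized order."""
    duration = 1000.0 / rate_hz
    positions = [(x, y) for x in grid_x_deg for y in grid_y_deg] * repeats
    order = rng.permutation(len(positions))
    half = probe_size_deg / 2.0
    c = (size - 1) / 2.0
    frames = []
    for i, j in enumerate(order):
        x, y = positions[j]
        raster = np.full((size, size), background)
        x0 = int(round((x - half) / deg_per_px + c))
        x1 = int(round((x + half) / deg_per_px + c)) + 1
        y0 = int(round((y - half) / deg_per_px + c))
        y1 = int(round((y + half) / deg_per_px + c)) + 1
        raster[max(y0, 0) : y1, max(x0, 0) : x1] = 1.0
        frames.append(
            FrameSpec(
                frame_id=i,
                kind="probe",
                onset_ms=i * duration,
                duration_ms=duration,
                probe_xy_deg=(x, y),
                raster=raster,
            )
        )
    return frames


def frames_table(frames: list[FrameSpec], eye_offsets_deg: np.ndarray) -> pd.DataFrame:
    """Assemble the SessionLog frames DataFrame from FrameSpecs."""
    rows = []
    for fr, (ex, ey) in zip(frames, eye_offsets_deg):
        g = fr.grating
        px, py = fr.probe_xy_deg if fr.probe_xy_deg else (np.nan, np.nan)
        rows.append(
            (
                fr.frame_id,
                fr.kind,
                fr.onset_ms,
                fr.duration_ms,
                fr.base_image_id,
                g.orientation_deg if g else np.nan,
                g.sf_cpd if g else np.nan,
                g.phase_deg if g else np.nan,
                px,
                py,
                ex,
                ey,
            )
        )
    return pd.DataFrame(rows, columns=FRAME_COLUMNS)


def masks_table(frames: list[FrameSpec]) -> pd.DataFrame | None:
    """Long-format bubble-center table (frame_id, window_index, x_px, y_px)."""
    rows = []
    for fr in frames:
        if fr.mask is None:
            continue
        for w, (x, y) in enumerate(fr.mask.centers):
            rows.append((fr.frame_id, w, x, y))
    if not rows:
        return None
    return pd.DataFrame(rows, columns=["frame_id", "window_index", "x_px", "y_px"])
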