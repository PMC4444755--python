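"""Classical spatial RF and spectral receptive field (SRF) estimation.

The spatial RF is summarized as a circle fitted to the half-maximal
iso-response contour of the probe response map (algebraic least-squares on
the x4 bicubically upsampled map).  The SRF is the parametric
spike-triggered average over the grating parameter grid — mean firing rate
in a fixed ``[onset + latency, onset + latency + window)`` response window
per (orientation, spatial frequency, phase) cell — collapsed across phase
by averaging, since V4 shows little tuning for absolute spatial phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .exceptions import InsufficientDataError, NoReceptiveFieldError
from .session import SessionLog, frame_rates


@dataclass
class SpatialRF:
    """Probe response map with the fitted classical RF circle (deg)."""

    response_map: np.ndarray  # (n_y, n_x) spikes/s
    grid_x_deg: np.ndarray
    grid_y_deg: np.ndarray
    center_deg: tuple[float, float]
    radius_deg: float


@dataclass
class SRF:
    """Phase-collapsed orientation x spatial-frequency response matrix."""

    orientations_deg: np.ndarray
    spatial_freqs_cpd: np.ndarray
    phases_deg: np.ndarray
    response: np.ndarray  # (n_orient, n_sf) spikes/s, NaN where undersampled
    per_phase: np.ndarray  # (n_orient, n_sf, n_phase)
    counts: np.ndarray  # frames per (orient, sf, phase) cell

    @property
    def peak(self) -> tuple[float, float]:
        """(orientation, spatial frequency) of the response maximum."""
        r = np.nan_to_num(self.response, nan=-np.inf)
        i, j = np.unravel_index(np.argmax(r), r.shape)
        return float(self.orientations_deg[i]), float(self.spatial_freqs_cpd[j])


def fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit; returns (cx, cy, r)."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    r = float(np.sqrt(max(c + cx**2 + cy**2, 0.0)))
    return float(cx), float(cy), r


def estimate_spatial_rf(
    probe_session: SessionLog,
    latency_ms: float = 50.0,
    window_ms: float = 100.0,
    upsample: int = 4,
) -> SpatialRF:
    """Fit the classical RF circle from a flashed-probe session."""
    frames = probe_session.frames
    probes = frames[frames["kind"] == "probe"].copy()
    if probes.empty:
        raise InsufficientDataError("session contains no probe frames")
    rates = frame_rates(probes, probe_session.spikes, latency_ms, window_ms)
    probes["rate"] = rates
    table = probes.pivot_table(
        index="probe_y_deg", columns="probe_x_deg", values="rate", aggfunc="mean"
    )
    grid_y = table.index.to_numpy(dtype=float)
    grid_x = table.columns.to_numpy(dtype=float)
    rf_map = table.to_numpy(dtype=float)
    if np.isnan(rf_map).any():
        raise InsufficientDataError("some probe grid cells were never presented")
    if np.ptp(rf_map) == 0:
        raise NoReceptiveFieldError("probe response map is uniform")

    up = ndimage.zoom(rf_map, upsample, order=3)
    level = up.min() + 0.5 * np.ptp(up)
    contours = measure.find_contours(up, level)
    if not contours:
        raise NoReceptiveFieldError("no half-max contour found")
    contour = max(contours, key=len)  # (row, col) in upsampled index units
    dx = grid_x[1] - grid_x[0] if grid_x.size > 1 else 1.0
    dy = grid_y[1] - grid_y[0] if grid_y.size > 1 else 1.0
    # zoom maps original index i to i * (len*up - 1)/(len - 1) in the output
    sy = (len(grid_y) * upsample - 1) / max(len(grid_y) - 1, 1)
    sx = (len(grid_x) * upsample - 1) / max(len(grid_x) - 1, 1)
    ys = grid_y[0] + contour[:, 0] / sy * dy
    xs = grid_x[0] + contour[:, 1] / sx * dx
    cx, cy, r = fit_circle(np.column_stack([xs, ys]))
    if r <= 0:
        raise NoReceptiveFieldError("degenerate circle fit")
    return SpatialRF(
        response_map=rf_map,
        grid_x_deg=grid_x,
        grid_y_deg=grid_y,
        center_deg=(cx, cy),
        radius_deg=r,
    )


def estimate_srf(
    grating_session: SessionLog,
    latency_ms: float = 50.0,
    window_ms: float = 100.0,
    min_count: int = 5,
) -> SRF:
    """Estimate the SRF from a dynamic grating session.

    Cells sampled fewer than ``min_count`` times are flagged (NaN in the
    collapsed matrix) and excluded from downstream fits.
    """
    frames = grating_session.frames
    g = frames[frames["kind"] == "grating"].copy()
    if g.empty:
        raise InsufficientDataError("session contains no grating frames")
    g["rate"] = frame_rates(g, grating_session.spikes, latency_ms, window_ms)

    orientations = np.sort(g["orientation_deg"].unique())
    sfs = np.sort(g["sf_cpd"].unique())
    phases = np.sort(g["phase_deg"].unique())
    shape = (orientations.size, sfs.size, phases.size)
    sums = np.zeros(shape)
    counts = np.zeros(shape, dtype=int)
    io = np.searchsorted(orientations, g["orientation_deg"].to_numpy())
    jf = np.searchsorted(sfs, g["sf_cpd"].to_numpy())
    kp = np.searchsorted(phases, g["phase_deg"].to_numpy())
    np.add.at(sums, (io, jf, kp), g["rate"].to_numpy())
    np.add.at(counts, (io, jf, kp), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_phase = sums / counts
    per_phase[counts == 0] = np.nan

    undersampled = (counts < min_count).any(axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        response = np.nanmean(per_phase, axis=2)
    response = np.where(undersampled, np.nan, response)
    if undersampled.any():
        warnings.warn(
            f"{int(undersampled.sum())} SRF cells sampled < {min_count} times; "
            "flagged NaN",
            stacklevel=2,
        )
    return SRF(
        orientations_deg=orientations,
        spatial_freqs_cpd=sfs,
        phases_deg=phases,
        response=response,
        per_phase=per_phase,
        counts=counts,
    )


def orientation_tuning(srf: SRF):
    """Mean +/- sd of the SRF across spatial frequency, per orientation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(srf.response, axis=1)
        sd = np.nanstd(srf.response, axis=1)
    return srf.orientations_deg, mean, sd


def osi(
    orientations_deg: np.ndarray,
    values: np.ndarray,
    max_osi: float = 100.0,
) -> float:
    """Orientation selectivity index ``(R_pref - R_orth) / R_orth``.

    ``R_pref`` is the curve maximum; ``R_orth`` the (linearly interpolated)
    response 90 deg away.  0 for a flat curve, unbounded above; capped at
    ``max_osi`` with a warning when ``R_orth <= 0``.
    """
    og = np.asarray(orientations_deg, dtype=float)
    vals = np.asarray(values, dtype=float)
    finite = np.isfinite(vals)
    og, vals = og[finite], vals[finite]
    if og.size < 4:
        raise InsufficientDataError("need at least 4 finite orientation samples")
    if np.ptp(vals) == 0:
        return 0.0
    k = int(np.argmax(vals))
    r_pref = float(vals[k])
    # interpolate on the period-180 extension, mapping the orthogonal
    # orientation into the covered interval
    theta_orth = og[0] + (og[k] + 90.0 - og[0]) % 180.0
    og_ext = np.concatenate([og, [og[0] + 180.0]])
    vals_ext = np.concatenate([vals, [vals[0]]])
    r_orth = float(np.interp(theta_orth, og_ext, vals_ext))
    if r_orth <= 0:
        warnings.warn("orthogonal response <= 0; OSI capped", stacklevel=2)
        return max_osi
    return (r_pref - r_orth) / r_orth
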