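"""Spike-triggered masks: rate-weighted bubble-mask averages with a
shuffle-null significance test, plus the derived mask metrics.

The spike-triggered mask (STM) for one base image is the average of the
bubble transparency fields shown with that image, weighted by the evoked
response ``w_n`` (mean rate 50-150 ms after frame onset).  Pixel-wise
significance comes from a null ensemble built by shuffling responses across
the mask ensemble: pixels of the raw weighted average inside the central
``1 - alpha`` interval of the null are set to zero; survivors above the
interval are labeled excitatory, below it suppressive.  Reported weights
are null-mean-subtracted so their sign is meaningful.  Masks are never
smoothed; the bubbles' own spatial correlation (scale ~ sigma) makes the
STM an upper bound on the true driving pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyResponseError,
    InsufficientDataError,
    InvalidConfigurationError,
)
from .session import SessionLog, frame_rates, mask_stack
from .stimuli import _as_rng

MIN_FRAMES_PER_IMAGE = 50


@dataclass
class SpikeTriggeredMask:
    """Per-pixel weight map with significance labels and summary geometry."""

    base_image_id: str | None
    weights: np.ndarray  # (H, W), null-mean-subtracted
    labels: np.ndarray  # int8: +1 excitatory, -1 suppressive, 0 n.s.
    n_frames: int
    alpha: float
    n_shuffles: int

    @property
    def valid(self) -> bool:
        """A valid mask has at least one significant driving pixel."""
        return bool(np.any(self.labels != 0))

    @property
    def area(self) -> int:
        """Significant pixel count (excitatory + suppressive)."""
        return int(np.count_nonzero(self.labels))

    @property
    def excitatory(self) -> np.ndarray:
        return self.labels == 1

    @property
    def suppressive(self) -> np.ndarray:
        return self.labels == -1

    @property
    def centroid_px(self) -> tuple[float, float] | None:
        """|weight|-weighted centroid (x, y) of the excitatory component."""
        exc = self.excitatory
        if not exc.any():
            return None
        w = np.abs(self.weights[exc])
        ys, xs = np.nonzero(exc)
        wsum = w.sum()
        if wsum == 0:
            return float(xs.mean()), float(ys.mean())
        return float((xs * w).sum() / wsum), float((ys * w).sum() / wsum)


def compute_frame_responses(
    session: SessionLog, window_ms: tuple[float, float] = (50.0, 150.0)
) -> pd.DataFrame:
    """Evoked response ``w_n`` per frame: mean rate in the half-open window
    ``[onset + w0, onset + w1)``.  Returns columns (frame_id, rate_hz)."""
    w0, w1 = window_ms
    if w1 <= w0:
        raise InvalidConfigurationError("response window must have positive length")
    rates = frame_rates(session.frames, session.spikes, w0, w1 - w0)
    return pd.DataFrame(
        {"frame_id": session.frames["frame_id"].to_numpy(), "rate_hz": rates}
    )


def raw_stm(
    transparencies: np.ndarray,
    responses: np.ndarray,
    subtract_mean_mask: bool = True,
) -> np.ndarray:
    """Response-weighted mean of the bubble masks.

    With ``subtract_mean_mask`` the unweighted ensemble mean — the exact
    expectation of the shuffle null — is removed, centering the map near
    zero when responses are independent of the masks.
    """
    T = np.asarray(transparencies)
    w = np.asarray(responses, dtype=float)
    if T.shape[0] != w.size:
        raise InvalidConfigurationError("need one mask per response")
    total = w.sum()
    if total == 0:
        raise EmptyResponseError("all responses are zero")
    m = np.tensordot(w, T, axes=(0, 0)) / total
    if subtract_mean_mask:
        m = m - T.mean(axis=0)
    return np.asarray(m, dtype=float)


def significance(
    transparencies: np.ndarray,
    responses: np.ndarray,
    *,
    n_shuffles: int = 1000,
    alpha: float = 0.01,
    rng=None,
    base_image_id: str | None = None,
    min_frames: int = MIN_FRAMES_PER_IMAGE,
) -> SpikeTriggeredMask:
    """Shuffle-null pixel significance test for the spike-triggered mask.

    The null ensemble recomputes the weighted average after permuting
    responses across frames; the observed map is zeroed wherever it falls
    inside the central ``1 - alpha`` interval of the per-pixel null.
    """
    if n_shuffles < 200:
        raise InvalidConfigurationError("n_shuffles must be >= 200")
    if not 0.0 < alpha <= 1.0:
        raise InvalidConfigurationError("alpha must lie in (0, 1]")
    if alpha < 1.0 and n_shuffles * alpha / 2.0 < 1.0:
        raise InvalidConfigurationError("n_shuffles too small to resolve alpha")
    T = np.asarray(transparencies)
    w = np.asarray(responses, dtype=float)
    n = T.shape[0]
    if n < min_frames:
        raise InsufficientDataError(
            f"{n} frames < minimum {min_frames} for a spike-triggered mask"
        )
    total = w.sum()
    if total == 0:
        raise EmptyResponseError("all responses are zero")
    rng = _as_rng(rng)

    shape = T.shape[1:]
    flat = T.reshape(n, -1)
    wf = w.astype(flat.dtype, copy=False)
    observed = (wf @ flat) / flat.dtype.type(total)

    W = np.empty((n_shuffles, n), dtype=flat.dtype)
    for k in range(n_shuffles):
        W[k] = wf[rng.permutation(n)]
    null = (W @ flat) / flat.dtype.type(total)
    null_mean = null.mean(axis=0)
    lo_q = 100.0 * alpha / 2.0
    lo, hi = np.percentile(null, [lo_q, 100.0 - lo_q], axis=0)

    labels = np.zeros(observed.shape, dtype=np.int8)
    labels[observed > hi] = 1
    labels[observed < lo] = -1
    weights = (observed - null_mean).astype(float)
    return SpikeTriggeredMask(
        base_image_id=base_image_id,
        weights=weights.reshape(shape),
        labels=labels.reshape(shape),
        n_frames=n,
        alpha=alpha,
        n_shuffles=n_shuffles,
    )


def stms_from_session(
    session: SessionLog,
    *,
    window_ms: tuple[float, float] = (50.0, 150.0),
    n_shuffles: int = 1000,
    alpha: float = 0.01,
    rng=None,
    min_frames: int = MIN_FRAMES_PER_IMAGE,
) -> dict[str, SpikeTriggeredMask]:
    """Compute one STM per base image present in a bubble session."""
    rng = _as_rng(rng)
    responses = compute_frame_responses(session, window_ms)["rate_hz"].to_numpy()
    out: dict[str, SpikeTriggeredMask] = {}
    bubble = session.frames[session.frames["kind"] == "bubble"]
    for image_id in sorted(bubble["base_image_id"].dropna().unique()):
        idx, T = mask_stack(session, image_id)
        if idx.size < min_frames:
            continue
        out[image_id] = significance(
            T,
            responses[idx],
            n_shuffles=n_shuffles,
            alpha=alpha,
            rng=rng,
            base_image_id=image_id,
            min_frames=min_frames,
        )
    return out


# ---------------------------------------------------------------------------
# Mask metrics and comparisons
# ---------------------------------------------------------------------------


def mask_metrics(stm: SpikeTriggeredMask, spatial_rf, deg_per_px: float) -> dict:
    """Mask area relative to the CRF circle, centroid, and whether any
    excitatory pixel falls outside the CRF."""
    size = stm.labels.shape[0]
    c = (size - 1) / 2.0
    radius_px = spatial_rf.radius_deg / deg_per_px
    cx_px = spatial_rf.center_deg[0] / deg_per_px + c
    cy_px = spatial_rf.center_deg[1] / deg_per_px + c
    crf_area = np.pi * radius_px**2
    out = {
        "area_px": stm.area,
        "area_fraction_of_crf": stm.area / crf_area if crf_area > 0 else np.nan,
        "centroid_px": stm.centroid_px,
        "crf_outside_flag": False,
    }
    ys, xs = np.nonzero(stm.excitatory)
    if xs.size:
        d = np.hypot(xs - cx_px, ys - cy_px)
        out["crf_outside_flag"] = bool(np.any(d > radius_px))
    return out


def similarity_analysis(
    stm: SpikeTriggeredMask,
    transparencies: np.ndarray,
    responses: np.ndarray,
    unmasked_rate: float | None = None,
    q: float = 90.0,
) -> dict:
    """Dot product of the STM with every frame mask, and the mean response
    of frames at or above the ``q``-th similarity percentile.

    Similarities can be negative through the suppressive STM component.
    """
    T = np.asarray(transparencies)
    w = np.asarray(responses, dtype=float)
    if T.shape[1:] != stm.weights.shape:
        raise InvalidConfigurationError("STM and frame masks must share the raster")
    sims = T.reshape(T.shape[0], -1) @ stm.weights.ravel().astype(T.dtype)
    sims = sims.astype(float)
    thr = float(np.percentile(sims, q))
    top = sims >= thr
    return {
        "similarity": sims,
        "threshold": thr,
        "top_mean_rate": float(w[top].mean()) if top.any() else np.nan,
        "unmasked_mean_rate": unmasked_rate,
    }


def _overlap_pct(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if max(na, nb) == 0:
        return np.nan
    return 100.0 * int((a & b).sum()) / max(na, nb)


def intermask_comparison(stms: list[SpikeTriggeredMask]) -> pd.DataFrame:
    """Pairwise fractional overlap (%) of significant pixel sets and size
    difference (%) relative to the larger mask of each pair."""
    valid = [s for s in stms if s.valid]
    if len(valid) < 2:
        raise InsufficientDataError("need at least 2 valid masks to compare")
    rows = []
    for i in range(len(valid)):
        for j in range(i + 1, len(valid)):
            a = valid[i].labels != 0
            b = valid[j].labels != 0
            na, nb = int(a.sum()), int(b.sum())
            rows.append(
                {
                    "image_a": valid[i].base_image_id,
                    "image_b": valid[j].base_image_id,
                    "overlap_pct": _overlap_pct(a, b),
                    "size_diff_pct": 100.0 * (max(na, nb) - min(na, nb)) / max(na, nb),
                }
            )
    return pd.DataFrame(rows)
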