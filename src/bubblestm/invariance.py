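"""Gaze-contingent spike-triggered masks and translation-invariance slopes.

Frames are partitioned into equal-count bins by modal vertical eye
position; a conditional STM is computed per bin, and the vertical centroid
of its excitatory component is regressed on the per-bin mean gaze offset.
A slope of 1 marks a retinotopic (translation-sensitive) neuron whose
driving region follows gaze across the image; a slope of 0 marks a
head/image-centered (translation-invariant) neuron.  Per-mask slopes rest
on at most a handful of points and carry no individual significance; the
population-level one-sample t tests against 1 and against 0 are the
meaningful statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .session import SessionLog, mask_stack
from .stm import MIN_FRAMES_PER_IMAGE, SpikeTriggeredMask, significance
from .stimuli import _as_rng


@dataclass
class GazePartition:
    """Equal-count partition of bubble frames by modal eye offset."""

    frame_index: list[np.ndarray]  # per bin, row indices into session.frames
    bin_edges_deg: np.ndarray  # interior quantile edges (n_bins - 1)
    mean_offset_deg: np.ndarray  # per-bin mean modal offset
    counts: np.ndarray
    degenerate: bool  # all offsets identical
    axis: str


@dataclass
class GazeBinnedSTM:
    """Conditional STMs per gaze bin for one base image."""

    base_image_id: str
    bin_edges_deg: np.ndarray
    mean_offset_deg: np.ndarray
    stms: list[SpikeTriggeredMask | None]  # None where a bin had too few frames
    counts: np.ndarray


@dataclass
class SlopeResult:
    """OLS slope of mask centroid (deg) on gaze offset (deg)."""

    slope: float
    intercept: float
    n_points: int
    valid: bool


def bin_by_gaze(
    session: SessionLog,
    n_bins: int = 4,
    min_frames: int = 100,
    axis: str = "y",
) -> GazePartition:
    """Partition bubble frames into ``n_bins`` equal-count gaze bins.

    Rank-based assignment gives bin counts that differ by at most one.
    The vertical axis is the default, matching the dominance of vertical
    fixational eye movements in the recordings this emulates.
    """
    frames = session.frames
    idx = np.flatnonzero((frames["kind"] == "bubble").to_numpy())
    if idx.size < n_bins * min_frames:
        raise InsufficientDataError(
            f"{idx.size} bubble frames < {n_bins} bins x {min_frames} frames"
        )
    col = "eye_y_deg" if axis == "y" else "eye_x_deg"
    offs = frames[col].to_numpy()[idx]
    degenerate = bool(np.ptp(offs) == 0)
    order = np.argsort(offs, kind="stable")
    bins = np.empty(idx.size, dtype=int)
    bins[order] = np.arange(idx.size) * n_bins // idx.size
    frame_index = [idx[bins == b] for b in range(n_bins)]
    edges = np.quantile(offs, np.arange(1, n_bins) / n_bins)
    mean_offset = np.array(
        [offs[bins == b].mean() if np.any(bins == b) else np.nan for b in range(n_bins)]
    )
    counts = np.array([fi.size for fi in frame_index])
    return GazePartition(
        frame_index=frame_index,
        bin_edges_deg=edges,
        mean_offset_deg=mean_offset,
        counts=counts,
        degenerate=degenerate,
        axis=axis,
    )


def conditional_stms(
    session: SessionLog,
    partition: GazePartition,
    base_image_id: str,
    *,
    responses: np.ndarray | None = None,
    window_ms: tuple[float, float] = (50.0, 150.0),
    n_shuffles: int = 1000,
    alpha: float = 0.01,
    rng=None,
    min_frames: int = 100,
) -> GazeBinnedSTM:
    """Recompute the STM separately for the frames of each gaze bin.

    All bins share the shuffle settings; a bin whose intersection with the
    base image has fewer than ``min_frames`` frames yields ``None``.
    """
    from .stm import compute_frame_responses  # local to avoid cycle at import

    rng = _as_rng(rng)
    if responses is None:
        responses = compute_frame_responses(session, window_ms)["rate_hz"].to_numpy()
    img_idx, T = mask_stack(session, base_image_id)
    pos = {int(i): k for k, i in enumerate(img_idx)}
    stms: list[SpikeTriggeredMask | None] = []
    counts = []
    for bin_rows in partition.frame_index:
        rows = [pos[int(i)] for i in bin_rows if int(i) in pos]
        counts.append(len(rows))
        if len(rows) < min_frames:
            stms.append(None)
            continue
        rows = np.asarray(rows)
        stms.append(
            significance(
                T[rows],
                responses[img_idx[rows]],
                n_shuffles=n_shuffles,
                alpha=alpha,
                rng=rng,
                base_image_id=base_image_id,
                min_frames=min(min_frames, MIN_FRAMES_PER_IMAGE),
            )
        )
    return GazeBinnedSTM(
        base_image_id=base_image_id,
        bin_edges_deg=partition.bin_edges_deg,
        mean_offset_deg=partition.mean_offset_deg,
        stms=stms,
        counts=np.asarray(counts),
    )


def invariance_slope(
    binned: GazeBinnedSTM, deg_per_px: float, size_px: int
) -> SlopeResult:
    """Unweighted OLS of excitatory-centroid vertical position (deg) on
    per-bin mean gaze offset (deg)."""
    xs, ys = [], []
    c = (size_px - 1) / 2.0
    for off, s in zip(binned.mean_offset_deg, binned.stms):
        if s is None or not s.valid:
            continue
        centroid = s.centroid_px
        if centroid is None:
            continue
        xs.append(off)
        ys.append((centroid[1] - c) * deg_per_px)
    n = len(xs)
    if n < 3 or np.ptp(xs) == 0:
        return SlopeResult(slope=np.nan, intercept=np.nan, n_points=n, valid=False)
    slope, intercept = np.polyfit(xs, ys, 1)
    return SlopeResult(
        slope=float(slope), intercept=float(intercept), n_points=n, valid=True
    )


def population_tests(
    slopes: pd.DataFrame,
    radii_deg: dict[str, float] | None = None,
    min_slopes: int = 5,
) -> dict:
    """Population summary of translation-invariance slopes.

    ``slopes`` needs columns (neuron_id, base_image_id, slope).  Reports
    per-mask and per-neuron-averaged distributions with one-tailed
    one-sample t tests against 1 (translation sensitive) and against 0
    (translation invariant), plus the Pearson correlation between each
    neuron's mean slope and its CRF radius when radii are supplied.
    """
    vals = slopes["slope"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]

    def summary(x: np.ndarray) -> dict:
        out = {"n": int(x.size), "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))
               if x.size > 1 else np.nan}
        if x.size >= min_slopes:
            t1 = stats.ttest_1samp(x, 1.0, alternative="less")
            t0 = stats.ttest_1samp(x, 0.0, alternative="greater")
            out["t_vs_1"] = {"stat": float(t1.statistic), "p": float(t1.pvalue)}
            out["t_vs_0"] = {"stat": float(t0.statistic), "p": float(t0.pvalue)}
        return out

    per_neuron = (
        slopes.dropna(subset=["slope"]).groupby("neuron_id")["slope"].mean()
    )
    result = {
        "per_mask": summary(vals),
        "per_neuron": summary(per_neuron.to_numpy(dtype=float)),
    }
    if radii_deg is not None:
        paired = [
            (per_neuron[nid], radii_deg[nid])
            for nid in per_neuron.index
            if nid in radii_deg
        ]
        if len(paired) >= 3:
            s, r = zip(*paired)
            corr = stats.pearsonr(s, r)
            result["slope_vs_radius"] = {
                "r": float(corr.statistic),
                "p": float(corr.pvalue),
                "n": len(paired),
            }
    return result
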