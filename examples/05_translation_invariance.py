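"""Quantify translation invariance from gaze-contingent masks.

Frames are binned by modal vertical eye position; conditional
spike-triggered masks are recomputed per bin and the excitatory centroid
is regressed on gaze.  Slope 1 = retinotopic (the driving region follows
gaze), slope 0 = head/image-centered (invariant).
"""

import numpy as np

from bubblestm import (
    bin_by_gaze,
    conditional_stms,
    feature_neuron,
    gen_eye_trace,
    generate_base_image,
    invariance_slope,
    simulate_session,
)
from bubblestm.session import bubble_frame_stream

image = generate_base_image(128, 1.0, np.random.default_rng(42), image_id="img0")

for v in (0.0, 1.0):
    rng = np.random.default_rng(1000)
    neuron = feature_neuron(
        f"v={v}", image, (64, 64), patch_radius_px=10,
        position_coding=v, feature_kind="energy",
    )
    frames = bubble_frame_stream([image], 2000, rng)
    eye = gen_eye_trace(2000, sd_deg=0.4, rng=rng)
    log = simulate_session(neuron, frames, eye, rng)

    part = bin_by_gaze(log, n_bins=4, min_frames=100)
    binned = conditional_stms(
        log, part, "img0", n_shuffles=300, rng=rng, min_frames=100
    )
    res = invariance_slope(binned, deg_per_px=0.025, size_px=128)
    kind = "retinotopic" if v == 0 else "head-centered"
    print(f"position coding v = {v} ({kind}): slope = {res.slope:+.2f} "
          f"over {res.n_points} gaze bins")
print("-> the slope reads out the neuron's coordinate frame; real V4")
print("   populations fall on a continuum between these two extremes.")
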