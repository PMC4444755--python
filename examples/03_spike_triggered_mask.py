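"""Estimate a spike-triggered mask and test pixel significance.

Response-weighted averaging of the bubble masks, followed by the
shuffle-null test (central 99% interval), recovers the neuron's excitatory
and suppressive driving features without any knowledge of the generator.
"""

import numpy as np

from bubblestm import feature_neuron, generate_base_image, simulate_session
from bubblestm import stms_from_session
from bubblestm.session import bubble_frame_stream

rng = np.random.default_rng(4)
image = generate_base_image(128, 1.0, np.random.default_rng(42), image_id="img0")
exc_c, sup_c = (48, 80), (88, 48)
neuron = feature_neuron(
    "demo", image, exc_c, suppressive_center_px=sup_c, patch_radius_px=10
)

frames = bubble_frame_stream([image], 2000, rng)
log = simulate_session(neuron, frames, None, rng)
mask = stms_from_session(log, n_shuffles=500, alpha=0.01, rng=rng)["img0"]

cx, cy = mask.centroid_px
print(f"valid mask: {mask.valid}; significant area {mask.area} px "
      f"({100 * mask.area / mask.labels.size:.1f}% of the raster)")
print(f"excitatory centroid ({cx:.1f}, {cy:.1f}) px; ground truth {exc_c}")
ys, xs = np.nonzero(mask.suppressive)
print(f"suppressive centroid ({xs.mean():.1f}, {ys.mean():.1f}) px; "
      f"ground truth {sup_c}")
print("-> the mask localizes both driving features to within a bubble width;")
print("   suppressive pixels carry negative null-subtracted weights.")
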