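"""Simulate a recording session from a ground-truth model neuron.

A feature-conjunction neuron (excitatory image-fragment template plus a
spatially separate suppressive patch) views a 4.25 Hz bubble-masked image
stream; Poisson spikes are logged together with every stimulus descriptor.
"""

import numpy as np

from bubblestm import compute_frame_responses, feature_neuron, generate_base_image
from bubblestm import simulate_session
from bubblestm.session import bubble_frame_stream

rng = np.random.default_rng(1)
image = generate_base_image(128, 1.0, np.random.default_rng(42), image_id="img0")
neuron = feature_neuron(
    "demo-conjunction",
    image,
    excitatory_center_px=(48, 80),
    suppressive_center_px=(88, 48),
    patch_radius_px=10,
)

frames = bubble_frame_stream([image], n_frames=800, rng=rng)
log = simulate_session(neuron, frames, None, rng)

responses = compute_frame_responses(log)["rate_hz"]
print(f"{len(log.frames)} frames, {log.spikes.size} spikes")
print(f"evoked rate (50-150 ms window): mean {responses.mean():.1f} sp/s, "
      f"max {responses.max():.0f} sp/s")
print("-> frames revealing the excitatory fragment fire hardest; frames")
print("   revealing the suppressive patch dip below the 20 sp/s baseline.")
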