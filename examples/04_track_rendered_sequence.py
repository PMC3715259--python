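"""Closed-loop tracking: render a known landmark trajectory as textured
grayscale frames, re-track it with Gabor-jet displacement estimation, and
measure the recovery error.
"""

import numpy as np

from geomexpr import LandmarkSequence, render_sequence, track_sequence
from geomexpr.synthetic import TextureParams

rng = np.random.default_rng(4)
gx, gy = np.meshgrid([40.0, 75.0, 110.0], [40.0, 75.0, 110.0])
start = np.stack([gx.ravel(), gy.ravel()], axis=1)
vel = rng.uniform(-1.5, 1.5, size=(len(start), 2))  # px/frame
coords = start[:, None, :] + vel[:, None, :] * np.arange(6)[None, :, None]

truth = LandmarkSequence(coords=coords)
frames = render_sequence(truth, TextureParams(canvas_shape=(160, 160)))
tracked = track_sequence(frames, start)

err = np.hypot(*(tracked.coords - coords).transpose(2, 0, 1))
print(f"{len(start)} landmarks, {len(frames)} frames, "
      f"motions up to {np.abs(vel).max():.2f} px/frame")
print(f"RMS tracking error: {np.sqrt((err**2).mean()):.3f} px "
      f"(max {err.max():.3f} px)")
# Sub-0.1 px errors are expected here: each landmark carries a unique
# band-limited texture and the phase-based estimator is iterated to
# convergence each frame.
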