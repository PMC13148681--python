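"""Map descent footage to a depth-resolved light profile.

Builds a synthetic descent (green/blue attenuate exponentially, red held by
the camera's own LEDs), converts frames to depths at the deployment's
descent rate, and prints the binned RGB profile and the depth below which
green and blue are effectively gone.
"""

import numpy as np

from fjordcam.descent import descent_rate, frames_to_depth, rgb_depth_profile
from fjordcam.video_io import FrameStack
from datetime import datetime, timezone

rate = descent_rate(260.0, 141.0)
print(f"descent rate: {rate:.2f} m/s; vertical resolution {100 * rate / 30:.1f} cm/frame")

fps, n = 30.0, int(30 * 141)
frames = np.zeros((n, 24, 32, 3), dtype=np.uint8)
for k in range(n):
    depth = rate * k / fps
    gb = 120.0 * np.exp(-3.0 * depth / 80.0)
    frames[k, ..., 0] = 60
    frames[k, ..., 1] = int(round(gb))
    frames[k, ..., 2] = int(round(gb * 0.8))
stack = FrameStack(frames, fps, datetime(2025, 8, 1, 19, 56, tzinfo=timezone.utc))

depths = frames_to_depth(stack, drop_frame=0, rate_m_s=rate)
prof = rgb_depth_profile(stack, depths, bin_m=10.0, rate_m_s=rate, gb_floor=5.0)
print("depth (m)   R      G      B")
for d, r, g, b, m in zip(prof.depth_bins_m, prof.mean_r, prof.mean_g,
                         prof.mean_b, prof.n_frames):
    if m:
        print(f"{d:8.1f} {r:6.1f} {g:6.1f} {b:6.1f}")
print(f"green/blue below the floor from {prof.gb_transition_depth_m:.1f} m on: "
      "beyond that depth the scene looks like the red-lit seafloor.")
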