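"""Generate the two exploration styles and summarize their statistics.

The center-biased style (S1) wanders unevenly around the middle of the
arena; the wall-following style (S2) hugs the walls but still covers the
whole arena over time.  Both start at the center and respect a speed cap.
"""

import numpy as np

from gridplace import Arena, default_landmarks, generate_trajectory

arena = Arena(side_length=100.0, landmarks=default_landmarks())

for style in ("center_biased", "wall_following"):
    traj = generate_trajectory(style, n_steps=10000, arena=arena, seed=1)
    pos = traj.pos
    wall = np.minimum.reduce([pos[:, 0], pos[:, 1], 100 - pos[:, 0], 100 - pos[:, 1]])
    occ, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=10, range=[[0, 100]] * 2)
    speed = np.linalg.norm(traj.vel[1:], axis=1)
    print(f"{style:15s} coverage={np.mean(occ > 0):.0%} "
          f"near-wall={np.mean(wall <= 15):.0%} "
          f"mean speed={speed.mean():.2f} a.u./step")

# coverage: fraction of 10x10 occupancy bins ever visited (both styles
# should reach ~100%); near-wall: fraction of time within 15 a.u. of a wall
# (high only for the wall-following style).
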