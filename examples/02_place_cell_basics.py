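"""Single place-cell building blocks: tuning, spiking, feature matching.

Shows the Gaussian firing power around a cell's proximity tuning point, the
Hodgkin-Huxley unit's response to sustained current, and the conjunctive
two-blob visual activation.
"""

import numpy as np

from gridplace import Arena, default_landmarks, generate_blobs, sense_proximity
from gridplace.hh import HHState, hh_run
from gridplace.place import feature_similarity, firing_power, place_activation

arena = Arena(side_length=100.0, landmarks=default_landmarks())

# firing power peaks where the normalized sensor vector equals the weights
w = np.array([0.5, 0.5, 0.5])
for offset in (0.0, 0.03, 0.1):
    x = w + [offset, 0, 0]
    p = firing_power(w, x, sigma_j=0.03, c_rm=1.0)
    print(f"|X'/L - w| = {offset:.2f}  ->  normalized firing power {p:.4f}")

# the H-H unit is silent at rest and fires tonically at the printed current
for current in (0.0, 10.0):
    _, spikes = hh_run(HHState(), current, dt=0.01, n_steps=100000)  # 1 s
    print(f"I = {current:4.1f} uA/cm2 -> {spikes} spikes in 1 s")

# noisy proximity reading feeding the firing power above
reading = sense_proximity((30.0, 40.0), arena, alpha=0.1, rng=np.random.default_rng(0))
print("proximity X' =", np.round(reading.x_noisy, 1), "(true", reading.x_true, ")")

# visual activation: product of feature similarities over the two best blobs
blobs = generate_blobs((30.0, 40.0), heading=1.0, arena=arena)
m1, m2 = blobs[0].as_vector(), blobs[1].as_vector()
print(f"{len(blobs)} blobs in view; perfectly matched cell activation:",
      place_activation(blobs, m1, m2))
print("similarity of one feature off by sigma_f:", feature_similarity(0.5, 1.0, 0.5))
# a cell whose preferences equal two visible blobs activates at 1.0;
# mismatches decay as a Gaussian with width sigma_f = 0.5 per feature.
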