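# gridplace

A desk-scale simulator of the coupled place-cell / grid-cell path-integration
system of the rodent hippocampal formation.

Grid cells in medial entorhinal cortex integrate the animal's velocity on a
continuous attractor — a localized activity bump on a twisted-torus neural
sheet — and read the bump's movement out as a position estimate.  That
estimate drifts: the readout counts the bump's movement in whole
neuron-lattice units, and the rounding residuals accumulate.  Hippocampal
place cells, driven by noisy wall-proximity sensing and salient visual-blob
features (and gated by input from the grid modules and by Hodgkin-Huxley
spiking), develop place fields during exploration; their field centers act
as spatial anchors that reset the grid estimates whenever the modules
disagree about where the animal is.  `gridplace` implements the full loop
and the analysis battery used to characterize it.

## The model in brief

* **Grid network** — five modules of 20 x 20 neurons on a twisted torus
  (c_x = (l_x−0.5)/N_x, c_y = √(3/2)(l_y−0.5)/N_x), Gaussian
  excitation/inhibition weights shifted by the gain-modulated velocity
  v_R = α·R(β)v with gains [0.04 … 0.08], activity update
  A ← f((1−τ)B + τB/mean(B)), τ = 0.95.  Per-module position estimate
  pos(t+1) = pos(t) + γΔA with γ calibrated per module and a 0.95
  dorsal-to-ventral spacing factor.
* **Place network** — 2000 cells; firing power
  P_j = C_j R_m exp(−(‖X′/L − w_j‖/n)²/2σ_j²) over three noisy proximity
  sensors; competitive weight learning dW = μ(X′/L − W); Gaussian feature
  matching G = exp(−((x_f−μ_f)/σ_f)²) of two preferred blob sets per cell;
  Hodgkin-Huxley energy model deciding when a cell fires.
* **Coupling** — a field emerges where a cell fires, receives > 1.1 a.u. of
  grid drive, matches the scene visually, and the cross-module estimate
  spread E = √(std(pos_x)² + std(pos_y)²) exceeds 1.5 a.u.; on such
  uncertain steps the estimates snap to the nearest field center within
  2.5 a.u.
* **Metrics** — spike rate maps, Pearson spatial autocorrelograms, rotated-
  ring hexagonal and square gridness, and the entropy/complexity suite
  (H, r = H/log n, R = 1−r, I, and H = S + Z).

See `docs/methods.md` for the complete account, including the numerical
choices and known limitations.

## Worked example

Run a short coupled exploration with and without place-field input and
compare the per-module position error:

```python
import numpy as np
from gridplace import ExperimentConfig, run_experiment

errors = {}
for arm, place_input in (("on", True), ("off", False)):
    cfg = ExperimentConfig.model_validate({
        "seed": 0,
        "trajectory": {"n_steps": 1000},
        "coupling": {"place_input": place_input,
                     "field_mode": "emergent" if place_input else "fixed"},
    })
    res = run_experiment(cfg)
    err = np.linalg.norm(res.log.estimates[1:] - res.trajectory.pos[1:, None, :], axis=2)
    errors[arm] = np.nanmean(err, axis=0)
    if place_input:
        print(f"fields emerged: {int(res.log.n_fields[-1])}, "
              f"corrections: {len(res.log.corrections)}")
for arm, e in errors.items():
    print(arm, np.round(e, 2))
```

Output:

```
fields emerged: 209, corrections: 52
on [3.59 2.77 2.4  2.28 2.45]
off [16.65 12.39  9.97  9.53  8.96]
```

Each number is the mean Euclidean distance (a.u.) between a module's
integrated position estimate and the animal's true position over a
1000-step center-biased exploration, dorsal module first.  With place-field
input ON, ~200 place fields emerge, ~50 corrections fire, and every
module's error is several-fold smaller than the uncorrected OFF arm, whose
estimates drift without bound.

The same protocols are available from the shell:

```bash
gridplace simulate --seed 1 --out results/run1 --place-input on
gridplace recipe fig4_error_reduction --out results/fig4 --seeds 10
gridplace make-trajectory s2 --steps 10000 --seed 1 --out s2.csv
```

`examples/` contains one short narrative script per capability.

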