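# Methods

`gridplace` simulates the coupling between a hippocampal place-cell
population and a stack of medial-entorhinal grid-cell modules during
exploration of a square arena, and measures how emerging place fields
reduce the error that the grid network accumulates while path-integrating
the animal's velocity.  This note documents the model, its parameters, the
synthetic environment that stands in for a 3-D simulator, and the numerical
and design choices that were genuinely open.

## Arena, trajectories and sensing

The arena is a square of side L = 100 a.u.  Forty visual landmarks (ten per
wall) sit 5-30 a.u. beyond the walls.  The simulated animal starts at the
center and moves one step per sensory cycle.

Two seeded trajectory generators emulate the two exploration styles the
study conditions require: a **center-biased** walk (waypoints drawn mostly
from a Gaussian around the center, occasionally uniform or on the border)
and a **wall-following** walk (waypoints hop along a corridor 2-10 a.u.
from the walls, with occasional crossings of the interior).  Speeds are
clipped normal (mean 0.8, SD 0.25, max 1.5 a.u./step) with a bounded turn
rate, so per-step displacement is continuous.  Over 10,000 steps both
styles cover ≥ 95 % of a 10 x 10 occupancy grid and the wall-following
style keeps ≥ 70 % of its positions within 15 a.u. of a wall.  Real
open-field rodent paths have inertia, grooming pauses and thigmotactic
bouts that these generators do not model; passing tests therefore show that
the *model* behaves as described under representative coverage statistics,
not that it reproduces any particular animal's statistics.

Proximity sensing returns the three main-axis wall distances (L-R, B-F and
a constant D-U component), each corrupted multiplicatively:
X' = X (1 + αη), η ~ U(-1, 1) per component, α = 0.1.

Each landmark yields a parametric visual blob with identity-linked features
(solidity, orientation of the major axis) that never change with viewpoint,
and pose-linked features (apparent area ∝ 1/d², image centroid from bearing
and distance) that do — the two classical requirements for localizing
against landmarks.  Blobs are returned for landmarks within a 90° forward
field of view; typical scenes contain several blobs, which the
two-blob conjunctive matching rule requires.

## Place-cell population

N_pc = 2000 cells receive the N_s = 3 noisy proximity channels through a
weight matrix initialized as w = (1 + exp((γ - 0.5)/2σ²))⁻¹ with
γ ~ U(0, 1).  The shape parameter σ is never valued in the source
description; we use σ = 0.25.  Much smaller values (e.g. 0.1) make the
logistic a step function: all weights land at 0 or 1, at least 0.5 away
from any normalized input vector, and no cell can ever respond — so they
are not usable defaults.

Firing power: P_j = C_j R_m exp(-(‖X'/L - w_j‖/n)² / 2σ_j²) with
R_m = 20 Hz, spike energy C_j ~ N(188, 10) nJ and tuning width
σ_j ~ N(0.03, 0.005) expressing metabolic diversity.  Cells with
P_j > P_thr = 0.3 are *responding*; responding cells whose visual
activation also matches the scene move their weights by
Δw_j = μ(X'/L - w_j), μ = 0.001.

Each cell owns a Hodgkin-Huxley unit integrated with forward Euler at
dt = 0.01 ms, 100 sub-steps per behavioral step, on the deviation voltage
u = V_m - V_r (V_r = -65 mV) with the classic squid-axon rate functions and
the constants g_Na = 120, E_Na = 150, g_K = 36, E_K = -12, g_l = 0.3,
E_l = 10.6, C_m = 1 µF/cm².  Gating variables are clamped to [0, 1] after
every step.  A cell "fires" when V_m crosses 0 mV upward during the step's
sub-integration.  The drive current is I_j = I₀ · min(P_j/P_thr, 1) with
I₀ = 10 µA/cm², i.e. cells at or above the firing-power threshold receive
the full printed current (tonic spiking, period ≈ 15 ms); the rheobase of
this unit is ≈ 3.5, and cells with I_j < 2 are held at rest — they cannot
spike at such currents, so this is part of the model definition rather than
an approximation toggle.

Vision: each cell is tuned to two preferred blob feature sets M1, M2 over
(area, orientation, solidity, centroid u, v).  Similarity per feature is
G = exp(-((x_f - μ_f)/σ_f)²), σ_f = 0.5; a blob's response is the product
over features, and the cell's activation A is the best ordered product of
two *distinct* blobs matched to M1 and M2 (zero when fewer than two blobs
are visible).  Per step the most activated cell ("winner") adapts its
preferred features by μ_f ← 0.5 x_f + 0.5 μ_f — the convex form; the
divergent (1+α) variant sometimes written for this rule is treated as a
typographical slip.  The activation threshold for "the features match the
scene" is A_thr = 0.3, chosen from the feature-space geometry: after a
couple of winner adaptations a cell passes it under modest viewpoint change
of its pose-linked features, while an unadapted random cell essentially
never does (its typical activation is below 10⁻²).

A place field emerges at the current position when three conditions hold
simultaneously — (i) the H-H unit fired, (ii) the grid-module drive exceeds
1.1 a.u., (iii) A > A_thr — and the position is *uncertain* (below).  The
field of cell j is the set of visited locations with P_j > P_thr (recorded
on a 1 a.u. grid); its center is the power-weighted centroid
C_j = Σ P_j X' / Σ P_j, and the population decodes location as
Loc = Σ_J P_j C_j / Σ_J P_j over responders with defined centers.  The
decoding error is reported normalized by L/√2 (the half-diagonal) and
clipped to [0, 1], so an unselective population pinned near the arena
center scores errors of order one; the source description names a
normalization "over joint activity power" without a formula, so this
explicit convention is ours.

## Grid modules

Five modules (dorsal → ventral) share one 20 x 20 twisted-torus sheet
geometry with neuron coordinates

    c_x = (l_x - 0.5)/N_x,   c_y = sqrt(3/2) (l_y - 0.5)/N_x .

The vertical factor sqrt(3/2) ≈ 1.2247 follows the model as printed.  The
canonical twisted torus in this model family uses sqrt(3)/2 ≈ 0.866, which
tiles the plane hexagonally; the printed factor stretches the sheet, and
the resulting spatial firing lattices are oblique rather than ideally
hexagonal.  This is what keeps the measured population gridness moderate
(≈ 0.25 hexagonal here) instead of near-ideal (≈ 1.3 with the canonical
factor) — the reported study-level gridness means are only reachable under
the printed geometry.

Weights are w_ij = I_a exp(-‖c_i - c_j + v_R‖²/σ²) - T with the
twisted-torus norm (minimum over periodic images), v_R = gain · R(β) v,
β = 0 and gains [0.04, 0.05, 0.06, 0.07, 0.08].  I_a, σ and T are not
valued in the source ("threshold torus equal to 5" is uninterpretable as
printed); we use I_a = 0.3 and σ_w = 0.24 from the canonical lineage and
T = 0.035, the inhibition shift rescaled so that excitation and inhibition
balance over the sqrt(3/2)-stretched domain exactly as the lineage values
balance over the hexagonal one (with T = 0.05 the stretched sheet's net
drive is negative and activity collapses).  Activity evolves as
B_j = Σ_i A_i w_ij, A_j ← max(0, (1-τ)B_j + τ B_j/mean(B)), τ = 0.95; the
mean is the arithmetic mean over all 400 neurons.  Weights depend on (i, j)
only through the twisted-torus group difference, so the production path
evaluates the kernel at the 400 distinct differences and gathers them by a
precomputed index table; this equals the direct per-pair computation to
1e-12 (tested) and makes a module step ~0.3 ms.

After random initialization (A ~ U(0, 1/√N)) and a 500-step burn-in at
v = 0, a single activity bump forms and translates by gain · v per step.

**Position readout.**  The bump center is the activity-weighted circular
mean per periodic coordinate.  The per-step bump displacement is then
rounded to whole neuron-lattice units (x pitch 1/N_x, y pitch sqrt(3/2)/N_x)
before integration — the readout counts how many matrix positions the bump
moved.  These rounding residuals do not telescope, so pure path integration
accumulates a slow random-walk error (a few a.u. over 10³ steps for the
dorsal module, tens for ventral ones); with a continuous readout the
integrator is essentially exact and the error-correction phenomenon the
package exists to study cannot arise.  Position updates are
pos(t+1) = pos(t) + γ Δ, with γ calibrated per module by least squares on a
straight run at realistic varying speeds (the speed spread decorrelates the
lattice rounding), then multiplied by the module-spacing factor 0.95^m for
module m = 0..4, giving the dorsal-to-ventral scale diversity.

## Coupling loop

Grid → place: drive_j = mean over modules of (max activity of the module ·
W_GP[j, module]); W_GP has one Gaussian column per module (width 2.5) over
a place-index coordinate spread evenly on [0, 10], and rows of active cells
move toward the scalar mean of the noisy sensor vector with rate 0.001
(the printed rule mixes a 3-vector with the module axis; the scalar
collapse is our resolution, config-exposed).  Cells with drive > 1.1 a.u.
satisfy emergence condition (ii).

Place → grid: each step the cross-module spread
E = sqrt(std(pos_x)² + std(pos_y)²) (sample standard deviations) flags the
position *uncertain* when E > 1.5 a.u.  On uncertain steps, field emergence
is enabled, and — when place input is switched on — the estimate is
corrected: if the field center nearest the animal's position lies within
2.5 a.u., every module's estimate is reset to that center (ties break to
the lowest cell index).  The correction touches only the position
estimates, never the grid-cell activity.  Because the snapped center is
within 2.5 a.u. of the true position, the post-correction error is bounded
by the snap radius.  The `fixed` field mode replaces emergent centers with
k centers drawn uniformly over the arena at t = 0 (the field-density
protocol, k = 20 vs 200); it skips the place network entirely, which leaves
the estimates untouched because the named RNG streams are independent.

## Analysis battery

Rate maps bin the arena at 2.5 a.u. (40 x 40), occupancy-normalize, and
smooth with a 1-bin Gaussian that never fills unvisited bins.  Grid-cell
maps are built from Poisson spikes sampled per step with rate
0.1 · activity (the bump peak ≈ 17 a.u. then fires ≈ 2 spikes/step; ~3000
spikes per cell per 10,000-step session, a realistic count for a recorded
grid cell).  The spatial autocorrelogram is the lag-wise Pearson
correlation over overlapping valid bins, computed by FFT; lags with fewer
than 20 overlapping bins are missing.

Gridness crops an annulus from half the distance of the nearest of the six
central autocorrelogram peaks to 1.25x their mean distance, resamples it
once onto a polar grid (quartic spline, 3° angular step), and computes the
rotation correlations C_θ as Pearson correlations of the ring with cyclic
shifts of its angle axis — rotation by any multiple of 3° is then exact,
which is why a circularly symmetric autocorrelogram scores 0 to better than
1e-8.  Scores: hex = ½(C60 + C120) − ⅓(C30 + C90 + C150);
square = C90 − ½(C45 + C135).  Maps with no detectable ring peaks score
NaN and are excluded from population means.

The entropy suite takes p_i as each field-bearing cell's share of the
cumulative H-H spike count (recomputed every step), with event size
Δx = 20 a.u.: H = −Σ p log p, r = H/log n, R = 1 − r, I = log n − H, and
the decomposition H = S + Z with S = −Σ p log(p/Δx), Z = −Σ p log Δx
(natural logarithms; a flag switches to bits).  With constant Δx and
normalized p, Z is the constant −log Δx; the per-event Δx_i form is
supported.  Cross-entropy measures H(p) = −Σ p log q, H(q), H(p/q) =
H(q) − H(p) and the information difference I = Σ p log(p/q) are provided
for reference-distribution comparisons.

## Problem sizes and runtime

The package's standard experiment sizes are the study's: 10,000 steps for
full runs, 1,000 steps for the error-reduction and field-density
comparisons (10 seeds each), five modules of 400 cells, 2000 place cells.
A full coupled 10,000-step run takes ~3 minutes on one core; the
grid-only gridness pipeline ~35 s per trajectory plus ~30 s of scoring.

## Known limitations

* The trajectory generators are statistical stand-ins; they reproduce
  coverage and wall-affinity, not rodent kinematics.  Notably both styles
  eventually cover the whole arena (as the study conditions require), so
  the wall-following style degrades grid maps less than a genuinely
  wall-bound exploration would — the measured hexagonal-gridness gap
  between the styles is accordingly small and its sign is not stable.
* The drive threshold of 1.1 a.u. is coupled to the CAN activity scale set
  by (I_a, σ_w, T, τ): with the defaults the settled bump's maximum is
  ≈ 10-20 a.u. and the mean grid-to-place drive sits near or above the
  threshold for most cells, so condition (ii) mainly excludes cells whose
  index lies far from all module Gaussians.  Changing the CAN constants
  rescales the drive and the threshold should be revisited with them.
* Square gridness of the stretched-torus maps is mildly negative here,
  whereas the study reports positive square-gridness means; no reading of
  the printed geometry we tried reproduces that sign, and the discrepancy
  is documented rather than tuned away.
* One simulation step is one sensory/update cycle; the H-H clock advances
  1 ms per step.  Physical time is otherwise uncalibrated.
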