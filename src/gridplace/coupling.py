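"""Bidirectional place-grid loop: drive, emergence gating, error correction.

Grid modules push a per-cell drive into the place population (the maximum
activity of each module, weighted by a symmetric Gaussian grid-to-place
matrix, averaged across modules).  A place field emerges at the current
position only when three conditions hold simultaneously for a cell --

  (i)   its Hodgkin-Huxley unit fired this step,
  (ii)  its grid-module drive exceeds 1.1 a.u.,
  (iii) its preferred features match the visual scene (activation > A_thr)

-- and the stack of module position estimates currently disagrees enough to
flag the position as uncertain (cross-module spread E_error > 1.5 a.u.).

In the opposite direction, emerged (or fixed, for the field-density
protocol) place-field centers correct the path-integration estimates: on an
uncertain step, if the center nearest the animal's position lies within the
snap radius (2.5 a.u.), every module's estimate is reset to that center.
The correction touches only the position estimates, never the grid-cell
activity itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import Arena, Trajectory, generate_blobs, sense_proximity
from .can import ModuleStack
from .place import FieldTracker, PlaceNetwork, decode_location

__all__ = [
    "GridToPlaceMap",
    "CorrectionPolicy",
    "grid_drive",
    "emergence_gate",
    "estimate_error",
    "correct_position",
    "update_gp_weights",
    "Simulation",
]


@dataclass
class GridToPlaceMap:
    """Gaussian grid-to-place weight matrix over a place-index coordinate.

    Cells are laid out on [0, 10]; each module contributes one Gaussian
    column with centers spread evenly over the range and width 2.5.
    """

    n_cells: int
    n_modules: int = 5
    width: float = 2.5
    mu: float = 0.001
    drive_threshold: float = 1.1
    w: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.drive_threshold <= 0:
            raise ValueError("drive threshold must be positive")
        if self.w is None:
            x = np.linspace(0.0, 10.0, self.n_cells)
            centers = (np.arange(self.n_modules) + 0.5) * 10.0 / self.n_modules
            self.w = np.exp(
                -((x[:, None] - centers[None, :]) ** 2) / (2.0 * self.width**2)
            )


def grid_drive(module_maxima, gp_map: GridToPlaceMap) -> np.ndarray:
    """Per-cell drive: mean over modules of (max module activity x weight)."""
    maxima = np.asarray(module_maxima, dtype=float)
    return (gp_map.w * maxima[None, :]).mean(axis=1)


def emergence_gate(fired, drive, activation, drive_thr: float = 1.1, a_thr: float = 0.3):
    """Conjunction of the three emergence conditions (vectorized)."""
    return (
        np.asarray(fired, dtype=bool)
        & (np.asarray(drive) > drive_thr)
        & (np.asarray(activation) > a_thr)
    )


def estimate_error(estimates) -> float:
    """Cross-module position spread E = sqrt(std(x)^2 + std(y)^2), ddof=1."""
    est = np.asarray(estimates, dtype=float)
    if est.shape[0] < 2:
        raise ValueError("estimate_error needs at least two module estimates")
    sx = est[:, 0].std(ddof=1)
    sy = est[:, 1].std(ddof=1)
    return float(np.hypot(sx, sy))


@dataclass(frozen=True)
class CorrectionPolicy:
    e_thr: float = 1.5        # uncertainty threshold on E_error (a.u.)
    snap_radius: float = 2.5  # max center distance for a correction (a.u.)

    def __post_init__(self) -> None:
        if self.e_thr <= 0 or self.snap_radius <= 0:
            raise ValueError("correction radii must be positive")


def correct_position(
    estimates: np.ndarray,
    centers: np.ndarray,
    true_pos,
    policy: CorrectionPolicy,
) -> tuple[np.ndarray, dict | None]:
    """Snap all module estimates to the nearest field center, if close enough.

    The nearest center is selected by distance to the animal's current
    position; ties break to the lowest center index.  Returns the (possibly
    updated) estimates and an event record (or None).
    """
    est = np.array(estimates, dtype=float, copy=True)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        return est, None
    d = np.linalg.norm(centers - np.asarray(true_pos, dtype=float)[None, :], axis=1)
    k = int(np.argmin(d))  # argmin takes the first (lowest-index) minimum
    if d[k] <= policy.snap_radius:
        event = {"center": centers[k].copy(), "distance": float(d[k]),
                 "pre_estimates": est.copy()}
        est[:] = centers[k]
        return est, event
    return est, None


def update_gp_weights(gp_map: GridToPlaceMap, x_noisy, active) -> GridToPlaceMap:
    """W_GP <- W_GP + mu (X' - W_GP) on rows of active cells.

    The sensor vector is collapsed to its scalar mean (the printed rule is
    dimension-mismatched between the 3 sensors and the module axis).
    """
    s = float(np.mean(np.asarray(x_noisy, dtype=float)))
    active = np.asarray(active)
    gp_map.w[active] += gp_map.mu * (s - gp_map.w[active])
    return gp_map


# ---------------------------------------------------------------------------


@dataclass
class StepLog:
    estimates: np.ndarray     # (T, M, 2)
    e_error: np.ndarray       # (T,)
    n_fields: np.ndarray      # (T,)
    decoded: np.ndarray       # (T, 3): loc_x, loc_y, err_norm
    entropy: np.ndarray       # (T, 7): n, H, S, Z, r, R, I
    bump_centers: np.ndarray | None = None  # (T, M, 2) torus coordinates
    corrections: list = field(default_factory=list)


class Simulation:
    """One coupled run over a trajectory.

    ``place_input`` switches the grid-estimate correction on or off;
    ``field_mode`` selects emergent fields (full place network) or a fixed
    random set of ``n_fixed_fields`` centers drawn once at t=0 (the
    field-density protocol, which skips the place network entirely since
    fixed centers do not depend on it).
    """

    def __init__(
        self,
        arena: Arena,
        trajectory: Trajectory,
        stack: ModuleStack,
        network: PlaceNetwork | None,
        gp_map: GridToPlaceMap | None,
        policy: CorrectionPolicy,
        noise_rng: np.random.Generator,
        alpha: float = 0.1,
        place_input: bool = True,
        field_mode: str = "emergent",
        n_fixed_fields: int = 20,
        field_rng: np.random.Generator | None = None,
        dx_field: float = 20.0,
        record_activity: bool = False,
    ) -> None:
        if field_mode not in ("emergent", "fixed"):
            raise ValueError(f"unknown field_mode: {field_mode!r}")
        self.arena = arena
        self.traj = trajectory
        self.stack = stack
        self.network = network
        self.gp_map = gp_map
        self.policy = policy
        self.noise_rng = noise_rng
        self.alpha = alpha
        self.place_input = place_input
        self.field_mode = field_mode
        self.dx_field = dx_field
        self.record_activity = record_activity

        n_steps = len(trajectory)
        n_mod = len(stack.modules)
        self.log = StepLog(
            estimates=np.full((n_steps, n_mod, 2), np.nan),
            e_error=np.full(n_steps, np.nan),
            n_fields=np.zeros(n_steps),
            decoded=np.full((n_steps, 3), np.nan),
            entropy=np.full((n_steps, 7), np.nan),
            bump_centers=np.full((n_steps, n_mod, 2), np.nan),
        )
        self.log.estimates[0] = stack.estimates
        self.log.bump_centers[0] = np.asarray(stack._prev_centers)
        if field_mode == "fixed":
            rng = field_rng or noise_rng
            self.fixed_centers = rng.uniform(
                0.0, arena.side_length, size=(n_fixed_fields, 2)
            )
            self.tracker = None
        else:
            if network is None or gp_map is None:
                raise ValueError("emergent mode needs a place network and GP map")
            self.fixed_centers = None
            self.tracker = FieldTracker(network.n_cells, arena.side_length)
        # occupancy-binned activity sums for rate maps (filled when recording)
        self._activity_log = [] if record_activity else None

    # -- single step --------------------------------------------------------

    def step(self, t: int) -> None:
        pos = self.traj.pos[t]
        v = pos - self.traj.pos[t - 1]
        self.stack.step(v)
        e_err = estimate_error(self.stack.estimates)
        uncertain = e_err > self.policy.e_thr

        centers, have_centers = self._current_centers()

        if self.tracker is not None:
            reading = sense_proximity(pos, self.arena, self.alpha, self.noise_rng)
            x_norm = reading.x_noisy / self.arena.side_length
            net = self.network
            powers = net.firing_powers(x_norm)
            responding = powers > net.p_thr
            blobs = generate_blobs(pos, self.traj.heading[t], self.arena)
            activation, pairs = net.activations(blobs)
            fired = net.hh_update(powers)
            learn_set = responding & (activation > net.a_thr)
            net.learn(x_norm, learn_set)
            if len(blobs) >= 2:
                winner = int(np.argmax(activation))
                net.adapt_winner(winner, blobs, pairs[winner])
            drive = grid_drive(self._module_maxima(), self.gp_map)
            gate = emergence_gate(
                fired, drive, activation, self.gp_map.drive_threshold, net.a_thr
            )
            if not uncertain:
                gate = np.zeros_like(gate)
            self.tracker.update(
                t, powers, responding, reading.x_noisy[:2], fired, gate
            )
            update_gp_weights(self.gp_map, reading.x_noisy, learn_set)
            c, valid = self.tracker.centers()
            loc, err_norm = decode_location(
                powers, c, responding & valid, pos, self.arena.side_length
            )
            if loc is not None:
                self.log.decoded[t] = (loc[0], loc[1], err_norm)
            self.log.n_fields[t] = self.tracker.n_fields
            self.log.entropy[t] = self._entropy_row()
            centers, have_centers = self._current_centers()

        if self.place_input and uncertain and have_centers:
            new_est, event = correct_position(
                self.stack.estimates, centers, pos, self.policy
            )
            if event is not None:
                self.stack.estimates[:] = new_est
                event["t"] = t
                self.log.corrections.append(event)

        self.log.estimates[t] = self.stack.estimates
        self.log.bump_centers[t] = np.asarray(self.stack._prev_centers)
        self.log.e_error[t] = e_err
        if self._activity_log is not None:
            self._activity_log.append(
                np.stack([m.activity for m in self.stack.modules])
            )

    def run(self) -> StepLog:
        for t in range(1, len(self.traj)):
            self.step(t)
        return self.log

    # -- helpers -------------------------------------------------------------

    def _module_maxima(self) -> np.ndarray:
        return np.array([m.activity.max() for m in self.stack.modules])

    def _current_centers(self) -> tuple[np.ndarray, bool]:
        if self.field_mode == "fixed":
            return self.fixed_centers, True
        if self.tracker is None:
            return np.empty((0, 2)), False
        c, valid = self.tracker.centers()
        if not valid.any():
            return np.empty((0, 2)), False
        return c[valid], True

    def _entropy_row(self) -> np.ndarray:
        """(n, H, S, Z, r, R, I) from cumulative spike counts of field cells."""
        from .metrics import entropy_suite

        emerged = self.tracker.emerged
        n = int(emerged.sum())
        counts = self.tracker.spike_count[emerged]
        total = counts.sum()
        if n == 0 or total == 0:
            return np.array([n, *([np.nan] * 6)])
        p = counts / total
        es = entropy_suite(p, dx=self.dx_field)
        return np.array([n, es.H, es.S, es.Z, es.ratio, es.complexity, es.info])
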