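"""Synthetic square-arena environment.

Stands in for a 3-D exploration environment: a square arena of side ``L``
(arbitrary units), wall/beyond-wall visual landmarks, seeded trajectory
generators in two exploration styles (center-biased "S1" and wall-following
"S2"), noisy wall-proximity sensing along the main axes, and parametric
visual-blob features extracted from the landmarks in the forward field of
view.

The blob generator honours the two classical conditions for landmark-based
self-localization: some features (solidity, orientation of the major axis)
depend only on the landmark identity and are invariant to viewpoint, while
others (apparent area, centroid position in the image) depend on the
observer's pose relative to the landmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Arena",
    "Landmark",
    "Trajectory",
    "NoisySensorReading",
    "BlobFeature",
    "default_landmarks",
    "generate_trajectory",
    "sense_proximity",
    "generate_blobs",
    "read_trajectory_csv",
    "write_trajectory_csv",
]


@dataclass(frozen=True)
class Landmark:
    """A visually distinct landmark on or beyond an arena wall.

    ``solidity`` and ``orientation`` are identity-linked features (constant
    across viewpoints); ``base_area`` scales the pose-linked apparent area
    (area = base_area / distance**2); ``height`` drives the vertical centroid.
    """

    ident: int
    x: float
    y: float
    solidity: float      # dimensionless, in [0, 1]
    orientation: float   # radians, major-axis angle in (-pi/2, pi/2]
    base_area: float     # scene fraction at unit distance
    height: float        # a.u., sets the vertical image centroid


@dataclass(frozen=True)
class Arena:
    side_length: float = 100.0
    landmarks: tuple[Landmark, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        idents = [lm.ident for lm in self.landmarks]
        if len(idents) != len(set(idents)):
            raise ValueError("landmark identities must be distinct")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.side_length / 2.0, self.side_length / 2.0])

    def contains(self, pos) -> bool:
        x, y = float(pos[0]), float(pos[1])
        return 0.0 <= x <= self.side_length and 0.0 <= y <= self.side_length


def default_landmarks(
    L: float = 100.0,
    n_per_wall: int = 10,
    seed: int = 0,
    offset_range: tuple[float, float] = (5.0, 30.0),
) -> tuple[Landmark, ...]:
    """Place ``4 * n_per_wall`` landmarks just beyond the four walls.

    Positions are evenly spread along each wall; identity features are drawn
    once from a seeded generator so the landmark set is a pure function of
    (L, n_per_wall, seed).
    """
    rng = np.random.default_rng(seed)
    landmarks = []
    along = (np.arange(n_per_wall) + 0.5) / n_per_wall * L
    ident = 0
    for wall in range(4):
        for a in along:
            off = rng.uniform(*offset_range)
            if wall == 0:    # below y=0
                x, y = a, -off
            elif wall == 1:  # right of x=L
                x, y = L + off, a
            elif wall == 2:  # above y=L
                x, y = a, L + off
            else:            # left of x=0
                x, y = -off, a
            landmarks.append(
                Landmark(
                    ident=ident,
                    x=float(x),
                    y=float(y),
                    solidity=float(rng.uniform(0.55, 0.95)),
                    orientation=float(rng.uniform(-np.pi / 2, np.pi / 2)),
                    base_area=float(rng.uniform(100.0, 400.0)),
                    height=float(rng.uniform(1.0, 8.0)),
                )
            )
            ident += 1
    return tuple(landmarks)


@dataclass
class Trajectory:
    """Time-indexed 2-D path: positions, headings and per-step velocities.

    ``vel[t] = pos[t] - pos[t-1]`` (vel[0] = 0); the first position is the
    arena center.
    """

    pos: np.ndarray      # (n, 2)
    heading: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)

    def __len__(self) -> int:
        return self.pos.shape[0]

    @property
    def vel(self) -> np.ndarray:
        v = np.zeros_like(self.pos)
        v[1:] = np.diff(self.pos, axis=0)
        return v


@dataclass(frozen=True)
class NoisySensorReading:
    """Per-axis wall distances (L-R, B-F, D-U) with multiplicative noise.

    The D-U component is constant (the agent moves in the plane).
    ``x_noisy = x_true * (1 + alpha * eta)`` with eta ~ U(-1, 1) per component.
    """

    x_true: np.ndarray
    x_noisy: np.ndarray
    alpha: float


@dataclass(frozen=True)
class BlobFeature:
    """Parametric visual-blob features for one landmark in the field of view."""

    area: float          # scene fraction
    orientation: float   # radians
    solidity: float      # [0, 1]
    centroid: tuple[float, float]  # (u, v) normalized image coordinates

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.area, self.orientation, self.solidity, *self.centroid]
        )


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def _perimeter_point(s: float, L: float) -> tuple[float, float]:
    """Map a perimeter arc-length parameter (mod 4L) to wall coordinates."""
    s = s % (4.0 * L)
    if s < L:
        return s, 0.0
    if s < 2 * L:
        return L, s - L
    if s < 3 * L:
        return L - (s - 2 * L), L
    return 0.0, s - 3 * L


def generate_trajectory(
    style: str,
    n_steps: int,
    arena: Arena,
    seed: int,
    max_speed: float = 1.5,
    mean_speed: float = 0.8,
    turn_rate: float = 0.35,
    heading_noise: float = 0.15,
) -> Trajectory:
    """Generate a seeded exploratory trajectory starting at the arena center.

    ``style='center_biased'`` steers between waypoints drawn mostly from a
    Gaussian around the center (S1-like uneven central coverage);
    ``style='wall_following'`` walks along a corridor near the walls with
    occasional crossings of the interior (S2-like), still covering the whole
    arena over long runs.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if style not in ("center_biased", "wall_following"):
        raise ValueError(f"unknown trajectory style: {style!r}")
    L = arena.side_length
    rng = np.random.default_rng(seed)
    margin = 1.0
    pos = np.empty((n_steps, 2))
    heading = np.empty(n_steps)
    p = arena.center.copy()
    h = rng.uniform(0.0, 2 * np.pi)
    pos[0] = p
    heading[0] = h

    # waypoint state
    wall_s = rng.uniform(0.0, 4 * L)       # perimeter parameter (S2)
    wall_dir = rng.choice([-1.0, 1.0])

    def new_waypoint() -> np.ndarray:
        nonlocal wall_s, wall_dir
        if style == "center_biased":
            u = rng.uniform()
            if u < 0.60:
                w = rng.normal(L / 2.0, L / 4.0, size=2)
            elif u < 0.85:
                w = rng.uniform(2.0, L - 2.0, size=2)
            else:
                # occasional border visit so long runs cover the full arena
                wx, wy = _perimeter_point(rng.uniform(0.0, 4 * L), L)
                w = np.array([wx, wy])
                w += (arena.center - w) / np.linalg.norm(arena.center - w) * rng.uniform(2.0, 8.0)
            return np.clip(w, 2.0, L - 2.0)
        # wall_following
        if rng.uniform() < 0.90:
            if rng.uniform() < 0.02:
                wall_dir = -wall_dir
            wall_s += wall_dir * rng.uniform(15.0, 40.0)
            wx, wy = _perimeter_point(wall_s, L)
            off = rng.uniform(2.0, 10.0)
            w = np.array([wx, wy])
            w += (arena.center - w) / np.linalg.norm(arena.center - w) * off
            return np.clip(w, 2.0, L - 2.0)
        return rng.uniform(5.0, L - 5.0, size=2)

    waypoint = new_waypoint()
    steps_on_wp = 0
    for t in range(1, n_steps):
        d = waypoint - p
        dist = np.linalg.norm(d)
        if dist < 2.5 or steps_on_wp > 250:
            waypoint = new_waypoint()
            steps_on_wp = 0
            d = waypoint - p
            dist = np.linalg.norm(d)
        steps_on_wp += 1
        desired = np.arctan2(d[1], d[0])
        dh = np.angle(np.exp(1j * (desired - h)))
        h = h + np.clip(dh, -turn_rate, turn_rate) + heading_noise * rng.normal()
        speed = np.clip(rng.normal(mean_speed, 0.25), 0.1, max_speed)
        q = p + speed * np.array([np.cos(h), np.sin(h)])
        q = np.clip(q, margin, L - margin)
        # a clip shortens the step; never lengthens it, so the speed cap holds
        p = q
        pos[t] = p
        heading[t] = np.angle(np.exp(1j * h))
    return Trajectory(pos=pos, heading=heading)


# ---------------------------------------------------------------------------
# sensing
# ---------------------------------------------------------------------------

def sense_proximity(
    pos,
    arena: Arena,
    alpha: float = 0.1,
    rng: np.random.Generator | None = None,
    z_const: float | None = None,
) -> NoisySensorReading:
    """Noisy per-axis wall distances at ``pos``.

    The three components are the distance to the left wall (L-R axis), to the
    bottom wall (B-F axis), and a constant vertical (D-U) reading, each
    perturbed multiplicatively by ``1 + alpha * eta`` with independent
    eta ~ U(-1, 1).
    """
    if not arena.contains(pos):
        raise ValueError(f"position {pos} outside arena")
    if z_const is None:
        z_const = arena.side_length / 2.0
    x_true = np.array([float(pos[0]), float(pos[1]), float(z_const)])
    if alpha == 0.0 or rng is None:
        eta = np.zeros(3)
    else:
        eta = rng.uniform(-1.0, 1.0, size=3)
    x_noisy = x_true * (1.0 + alpha * eta)
    return NoisySensorReading(x_true=x_true, x_noisy=x_noisy, alpha=alpha)


def generate_blobs(
    pos,
    heading: float,
    arena: Arena,
    fov: float = np.pi / 2,
    max_area: float = 0.5,
) -> list[BlobFeature]:
    """Blob features for every landmark inside the forward field of view.

    Deterministic given (pos, heading, arena): identity features come straight
    from the landmark, pose features from distance (area ~ 1/d^2) and bearing
    (horizontal centroid u) / elevation (vertical centroid v).
    """
    if not arena.contains(pos):
        raise ValueError(f"position {pos} outside arena")
    px, py = float(pos[0]), float(pos[1])
    blobs: list[BlobFeature] = []
    for lm in arena.landmarks:
        dx, dy = lm.x - px, lm.y - py
        d = float(np.hypot(dx, dy))
        if d < 1e-9:
            continue
        bearing = float(np.angle(np.exp(1j * (np.arctan2(dy, dx) - heading))))
        if abs(bearing) > fov / 2.0:
            continue
        area = min(lm.base_area / d**2, max_area)
        u = 0.5 + bearing / fov                      # in [0, 1]
        v = float(np.clip(0.5 + lm.height / d, 0.0, 1.0))
        blobs.append(
            BlobFeature(
                area=float(area),
                orientation=lm.orientation,
                solidity=lm.solidity,
                centroid=(float(u), v),
            )
        )
    return blobs


# ---------------------------------------------------------------------------
# trajectory CSV interface: columns t,x,y,heading
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path) -> None:
    df = pd.DataFrame(
        {
            "t": np.arange(len(traj)),
            "x": traj.pos[:, 0],
            "y": traj.pos[:, 1],
            "heading": traj.heading,
        }
    )
    df.to_csv(path, index=False)


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path)
    for col in ("t", "x", "y", "heading"):
        if col not in df.columns:
            raise ValueError(f"trajectory CSV missing column {col!r}")
    df = df.sort_values("t")
    return Trajectory(
        pos=df[["x", "y"]].to_numpy(dtype=float),
        heading=df["heading"].to_numpy(dtype=float),
    )
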