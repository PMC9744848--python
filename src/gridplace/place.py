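"""Place-cell population: proximity tuning, H-H firing, vision matching.

The population links N_s = 3 wall-proximity sensors to N_pc = 2000 place
cells.  Each cell j carries

* a sensor weight vector w_j (its proximity tuning point, in wall-distance
  units normalized by the arena side L),
* a spike energy draw C_j ~ N(188, 10) nJ and tuning width
  sigma_j ~ N(0.03, 0.005) expressing metabolic diversity,
* two preferred visual-blob feature sets M1, M2 (area, orientation,
  solidity, centroid u, v) for conjunctive feature matching, and
* a Hodgkin-Huxley unit whose spiking defines "the cell fired".

Firing power:  P_j = C_j R_m exp(-(||X'/L - w_j|| / n)^2 / (2 sigma_j^2))
Learning:      w_j <- w_j + mu (X'/L - w_j)   for responding cells
Activation:    A = max_i A_Bi(M1) * max_{j != i} A_Bj(M2)  over visible blobs
Field center:  C_j = sum_t P_j X' / sum_t P_j  (power-weighted centroid)
Decoding:      Loc = sum_J P_j C_j / sum_J P_j  over responders J

The normalized decoding error is ||Loc - pos|| / (L / sqrt(2)) clipped to
[0, 1], so an unselective population (Loc pinned near the arena center)
scores errors of order one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hh
from .arena import BlobFeature

__all__ = [
    "PlaceNetwork",
    "FieldTracker",
    "weight_init",
    "firing_power",
    "competitive_update",
    "feature_similarity",
    "place_activation",
    "adapt_feature_centers",
    "field_center",
    "decode_location",
]

N_FEATURES = 5  # area, orientation, solidity, centroid u, centroid v


def weight_init(
    rng: np.random.Generator, size=None, sigma_init: float = 0.25
) -> np.ndarray | float:
    """Logistic-transformed uniform weights, symmetric about 0.5.

    w = (1 + exp((gamma - E[gamma]) / (2 sigma^2)))^-1 with gamma ~ U(0, 1).
    """
    gamma = rng.uniform(0.0, 1.0, size=size)
    return 1.0 / (1.0 + np.exp((gamma - 0.5) / (2.0 * sigma_init**2)))


def firing_power(w_j, x_norm, sigma_j, c_rm, n_sensors: int = 3):
    """Gaussian firing power; maximal (= C R_m) when X'/L equals w_j."""
    d = np.linalg.norm(np.asarray(x_norm, dtype=float) - np.asarray(w_j, dtype=float), axis=-1)
    return c_rm * np.exp(-((d / n_sensors) ** 2) / (2.0 * np.asarray(sigma_j) ** 2))


def competitive_update(w, x_norm, mu: float, responding) -> np.ndarray:
    """w_j <- w_j + mu (X'/L - w_j) for responding cells only."""
    w = np.array(w, dtype=float, copy=True)
    responding = np.asarray(responding)
    w[responding] += mu * (np.asarray(x_norm, dtype=float) - w[responding])
    return w


def feature_similarity(x_f, mu_f, sigma_f: float = 0.5):
    """Gaussian similarity G = exp(-((x_f - mu_f) / sigma_f)^2) in (0, 1]."""
    if np.any(np.asarray(sigma_f) <= 0):
        raise ValueError("sigma_f must be positive")
    return np.exp(-(((np.asarray(x_f) - np.asarray(mu_f)) / sigma_f) ** 2))


def _blob_response(blob_feats: np.ndarray, mu: np.ndarray, sigma_f: float) -> np.ndarray:
    """Product of feature similarities: shape (..., n_blobs)."""
    # mu: (..., F); blob_feats: (k, F) -> (..., k)
    z = (blob_feats[None, :, :] - mu[..., None, :]) / sigma_f
    return np.exp(-np.sum(z * z, axis=-1))


def place_activation(
    blobs: list[BlobFeature], m1: np.ndarray, m2: np.ndarray, sigma_f: float = 0.5
) -> float:
    """Conjunctive two-blob activation of a single cell.

    A = max_i A_Bi(M1) * max_{j != i} A_Bj(M2) over distinct visible blobs;
    zero when fewer than two blobs are visible.
    """
    a = place_activation_all(blobs, np.atleast_2d(m1), np.atleast_2d(m2), sigma_f)
    return float(a[0])


def place_activation_all(
    blobs: list[BlobFeature], m1: np.ndarray, m2: np.ndarray, sigma_f: float = 0.5
) -> np.ndarray:
    """Vectorized two-blob activation for all cells, with best-pair indices.

    Returns the activation vector; ``place_activation_all.last_pairs`` holds
    the (i, j) blob indices of the winning ordered pair per cell.
    """
    n_cells = m1.shape[0]
    k = len(blobs)
    if k < 2:
        place_activation_all.last_pairs = np.zeros((n_cells, 2), dtype=int)
        return np.zeros(n_cells)
    feats = np.stack([b.as_vector() for b in blobs])  # (k, F)
    a1 = _blob_response(feats, m1, sigma_f)  # (n, k)
    a2 = _blob_response(feats, m2, sigma_f)
    prod = a1[:, :, None] * a2[:, None, :]   # (n, k, k): pair (i, j)
    ii = np.arange(k)
    prod[:, ii, ii] = -1.0                   # exclude i == j
    flat = prod.reshape(n_cells, -1)
    best = np.argmax(flat, axis=1)
    place_activation_all.last_pairs = np.column_stack([best // k, best % k])
    return flat[np.arange(n_cells), best]


place_activation_all.last_pairs = None


def adapt_feature_centers(mu_f, x_f, alpha: float = 0.5) -> np.ndarray:
    """Winner feature adaptation mu_f <- alpha x_f + (1 - alpha) mu_f.

    The convex combination is a contraction toward the observed features.
    """
    mu_f = np.asarray(mu_f, dtype=float)
    x_f = np.asarray(x_f, dtype=float)
    return alpha * x_f + (1.0 - alpha) * mu_f


def field_center(powers, positions) -> np.ndarray:
    """Power-weighted centroid of visited (noisy) positions."""
    p = np.asarray(powers, dtype=float)
    x = np.asarray(positions, dtype=float)
    s = p.sum()
    if s <= 0:
        raise ValueError("field center undefined: all powers are zero")
    return (p[:, None] * x).sum(axis=0) / s


def decode_location(
    powers, centers, responding, true_pos, side_length: float
) -> tuple[np.ndarray | None, float]:
    """Population location estimate and normalized decoding error.

    Loc is the power-weighted average of responder field centers; the error
    is ||Loc - pos|| / (L / sqrt(2)) clipped to [0, 1].  Returns (None, nan)
    when no responder has a defined center.
    """
    responding = np.asarray(responding)
    if responding.sum() == 0:
        return None, float("nan")
    p = np.asarray(powers, dtype=float)[responding]
    c = np.asarray(centers, dtype=float)[responding]
    loc = (p[:, None] * c).sum(axis=0) / p.sum()
    err = np.linalg.norm(loc - np.asarray(true_pos, dtype=float))
    return loc, float(min(err / (side_length / np.sqrt(2.0)), 1.0))


# ---------------------------------------------------------------------------


@dataclass
class PlaceNetwork:
    """Vectorized state of the whole place-cell population."""

    n_cells: int = 2000
    n_sensors: int = 3
    r_max: float = 20.0          # Hz
    p_thr: float = 0.3           # firing-power threshold
    mu: float = 0.001            # sensor-weight learning rate
    sigma_f: float = 0.5         # feature-similarity width
    alpha_adapt: float = 0.5     # winner feature adaptation rate
    a_thr: float = 0.3           # feature-match activation threshold
    i_drive: float = 10.0        # H-H drive at/above firing-power threshold
    i_gate: float = 2.0          # cells below this current are held at rest
    hh_dt: float = 0.01          # ms
    hh_substeps: int = 100
    weight_sigma_init: float = 0.25

    # state arrays (filled by init)
    w: np.ndarray = field(default=None, repr=False)
    c_energy: np.ndarray = field(default=None, repr=False)
    sigma_j: np.ndarray = field(default=None, repr=False)
    m1: np.ndarray = field(default=None, repr=False)
    m2: np.ndarray = field(default=None, repr=False)
    hh_u: np.ndarray = field(default=None, repr=False)
    hh_m: np.ndarray = field(default=None, repr=False)
    hh_h: np.ndarray = field(default=None, repr=False)
    hh_n: np.ndarray = field(default=None, repr=False)

    def init(self, rng: np.random.Generator) -> "PlaceNetwork":
        n = self.n_cells
        self.w = weight_init(rng, size=(n, self.n_sensors), sigma_init=self.weight_sigma_init)
        self.c_energy = rng.normal(188.0, 10.0, size=n)
        self.sigma_j = np.clip(rng.normal(0.03, 0.005, size=n), 1e-3, None)
        self.m1 = self._random_preferences(rng, n)
        self.m2 = self._random_preferences(rng, n)
        rest = _hh_rest_state()
        self.hh_u = np.full(n, rest[0])
        self.hh_m = np.full(n, rest[1])
        self.hh_h = np.full(n, rest[2])
        self.hh_n = np.full(n, rest[3])
        return self

    @staticmethod
    def _random_preferences(rng: np.random.Generator, n: int) -> np.ndarray:
        """Random blob-feature preferences on the blob feature scales."""
        return np.column_stack(
            [
                rng.uniform(0.0, 0.5, n),              # area (scene fraction)
                rng.uniform(-np.pi / 2, np.pi / 2, n),  # orientation
                rng.uniform(0.5, 1.0, n),               # solidity
                rng.uniform(0.0, 1.0, n),               # centroid u
                rng.uniform(0.0, 1.0, n),               # centroid v
            ]
        )

    @property
    def c_rm(self) -> np.ndarray:
        return self.c_energy * self.r_max

    def firing_powers(self, x_norm) -> np.ndarray:
        return firing_power(self.w, x_norm, self.sigma_j, self.c_rm, self.n_sensors)

    def activations(self, blobs: list[BlobFeature]) -> tuple[np.ndarray, np.ndarray]:
        a = place_activation_all(blobs, self.m1, self.m2, self.sigma_f)
        return a, place_activation_all.last_pairs

    def hh_update(self, powers: np.ndarray) -> np.ndarray:
        """Advance every driven H-H unit one behavioral step; return fired flags.

        Drive current is I_0 * min(P / P_thr, 1); cells whose current cannot
        reach rheobase are held at rest (they cannot fire by construction).
        """
        i_ext = self.i_drive * np.minimum(powers / self.p_thr, 1.0)
        excited = np.abs(self.hh_u) > 3.0
        active = np.flatnonzero((i_ext > self.i_gate) | excited)
        fired = hh.hh_integrate_cells(
            self.hh_u, self.hh_m, self.hh_h, self.hh_n,
            i_ext, active, self.hh_dt, self.hh_substeps,
            hh.SPIKE_THRESHOLD_MV - hh.V_REST,
        )
        return fired

    def learn(self, x_norm, responding) -> None:
        self.w = competitive_update(self.w, x_norm, self.mu, responding)

    def adapt_winner(self, winner: int, blobs: list[BlobFeature], pair) -> None:
        """Adapt the winning cell's M1/M2 toward its best-matching blob pair."""
        i, j = int(pair[0]), int(pair[1])
        self.m1[winner] = adapt_feature_centers(
            self.m1[winner], blobs[i].as_vector(), self.alpha_adapt
        )
        self.m2[winner] = adapt_feature_centers(
            self.m2[winner], blobs[j].as_vector(), self.alpha_adapt
        )


def train_post_navigation(
    network: PlaceNetwork, x_norm_series: np.ndarray, n_epochs: int = 1
) -> PlaceNetwork:
    """Batch (post-navigation) competitive training of the sensor weights.

    Replays recorded normalized sensor vectors after the run instead of
    updating online; used to speed up statistics when the coupled loop is
    not needed.  Only the firing-power threshold gates the updates (no
    visual or H-H conditions are evaluated offline).
    """
    x_norm_series = np.asarray(x_norm_series, dtype=float)
    for _ in range(n_epochs):
        for x in x_norm_series:
            powers = network.firing_powers(x)
            network.learn(x, powers > network.p_thr)
    return network


_REST_CACHE: np.ndarray | None = None


def _hh_rest_state() -> np.ndarray:
    """Resting (u, m, h, n) of the unforced H-H unit, found by relaxation."""
    global _REST_CACHE
    if _REST_CACHE is None:
        s, _ = hh.hh_run(hh.HHState(), 0.0, 0.01, 20000)
        _REST_CACHE = np.array([s.v_m - hh.V_REST, s.m, s.h, s.n])
    return _REST_CACHE


@dataclass
class FieldTracker:
    """Cumulative place-field bookkeeping over a run.

    Tracks, per cell: the power-weighted field-center sums, member locations
    on a 1 a.u. grid, the running firing-power peak and its location, the
    emergence step (first time the three-condition gate passed), and the
    H-H spike counts that feed the entropy suite.
    """

    n_cells: int
    side_length: float
    grid_res: float = 1.0

    def __post_init__(self) -> None:
        n_bins = int(np.ceil(self.side_length / self.grid_res))
        self._n_bins = n_bins
        self.member = np.zeros((self.n_cells, n_bins, n_bins), dtype=bool)
        self.sum_px = np.zeros((self.n_cells, 2))
        self.sum_p = np.zeros(self.n_cells)
        self.peak_power = np.zeros(self.n_cells)
        self.peak_pos = np.full((self.n_cells, 2), np.nan)
        self.emerged = np.zeros(self.n_cells, dtype=bool)
        self.emergence_step = np.full(self.n_cells, -1, dtype=int)
        self.spike_count = np.zeros(self.n_cells, dtype=np.int64)
        self.peak_shift_sum = 0.0          # per-step mean peak displacement
        self.peak_shift_series: list[float] = []

    def update(self, t: int, powers, responding, pos_xy, fired, gate) -> None:
        responding = np.asarray(responding)
        pos_xy = np.asarray(pos_xy, dtype=float)
        idx = np.flatnonzero(responding)
        if idx.size:
            p = powers[idx]
            self.sum_px[idx] += p[:, None] * pos_xy[None, :]
            self.sum_p[idx] += p
            bx = int(np.clip(pos_xy[0] / self.grid_res, 0, self._n_bins - 1))
            by = int(np.clip(pos_xy[1] / self.grid_res, 0, self._n_bins - 1))
            self.member[idx, bx, by] = True
            better = np.flatnonzero(responding & (powers > self.peak_power))
            if better.size:
                old = self.peak_pos[better]
                shift = np.linalg.norm(pos_xy[None, :] - old, axis=1)
                shift = shift[np.isfinite(shift)]
                self.peak_power[better] = powers[better]
                self.peak_pos[better] = pos_xy
                n_emerged = max(int(self.emerged.sum()), 1)
                self.peak_shift_series.append(float(shift.sum()) / n_emerged)
            else:
                self.peak_shift_series.append(0.0)
        else:
            self.peak_shift_series.append(0.0)
        self.spike_count[np.asarray(fired)] += 1
        newly = np.asarray(gate) & ~self.emerged
        if newly.any():
            self.emerged[newly] = True
            self.emergence_step[newly] = t

    @property
    def n_fields(self) -> int:
        return int(self.emerged.sum())

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(centers, valid): power-weighted centers of emerged cells."""
        valid = self.emerged & (self.sum_p > 0)
        centers = np.full((self.n_cells, 2), np.nan)
        nz = np.flatnonzero(valid)
        centers[nz] = self.sum_px[nz] / self.sum_p[nz, None]
        return centers, valid

    def field_table(self) -> "pd.DataFrame":
        import pandas as pd

        centers, valid = self.centers()
        idx = np.flatnonzero(valid)
        return pd.DataFrame(
            {
                "cell_id": idx,
                "emergence_step": self.emergence_step[idx],
                "center_x": centers[idx, 0],
                "center_y": centers[idx, 1],
                "peak_x": self.peak_pos[idx, 0],
                "peak_y": self.peak_pos[idx, 1],
                "n_member_locations": self.member[idx].sum(axis=(1, 2)),
            }
        )
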