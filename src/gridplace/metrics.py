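"""Spatial firing analysis: rate maps, autocorrelograms, gridness, entropy.

The gridness scores follow the rotated-ring procedure: the spatial
autocorrelogram (lag-wise Pearson correlation of the rate map with itself)
is cropped to an annulus spanning the six fields nearest the center, the
annulus is rotated, and the Pearson correlation C_theta between rotated and
unrotated annuli is combined as

    hexagonal gridness = 1/2 (C60 + C120) - 1/3 (C30 + C90 + C150)
    square   gridness = C90 - 1/2 (C45 + C135)

The entropy suite characterizes the place-field event distribution p_i
(spike share per field-bearing cell): Shannon entropy H = -sum p log p,
entropy ratio r = H / log n, complexity ratio R = 1 - r, information
difference I = log n - H, and the decomposition H = S + Z into spatial
entropy S = -sum p log(p / dx) and information density Z = -sum p log dx.
Natural logarithms throughout (a ``base2`` flag switches to bits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "RateMap",
    "rate_map",
    "accumulate_rate_maps",
    "autocorrelogram",
    "gridness_hex",
    "gridness_square",
    "rotation_correlations",
    "EntropySuite",
    "entropy_suite",
    "cross_entropy_measures",
    "error_summaries",
]


# ---------------------------------------------------------------------------
# rate maps
# ---------------------------------------------------------------------------


@dataclass
class RateMap:
    """Occupancy-normalized binned mean activity; NaN marks unvisited bins."""

    values: np.ndarray     # (nb, nb), NaN where occupancy == 0
    occupancy: np.ndarray  # (nb, nb) visit counts
    bin_size: float


def _smooth_nan(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that ignores NaN bins (normalized convolution)."""
    if sigma <= 0:
        return values
    valid = np.isfinite(values)
    filled = np.where(valid, values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(valid.astype(float), sigma)
    out = np.full_like(values, np.nan)
    good = den > 1e-12
    out[good] = num[good] / den[good]
    out[~valid] = np.nan
    return out


def rate_map(
    activity,
    positions,
    side_length: float,
    bin_size: float = 2.5,
    smooth_sigma: float = 1.0,
) -> RateMap:
    """Binned occupancy-normalized mean activity of one cell.

    ``smooth_sigma`` is in bins; unvisited bins stay missing and are never
    filled by smoothing.
    """
    activity = np.asarray(activity, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("empty trajectory")
    nb = int(np.ceil(side_length / bin_size))
    ix = np.clip((positions[:, 0] / bin_size).astype(int), 0, nb - 1)
    iy = np.clip((positions[:, 1] / bin_size).astype(int), 0, nb - 1)
    occ = np.zeros((nb, nb))
    tot = np.zeros((nb, nb))
    np.add.at(occ, (ix, iy), 1.0)
    np.add.at(tot, (ix, iy), activity)
    values = np.full((nb, nb), np.nan)
    visited = occ > 0
    values[visited] = tot[visited] / occ[visited]
    return RateMap(_smooth_nan(values, smooth_sigma), occ, bin_size)


def accumulate_rate_maps(
    activity_sums: np.ndarray,
    occupancy: np.ndarray,
    bin_size: float = 2.5,
    smooth_sigma: float = 1.0,
) -> list[RateMap]:
    """Rate maps for many cells from pre-binned activity sums.

    ``activity_sums`` has shape (n_cells, nb, nb); ``occupancy`` (nb, nb).
    """
    visited = occupancy > 0
    maps = []
    for k in range(activity_sums.shape[0]):
        values = np.full(occupancy.shape, np.nan)
        values[visited] = activity_sums[k][visited] / occupancy[visited]
        maps.append(RateMap(_smooth_nan(values, smooth_sigma), occupancy, bin_size))
    return maps


# ---------------------------------------------------------------------------
# spatial autocorrelogram and gridness
# ---------------------------------------------------------------------------


def autocorrelogram(rmap: RateMap, min_overlap: int = 20) -> np.ndarray:
    """Lag-wise Pearson spatial autocorrelation of a rate map.

    Computed over the overlapping valid bins at every lag via FFT
    correlation of the map and its validity mask; lags with fewer than
    ``min_overlap`` overlapping bins are NaN.  The zero-lag value is 1 and
    the surface is centro-symmetric.
    """
    x = np.asarray(rmap.values, dtype=float)
    valid = np.isfinite(x)
    if valid.sum() < 2:
        raise ValueError("autocorrelogram needs at least two valid bins")
    xf = np.where(valid, x, 0.0)
    m = valid.astype(float)

    def corr(a, b):
        return signal.fftconvolve(a, b[::-1, ::-1], mode="full")

    n = corr(m, m)
    sx = corr(xf, m)
    sy = corr(m, xf)
    sxy = corr(xf, xf)
    sxx = corr(xf**2, m)
    syy = corr(m, xf**2)
    n_r = np.rint(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = np.sqrt(np.maximum(n * sxx - sx**2, 0.0) * np.maximum(n * syy - sy**2, 0.0))
        ac = num / den
    ac[(n_r < min_overlap) | (den <= 1e-12 * np.maximum(n, 1.0))] = np.nan
    return np.clip(ac, -1.0, 1.0)


def _central_peaks(ac: np.ndarray, n_peaks: int = 6) -> np.ndarray:
    """Distances/offsets of the local maxima nearest the center (excl. it)."""
    filled = np.where(np.isfinite(ac), ac, -np.inf)
    smooth = ndimage.gaussian_filter(np.where(np.isfinite(ac), ac, 0.0), 1.0)
    local_max = (ndimage.maximum_filter(smooth, size=3) == smooth) & np.isfinite(ac)
    cy, cx = (np.array(ac.shape) - 1) / 2.0
    pts = np.argwhere(local_max)
    if pts.size == 0:
        return np.empty((0, 2))
    off = pts - np.array([cy, cx])
    dist = np.linalg.norm(off, axis=1)
    keep = dist > 2.0  # exclude the central peak plateau
    off, dist = off[keep], dist[keep]
    pos_val = smooth[pts[keep][:, 0], pts[keep][:, 1]] > 0
    off, dist = off[pos_val], dist[pos_val]
    order = np.argsort(dist)
    return off[order[:n_peaks]]


def rotation_correlations(
    ac: np.ndarray, angles, dphi: float = 3.0, dr: float = 0.5
) -> dict[float, float]:
    """Pearson correlation of the cropped annulus with its rotations.

    The annulus spans from half the distance of the nearest of the six
    central peaks to 1.25x their mean distance.  It is resampled once onto a
    polar grid (cubic interpolation, angular step ``dphi`` degrees), after
    which a rotation by any multiple of ``dphi`` is an exact cyclic shift of
    the angle axis; bins touching missing data are excluded pairwise.
    Returns NaN correlations when no peaks are detectable.
    """
    peaks = _central_peaks(ac)
    if peaks.shape[0] == 0:
        return {float(a): float("nan") for a in angles}
    for a in angles:
        if abs(a / dphi - round(a / dphi)) > 1e-9:
            raise ValueError(f"rotation angle {a} not a multiple of dphi={dphi}")
    dist = np.linalg.norm(peaks, axis=1)
    inner = 0.5 * dist.min()
    # keep the cubic stencil clear of the array boundary
    outer = min(1.25 * dist.mean(), (min(ac.shape) - 1) / 2.0 - 2.0)
    cy, cx = (np.array(ac.shape) - 1) / 2.0
    radii = np.arange(inner, outer + 1e-9, dr)
    phis = np.deg2rad(np.arange(0.0, 360.0, dphi))
    yy = cy + radii[:, None] * np.sin(phis)[None, :]
    xx = cx + radii[:, None] * np.cos(phis)[None, :]
    valid = np.isfinite(ac)
    vals = ndimage.map_coordinates(
        np.where(valid, ac, 0.0), [yy, xx], order=4, mode="nearest"
    )
    supp = ndimage.map_coordinates(
        valid.astype(float), [yy, xx], order=1, mode="constant", cval=0.0
    )
    good = supp > 0.999
    out: dict[float, float] = {}
    for a in angles:
        k = int(round(a / dphi))
        vr = np.roll(vals, -k, axis=1)
        gr = np.roll(good, -k, axis=1)
        ok = good & gr
        if ok.sum() < 20:
            out[float(a)] = float("nan")
            continue
        u, v = vals[ok], vr[ok]
        du, dv = u - u.mean(), v - v.mean()
        denom = np.sqrt((du @ du) * (dv @ dv))
        out[float(a)] = float(du @ dv / denom) if denom > 1e-12 else float("nan")
    return out


def gridness_hex(ac: np.ndarray) -> float:
    """Hexagonal gridness 1/2 (C60 + C120) - 1/3 (C30 + C90 + C150)."""
    c = rotation_correlations(ac, (30, 60, 90, 120, 150))
    return 0.5 * (c[60] + c[120]) - (c[30] + c[90] + c[150]) / 3.0


def gridness_square(ac: np.ndarray) -> float:
    """Square gridness C90 - 1/2 (C45 + C135)."""
    c = rotation_correlations(ac, (45, 90, 135))
    return c[90] - 0.5 * (c[45] + c[135])


# ---------------------------------------------------------------------------
# entropy / complexity suite
# ---------------------------------------------------------------------------


class EntropySuite(NamedTuple):
    H: float          # Shannon entropy
    H_max: float      # log n
    ratio: float      # r = H / H_max
    complexity: float  # R = 1 - r
    info: float       # I = H_max - H
    S: float          # spatial entropy
    Z: float          # information density


def _check_dist(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"distribution not normalized: sum = {p.sum()}")
    return np.clip(p, 0.0, None)


def entropy_suite(p, dx=20.0, base2: bool = False) -> EntropySuite:
    """Entropy, ratio/complexity/information and the H = S + Z split.

    ``dx`` is the event (place-field) size, scalar or per-event; the
    convention 0 log 0 = 0 applies throughout.
    """
    p = _check_dist(p)
    log = np.log2 if base2 else np.log
    n = p.size
    dx = np.broadcast_to(np.asarray(dx, dtype=float), p.shape)
    if np.any(dx <= 0):
        raise ValueError("event sizes must be positive")
    nz = p > 0
    h = float(-(p[nz] * log(p[nz])).sum())
    s = float(-(p[nz] * log(p[nz] / dx[nz])).sum())
    z = float(-(p[nz] * log(dx[nz])).sum())
    h_max = float(log(n)) if n > 1 else 0.0
    if h_max > 0:
        r = h / h_max
    else:
        r = 1.0  # single-event distribution: trivially at its maximum
    return EntropySuite(
        H=h, H_max=h_max, ratio=r, complexity=1.0 - r, info=h_max - h, S=s, Z=z
    )


def cross_entropy_measures(p, q, base2: bool = False):
    """(H(p), H(q), H(p/q), I) against a reference distribution q.

    H(p) = -sum p log q (the cross term), H(q) = -sum q log q,
    H(p/q) = H(q) - H(p), and I = sum p log(p/q) (the information
    difference, a KL divergence).  Requires q > 0 wherever p > 0.
    """
    p = _check_dist(p)
    q = _check_dist(q)
    log = np.log2 if base2 else np.log
    nz = p > 0
    if np.any(q[nz] <= 0):
        raise ValueError("q must be positive on the support of p")
    hp = float(-(p[nz] * log(q[nz])).sum())
    qnz = q > 0
    hq = float(-(q[qnz] * log(q[qnz])).sum())
    hpq = hq - hp
    i = float((p[nz] * log(p[nz] / q[nz])).sum())
    return hp, hq, hpq, i


# ---------------------------------------------------------------------------
# error summaries
# ---------------------------------------------------------------------------


def error_summaries(
    estimates: np.ndarray, truth: np.ndarray, n_bins: int = 100
) -> dict[str, pd.DataFrame]:
    """Per-module error series, cross-module spread, and binned means.

    ``estimates`` has shape (T, M, 2) and ``truth`` (T, 2).  Returns
    time-series and binned-mean tables; the cross-module spread uses the
    sample (n-1) standard deviation in each coordinate.
    """
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.shape[0] != truth.shape[0]:
        raise ValueError("estimates and trajectory lengths differ")
    t_len, n_mod = estimates.shape[0], estimates.shape[1]
    err = np.linalg.norm(estimates - truth[:, None, :], axis=2)  # (T, M)
    sx = estimates[:, :, 0].std(axis=1, ddof=1)
    sy = estimates[:, :, 1].std(axis=1, ddof=1)
    e_error = np.hypot(sx, sy)
    variance = sx**2 + sy**2
    series = pd.DataFrame(
        {"t": np.arange(t_len), "e_error": e_error, "variance": variance}
    )
    for m in range(n_mod):
        series[f"err_module{m + 1}"] = err[:, m]
    bins = np.array_split(np.arange(t_len), min(n_bins, t_len))
    rows = []
    for b in bins:
        row = {"t_mid": float(np.mean(b))}
        for m in range(n_mod):
            row[f"err_module{m + 1}"] = float(np.nanmean(err[b, m]))
        row["e_error"] = float(np.nanmean(e_error[b]))
        rows.append(row)
    return {"series": series, "binned": pd.DataFrame(rows)}
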