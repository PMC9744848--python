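import numpy as np
import pytest

from gridplace.arena import Arena, default_landmarks
from gridplace.can import TorusGeometry
from gridplace.metrics import RateMap


@pytest.fixture(scope="session")
def arena():
    return Arena(side_length=100.0, landmarks=default_landmarks())


@pytest.fixture(scope="session")
def geometry():
    return TorusGeometry()


def lattice_map(kind: str, spacing: float = 20.0, angle: float = 0.0,
                width: float = 4.0, nb: int = 40, bin_size: float = 2.5) -> RateMap:
    """Synthetic rate map whose fields tile a hexagonal or square lattice."""
    xs = (np.arange(nb) + 0.5) * bin_size
    x, y = np.meshgrid(xs, xs, indexing="ij")
    if kind == "hex":
        basis = np.array([[1.0, 0.0], [0.5, np.sqrt(3) / 2]]) * spacing
    elif kind == "square":
        basis = np.array([[1.0, 0.0], [0.0, 1.0]]) * spacing
    else:
        raise ValueError(kind)
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    basis = basis @ rot.T
    center = nb * bin_size / 2.0
    vals = np.zeros_like(x)
    for a in range(-10, 11):
        for b in range(-10, 11):
            cx, cy = a * basis[0] + b * basis[1] + center
            vals += np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2))
    return RateMap(vals, np.ones_like(vals), bin_size)


def symmetric_autocorrelogram(n: int = 79) -> np.ndarray:
    """A circularly symmetric autocorrelogram-like surface (ring + center)."""
    c = (n - 1) / 2.0
    yy, xx = np.indices((n, n))
    r = np.hypot(yy - c, xx - c)
    return np.exp(-(r**2) / (2 * 4.5**2)) + 0.8 * np.exp(-((r - 10.0) ** 2) / (2 * 3.0**2))
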