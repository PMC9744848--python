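"""Hodgkin–Huxley point-neuron dynamics for the place-cell energy model.

The classic squid-axon equations are integrated with forward Euler on the
deviation voltage u = V_m − V_r (rest at u ≈ 0, V_r = −65 mV):

    C_m du/dt = g_l (E_l − u) + g_Na m³h (E_Na − u) + g_K n⁴ (E_K − u) + I
    dx/dt     = α_x(u) (1 − x) − β_x(u) x          for x in {m, h, n}

with the standard rate functions and the conductance/reversal constants
g_Na = 120, E_Na = 150, g_K = 36, E_K = −12, g_l = 0.3, E_l = 10.6 (mS/cm²
and mV on the deviation scale), C_m = 1 µF/cm², dt = 0.01 ms.  Gating
variables are clamped to [0, 1] after every Euler step, which keeps large-dt
overshoot from leaving the admissible range.

A spike is an upward crossing of V_m = 0 mV (u = 65).  A sustained current of
I = 10 µA/cm² produces the classic periodic spiking; the rheobase is ≈ 6.

Scalar/vector wrappers are plain NumPy; the network path uses a numba kernel
that integrates only the driven subset of cells (see :mod:`gridplace.place`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["HHState", "HH_PARAMS", "hh_step", "hh_run", "hh_integrate_cells"]

V_REST = -65.0  # mV, resting membrane potential V_r
SPIKE_THRESHOLD_MV = 0.0  # absolute V_m of the spike-detection crossing

#: conductances (mS/cm²), reversal potentials (mV, deviation scale), C_m (µF/cm²)
HH_PARAMS = dict(g_na=120.0, e_na=150.0, g_k=36.0, e_k=-12.0,
                 g_l=0.3, e_l=10.6, c_m=1.0)


@dataclass
class HHState:
    """Membrane potential (absolute mV) and gating variables of one neuron."""

    v_m: float = V_REST
    m: float = 0.5
    h: float = 0.06
    n: float = 0.5

    def as_array(self) -> np.ndarray:
        return np.array([self.v_m, self.m, self.h, self.n])


@njit(cache=False)
def _rates(u):
    """Voltage-dependent channel rate constants at deviation voltage u (mV)."""
    if abs(10.0 - u) < 1e-7:
        a_n = 0.1  # removable singularity of x/(exp(x/10)-1) at x=0
    else:
        a_n = 0.01 * (10.0 - u) / (np.exp((10.0 - u) / 10.0) - 1.0)
    b_n = 0.125 * np.exp(-u / 80.0)
    if abs(25.0 - u) < 1e-7:
        a_m = 1.0
    else:
        a_m = 0.1 * (25.0 - u) / (np.exp((25.0 - u) / 10.0) - 1.0)
    b_m = 4.0 * np.exp(-u / 18.0)
    a_h = 0.07 * np.exp(-u / 20.0)
    b_h = 1.0 / (np.exp((30.0 - u) / 10.0) + 1.0)
    return a_n, b_n, a_m, b_m, a_h, b_h


@njit(cache=False)
def _euler_step(u, m, h, n, i_ext, dt):
    a_n, b_n, a_m, b_m, a_h, b_h = _rates(u)
    du = (HH_G_L * (HH_E_L - u)
          + HH_G_NA * m**3 * h * (HH_E_NA - u)
          + HH_G_K * n**4 * (HH_E_K - u)
          + i_ext) / HH_C_M
    u2 = u + dt * du
    m2 = m + dt * (a_m * (1.0 - m) - b_m * m)
    h2 = h + dt * (a_h * (1.0 - h) - b_h * h)
    n2 = n + dt * (a_n * (1.0 - n) - b_n * n)
    # clamp gating to [0, 1]
    m2 = min(max(m2, 0.0), 1.0)
    h2 = min(max(h2, 0.0), 1.0)
    n2 = min(max(n2, 0.0), 1.0)
    return u2, m2, h2, n2


# numba closures cannot see dict items; bind the constants as module globals
HH_G_NA = HH_PARAMS["g_na"]
HH_E_NA = HH_PARAMS["e_na"]
HH_G_K = HH_PARAMS["g_k"]
HH_E_K = HH_PARAMS["e_k"]
HH_G_L = HH_PARAMS["g_l"]
HH_E_L = HH_PARAMS["e_l"]
HH_C_M = HH_PARAMS["c_m"]


def hh_step(state: HHState, i_ext: float, dt: float = 0.01) -> HHState:
    """One forward-Euler update of (V_m, m, h, n).

    Raises an ``ArithmeticError`` with a state snapshot if the integration
    blows up (possible at very large ``dt``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = state.v_m - V_REST
    u2, m2, h2, n2 = _euler_step(u, state.m, state.h, state.n, i_ext, dt)
    if not np.isfinite(u2):
        raise ArithmeticError(f"H-H integration overflow from state {state}")
    return HHState(v_m=u2 + V_REST, m=m2, h=h2, n=n2)


@njit(cache=False)
def _run_kernel(u, m, h, n, i_ext, dt, n_steps, spike_u):
    n_spikes = 0
    above = u >= spike_u
    for _ in range(n_steps):
        u, m, h, n = _euler_step(u, m, h, n, i_ext, dt)
        if u >= spike_u and not above:
            n_spikes += 1
        above = u >= spike_u
    return u, m, h, n, n_spikes


def hh_run(
    state: HHState, i_ext: float, dt: float, n_steps: int
) -> tuple[HHState, int]:
    """Integrate ``n_steps`` Euler steps; return final state and spike count.

    Spikes are upward crossings of V_m = 0 mV.
    """
    u, m, h, n, spikes = _run_kernel(
        state.v_m - V_REST, state.m, state.h, state.n,
        float(i_ext), float(dt), int(n_steps),
        SPIKE_THRESHOLD_MV - V_REST,
    )
    if not np.isfinite(u):
        raise ArithmeticError(f"H-H integration overflow from state {state}")
    return HHState(v_m=u + V_REST, m=m, h=h, n=n), spikes


@njit(cache=False)
def hh_integrate_cells(u, m, h, n, i_ext, active_idx, dt, n_sub, spike_u):
    """Integrate a subset of cells in place; return per-cell spike flags.

    ``u, m, h, n`` are state vectors over the whole population (u is the
    deviation voltage); only indices in ``active_idx`` are advanced, by
    ``n_sub`` Euler sub-steps of size ``dt`` under constant ``i_ext``.
    """
    fired = np.zeros(u.shape[0], dtype=np.bool_)
    for k in range(active_idx.shape[0]):
        j = active_idx[k]
        uj, mj, hj, nj = u[j], m[j], h[j], n[j]
        above = uj >= spike_u
        ij = i_ext[j]
        for _ in range(n_sub):
            uj, mj, hj, nj = _euler_step(uj, mj, hj, nj, ij, dt)
            if uj >= spike_u and not above:
                fired[j] = True
            above = uj >= spike_u
        u[j], m[j], h[j], n[j] = uj, mj, hj, nj
    return fired
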