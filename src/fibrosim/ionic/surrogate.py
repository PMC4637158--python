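"""Two-variable excitable surrogate for fast solver exercises.

A Mitchell–Schaeffer threshold-and-recovery unit rescaled to millivolts
and murine-like time scales (upstroke well under 1 ms, action-potential
duration a few tens of ms).  It shares the reaction interface of the
full ionic model, so every piece of solver plumbing — operator
splitting, stimulus handling, activation mapping, reentry detection —
can be exercised in seconds.  It is a stand-in for speed only; all
electrophysiological quantities quoted for the tissue models come from
the Bondarenko kinetics.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .base import IonicModel

__all__ = ["SurrogateModel"]

# gate dynamics (ms)
TAU_IN = 0.3
TAU_OUT = 4.0
TAU_OPEN = 30.0
TAU_CLOSE = 15.0
V_GATE = 0.22        # dimensionless threshold (see docs/methods.md)
V_REST = -82.0       # mV
V_AMP = 120.0        # mV, rest-to-peak scale


@njit(cache=True)
def _step(V, eta, I_stim, dt, n_sub):
    n = V.shape[0]
    for _ in range(n_sub):
        for i in range(n):
            v = (V[i] - V_REST) / V_AMP
            h = eta[i, 0]
            dv = h * v * v * (1.0 - v) / TAU_IN - v / TAU_OUT
            if v < V_GATE:
                dh = (1.0 - h) / TAU_OPEN
            else:
                dh = -h / TAU_CLOSE
            V[i] += dt * (V_AMP * dv + I_stim[i])
            eta[i, 0] = h + dt * dh


@njit(cache=True)
def _step_rl(V, eta, I_stim, dt, n_sub):
    # Rush–Larsen update of the single recovery gate: exact exponential
    # relaxation toward its voltage-dependent target.
    n = V.shape[0]
    for _ in range(n_sub):
        for i in range(n):
            v = (V[i] - V_REST) / V_AMP
            h = eta[i, 0]
            dv = h * v * v * (1.0 - v) / TAU_IN - v / TAU_OUT
            if v < V_GATE:
                h_inf, tau = 1.0, TAU_OPEN
            else:
                h_inf, tau = 0.0, TAU_CLOSE
            V[i] += dt * (V_AMP * dv + I_stim[i])
            eta[i, 0] = h_inf + (h - h_inf) * np.exp(-dt / tau)


class SurrogateModel(IonicModel):
    """Threshold-recovery membrane unit (1 gate, mV/ms scale)."""

    name = "surrogate"
    n_states = 1
    V_rest = V_REST
    # twice the tissue-level diastolic threshold (~177 pA/pF by
    # bisection on the calibrated homogeneous strip) of a 2 ms
    # edge-band pulse
    default_stim_amplitude = 355.0
    default_stim_duration = 2.0
    quiescence_tol = 1e-9

    def initial_state(self) -> np.ndarray:
        return np.array([1.0])

    def f(self, V, eta):
        V = np.asarray(V, dtype=float)
        v = (V - V_REST) / V_AMP
        h = eta[..., 0]
        dh = np.where(v < V_GATE, (1.0 - h) / TAU_OPEN, -h / TAU_CLOSE)
        return dh[..., None]

    def I_ion(self, V, eta):
        V = np.asarray(V, dtype=float)
        v = (V - V_REST) / V_AMP
        h = eta[..., 0]
        dv = h * v * v * (1.0 - v) / TAU_IN - v / TAU_OUT
        return -V_AMP * dv

    def stepper(self, rush_larsen: bool = False):
        return _step_rl if rush_larsen else _step
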