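"""Membrane-kinetics interface shared by all ionic models.

Unit system: mV, ms, μM; ionic currents are expressed per unit membrane
capacitance (pA/pF), so the reaction update for the transmembrane
voltage is simply ``dV/dt = -I_ion + I_stim`` in mV/ms.

Every model exposes a state vector η (all differential variables except
V), rate functions ``f(V, η)`` and ``I_ion(V, η)``, and a compiled
explicit-Euler stepping kernel used by both tissue solvers.  The kernel
advances all cells of a tissue in lock-step with a fixed ODE substep
``dt_o`` (default 0.0001 ms, the step the Markov-chain kinetics demand
for stability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DT_O_DEFAULT = 1e-4  # ms

__all__ = ["CellState", "IonicModel", "reaction_step", "integrate_reaction", "DT_O_DEFAULT"]


@dataclass
class CellState:
    """Voltage (mV) plus the model state vector η of one cell."""

    V: float
    eta: np.ndarray

    def copy(self) -> "CellState":
        return CellState(float(self.V), self.eta.copy())


class IonicModel:
    """Base class; subclasses fill in the kinetics.

    Attributes
    ----------
    name : str
    n_states : int
        Length of η (V is carried separately).
    V_rest : float
        Resting potential in mV.
    default_stim_amplitude : float
        Depolarizing stimulus (pA/pF) used by the built-in protocols:
        twice the diastolic threshold of a 2 ms pulse.
    default_stim_duration : float
        Stimulus duration in ms.
    """

    name: str = "abstract"
    n_states: int = 0
    V_rest: float = 0.0
    default_stim_amplitude: float = 0.0
    default_stim_duration: float = 2.0
    quiescence_tol: float = 1e-3  # |dV/dt| at rest, mV/ms

    def initial_state(self) -> np.ndarray:
        """η at rest (copy)."""
        raise NotImplementedError

    def initial_cell(self) -> CellState:
        return CellState(self.V_rest, self.initial_state())

    def f(self, V: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """dη/dt for voltages V (n,) and states eta (n, n_states)."""
        raise NotImplementedError

    def I_ion(self, V: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """Total ionic current (pA/pF), vectorized like :meth:`f`."""
        raise NotImplementedError

    def stepper(self, rush_larsen: bool = False):
        """Compiled kernel ``step(V, eta, I_stim, dt_o, n_sub)``.

        Advances arrays in place: ``V`` (n,), ``eta`` (n, n_states),
        ``I_stim`` (n,) held constant over the ``n_sub`` substeps.
        ``rush_larsen=True`` integrates Hodgkin–Huxley-type gates
        exponentially (where the model declares any); the default is the
        plain explicit Euler scheme.
        """
        raise NotImplementedError

    def pack_states(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Rest-state arrays for a tissue of n cells."""
        V = np.full(n, self.V_rest)
        eta = np.tile(self.initial_state(), (n, 1))
        return V, eta


def _check_finite(V: np.ndarray, eta: np.ndarray, model: IonicModel) -> None:
    if not np.isfinite(V).all():
        raise FloatingPointError(f"{model.name}: V became non-finite")
    if not np.isfinite(eta).all():
        bad = np.argwhere(~np.isfinite(eta))
        raise FloatingPointError(
            f"{model.name}: state variable index {int(bad[0, 1])} became non-finite"
        )


def reaction_step(
    model: IonicModel,
    state: CellState,
    I_stim: float = 0.0,
    dt_o: float = DT_O_DEFAULT,
    rush_larsen: bool = False,
) -> CellState:
    """One explicit-Euler update of a single cell."""
    return integrate_reaction(model, state, I_stim, 1, dt_o, rush_larsen=rush_larsen)


def integrate_reaction(
    model: IonicModel,
    state: CellState,
    I_stim: float,
    N_o: int,
    dt_o: float = DT_O_DEFAULT,
    rush_larsen: bool = False,
) -> CellState:
    """N_o successive reaction steps of a single cell."""
    if dt_o <= 0:
        raise ValueError("dt_o must be positive")
    if N_o < 1:
        raise ValueError("N_o must be >= 1")
    V = np.array([state.V], dtype=np.float64)
    eta = state.eta[None, :].astype(np.float64).copy()
    stim = np.array([I_stim], dtype=np.float64)
    model.stepper(rush_larsen=rush_larsen)(V, eta, stim, dt_o, N_o)
    _check_finite(V, eta, model)
    return CellState(float(V[0]), eta[0])
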