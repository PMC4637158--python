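"""Membrane kinetics: surrogate and the Bondarenko mouse ventricular port."""

import numpy as np
import pytest

from fibrosim.ionic import (CellState, reaction_step, integrate_reaction,
                            BondarenkoModel, SurrogateModel, get_model)
from fibrosim.ionic.bondarenko import MARKOV_CHAINS, STATE_NAMES


def test_model_registry():
    assert isinstance(get_model("surrogate"), SurrogateModel)
    assert isinstance(get_model("bondarenko"), BondarenkoModel)
    with pytest.raises(ValueError):
        get_model("hodgkin1952")


def test_surrogate_rest_is_fixed_point(surrogate):
    s = surrogate.initial_cell()
    out = integrate_reaction(surrogate, s, 0.0, 1000, 1e-3)
    assert abs(out.V - surrogate.V_rest) < 1e-9
    assert np.allclose(out.eta, s.eta, atol=1e-12)


def test_surrogate_suprathreshold_upstroke_matches_reference_integrator(surrogate):
    """Explicit-Euler single-cell AP against an adaptive-step oracle."""
    from scipy.integrate import solve_ivp

    amp, dur = 60.0, 2.0

    def rhs(t, y):
        V, h = y
        eta = np.array([[h]])
        dV = -surrogate.I_ion(np.array([V]), eta)[0] + (amp if t < dur else 0.0)
        dh = surrogate.f(np.array([V]), eta)[0, 0]
        return [dV, dh]

    ref = solve_ivp(rhs, (0.0, 5.0), [surrogate.V_rest, 1.0],
                    rtol=1e-9, atol=1e-10, dense_output=True)
    s = surrogate.initial_cell()
    crossed_at = None
    t = 0.0
    for _ in range(50):  # 5 ms in 0.1 ms chunks
        I = amp if t < dur else 0.0
        s = integrate_reaction(surrogate, s, I, 1000, 1e-4)
        t += 0.1
        if crossed_at is None and s.V > 0.0:
            crossed_at = t
        assert abs(s.V - ref.sol(t)[0]) < 1.0  # mV, Euler vs adaptive
    assert crossed_at is not None and crossed_at < 5.0


def test_integrate_reaction_composes_steps(surrogate):
    s = surrogate.initial_cell()
    a = integrate_reaction(surrogate, s, 30.0, 5, 1e-3)
    b = s
    for _ in range(5):
        b = reaction_step(surrogate, b, 30.0, 1e-3)
    assert a.V == pytest.approx(b.V, abs=1e-12)
    assert np.allclose(a.eta, b.eta, atol=1e-12)


def test_integrate_reaction_input_validation(surrogate):
    s = surrogate.initial_cell()
    with pytest.raises(ValueError):
        integrate_reaction(surrogate, s, 0.0, 0)
    with pytest.raises(ValueError):
        integrate_reaction(surrogate, s, 0.0, 1, -1e-4)


def test_nonfinite_state_raises_named_error(surrogate):
    s = surrogate.initial_cell()
    s.eta[0] = np.nan
    with pytest.raises(FloatingPointError):
        reaction_step(surrogate, s, 0.0)


def test_bondarenko_dimensions_and_rest(bondarenko):
    assert bondarenko.n_states == 40            # 41 differential variables with V
    assert len(STATE_NAMES) == 40
    eta = bondarenko.initial_state()
    dV = -bondarenko.I_ion(np.array([bondarenko.V_rest]), eta[None, :])[0]
    assert abs(dV) < bondarenko.quiescence_tol
    assert -90.0 < bondarenko.V_rest < -75.0    # murine resting potential


def test_bondarenko_rest_unchanged_without_stimulus(bondarenko):
    s = bondarenko.initial_cell()
    out = integrate_reaction(bondarenko, s, 0.0, 10000, 1e-4)  # 1 ms
    assert abs(out.V - s.V) < 1e-2
    gates = slice(27, 36)
    assert np.allclose(out.eta[gates], s.eta[gates], atol=1e-6)


def test_bondarenko_murine_ap_morphology(bondarenko):
    """Rapid upstroke, positive overshoot, APD90 well under 100 ms."""
    s = bondarenko.initial_cell()
    dt, chunk = 1e-4, 500  # 0.05 ms resolution
    trace = [s.V]
    for k in range(int(80.0 / (dt * chunk))):
        I = 21.0 if k * dt * chunk < 2.0 else 0.0
        s = integrate_reaction(bondarenko, s, I, chunk, dt)
        trace.append(s.V)
    tr = np.array(trace)
    peak = tr.max()
    assert peak > 0.0
    dvdt_max = np.max(np.diff(tr)) / (dt * chunk)
    assert dvdt_max > 100.0  # mV/ms
    level90 = bondarenko.V_rest + 0.1 * (peak - bondarenko.V_rest)
    below = np.flatnonzero((tr < level90) & (np.arange(tr.size) > tr.argmax()))
    apd90 = below[0] * dt * chunk - 2.0
    assert apd90 < 100.0
    assert abs(tr[-1] - bondarenko.V_rest) < 5.0


def test_bondarenko_markov_chains_stay_physical_over_long_integration(bondarenko):
    """1e5 explicit-Euler steps through an AP: every Markov-chain state
    and its algebraic complement remain occupancies in [0, 1].

    Chain conservation is structural (one state is the complement of
    the others and each transition enters twice with opposite signs);
    what can silently break is positivity, which this guards."""
    s = bondarenko.initial_cell()
    tol = 1e-4
    for k in range(100):  # 100 chunks x 1000 steps = 1e5 steps = 10 ms
        I = 21.0 if k < 20 else 0.0
        s = integrate_reaction(bondarenko, s, I, 1000, 1e-4)
        for name, chain in MARKOV_CHAINS.items():
            occ = s.eta[list(chain["states"])]
            total = occ.sum()
            assert occ.min() > -tol, f"{name}: negative occupancy"
            assert total < 1 + tol, f"{name}: occupancy sum {total}"


def test_bondarenko_markov_f_is_conservative(bondarenko, rng):
    """Occupancy leaves each chain only through its complement state.

    The summed rate of the explicit states must equal the hand-derived
    net flux out of the algebraic complement (which exchanges with a
    known, small set of states) — this catches any transition booked
    with one sign but not the other.  Checked for the RyR and rapid
    delayed-rectifier chains, whose complement kinetics involve one and
    two rates respectively."""
    eta = bondarenko.initial_state()[None, :].copy()
    V = -20.0
    for chain in MARKOV_CHAINS.values():
        idx = list(chain["states"])
        eta[0, idx] = rng.dirichlet(np.ones(len(idx) + 1))[:-1]
    d = bondarenko.f(np.array([V]), eta)[0]

    # RyR: P_C1 exchanges only with P_O1 (Ca-dependent opening)
    Cass = eta[0, 1]
    PO1, PO2, PC2 = eta[0, 7], eta[0, 8], eta[0, 9]
    PC1 = 1.0 - (PO1 + PO2 + PC2)
    flux_ryr = 0.006075 * Cass**4 * PC1 - 0.07125 * PO1
    assert d[[7, 8, 9]].sum() == pytest.approx(flux_ryr, abs=1e-12)

    # Kr: C_K0 exchanges only with C_K1 (voltage-dependent activation)
    CK1, CK2, OK, IK = eta[0, 36:40]
    CK0 = 1.0 - (CK1 + CK2 + OK + IK)
    aa0 = 0.022348 * np.exp(0.01176 * V)
    ba0 = 0.047002 * np.exp(-0.0631 * V)
    flux_kr = aa0 * CK0 - ba0 * CK1
    assert d[36:40].sum() == pytest.approx(flux_kr, abs=1e-12)


def test_no_stimulus_no_activation_both_models(surrogate, bondarenko):
    for model in (surrogate, bondarenko):
        s = model.initial_cell()
        out = integrate_reaction(model, s, 0.0, 5000, 1e-3)  # 5 ms
        assert out.V < -70.0


def test_rush_larsen_variant_tracks_euler(bondarenko):
    s_e = bondarenko.initial_cell()
    s_rl = bondarenko.initial_cell()
    for k in range(20):  # 2 ms stimulated
        s_e = integrate_reaction(bondarenko, s_e, 21.0, 1000, 1e-4)
        s_rl = integrate_reaction(bondarenko, s_rl, 21.0, 1000, 1e-4,
                                  rush_larsen=True)
    assert abs(s_e.V - s_rl.V) < 1.0
    assert np.allclose(s_e.eta[27:36], s_rl.eta[27:36], atol=1e-3)
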