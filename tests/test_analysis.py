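"""Reentry detection, activity classes, CV measurement and percolation."""

import numpy as np
import pytest

from fibrosim.analysis import (ActivityClass, PercolationCurve, classify_activity,
                               conduction_velocity, default_check_time,
                               detect_reentry, percolation_threshold,
                               percolation_curve, side_connectivity, cv_vs_phi,
                               plane_activation_cv)
from fibrosim.fixtures import grid_network, ring_network
from fibrosim.discrete import reduce_to_network, simulate_discrete, network_plane_protocol
from fibrosim.fibrosis import apply_fibrosis_network
from fibrosim.microstructure import tile_template
from fibrosim.monodomain import MonodomainParams, StimulusProtocol


# ---------------------------------------------------------------------------
# activity classification
# ---------------------------------------------------------------------------

def _ap(t0, times, width=15.0):
    """Synthetic AP bump: -82 -> +20 mV over [t0, t0+width]."""
    v = np.full_like(times, -82.0)
    inside = (times >= t0) & (times < t0 + width)
    v[inside] = 20.0
    return v


def test_classify_flat_trace_is_no_activity():
    t = np.arange(0, 100, 0.1)
    cls, stop = classify_activity(np.full_like(t, -82.0), t, 100.0)
    assert cls == ActivityClass.NA and stop is None


def test_classify_single_ap():
    t = np.arange(0, 100, 0.1)
    cls, stop = classify_activity(_ap(5.0, t), t, 100.0)
    assert cls == ActivityClass.A and stop is None


def test_classify_nonsustained_reentry_reports_stop_time():
    t = np.arange(0, 100, 0.1)
    v = np.maximum(_ap(5.0, t), _ap(40.0, t))
    cls, stop = classify_activity(v, t, 100.0)
    assert cls == ActivityClass.NS
    assert stop == pytest.approx(54.9, abs=0.2)


def test_classify_sustained_reentry_active_at_end():
    t = np.arange(0, 100.05, 0.1)
    v = np.maximum(_ap(5.0, t), _ap(90.0, t, width=20.0))
    cls, stop = classify_activity(v, t, 100.0)
    assert cls == ActivityClass.S


def test_ap_counting_hysteresis_ignores_notched_upstroke():
    t = np.arange(0, 30, 0.1)
    v = np.full_like(t, -82.0)
    v[(t >= 5) & (t < 10)] = 0.0
    v[(t >= 10) & (t < 10.5)] = -40.0   # notch above the re-arm level
    v[(t >= 10.5) & (t < 15)] = 10.0
    cls, _ = classify_activity(v, t, 30.0)
    assert cls == ActivityClass.A


# ---------------------------------------------------------------------------
# reentry detection
# ---------------------------------------------------------------------------

def test_default_check_times_for_the_centimetre_tissue():
    assert default_check_time("LP", extent_um=1e4) == pytest.approx(120.0)
    assert default_check_time("TP", extent_um=1e4) == pytest.approx(300.0)
    with pytest.raises(ValueError):
        default_check_time("diagonal")


def test_homogeneous_tissue_shows_no_reentry(surrogate, unit_mesh):
    net = reduce_to_network(tile_template(unit_mesh, 4, 4))
    params = MonodomainParams(dt_o=0.01, dt_p=0.02)
    check = default_check_time("LP", net)
    T = np.ceil(check / params.dt_p) * params.dt_p
    res = simulate_discrete(net, surrogate, params,
                            network_plane_protocol(net, surrogate, "left"), T_end=T)
    assert detect_reentry(res, "LP", check_time=check) is False


def test_circulating_wave_on_ring_is_reentry(surrogate):
    """Anatomical reentry: a unidirectional wave on a closed ring keeps
    re-exciting tissue long after a single passage would have died."""
    n, tail = 128, 12
    net = ring_network(n_cells=n, G_link=0.1)
    V = np.full(n, surrogate.V_rest)
    eta = np.tile(surrogate.initial_state(), (n, 1))
    V[0:3] = 10.0
    eta[0:3, 0] = 0.8                      # excited, excitable head
    V[n - tail:] = -78.0
    eta[n - tail:, 0] = 0.01               # refractory tail blocks retrograde
    params = MonodomainParams(dt_o=0.01)
    res = simulate_discrete(net, surrogate, params, StimulusProtocol(pulses=[]),
                            T_end=160.0, initial_state=(V, eta))
    assert detect_reentry(res, "LP", check_time=150.0) is True
    # necessity: reentry implies some cell fired at least twice
    assert res.tracker.ap_count.max() >= 2


def test_reentry_check_beyond_simulation_errors(surrogate, unit_mesh):
    net = reduce_to_network(tile_template(unit_mesh, 2, 2))
    params = MonodomainParams(dt_o=0.01)
    res = simulate_discrete(net, surrogate, params,
                            network_plane_protocol(net, surrogate, "left"), T_end=10.0)
    with pytest.raises(ValueError):
        detect_reentry(res, "LP", check_time=50.0)


# ---------------------------------------------------------------------------
# conduction velocity
# ---------------------------------------------------------------------------

def test_conduction_velocity_arithmetic():
    act = np.array([1.0, 3.0])
    pos = np.array([[0.0, 0.0], [800.0, 0.0]])
    assert conduction_velocity(act, pos, 0, 1, min_sep_um=500.0) == pytest.approx(400.0)


def test_conduction_velocity_preconditions():
    act = np.array([1.0, np.nan])
    pos = np.array([[0.0, 0.0], [800.0, 0.0]])
    with pytest.raises(ValueError):
        conduction_velocity(act, pos, 0, 1)
    act2 = np.array([1.0, 3.0])
    with pytest.raises(ValueError):
        conduction_velocity(act2, pos, 0, 1, min_sep_um=1000.0)


def test_plane_cv_of_uniform_front():
    x = np.linspace(0, 4000, 400)
    act = x / 400.0  # 400 um/ms front
    assert plane_activation_cv(act, x) == pytest.approx(400.0, rel=0.02)


def test_plane_cv_nan_when_far_plane_never_reached():
    x = np.linspace(0, 4000, 400)
    act = np.where(x < 2000, x / 400.0, np.nan)
    assert np.isnan(plane_activation_cv(act, x))


def test_cv_vs_phi_summarises_and_counts_blocked_runs():
    import pandas as pd

    runs = pd.DataFrame({
        "phi": [0.0, 0.0, 0.4, 0.4, 0.4],
        "cv": [400.0, 400.0, 100.0, 150.0, np.nan],
    })
    out = cv_vs_phi(runs)
    r0 = out[out.phi == 0.0].iloc[0]
    assert r0.cv_mean == 400.0 and r0.cv_sd == 0.0 and r0.n_blocked == 0
    r4 = out[out.phi == 0.4].iloc[0]
    assert r4.n_traversed == 2 and r4.n_blocked == 1
    assert r4.cv_mean == pytest.approx(125.0)


# ---------------------------------------------------------------------------
# percolation
# ---------------------------------------------------------------------------

def test_side_connectivity_trivial_limits():
    g = grid_network(3, 3)
    assert side_connectivity(g, "LP") and side_connectivity(g, "TP")
    removed = np.ones(9, dtype=bool)
    assert not side_connectivity(g, "LP", removed=removed)


def test_side_connectivity_known_cut():
    g = grid_network(3, 3)
    removed = np.zeros(9, dtype=bool)
    removed[[1, 4, 7]] = True  # middle column cuts left-right only
    assert not side_connectivity(g, "LP", removed=removed)
    assert side_connectivity(g, "TP", removed=removed)
    removed2 = np.zeros(9, dtype=bool)
    removed2[[3, 4, 5]] = True  # middle row cuts bottom-top only
    assert side_connectivity(g, "LP", removed=removed2)  # top row still crosses
    assert not side_connectivity(g, "TP", removed=removed2)


def test_side_connectivity_matches_exhaustive_search(rng):
    """Union-find against brute-force path enumeration on a 3x3 grid."""
    from itertools import product

    g = grid_network(3, 3)
    adj = {i: set() for i in range(9)}
    for a, b in g.edges:
        adj[a].add(b)
        adj[b].add(a)

    def brute(removed, src_nodes, dst_nodes):
        alive = [i for i in range(9) if not removed[i]]
        reach = set(s for s in src_nodes if not removed[s])
        frontier = set(reach)
        while frontier:
            nxt = set()
            for u in frontier:
                for v in adj[u]:
                    if not removed[v] and v not in reach:
                        nxt.add(v)
            reach |= nxt
            frontier = nxt
        return any(d in reach for d in dst_nodes if not removed[d])

    for bits in product([False, True], repeat=9):
        removed = np.array(bits)
        expect_lp = brute(removed, [0, 3, 6], [2, 5, 8])
        expect_tp = brute(removed, [0, 1, 2], [6, 7, 8])
        assert side_connectivity(g, "LP", removed=removed) == expect_lp
        assert side_connectivity(g, "TP", removed=removed) == expect_tp


def test_connectivity_is_monotone_under_cell_restoration(rng):
    g = grid_network(4, 4)
    for _ in range(50):
        removed = rng.random(16) < 0.5
        if side_connectivity(g, "LP", removed=removed):
            # restoring any cell must keep it connected
            for c in np.flatnonzero(removed):
                r2 = removed.copy()
                r2[c] = False
                assert side_connectivity(g, "LP", removed=r2)


def test_percolation_threshold_closed_form_line():
    phis = np.linspace(0, 1, 101)
    curve = PercolationCurve(phis, 1 - phis, "LP", 1)
    assert percolation_threshold(curve) == pytest.approx(0.5, abs=1e-12)
    assert percolation_threshold(curve, fit="logistic") == pytest.approx(0.5, abs=0.01)


def test_percolation_threshold_requires_spanning_transition():
    phis = np.linspace(0, 0.2, 5)
    curve = PercolationCurve(phis, np.full(5, 1.0), "LP", 1)
    with pytest.raises(ValueError):
        percolation_threshold(curve)


def test_percolation_curve_extremes_on_small_tissue(unit_mesh):
    net = reduce_to_network(tile_template(unit_mesh, 3, 3))
    curve = percolation_curve(net, [0.0, 1.0], 5, base_seed=0, direction="LP")
    assert curve.C[0] == 1.0 and curve.C[1] == 0.0
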