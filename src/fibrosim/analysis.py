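"""Reentry detection, activity classification, CV and percolation analysis.

Reentry is declared when any part of the tissue is still depolarized
(above the activity threshold, default -60 mV) at a check time chosen
so that a plane wave crossing the most tortuous still-conducting maze
would long have left: the traversal time of the slowest coherent wave
plus a 60 ms margin.  For the 1 cm tissue this gives the canonical
120 ms (longitudinal) and 300 ms (transversal) check times.

Connectivity analysis works on the cell network: a tissue percolates in
a direction when a path of retained gap-junction links joins a retained
cell on the source side to one on the opposite side.  The percolation
threshold φ_c is the 50 % crossing of a straight line fitted to the
transition points of C(φ).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from numba import njit

from .discrete import DiscreteNetwork
from .fibrosis import realization_seed
from .monodomain import SimulationResult, V_ACT_DEFAULT

__all__ = [
    "ActivityClass", "PercolationCurve",
    "default_check_time", "detect_reentry",
    "classify_activity", "classify_run",
    "conduction_velocity", "plane_activation_cv", "ensemble_cv",
    "side_connectivity", "percolation_curve", "percolation_threshold",
    "cv_vs_phi",
]

# Effective traversal speeds of a coherent plane wave at φ = 0.45
# (μm/ms); they reproduce the canonical 60 ms / 240 ms traversals of
# the 1 cm tissue and scale the check time for other tissue sizes.
TRAVERSAL_SPEED = {"LP": 10000.0 / 60.0, "TP": 10000.0 / 240.0}
REENTRY_MARGIN_MS = 60.0


class ActivityClass(Enum):
    NA = "NA"   # no activity
    A = "A"     # a single AP, no reentry
    S = "S"     # sustained reentry: multiple APs, tissue active at T_end
    NS = "NS"   # nonsustained reentry: multiple APs, dies out before T_end


@dataclass
class PercolationCurve:
    phis: np.ndarray
    C: np.ndarray
    direction: str
    n_realizations: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"phi": self.phis, "C": self.C})


# ---------------------------------------------------------------------------
# Reentry and activity classes
# ---------------------------------------------------------------------------

def default_check_time(direction: str, net: DiscreteNetwork | None = None,
                       extent_um: float | None = None) -> float:
    """Traversal time of the slow coherent wave plus a 60 ms margin."""
    if direction not in TRAVERSAL_SPEED:
        raise ValueError("direction must be 'LP' or 'TP'")
    if extent_um is None:
        extent_um = 10000.0 if net is None else net.extent_um[0 if direction == "LP" else 1]
    return extent_um / TRAVERSAL_SPEED[direction] + REENTRY_MARGIN_MS


def detect_reentry(result: SimulationResult, direction: str,
                   check_time: float | None = None) -> bool:
    """Activity anywhere at the check time = a wave re-entered the maze."""
    t = check_time if check_time is not None else default_check_time(direction)
    return result.active_at(t)


def classify_activity(trace: np.ndarray, times: np.ndarray, T_end: float,
                      v_act: float = V_ACT_DEFAULT, ap_up: float = -30.0,
                      ap_rearm: float = -60.0) -> tuple[ActivityClass, float | None]:
    """Classify one voltage trace; returns (class, stop time for NS)."""
    trace = np.asarray(trace, dtype=float)
    armed = True
    count = 0
    for v in trace:
        if armed and v >= ap_up:
            count += 1
            armed = False
        elif not armed and v <= ap_rearm:
            armed = True
    active = trace >= v_act
    last_active = times[active][-1] if active.any() else None
    if count == 0:
        return ActivityClass.NA, None
    if count == 1:
        return ActivityClass.A, None
    if last_active is not None and last_active >= T_end - 1e-9:
        return ActivityClass.S, None
    return ActivityClass.NS, float(last_active) if last_active is not None else None


def classify_run(result: SimulationResult, net: DiscreteNetwork | None = None,
                 weights: np.ndarray | None = None) -> dict:
    """Tissue-level NA/A/S/NS area percentages of one run.

    Per-cell AP counts come from the run's hysteresis counter; cells
    with multiple APs are S when the tissue is still active at T_end
    and NS otherwise (the run's stop time is the last time anything was
    above the activity threshold).  Percentages are area-weighted.
    """
    counts = result.tracker.ap_count
    if weights is None:
        weights = net.area if net is not None else np.ones_like(counts, dtype=float)
    w = weights / weights.sum() * 100.0
    still_active = result.tracker.n_active_series[-1] > 0
    na = float(w[counts == 0].sum())
    a = float(w[counts == 1].sum())
    multi = counts >= 2
    s = float(w[multi].sum()) if still_active else 0.0
    ns = 0.0 if still_active else float(w[multi].sum())
    stop = result.tracker.last_active_time if (ns > 0 or not still_active) else None
    return {"pct_NA": na, "pct_A": a, "pct_S": s, "pct_NS": ns,
            "stop_time": (None if stop in (None, -np.inf) else float(stop))}


# ---------------------------------------------------------------------------
# Conduction velocity
# ---------------------------------------------------------------------------

def conduction_velocity(activation_time: np.ndarray, positions_um: np.ndarray,
                        p1: int, p2: int, min_sep_um: float = 1000.0) -> float:
    """Euclidean probe separation over activation-time difference (μm/ms)."""
    t1, t2 = activation_time[p1], activation_time[p2]
    if np.isnan(t1) or np.isnan(t2):
        raise ValueError("both probes must have activated")
    sep = float(np.linalg.norm(positions_um[p2] - positions_um[p1]))
    if sep < min_sep_um:
        raise ValueError(f"probes only {sep:.0f} μm apart (< {min_sep_um:.0f})")
    dt = abs(t2 - t1)
    if dt <= 0:
        raise ValueError("probes activated simultaneously")
    return sep / dt


def plane_activation_cv(activation_time: np.ndarray, coord_um: np.ndarray,
                        lo_frac: float = 0.2, hi_frac: float = 0.8,
                        band_um: float = 100.0,
                        min_frac: float = 0.05) -> float:
    """Front speed from median activation at two transverse planes.

    Robust against tortuous (maze-like) propagation: the median first
    activation of all units near the 20 % and 80 % planes of the
    propagation axis.  NaN when either plane was not reached.
    """
    c = np.asarray(coord_um, dtype=float)
    span = c.max() - c.min()
    out = []
    for frac in (lo_frac, hi_frac):
        target = c.min() + frac * span
        band = np.abs(c - target) <= band_um
        act = activation_time[band]
        good = act[~np.isnan(act)]
        if band.sum() == 0 or len(good) < min_frac * band.sum() or len(good) == 0:
            return np.nan
        out.append(np.median(good))
    dt = out[1] - out[0]
    if dt <= 0:
        return np.nan
    return float((hi_frac - lo_frac) * span / dt)


def ensemble_cv(result: SimulationResult, net: DiscreteNetwork, direction: str) -> float:
    axis = 0 if direction == "LP" else 1
    return plane_activation_cv(result.activation_map, net.centroid_um[:, axis])


# ---------------------------------------------------------------------------
# Percolation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _percolates_uf(n, ea, eb, removed, src, dst):
    parent = np.arange(n)
    for k in range(ea.size):
        a, b = ea[k], eb[k]
        if removed[a] or removed[b]:
            continue
        ra = a
        while parent[ra] != ra:
            parent[ra] = parent[parent[ra]]
            ra = parent[ra]
        rb = b
        while parent[rb] != rb:
            parent[rb] = parent[parent[rb]]
            rb = parent[rb]
        if ra != rb:
            parent[rb] = ra
    mark = np.zeros(n, dtype=np.uint8)
    for i in range(n):
        if src[i] and not removed[i]:
            r = i
            while parent[r] != r:
                parent[r] = parent[parent[r]]
                r = parent[r]
            mark[r] = 1
    for i in range(n):
        if dst[i] and not removed[i]:
            r = i
            while parent[r] != r:
                parent[r] = parent[parent[r]]
                r = parent[r]
            if mark[r] == 1:
                return True
    return False


def side_connectivity(net: DiscreteNetwork, direction: str,
                      removed: np.ndarray | None = None) -> bool:
    """True iff retained links join the two opposing sides.

    LP connects left to right (along the fibers), TP bottom to top.
    ``removed`` defaults to the network's own fibrosis flags.
    """
    if direction == "LP":
        src, dst = net.touches["left"], net.touches["right"]
    elif direction == "TP":
        src, dst = net.touches["bottom"], net.touches["top"]
    else:
        raise ValueError("direction must be 'LP' or 'TP'")
    if removed is None:
        removed = net.removed if net.removed is not None else np.zeros(net.n_cells, dtype=bool)
    return bool(
        _percolates_uf(net.n_cells, net.edges[:, 0], net.edges[:, 1],
                       np.ascontiguousarray(removed),
                       np.ascontiguousarray(src), np.ascontiguousarray(dst))
    )


def percolation_curve(net: DiscreteNetwork, phis, n_realizations: int,
                      base_seed: int, direction: str) -> PercolationCurve:
    """Topology-only Monte Carlo of the side-to-side connection probability."""
    phis = np.asarray(list(phis), dtype=float)
    C = np.empty(phis.size)
    from .fibrosis import select_removed_cells

    for ip, phi in enumerate(phis):
        hits = 0
        for rep in range(n_realizations):
            seed = realization_seed(base_seed, ip, rep)
            rem_ids = select_removed_cells(net.n_cells, phi, seed)
            removed = np.zeros(net.n_cells, dtype=bool)
            removed[rem_ids] = True
            hits += side_connectivity(net, direction, removed=removed)
        C[ip] = hits / n_realizations
    return PercolationCurve(phis, C, direction, n_realizations)


def percolation_threshold(curve: PercolationCurve, fit: str = "linear",
                          band: tuple[float, float] = (0.1, 0.9)) -> float:
    """φ_c: the 50% crossing of a fit through the transition of C(φ)."""
    C, phis = curve.C, curve.phis
    if C.min() >= 0.5 or C.max() <= 0.5:
        raise ValueError("curve does not span the C = 50% transition")
    sel = (C >= band[0]) & (C <= band[1])
    if sel.sum() < 2:
        # degenerate (very sharp) transition: bracket the crossing instead
        above = np.flatnonzero(C > 0.5)
        i = above[-1] if phis[1] > phis[0] else above[0]
        sel = np.zeros_like(sel)
        sel[max(0, i - 1): i + 2] = True
    if fit == "linear":
        a, b = np.polyfit(phis[sel], C[sel], 1)
        return float((0.5 - b) / a)
    if fit == "logistic":
        from scipy.optimize import curve_fit

        def logi(x, x0, k):
            return 1.0 / (1.0 + np.exp((x - x0) / k))

        p0 = (phis[np.argmin(np.abs(C - 0.5))], 0.02)
        popt, _ = curve_fit(logi, phis, C, p0=p0, maxfev=10000)
        return float(popt[0])
    raise ValueError("fit must be 'linear' or 'logistic'")


def cv_vs_phi(runs: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD conduction velocity per φ over traversing realizations."""
    rows = []
    for phi, grp in runs.groupby("phi"):
        cvs = grp["cv"].to_numpy(dtype=float)
        good = cvs[np.isfinite(cvs)]
        rows.append({
            "phi": phi, "n": len(grp), "n_traversed": len(good),
            "n_blocked": int(len(grp) - len(good)),
            "cv_mean": good.mean() if len(good) else np.nan,
            "cv_sd": good.std() if len(good) else np.nan,
        })
    return pd.DataFrame(rows)
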