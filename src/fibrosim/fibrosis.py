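"""Seeded random microfibrosis realizations and Monte-Carlo ensembles.

Fibrosis is modelled at single-myocyte resolution: a fraction φ of the
cells is drawn uniformly without replacement and every gap junction of
a chosen cell is removed, so no current can enter or leave it.  On the
volume mesh the junction faces become plain membrane; on the cell
network the incident links are deleted (the node is kept, isolated).
Both operators use the same seeded draw, so a mesh and its reduced
network receive identical lesions, and removal commutes with the
network reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .microstructure import FaceType, TissueMesh, GAP_JUNCTION_TYPES
from .discrete import DiscreteNetwork, simulate_discrete, network_plane_protocol
from .monodomain import MonodomainParams
from .ionic.base import IonicModel

__all__ = ["FibrosisRealization", "EnsembleSpec", "select_removed_cells",
           "apply_fibrosis", "apply_fibrosis_mesh", "apply_fibrosis_network",
           "run_ensemble", "wilson_interval"]


@dataclass(frozen=True)
class FibrosisRealization:
    """One seeded lesion pattern at fraction φ."""

    phi: float
    seed: int
    removed_cells: tuple[int, ...]   # sorted cell ids

    @property
    def n_removed(self) -> int:
        return len(self.removed_cells)


def _removal_count(phi: float, n_cells: int) -> int:
    # round half away from zero
    return int(np.floor(phi * n_cells + 0.5))


def select_removed_cells(n_cells: int, phi: float, seed: int) -> np.ndarray:
    """Uniform draw without replacement of round(φN) cells."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = _removal_count(phi, n_cells)
    return np.sort(rng.choice(n_cells, size=k, replace=False))


def apply_fibrosis_mesh(mesh: TissueMesh, phi: float, seed: int) -> tuple[TissueMesh, FibrosisRealization]:
    """Turn the gap-junction faces of the chosen cells into membrane."""
    removed = select_removed_cells(mesh.n_cells, phi, seed)
    is_removed = np.zeros(mesh.n_cells, dtype=bool)
    is_removed[removed] = True

    def strip(face, axis):
        other = np.roll(mesh.cell_id, -1, axis=axis)
        gj = np.isin(face, GAP_JUNCTION_TYPES)
        hit = gj & (is_removed[mesh.cell_id] | is_removed[other])
        out = face.copy()
        out[hit] = FaceType.MEMBRANE
        return out

    new = replace(
        mesh,
        face_e=strip(mesh.face_e, 1),
        face_n=strip(mesh.face_n, 0),
        cell_id=mesh.cell_id.copy(),
    )
    return new, FibrosisRealization(phi, seed, tuple(int(c) for c in removed))


def apply_fibrosis_network(net: DiscreteNetwork, phi: float, seed: int) -> tuple[DiscreteNetwork, FibrosisRealization]:
    """Delete every link incident to the chosen cells (nodes kept)."""
    removed = select_removed_cells(net.n_cells, phi, seed)
    is_removed = np.zeros(net.n_cells, dtype=bool)
    is_removed[removed] = True
    keep = ~(is_removed[net.edges[:, 0]] | is_removed[net.edges[:, 1]])
    new = replace(net, edges=net.edges[keep], G=net.G[keep], removed=is_removed)
    return new, FibrosisRealization(phi, seed, tuple(int(c) for c in removed))


def apply_fibrosis(model_obj, phi: float, seed: int):
    """Dispatch on mesh vs network; identical cell selection for both."""
    if isinstance(model_obj, TissueMesh):
        return apply_fibrosis_mesh(model_obj, phi, seed)
    if isinstance(model_obj, DiscreteNetwork):
        return apply_fibrosis_network(model_obj, phi, seed)
    raise TypeError(f"cannot apply fibrosis to {type(model_obj).__name__}")


# ---------------------------------------------------------------------------
# Monte-Carlo ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleSpec:
    """Grid of fibrosis fractions and seeded repetitions."""

    phis: tuple[float, ...] = tuple(np.round(np.arange(0.40, 0.551, 0.01), 3))
    n_realizations: int = 100
    base_seed: int = 0
    direction: Literal["LP", "TP"] = "LP"
    T_end: float | None = None          # default: traversal-based check time + margin
    check_time: float | None = None     # reentry check; default per direction

    def __post_init__(self) -> None:
        if any(not 0 <= p <= 1 for p in self.phis):
            raise ValueError("phi values must lie in [0, 1]")
        if self.n_realizations < 1:
            raise ValueError("need at least one realization per phi")


def realization_seed(base_seed: int, phi_index: int, rep: int) -> int:
    """Deterministic per-run seed (< 2^31) from the ensemble base seed."""
    ss = np.random.SeedSequence([int(base_seed), int(phi_index), int(rep)])
    return int(ss.generate_state(1)[0] % (2**31))


def wilson_interval(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def run_ensemble(
    spec: EnsembleSpec,
    net: DiscreteNetwork,
    ionic: IonicModel,
    params: MonodomainParams | None = None,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate seeded fibrosis realizations on the discrete network.

    For every (φ, repetition): apply the lesion, stimulate a plane wave
    (left edge for LP, bottom edge for TP), and record the reentry
    outcome — activity at the direction's check time — together with
    the conduction velocity of the traversing wave and the NA/A/S/NS
    activity-class percentages.  Returns (per-run table, per-φ summary
    with Wilson 95% intervals).  Individual run failures are recorded
    and do not stop the ensemble.
    """
    from .analysis import (classify_run, detect_reentry, ensemble_cv,
                           default_check_time)

    params = params or MonodomainParams()
    side = "left" if spec.direction == "LP" else "bottom"
    check = spec.check_time or default_check_time(spec.direction, net)
    T_end = spec.T_end or check
    rows = []
    for ip, phi in enumerate(spec.phis):
        for rep in range(spec.n_realizations):
            seed = realization_seed(spec.base_seed, ip, rep)
            fib, real = apply_fibrosis_network(net, phi, seed)
            row = {"phi": phi, "rep": rep, "seed": seed,
                   "n_removed": real.n_removed}
            try:
                prot = network_plane_protocol(fib, ionic, side)
                res = simulate_discrete(fib, ionic, params, prot, T_end,
                                        stop_when_quiet=20.0)
                row["reentry"] = detect_reentry(res, spec.direction, check_time=check)
                row["cv"] = ensemble_cv(res, fib, spec.direction)
                row["max_ap"] = int(res.tracker.ap_count.max())
                row.update(classify_run(res, fib))
                row["error"] = ""
            except Exception as exc:  # noqa: BLE001 - ensemble must continue
                row.update({"reentry": None, "cv": np.nan, "error": str(exc)})
            rows.append(row)
            if progress:
                print(f"phi={phi:.2f} rep={rep} reentry={row.get('reentry')}")
    runs = pd.DataFrame(rows)
    summ = []
    for phi, grp in runs.groupby("phi"):
        done = grp[grp["error"] == ""]
        k = int(done["reentry"].sum()) if len(done) else 0
        n = len(done)
        lo, hi = wilson_interval(k, n)
        summ.append({"phi": phi, "n": n, "n_reentry": k,
                     "P": k / n if n else np.nan, "CI_low": lo, "CI_high": hi})
    return runs, pd.DataFrame(summ)
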