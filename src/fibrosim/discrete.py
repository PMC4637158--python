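"""Discrete cell-network reduction of the microscopic tissue model.

Each myocyte collapses to one isopotential network node of volume
A_i·d.  For every pair of touching cells the gap junctions along their
shared border combine like resistors: each junction k contributes a
series resistance

    R_ijk = dist_ijk / (σ_c h) + 1 / G_k,

where dist_ijk is the Manhattan volume count from the reference volume
of cell i to the junction volume in cell i plus the same on the j side
(pure index arithmetic — no path search), and the per-junction branches
add in parallel, G_ij = Σ_k 1/R_ijk.  The resulting network obeys the
same split monodomain scheme as the microscopic model with
α_i = β C_m A_i d / Δt_p.

The reference volume pr_i is the cell volume closest to the cell's
centroid (ties broken by lowest (x, y) index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import splu

from .microstructure import FaceType, TissueMesh
from .monodomain import (ActivityTracker, MonodomainParams, SimulationResult,
                         Stimulus, StimulusProtocol, run_split_loop)
from .ionic.base import IonicModel

__all__ = [
    "GapJunctionLink", "LinkTable", "DiscreteNetwork",
    "identify_cell_adjacency", "path_distance", "junction_resistance",
    "equivalent_conductance", "reduce_to_network", "simulate_discrete",
    "network_plane_protocol", "network_point_protocol",
    "save_network_csv", "load_network_csv",
]


@dataclass(frozen=True)
class GapJunctionLink:
    """One gap-junction face between two cells."""

    cell_i: int
    cell_j: int
    gp_i: tuple[int, int]       # junction volume (x, y) in cell i
    gp_j: tuple[int, int]
    ftype: FaceType
    G_k: float                  # μS


@dataclass
class LinkTable:
    """Columnar set of gap-junction links (one row per junction face)."""

    cell_i: np.ndarray
    cell_j: np.ndarray
    gp_i: np.ndarray            # (m, 2) volume indices (x, y), unwrapped frame
    gp_j: np.ndarray
    ftype: np.ndarray
    G_k: np.ndarray

    def __len__(self) -> int:
        return self.cell_i.size

    def __getitem__(self, k: int) -> GapJunctionLink:
        return GapJunctionLink(
            int(self.cell_i[k]), int(self.cell_j[k]),
            (int(self.gp_i[k, 0]), int(self.gp_i[k, 1])),
            (int(self.gp_j[k, 0]), int(self.gp_j[k, 1])),
            FaceType(int(self.ftype[k])), float(self.G_k[k]),
        )

    def ng(self, i: int, j: int) -> int:
        """Number of junction faces between one cell pair."""
        a, b = min(i, j), max(i, j)
        lo = np.minimum(self.cell_i, self.cell_j)
        hi = np.maximum(self.cell_i, self.cell_j)
        return int(np.sum((lo == a) & (hi == b)))


@dataclass
class DiscreteNetwork:
    """One node per myocyte with pairwise equivalent conductances."""

    n_cells: int
    area: np.ndarray            # A_i, μm^2
    pr: np.ndarray              # (n, 2) reference volume (x, y) index
    centroid_um: np.ndarray     # (n, 2) physical centroid
    edges: np.ndarray           # (m, 2) cell pairs, i < j
    G: np.ndarray               # (m,) equivalent conductance, μS
    h: float
    d: float
    extent_um: tuple[float, float]
    touches: dict = field(default_factory=dict)   # side -> bool array per cell
    removed: np.ndarray | None = None             # fibrosis flags

    @property
    def volume(self) -> np.ndarray:
        return self.area * self.d

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_cells)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def neighbor_lists(self) -> list[np.ndarray]:
        nn = [[] for _ in range(self.n_cells)]
        for (a, b) in self.edges:
            nn[a].append(b)
            nn[b].append(a)
        return [np.array(v, dtype=np.int64) for v in nn]


# ---------------------------------------------------------------------------
# Mesh-side helpers
# ---------------------------------------------------------------------------

def _unwrapped_x(mesh: TissueMesh) -> np.ndarray:
    """Per-volume x index, unwrapped for cells crossing a periodic seam.

    Only the standalone template unit contains such cells; volumes in
    the wrapped head of a cell (columns < its seam gap) are shifted by
    +nx so that Manhattan distances inside the cell are physical.
    """
    ny, nx = mesh.ny, mesh.nx
    jj, ii = np.mgrid[0:ny, 0:nx]
    x = ii.astype(np.int64).copy()
    if not mesh.periodic:
        return x
    cid = mesh.cell_id
    for c in np.unique(cid[:, [0, nx - 1]]):
        cols = np.unique(ii[cid == c])
        if cols.size == nx or cols[0] != 0 or cols[-1] != nx - 1:
            continue
        gaps = np.diff(cols)
        if gaps.max() <= 1:
            continue  # touches both edges but contiguous: spans everything
        split = cols[np.argmax(gaps)]  # last column before the gap
        sel = (cid == c) & (ii <= split)
        x[sel] += nx
    return x


def identify_cell_adjacency(mesh: TissueMesh, wrap: bool = False) -> LinkTable:
    """One link per gap-junction face of the mesh.

    By default the outer boundary is a physical no-flux edge and the
    stored wrap-around faces are ignored.  ``wrap=True`` includes them,
    which treats the mesh as a torus — the semantics under which the
    template unit reproduces the statistics of the infinite tiling.
    """
    cid = mesh.cell_id
    xu = _unwrapped_x(mesh)
    ny, nx = mesh.ny, mesh.nx
    jj = np.mgrid[0:ny, 0:nx][0]

    parts = []
    for face, axis in ((mesh.face_e, 1), (mesh.face_n, 0)):
        cid_b = np.roll(cid, -1, axis=axis)
        x_b = np.roll(xu, -1, axis=axis)
        j_b = np.roll(jj, -1, axis=axis)
        x_a = xu.copy()
        if axis == 1:
            # east neighbour of the last column lives one period to the right
            x_b = x_b.copy()
            x_b[:, nx - 1] += nx
        sel = face >= FaceType.PLICATE
        if not (wrap and mesh.periodic):
            sel = sel.copy()
            if axis == 1:
                sel[:, nx - 1] = False
            else:
                sel[ny - 1, :] = False
        parts.append((
            cid[sel], cid_b[sel],
            np.stack([x_a[sel], jj[sel]], axis=1),
            np.stack([x_b[sel], j_b[sel]], axis=1),
            face[sel],
        ))
    cell_i = np.concatenate([p[0] for p in parts])
    cell_j = np.concatenate([p[1] for p in parts])
    gp_i = np.concatenate([p[2] for p in parts])
    gp_j = np.concatenate([p[3] for p in parts])
    ftype = np.concatenate([p[4] for p in parts])
    t = mesh.conductances
    gk_lut = np.array([0.0, 0.0, t.G_p, t.G_i, t.G_c])
    return LinkTable(cell_i, cell_j, gp_i, gp_j, ftype, gk_lut[ftype.astype(np.int64)])


# ---------------------------------------------------------------------------
# Reduction arithmetic
# ---------------------------------------------------------------------------

def path_distance(pr_i, gp_ik, pr_j, gp_jk) -> int:
    """Manhattan volume count crossed on both sides of a junction."""
    return (
        abs(pr_i[0] - gp_ik[0]) + abs(pr_i[1] - gp_ik[1])
        + abs(pr_j[0] - gp_jk[0]) + abs(pr_j[1] - gp_jk[1])
    )


def junction_resistance(dist: float, G_k: float, sigma_c: float, h: float) -> float:
    """Series sum of the cytoplasmic path and the junction itself (μS⁻¹)."""
    if G_k <= 0:
        raise ValueError("junction with zero conductance must be removed upstream")
    if sigma_c <= 0 or h <= 0:
        raise ValueError("sigma_c and h must be positive")
    if dist < 0:
        raise ValueError("dist must be nonnegative")
    return dist / (sigma_c * h) + 1.0 / G_k


def equivalent_conductance(resistances) -> float:
    """Parallel combination 1/R_ij = Σ_k 1/R_ijk (μS)."""
    r = np.asarray(resistances, dtype=float)
    if r.size == 0:
        raise ValueError("cell pair has no junctions")
    return float(np.sum(1.0 / r))


# ---------------------------------------------------------------------------
# Full reduction
# ---------------------------------------------------------------------------

def _cell_geometry(mesh: TissueMesh):
    """Areas, reference volumes and centroids of every cell."""
    cid = mesh.cell_id.ravel()
    xu = _unwrapped_x(mesh).ravel()
    yy = np.mgrid[0 : mesh.ny, 0 : mesh.nx][0].ravel()
    n = mesh.n_cells

    counts = np.bincount(cid, minlength=n)
    sx = np.bincount(cid, weights=xu, minlength=n)
    sy = np.bincount(cid, weights=yy, minlength=n)
    cx, cy = sx / counts, sy / counts

    # reference volume: closest to centroid; ties -> lowest (x, y)
    d2 = (xu - cx[cid]) ** 2 + (yy - cy[cid]) ** 2
    order = np.lexsort((yy, xu, d2, cid))
    cid_sorted = cid[order]
    first = np.searchsorted(cid_sorted, np.arange(n))
    pick = order[first]
    pr = np.stack([xu[pick], yy[pick]], axis=1).astype(np.int64)

    area = counts * mesh.h * mesh.h
    centroid = np.stack([(cx + 0.5) * mesh.h, (cy + 0.5) * mesh.h], axis=1)
    return area, pr, centroid


def reduce_to_network(mesh: TissueMesh, audit: bool = False, wrap: bool = False) -> DiscreteNetwork:
    """Collapse a mesh to its equivalent one-node-per-myocyte network."""
    mesh.validate()
    links = identify_cell_adjacency(mesh, wrap=wrap)
    area, pr, centroid = _cell_geometry(mesh)
    t = mesh.conductances

    pr_i = pr[links.cell_i]
    pr_j = pr[links.cell_j]
    dist = (
        np.abs(pr_i[:, 0] - links.gp_i[:, 0]) + np.abs(pr_i[:, 1] - links.gp_i[:, 1])
        + np.abs(pr_j[:, 0] - links.gp_j[:, 0]) + np.abs(pr_j[:, 1] - links.gp_j[:, 1])
    )
    R = dist / (t.sigma_c * mesh.h) + 1.0 / links.G_k

    lo = np.minimum(links.cell_i, links.cell_j)
    hi = np.maximum(links.cell_i, links.cell_j)
    pair_key = lo.astype(np.int64) * mesh.n_cells + hi
    uniq, inv = np.unique(pair_key, return_inverse=True)
    Gsum = np.zeros(uniq.size)
    np.add.at(Gsum, inv, 1.0 / R)
    edges = np.stack([uniq // mesh.n_cells, uniq % mesh.n_cells], axis=1)

    touches = {
        "left": np.zeros(mesh.n_cells, dtype=bool),
        "right": np.zeros(mesh.n_cells, dtype=bool),
        "bottom": np.zeros(mesh.n_cells, dtype=bool),
        "top": np.zeros(mesh.n_cells, dtype=bool),
    }
    touches["left"][np.unique(mesh.cell_id[:, 0])] = True
    touches["right"][np.unique(mesh.cell_id[:, -1])] = True
    touches["bottom"][np.unique(mesh.cell_id[0, :])] = True
    touches["top"][np.unique(mesh.cell_id[-1, :])] = True

    net = DiscreteNetwork(
        n_cells=mesh.n_cells, area=area, pr=pr, centroid_um=centroid,
        edges=edges.astype(np.int64), G=Gsum, h=mesh.h, d=mesh.d,
        extent_um=mesh.extent_um, touches=touches,
    )
    if audit:
        net.audit = {"links": links, "dist": dist, "R": R}  # type: ignore[attr-defined]
    return net


# ---------------------------------------------------------------------------
# Stimulus presets on the network
# ---------------------------------------------------------------------------

def network_plane_protocol(net: DiscreteNetwork, model: IonicModel,
                           side: str = "left", start: float = 0.0,
                           duration: float | None = None,
                           amplitude: float | None = None,
                           depth_um: float | None = None) -> StimulusProtocol:
    """Stimulate the cells touching one tissue edge.

    ``depth_um`` widens the electrode to every cell whose centroid lies
    within that distance of the edge — needed for cross-fiber waves,
    where a single narrow cell row cannot source enough charge against
    the lateral load at physiological current densities.
    """
    if side not in net.touches:
        raise ValueError(f"unknown side {side!r}")
    # removed (isolated) cells under the electrode are stimulated too:
    # they fire alone and cannot propagate
    mask = net.touches[side].copy()
    if depth_um is not None:
        w, hgt = net.extent_um
        c = net.centroid_um
        if side == "left":
            mask |= c[:, 0] <= depth_um
        elif side == "right":
            mask |= c[:, 0] >= w - depth_um
        elif side == "bottom":
            mask |= c[:, 1] <= depth_um
        else:
            mask |= c[:, 1] >= hgt - depth_um
    return StimulusProtocol(
        pulses=[Stimulus(mask, start, duration or model.default_stim_duration,
                         amplitude or model.default_stim_amplitude)],
        name=f"{side}_edge_plane",
    )


def network_point_protocol(net: DiscreteNetwork, model: IonicModel,
                           radius_um: float = 150.0, start: float = 0.0,
                           duration: float | None = None,
                           amplitude: float | None = None) -> StimulusProtocol:
    cx, cy = net.extent_um[0] / 2, net.extent_um[1] / 2
    mask = ((net.centroid_um[:, 0] - cx) ** 2 + (net.centroid_um[:, 1] - cy) ** 2
            <= radius_um**2)
    return StimulusProtocol(
        pulses=[Stimulus(mask, start, duration or model.default_stim_duration,
                         amplitude or model.default_stim_amplitude)],
        name="center_point",
    )


# ---------------------------------------------------------------------------
# Time integration on the network
# ---------------------------------------------------------------------------

@dataclass
class NetworkDiffusionSystem:
    matrix: csr_matrix
    alpha: np.ndarray
    _lu: object = None

    def solve(self, V_star: np.ndarray) -> np.ndarray:
        if self._lu is None:
            self._lu = splu(self.matrix.tocsc())
        out = self._lu.solve(self.alpha * V_star)
        if not np.isfinite(out).all():
            raise FloatingPointError("network diffusion solve produced non-finite values")
        return out


def assemble_network_system(net: DiscreteNetwork, params: MonodomainParams) -> NetworkDiffusionSystem:
    """Implicit system (α_i + Σ_j G_ij) V_i − Σ_j G_ij V_j = α_i V_i*."""
    if (net.G < 0).any():
        raise ValueError("negative equivalent conductance")
    n = net.n_cells
    alpha = params.beta * params.C_m * net.area * net.d / params.dt_p
    a, b = net.edges[:, 0], net.edges[:, 1]
    diag = alpha.copy()
    np.add.at(diag, a, net.G)
    np.add.at(diag, b, net.G)
    rows = np.concatenate([a, b, np.arange(n)])
    cols = np.concatenate([b, a, np.arange(n)])
    vals = np.concatenate([-net.G, -net.G, diag])
    return NetworkDiffusionSystem(
        matrix=csr_matrix((vals, (rows, cols)), shape=(n, n)), alpha=alpha
    )


def default_network_probes(net: DiscreteNetwork, n: int = 5) -> np.ndarray:
    """Probes along the mid-height fiber line of the network."""
    w, hgt = net.extent_um
    ys = net.centroid_um[:, 1]
    band = np.abs(ys - hgt / 2) < hgt * 0.1 + 20.0
    cand = np.flatnonzero(band)
    xs = np.linspace(w * 0.1, w * 0.9, n)
    picks = [cand[np.argmin(np.abs(net.centroid_um[cand, 0] - x))] for x in xs]
    return np.array(sorted(set(picks)), dtype=np.int64)


def simulate_discrete(
    net: DiscreteNetwork,
    ionic: IonicModel,
    params: MonodomainParams,
    protocol: StimulusProtocol,
    T_end: float,
    probes: np.ndarray | None = None,
    snapshot_every: float | None = None,
    rush_larsen: bool = False,
    v_act: float | None = None,
    initial_state: tuple[np.ndarray, np.ndarray] | None = None,
    stop_when_quiet: float | None = None,
) -> SimulationResult:
    """Godunov-split monodomain run on the cell network.

    ``initial_state`` optionally replaces the rest state with explicit
    (V, eta) arrays — e.g. a manufactured unidirectional wavefront.
    """
    system = assemble_network_system(net, params)
    if initial_state is not None:
        V = np.array(initial_state[0], dtype=float)
        eta = np.array(initial_state[1], dtype=float)
    else:
        V, eta = ionic.pack_states(net.n_cells)
    tracker = ActivityTracker(net.n_cells, **({"v_act": v_act} if v_act is not None else {}))
    if probes is None:
        probes = default_network_probes(net)
    return run_split_loop(
        V, eta, ionic.stepper(rush_larsen=rush_larsen), system.solve,
        params, protocol, T_end, probes, tracker,
        snapshot_every=snapshot_every,
        stop_when_quiet=stop_when_quiet,
        metadata={
            "model": "discrete",
            "ionic": ionic.name,
            "n_cells": net.n_cells,
            "params": params,
            "protocol": protocol.name,
        },
    )


# ---------------------------------------------------------------------------
# Serialization: edge list + node table
# ---------------------------------------------------------------------------

def save_network_csv(net: DiscreteNetwork, edges_path: str, nodes_path: str) -> None:
    import pandas as pd

    pd.DataFrame({
        "cell_id_i": net.edges[:, 0], "cell_id_j": net.edges[:, 1],
        "G_ij_uS": net.G,
    }).to_csv(edges_path, index=False)
    pd.DataFrame({
        "cell_id": np.arange(net.n_cells),
        "A_um2": net.area,
        "pr_x": net.pr[:, 0], "pr_y": net.pr[:, 1],
        "x_um": net.centroid_um[:, 0], "y_um": net.centroid_um[:, 1],
    }).to_csv(nodes_path, index=False)


def load_network_csv(edges_path: str, nodes_path: str, h: float = 8.0,
                     d: float = 10.0) -> DiscreteNetwork:
    import pandas as pd

    e = pd.read_csv(edges_path)
    nd = pd.read_csv(nodes_path)
    return DiscreteNetwork(
        n_cells=len(nd),
        area=nd["A_um2"].to_numpy(float),
        pr=nd[["pr_x", "pr_y"]].to_numpy(np.int64),
        centroid_um=nd[["x_um", "y_um"]].to_numpy(float),
        edges=e[["cell_id_i", "cell_id_j"]].to_numpy(np.int64),
        G=e["G_ij_uS"].to_numpy(float),
        h=h, d=d,
        extent_um=(float(nd["x_um"].max()), float(nd["y_um"].max())),
    )
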