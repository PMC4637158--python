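"""Microscopic monodomain solver on the volume-resolved tissue mesh.

Finite-volume discretization on the uniform 8 μm grid: the flux through
each interior face is the face transmission coefficient (conductivity,
or gap-junction conductance divided by depth) times the voltage jump;
boundary faces carry no flux.  Each macro step solves the reaction ODEs
per volume (explicit Euler, N_o substeps) and then one implicit-Euler
diffusion step with the constant, symmetric, weakly diagonally dominant
system

    (α + Σ_f σ_f) V_i - Σ_f σ_f V_j = α V_i*,   α = β C_m h² / Δt_p,

whose sparse factorization is computed once and reused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import splu

from .microstructure import TissueMesh, face_coefficients
from .monodomain import (ActivityTracker, MonodomainParams, SimulationResult,
                         Stimulus, StimulusProtocol, run_split_loop)
from .ionic.base import IonicModel

__all__ = ["DiffusionSystem", "assemble_diffusion_system", "diffusion_step",
           "simulate_microscopic", "mesh_plane_protocol", "mesh_point_protocol",
           "mesh_s1s2_protocol"]


@dataclass
class DiffusionSystem:
    """Implicit-Euler diffusion operator of one mesh (factorized lazily)."""

    matrix: csr_matrix
    alpha: float
    n: int
    shape: tuple[int, int]      # (ny, nx)
    _lu: object = None

    def solve(self, V_star: np.ndarray) -> np.ndarray:
        if self._lu is None:
            self._lu = splu(self.matrix.tocsc())
        out = self._lu.solve(self.alpha * V_star)
        if not np.isfinite(out).all():
            raise FloatingPointError("implicit diffusion solve produced non-finite values")
        return out


def assemble_diffusion_system(mesh: TissueMesh, params: MonodomainParams) -> DiffusionSystem:
    """Build the sparse implicit-Euler system for one mesh.

    Rows sum to α for interior and boundary volumes alike (the Laplacian
    part has zero row sums: omitted boundary faces are the no-flux
    condition).
    """
    coefs = face_coefficients(mesh.conductances, mesh.d)
    if (coefs < 0).any():
        raise ValueError("negative face transmission coefficient")
    ny, nx = mesh.ny, mesh.nx
    n = nx * ny
    idx = np.arange(n).reshape(ny, nx)

    rows, cols, vals = [], [], []
    diag = np.full(n, params.alpha(mesh.h))

    ce = coefs[mesh.face_e[:, : nx - 1].astype(np.int64)]
    a = idx[:, : nx - 1].ravel()
    b = idx[:, 1:].ravel()
    ce = ce.ravel()
    nz = ce > 0
    rows += [a[nz], b[nz]]
    cols += [b[nz], a[nz]]
    vals += [-ce[nz], -ce[nz]]
    np.add.at(diag, a[nz], ce[nz])
    np.add.at(diag, b[nz], ce[nz])

    cn = coefs[mesh.face_n[: ny - 1, :].astype(np.int64)]
    a = idx[: ny - 1, :].ravel()
    b = idx[1:, :].ravel()
    cn = cn.ravel()
    nz = cn > 0
    rows += [a[nz], b[nz]]
    cols += [b[nz], a[nz]]
    vals += [-cn[nz], -cn[nz]]
    np.add.at(diag, a[nz], cn[nz])
    np.add.at(diag, b[nz], cn[nz])

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    mat = csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return DiffusionSystem(matrix=mat, alpha=params.alpha(mesh.h), n=n, shape=(ny, nx))


def diffusion_step(system: DiffusionSystem, V_star: np.ndarray) -> np.ndarray:
    """One implicit-Euler diffusion update (uniform fields are fixed points)."""
    return system.solve(np.asarray(V_star, dtype=float).ravel()).reshape(V_star.shape)


# ---------------------------------------------------------------------------
# Stimulus presets on the mesh
# ---------------------------------------------------------------------------

def _volume_centers(mesh: TissueMesh) -> tuple[np.ndarray, np.ndarray]:
    jj, ii = np.mgrid[0 : mesh.ny, 0 : mesh.nx]
    return (ii.ravel() + 0.5) * mesh.h, (jj.ravel() + 0.5) * mesh.h


def mesh_plane_protocol(
    mesh: TissueMesh,
    model: IonicModel,
    side: str = "left",
    depth_volumes: int = 2,
    start: float = 0.0,
    duration: float | None = None,
    amplitude: float | None = None,
) -> StimulusProtocol:
    """Plane-wave stimulus: a 2-volume-deep band along one tissue edge."""
    jj, ii = np.mgrid[0 : mesh.ny, 0 : mesh.nx]
    if side == "left":
        mask = ii < depth_volumes
    elif side == "right":
        mask = ii >= mesh.nx - depth_volumes
    elif side == "bottom":
        mask = jj < depth_volumes
    elif side == "top":
        mask = jj >= mesh.ny - depth_volumes
    else:
        raise ValueError(f"unknown side {side!r}")
    return StimulusProtocol(
        pulses=[Stimulus(mask.ravel(), start,
                         duration or model.default_stim_duration,
                         amplitude or model.default_stim_amplitude)],
        name=f"{side}_edge_plane",
    )


def mesh_point_protocol(mesh: TissueMesh, model: IonicModel,
                        radius_um: float = 100.0, start: float = 0.0,
                        duration: float | None = None,
                        amplitude: float | None = None) -> StimulusProtocol:
    """Central point stimulus (disc of the given radius)."""
    x, y = _volume_centers(mesh)
    cx, cy = mesh.nx * mesh.h / 2, mesh.ny * mesh.h / 2
    mask = (x - cx) ** 2 + (y - cy) ** 2 <= radius_um**2
    return StimulusProtocol(
        pulses=[Stimulus(mask, start, duration or model.default_stim_duration,
                         amplitude or model.default_stim_amplitude)],
        name="center_point",
    )


def mesh_s1s2_protocol(mesh: TissueMesh, model: IonicModel, s2_delay: float,
                       duration: float | None = None,
                       amplitude: float | None = None) -> StimulusProtocol:
    """Cross-field S1-S2: left-edge plane followed by a lower-left quadrant S2."""
    jj, ii = np.mgrid[0 : mesh.ny, 0 : mesh.nx]
    s1 = (ii < 16).ravel()
    s2 = ((ii < mesh.nx // 2) & (jj < mesh.ny // 2)).ravel()
    dur = duration or model.default_stim_duration
    amp = amplitude or model.default_stim_amplitude
    return StimulusProtocol(
        pulses=[Stimulus(s1, 0.0, dur, amp), Stimulus(s2, s2_delay, dur, amp)],
        name="s1s2_crossfield",
    )


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------

def default_mesh_probes(mesh: TissueMesh, n: int = 5) -> np.ndarray:
    """Probes spaced along the mid-height fiber line."""
    j = mesh.ny // 2
    ii = np.linspace(mesh.nx * 0.1, mesh.nx * 0.9, n).astype(int)
    return (j * mesh.nx + ii).astype(np.int64)


def simulate_microscopic(
    mesh: TissueMesh,
    ionic: IonicModel,
    params: MonodomainParams,
    protocol: StimulusProtocol,
    T_end: float,
    probes: np.ndarray | None = None,
    snapshot_every: float | None = None,
    rush_larsen: bool = False,
    v_act: float | None = None,
) -> SimulationResult:
    """Godunov-split monodomain run on the volume mesh."""
    mesh.validate()
    system = assemble_diffusion_system(mesh, params)
    V, eta = ionic.pack_states(system.n)
    tracker = ActivityTracker(system.n, **({"v_act": v_act} if v_act is not None else {}))
    if probes is None:
        probes = default_mesh_probes(mesh)
    return run_split_loop(
        V, eta, ionic.stepper(rush_larsen=rush_larsen), system.solve,
        params, protocol, T_end, probes, tracker,
        snapshot_every=snapshot_every,
        metadata={
            "model": "microscopic",
            "ionic": ionic.name,
            "mesh_shape": (mesh.ny, mesh.nx),
            "params": params,
            "protocol": protocol.name,
        },
    )
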