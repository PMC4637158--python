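"""Hand-checkable toy meshes and networks for oracle tests and demos.

Everything here is small enough to verify by explicit arithmetic or
exhaustive enumeration: two-cell meshes with a known junction layout,
a ring network that sustains an anatomical reentry, and tiny lattice
networks for connectivity checks.
"""

from __future__ import annotations

import numpy as np

from .microstructure import ConductanceTable, FaceType, TissueMesh
from .discrete import DiscreteNetwork

__all__ = ["two_cell_mesh", "ring_network", "grid_network", "uniform_field_mesh"]


def two_cell_mesh(n_junctions: int = 1, width: int = 2, length: int = 3,
                  ftype: FaceType = FaceType.PLICATE) -> TissueMesh:
    """Two rectangular cells abutting end to end.

    ``n_junctions`` of the ``width`` abutment faces carry a junction of
    the requested type (lowest rows first); the rest are membrane.
    """
    if not 1 <= n_junctions <= width:
        raise ValueError("n_junctions must be in [1, width]")
    nx, ny = 2 * length, width
    cell_id = np.zeros((ny, nx), dtype=np.int32)
    cell_id[:, length:] = 1
    face_e = np.full((ny, nx), FaceType.CYTOPLASM, dtype=np.uint8)
    face_e[:, length - 1] = FaceType.MEMBRANE
    face_e[:n_junctions, length - 1] = ftype
    face_e[:, nx - 1] = FaceType.MEMBRANE
    face_n = np.full((ny, nx), FaceType.CYTOPLASM, dtype=np.uint8)
    face_n[ny - 1, :] = FaceType.MEMBRANE
    return TissueMesh(nx=nx, ny=ny, h=8.0, d=10.0, cell_id=cell_id,
                      face_e=face_e, face_n=face_n, periodic=False)


def uniform_field_mesh(nx: int = 5, ny: int = 5, V: float = -82.0) -> tuple[TissueMesh, np.ndarray]:
    """Single-cell mesh plus a uniform voltage field (conservation toy)."""
    cell_id = np.zeros((ny, nx), dtype=np.int32)
    face_e = np.full((ny, nx), FaceType.CYTOPLASM, dtype=np.uint8)
    face_n = np.full((ny, nx), FaceType.CYTOPLASM, dtype=np.uint8)
    face_e[:, nx - 1] = FaceType.MEMBRANE
    face_n[ny - 1, :] = FaceType.MEMBRANE
    mesh = TissueMesh(nx=nx, ny=ny, h=8.0, d=10.0, cell_id=cell_id,
                      face_e=face_e, face_n=face_n, periodic=False)
    return mesh, np.full(nx * ny, V)


def ring_network(n_cells: int = 24, G_link: float = 0.05,
                 cell_area: float = 1920.0, d: float = 10.0) -> DiscreteNetwork:
    """Closed ring of identical cells — the anatomical reentry circuit.

    With a sufficiently slow circuit (small ``G_link``, many cells) a
    unidirectionally launched wave returns after the refractory period
    and circulates indefinitely.
    """
    edges = np.array([[i, (i + 1) % n_cells] for i in range(n_cells)], dtype=np.int64)
    edges = np.sort(edges, axis=1)
    theta = 2 * np.pi * np.arange(n_cells) / n_cells
    r = n_cells * 120.0 / (2 * np.pi)
    centroid = np.stack([r * np.cos(theta) + r, r * np.sin(theta) + r], axis=1)
    return DiscreteNetwork(
        n_cells=n_cells,
        area=np.full(n_cells, cell_area),
        pr=np.zeros((n_cells, 2), dtype=np.int64),
        centroid_um=centroid,
        edges=edges,
        G=np.full(n_cells, G_link),
        h=8.0, d=d,
        extent_um=(2 * r, 2 * r),
        touches={k: np.zeros(n_cells, dtype=bool) for k in ("left", "right", "bottom", "top")},
    )


def grid_network(nx: int = 3, ny: int = 3, G: float = 0.1,
                 spacing_um: float = 100.0) -> DiscreteNetwork:
    """Rectangular lattice network for connectivity toys."""
    n = nx * ny
    idx = np.arange(n).reshape(ny, nx)
    edges = []
    for j in range(ny):
        for i in range(nx):
            if i + 1 < nx:
                edges.append((idx[j, i], idx[j, i + 1]))
            if j + 1 < ny:
                edges.append((idx[j, i], idx[j + 1, i]))
    edges = np.array(edges, dtype=np.int64)
    jj, ii = np.mgrid[0:ny, 0:nx]
    centroid = np.stack([(ii.ravel() + 0.5) * spacing_um, (jj.ravel() + 0.5) * spacing_um], axis=1)
    touches = {
        "left": (ii.ravel() == 0), "right": (ii.ravel() == nx - 1),
        "bottom": (jj.ravel() == 0), "top": (jj.ravel() == ny - 1),
    }
    return DiscreteNetwork(
        n_cells=n, area=np.full(n, 1920.0),
        pr=np.zeros((n, 2), dtype=np.int64),
        centroid_um=centroid, edges=edges, G=np.full(len(edges), G),
        h=8.0, d=10.0, extent_um=(nx * spacing_um, ny * spacing_um),
        touches=touches,
    )
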