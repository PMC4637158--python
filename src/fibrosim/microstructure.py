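"""Myocyte-resolved microstructure of two-dimensional cardiac tissue.

The tissue is a uniform grid of 8 μm × 8 μm finite volumes (depth 10 μm).
Every interior face between two volumes carries one of five connection
types: cytoplasm (both volumes inside the same myocyte), membrane (no
flux), or one of three gap-junction flavours — plicate junctions at
longitudinal end-to-end abutments, interplicate junctions at stepped
contacts near the longitudinal ends of a cell, and combined plicate
junctions along the lateral (side-to-side) membrane.

The basic building block is a frozen, tileable unit of 32 myocytes
arranged as a staggered brick wall of eight horizontal strips.  Cell
lengths and widths were drawn once to match murine morphometry (mean
length ≈ 121 μm, mean width ≈ 18 μm, on average six neighbouring
myocytes per cell) and are kept as versioned constants, so every mesh
built from the unit is reproducible.  Strips are circular in x: a cell
may wrap around the unit's vertical edges, which is what makes the unit
tile seamlessly.  Wrapping cells are treated with torus semantics inside
a single unit and are merged across copy seams when the unit is tiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "FaceType",
    "ConductanceTable",
    "TemplateSpec",
    "TissueMesh",
    "CellStats",
    "build_template",
    "tile_template",
    "tile_to_extent",
    "cell_geometry_stats",
    "face_coefficient",
    "face_coefficients",
    "save_mesh_h5",
    "load_mesh_h5",
    "export_vtk",
]


class FaceType(IntEnum):
    """Connection type carried by one interior face of the volume grid."""

    MEMBRANE = 0
    CYTOPLASM = 1
    PLICATE = 2
    INTERPLICATE = 3
    COMBINED_PLICATE = 4


GAP_JUNCTION_TYPES = (FaceType.PLICATE, FaceType.INTERPLICATE, FaceType.COMBINED_PLICATE)


@dataclass(frozen=True)
class ConductanceTable:
    """Conductivities (μS/μm) and gap-junction conductances (μS).

    ``sigma_m`` is the impermeable membrane, ``sigma_c`` the cytoplasm
    conductivity; ``G_p``, ``G_i``, ``G_c`` are the plicate, interplicate
    and combined-plicate junction conductances.
    """

    sigma_m: float = 0.0
    sigma_c: float = 0.4
    G_p: float = 0.5
    G_i: float = 0.33
    G_c: float = 0.062

    def __post_init__(self) -> None:
        if self.sigma_m != 0.0:
            raise ValueError("membrane conductivity must be exactly zero")
        for name in ("sigma_c", "G_p", "G_i", "G_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TemplateSpec:
    """Target statistics and grid constants of the 32-cell basic unit."""

    h: float = 8.0              # volume edge, μm
    d: float = 10.0             # tissue depth, μm
    n_cells: int = 32
    target_mean_length: float = 120.9   # μm
    target_sd_length: float = 27.8      # μm
    target_mean_width: float = 18.3     # μm
    target_sd_width: float = 3.5        # μm
    target_mean_neighbors: float = 6.0
    rng_seed: int = 0           # kept for interface stability; the unit is frozen

    def __post_init__(self) -> None:
        if self.h <= 0 or self.d <= 0:
            raise ValueError("h and d must be positive")
        if self.n_cells != 32:
            raise ValueError("the basic unit is defined for exactly 32 myocytes")


@dataclass
class CellStats:
    mean_length: float
    sd_length: float
    mean_width: float
    sd_width: float
    mean_neighbors: float


@dataclass
class TissueMesh:
    """Volume grid with a myocyte label per volume and a type per face.

    Arrays are indexed ``[j, i]`` with ``i`` the x / fiber direction and
    ``j`` the y direction (both 0-based).  ``face_e[j, i]`` is the face
    between volumes ``(i, j)`` and ``(i+1, j)``; ``face_n[j, i]`` the face
    between ``(i, j)`` and ``(i, j+1)``.  The last column of ``face_e``
    and last row of ``face_n`` store the wrap-around faces that define
    how the mesh continues when tiled; solvers treat the outer boundary
    as no-flux and never read them.
    """

    nx: int
    ny: int
    h: float
    d: float
    cell_id: np.ndarray          # (ny, nx) int32
    face_e: np.ndarray           # (ny, nx) uint8
    face_n: np.ndarray           # (ny, nx) uint8
    periodic: bool = True
    conductances: ConductanceTable = field(default_factory=ConductanceTable)

    @property
    def n_cells(self) -> int:
        return int(self.cell_id.max()) + 1

    @property
    def extent_um(self) -> tuple[float, float]:
        return self.nx * self.h, self.ny * self.h

    def validate(self) -> None:
        if self.cell_id.shape != (self.ny, self.nx):
            raise ValueError("cell_id shape mismatch")
        if self.face_e.shape != (self.ny, self.nx) or self.face_n.shape != (self.ny, self.nx):
            raise ValueError("face array shape mismatch")
        # planar interior faces only: wrap faces of a tileable mesh may
        # join fragments that only become one cell under further tiling
        same_e = self.cell_id[:, : self.nx - 1] == self.cell_id[:, 1:]
        same_n = self.cell_id[: self.ny - 1, :] == self.cell_id[1:, :]
        if not np.all((self.face_e[:, : self.nx - 1] == FaceType.CYTOPLASM) == same_e):
            raise ValueError("cytoplasm faces must coincide with same-cell faces")
        if not np.all((self.face_n[: self.ny - 1, :] == FaceType.CYTOPLASM) == same_n):
            raise ValueError("cytoplasm faces must coincide with same-cell faces")


# ---------------------------------------------------------------------------
# The frozen basic unit: 60 × 18 volumes (480 μm × 144 μm), 8 strips,
# 4 cells per strip.  Boundaries are circular positions in [0, 60); a
# strip whose first boundary is nonzero contains one cell wrapping x=0.
# Adjacent strips (cyclically, including strip 7 against strip 0 of the
# tile above) share no boundary, which makes every interior cell touch
# exactly two longitudinal and four lateral neighbours.
# ---------------------------------------------------------------------------

UNIT_NX = 60
UNIT_NY = 18
STRIP_WIDTHS = (2, 2, 3, 2, 2, 3, 2, 2)
# Circular cell boundaries per strip.  Adjacent strips (cyclically)
# share no boundary, which fixes the mean neighbour count at exactly 6;
# the stagger between vertically adjacent cells is deliberately small
# (2-4 volumes), matching the modest end-to-end offsets of ventricular
# myocyte columns — large offsets would let the lumped discrete model
# propagate along spurious fast diagonals.
STRIP_BOUNDS = (
    (0, 16, 25, 46),
    (3, 19, 28, 43),
    (1, 17, 27, 45),
    (4, 20, 30, 47),
    (2, 18, 28, 44),
    (5, 21, 31, 48),
    (3, 18, 29, 46),
    (1, 17, 28, 44),
)
# Gap junctions are discrete plaques, not a property of every membrane
# face; the placement density below is the frozen conduction-velocity
# calibration (docs/methods.md).  Every touching cell pair keeps at
# least one junction, so the adjacency graph (and with it the neighbour
# statistics and percolation topology) is independent of the thinning.
INTERPLICATE_END_ZONE = 2     # lateral faces this close to a cell end are interplicate
LONG_FACES_PER_ABUTMENT = 1   # plicate faces kept per end-to-end abutment column
LATERAL_KEEP_MODULUS = 1      # keep lateral junction faces at x % k == 0 (k | 60)
# Stepped lateral contacts (short overlaps at offset cell ends) carry a
# single junction plaque; long side-to-side contacts keep a junction on
# every face.  This throttles the lumped model's fast diagonal relays
# without touching the cross-fiber coupling of the long contacts.
STEP_CONTACT_MAX_FACES = 5


def _strip_of_row() -> np.ndarray:
    """Strip index for each of the 18 unit rows."""
    out = np.empty(UNIT_NY, dtype=np.int32)
    j = 0
    for s, w in enumerate(STRIP_WIDTHS):
        out[j : j + w] = s
        j += w
    return out


def _arc_of_col(bounds: tuple[int, ...]) -> np.ndarray:
    """Cell (arc) index within a strip for each unit column."""
    b = np.asarray(bounds)
    x = np.arange(UNIT_NX)
    k = np.searchsorted(b, x, side="right") - 1
    k[x < b[0]] = len(b) - 1  # wrapped cell owns the columns before b[0]
    return k.astype(np.int32)


def _end_distance(bounds: tuple[int, ...]) -> np.ndarray:
    """Circular distance (volumes) of each column to the nearest cell end."""
    b = np.asarray(bounds)
    x = np.arange(UNIT_NX)
    diffs = np.abs(x[:, None] - b[None, :])
    circ = np.minimum(diffs, UNIT_NX - diffs)
    # distance measured between a column and the boundary line left of it
    # or right of it; the face-level rule only needs the nearest line
    left = circ.min(axis=1)
    right = np.minimum(np.abs(x[:, None] + 1 - b[None, :]), UNIT_NX - np.abs(x[:, None] + 1 - b[None, :])).min(axis=1)
    return np.minimum(left, right)


def build_template(spec: TemplateSpec | None = None) -> TissueMesh:
    """Construct the frozen 32-myocyte basic unit.

    The returned mesh is periodic (tileable): the last column of east
    faces and last row of north faces hold the wrap-around connections.
    Raises ``ValueError`` if ``spec`` asks for statistics the frozen unit
    cannot honour within its documented ±5 % band on the means.
    """
    spec = spec or TemplateSpec()
    if abs(spec.h - 8.0) > 1e-12:
        raise ValueError("the frozen unit is built on an 8 μm grid")

    strip = _strip_of_row()
    cell_id = np.empty((UNIT_NY, UNIT_NX), dtype=np.int32)
    for j in range(UNIT_NY):
        s = strip[j]
        cell_id[j, :] = s * 4 + _arc_of_col(STRIP_BOUNDS[s])

    # longitudinal faces: plicate plaques at end-to-end abutments.  An
    # abutment column has `width` candidate faces; the lowest-y face(s)
    # carry the junction, the rest are plain membrane.
    same_e = cell_id == np.roll(cell_id, -1, axis=1)
    face_e = np.where(same_e, FaceType.CYTOPLASM, FaceType.MEMBRANE).astype(np.uint8)
    for x in range(UNIT_NX):
        col = ~same_e[:, x]
        if not col.any():
            continue
        # contiguous runs of inter-cell faces in this column = abutments
        ys = np.flatnonzero(col)
        runs = np.split(ys, np.flatnonzero(np.diff(ys) > 1) + 1)
        for run in runs:
            face_e[run[:LONG_FACES_PER_ABUTMENT], x] = FaceType.PLICATE

    # lateral faces: interplicate plaques near either adjoining cell's
    # end, combined plicate along the body, thinned to every k-th column
    # with at least one junction per touching pair.
    end_dist = np.stack([_end_distance(STRIP_BOUNDS[s]) for s in range(8)])
    face_n = np.empty((UNIT_NY, UNIT_NX), dtype=np.uint8)
    xcols = np.arange(UNIT_NX)
    for j in range(UNIT_NY):
        jn = (j + 1) % UNIT_NY
        if strip[j] == strip[jn]:
            face_n[j, :] = FaceType.CYTOPLASM
            continue
        near_end = np.minimum(end_dist[strip[j]], end_dist[strip[jn]]) < INTERPLICATE_END_ZONE
        jtype = np.where(near_end, FaceType.INTERPLICATE, FaceType.COMBINED_PLICATE)
        keep = (xcols % LATERAL_KEEP_MODULUS) == 0
        # contact segments: circular runs of constant (cell below, cell above)
        pair_a = cell_id[j, :]
        pair_b = cell_id[jn, :]
        change = (np.roll(pair_a, 1) != pair_a) | (np.roll(pair_b, 1) != pair_b)
        seg_id = np.cumsum(change)
        if not change[0] and change.any():
            seg_id[seg_id == seg_id[0]] = seg_id[-1]  # join the wrap-around segment
        for seg in np.unique(seg_id):
            m = seg_id == seg
            if m.sum() <= STEP_CONTACT_MAX_FACES:
                keep[m] = False          # stepped contact: one plaque only
            if not keep[m].any():
                first = np.flatnonzero(m)[0]
                keep[first] = True
        face_n[j, :] = np.where(keep, jtype, FaceType.MEMBRANE)

    mesh = TissueMesh(
        nx=UNIT_NX, ny=UNIT_NY, h=spec.h, d=spec.d,
        cell_id=cell_id, face_e=face_e, face_n=face_n, periodic=True,
    )
    _check_template_targets(mesh, spec)
    return mesh


def _check_template_targets(mesh: TissueMesh, spec: TemplateSpec) -> None:
    stats = cell_geometry_stats(mesh)
    checks = [
        ("mean length", stats.mean_length, spec.target_mean_length),
        ("mean width", stats.mean_width, spec.target_mean_width),
    ]
    for name, got, want in checks:
        if abs(got - want) > 0.05 * want:
            raise ValueError(
                f"frozen unit {name} {got:.2f} μm misses the target {want:.2f} μm by >5%"
            )
    if abs(stats.mean_neighbors - spec.target_mean_neighbors) > 0.5:
        raise ValueError("frozen unit mean neighbour count misses the target by >0.5")


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_template(unit: TissueMesh, ux: int, uy: int) -> TissueMesh:
    """Tile ``ux`` × ``uy`` translated copies of a tileable unit.

    Cells cut by the unit's wrap-around line are merged across copy
    seams so that every interior cell of the tissue is an exact
    translate of its template cell; fragments clipped by the outer
    tissue boundary remain as smaller boundary cells.  Cell ids are
    relabelled to a globally unique, deterministic 0..n-1 range.
    """
    if ux < 1 or uy < 1:
        raise ValueError("ux and uy must be >= 1")
    if not unit.periodic:
        raise ValueError("unit is not tileable (periodic wrap faces missing)")
    unit.validate()
    if ux == 1 and uy == 1:
        return replace(unit, cell_id=unit.cell_id.copy(),
                       face_e=unit.face_e.copy(), face_n=unit.face_n.copy())

    ny, nx = unit.ny, unit.nx
    NY, NX = ny * uy, nx * ux
    face_e_t = np.tile(unit.face_e, (uy, ux))
    face_n_t = np.tile(unit.face_n, (uy, ux))

    # Cells of the tiled tissue are the connected components of volumes
    # joined by cytoplasm faces (seam faces included, outer boundary
    # not); this merges wrap-around cells across copy seams and leaves
    # clipped fragments at the tissue edge as their own boundary cells.
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    idx = np.arange(NY * NX, dtype=np.int64).reshape(NY, NX)
    cyto_e = face_e_t[:, : NX - 1] == FaceType.CYTOPLASM
    cyto_n = face_n_t[: NY - 1, :] == FaceType.CYTOPLASM
    ei = np.concatenate([idx[:, : NX - 1][cyto_e], idx[: NY - 1, :][cyto_n]])
    ej = np.concatenate([idx[:, 1:][cyto_e], idx[1:, :][cyto_n]])
    g = coo_matrix(
        (np.ones(ei.size, dtype=np.int8), (ei, ej)), shape=(NY * NX, NY * NX)
    )
    _, comp = connected_components(g, directed=False)

    # deterministic relabel: order components by first appearance in the grid
    _, first_idx, new_id = np.unique(comp, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first_idx))
    cell_id = order[new_id].reshape(NY, NX).astype(np.int32)

    return TissueMesh(
        nx=NX, ny=NY, h=unit.h, d=unit.d,
        cell_id=cell_id,
        face_e=face_e_t,
        face_n=face_n_t,
        periodic=True,
        conductances=unit.conductances,
    )


def tile_to_extent(unit: TissueMesh, width_um: float, height_um: float) -> TissueMesh:
    """Smallest tiling whose physical extent covers the requested size."""
    ux = int(np.ceil(width_um / (unit.nx * unit.h)))
    uy = int(np.ceil(height_um / (unit.ny * unit.h)))
    return tile_template(unit, max(ux, 1), max(uy, 1))


# ---------------------------------------------------------------------------
# Geometry statistics
# ---------------------------------------------------------------------------

def _circular_extent(occupied: np.ndarray, n: int, wrap: bool) -> int:
    """Extent (count of grid lines spanned) of a set of occupied indices.

    With ``wrap`` the minimal covering circular arc is used, so a cell
    crossing the periodic seam reports its true body length.
    """
    idx = np.unique(occupied)
    if not wrap or idx.size == n:
        return int(idx[-1] - idx[0] + 1)
    gaps = np.diff(np.concatenate([idx, idx[:1] + n]))
    return int(n - gaps.max() + 1)


def cell_geometry_stats(
    mesh: TissueMesh,
    wrap: bool | None = None,
    interior_only: bool = False,
) -> CellStats:
    """Bounding-box cell lengths/widths (μm) and mean neighbour count.

    Length is the extent along the fiber (x) axis, width along y.
    Neighbours are distinct cells sharing at least one gap-junction
    face.  ``wrap`` (default: ``mesh.periodic``) counts the wrap-around
    faces and measures wrap cells circularly — appropriate for the
    template unit, where it reproduces the statistics of the infinite
    tiling.  ``interior_only`` drops cells touching the tissue boundary
    (only meaningful with ``wrap=False``).
    """
    wrap = mesh.periodic if wrap is None else wrap
    ncell = mesh.n_cells
    jj, ii = np.mgrid[0 : mesh.ny, 0 : mesh.nx]
    cid = mesh.cell_id.ravel()
    cols = ii.ravel()
    rows = jj.ravel()

    keep = np.ones(ncell, dtype=bool)
    if interior_only:
        border = np.unique(
            np.concatenate([
                mesh.cell_id[0, :], mesh.cell_id[-1, :],
                mesh.cell_id[:, 0], mesh.cell_id[:, -1],
            ])
        )
        keep[border] = False
        if not keep.any():
            raise ValueError("no interior cells in this mesh")

    order = np.argsort(cid, kind="stable")
    cid_s, cols_s, rows_s = cid[order], cols[order], rows[order]
    starts = np.searchsorted(cid_s, np.arange(ncell))
    ends = np.searchsorted(cid_s, np.arange(ncell), side="right")
    lengths = np.empty(ncell)
    widths = np.empty(ncell)
    for c in range(ncell):
        sl = slice(starts[c], ends[c])
        lengths[c] = _circular_extent(cols_s[sl], mesh.nx, wrap) * mesh.h
        widths[c] = _circular_extent(rows_s[sl], mesh.ny, wrap) * mesh.h

    # neighbour pairs through gap-junction faces
    pairs = gap_junction_pairs(mesh, wrap=wrap)
    deg = np.zeros(ncell)
    if pairs.size:
        np.add.at(deg, pairs[:, 0], 1)
        np.add.at(deg, pairs[:, 1], 1)

    return CellStats(
        mean_length=float(lengths[keep].mean()),
        sd_length=float(lengths[keep].std()),
        mean_width=float(widths[keep].mean()),
        sd_width=float(widths[keep].std()),
        mean_neighbors=float(deg[keep].mean()),
    )


def gap_junction_pairs(mesh: TissueMesh, wrap: bool | None = None) -> np.ndarray:
    """Unique (cell, cell) pairs joined by ≥1 gap-junction face, sorted."""
    wrap = mesh.periodic if wrap is None else wrap
    cid = mesh.cell_id
    pair_list = []
    for face, axis in ((mesh.face_e, 1), (mesh.face_n, 0)):
        other = np.roll(cid, -1, axis=axis)
        is_gj = (face >= FaceType.PLICATE)
        if not wrap:
            if axis == 1:
                is_gj = is_gj.copy()
                is_gj[:, -1] = False
            else:
                is_gj = is_gj.copy()
                is_gj[-1, :] = False
        a = cid[is_gj]
        b = other[is_gj]
        pair_list.append(np.stack([np.minimum(a, b), np.maximum(a, b)], axis=1))
    if not pair_list:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.concatenate(pair_list)
    return np.unique(pairs, axis=0)


# ---------------------------------------------------------------------------
# Face transmission coefficients
# ---------------------------------------------------------------------------

def face_coefficient(ftype: FaceType, table: ConductanceTable, d: float) -> float:
    """Face transmission coefficient in μS/μm.

    Conductivities pass through unchanged; gap-junction conductances are
    divided by the tissue depth ``d`` so that, multiplied by the face
    area ``h·d`` and divided by ``h``, the flux through a junction face
    reduces to G·ΔV.
    """
    if d <= 0:
        raise ValueError("depth must be positive")
    if ftype == FaceType.MEMBRANE:
        return table.sigma_m
    if ftype == FaceType.CYTOPLASM:
        return table.sigma_c
    if ftype == FaceType.PLICATE:
        return table.G_p / d
    if ftype == FaceType.INTERPLICATE:
        return table.G_i / d
    if ftype == FaceType.COMBINED_PLICATE:
        return table.G_c / d
    raise ValueError(f"unknown face type {ftype!r}")


def face_coefficients(table: ConductanceTable, d: float) -> np.ndarray:
    """Lookup array mapping FaceType value → coefficient (μS/μm)."""
    return np.array([face_coefficient(FaceType(v), table, d) for v in range(5)])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_mesh_h5(mesh: TissueMesh, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["nx"] = mesh.nx
        f.attrs["ny"] = mesh.ny
        f.attrs["h"] = mesh.h
        f.attrs["d"] = mesh.d
        f.attrs["periodic"] = mesh.periodic
        t = mesh.conductances
        f.attrs["conductances"] = [t.sigma_m, t.sigma_c, t.G_p, t.G_i, t.G_c]
        f.create_dataset("cell_id", data=mesh.cell_id, compression="gzip")
        f.create_dataset("face_e", data=mesh.face_e, compression="gzip")
        f.create_dataset("face_n", data=mesh.face_n, compression="gzip")


def load_mesh_h5(path: str) -> TissueMesh:
    import h5py

    with h5py.File(path, "r") as f:
        c = f.attrs["conductances"]
        return TissueMesh(
            nx=int(f.attrs["nx"]), ny=int(f.attrs["ny"]),
            h=float(f.attrs["h"]), d=float(f.attrs["d"]),
            cell_id=f["cell_id"][()], face_e=f["face_e"][()], face_n=f["face_n"][()],
            periodic=bool(f.attrs["periodic"]),
            conductances=ConductanceTable(
                sigma_m=float(c[0]), sigma_c=float(c[1]),
                G_p=float(c[2]), G_i=float(c[3]), G_c=float(c[4]),
            ),
        )


def export_vtk(mesh: TissueMesh, path: str, field_arr: np.ndarray | None = None,
               name: str = "cell_id") -> None:
    """ASCII VTK structured-points export of cell ids (or any volume field)."""
    data = mesh.cell_id if field_arr is None else field_arr
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nfibrosim mesh\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {mesh.nx + 1} {mesh.ny + 1} 2\n")
        f.write("ORIGIN 0 0 0\n")
        f.write(f"SPACING {mesh.h} {mesh.h} {mesh.d}\n")
        f.write(f"CELL_DATA {mesh.nx * mesh.ny}\n")
        kind = "int" if np.issubdtype(data.dtype, np.integer) else "float"
        f.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, data.reshape(mesh.ny, mesh.nx), fmt="%g")
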