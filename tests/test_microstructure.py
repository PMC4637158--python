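"""The frozen 32-myocyte template, its tiling and geometry statistics."""

import numpy as np
import pytest

from fibrosim.microstructure import (
    ConductanceTable, FaceType, TemplateSpec, build_template, tile_template,
    tile_to_extent, cell_geometry_stats, face_coefficient, face_coefficients,
    gap_junction_pairs, save_mesh_h5, load_mesh_h5,
)
from fibrosim.fixtures import two_cell_mesh


def test_template_has_32_distinct_cells(unit_mesh):
    assert unit_mesh.n_cells == 32
    assert set(np.unique(unit_mesh.cell_id)) == set(range(32))


def test_template_morphometry_matches_murine_targets(unit_mesh):
    s = cell_geometry_stats(unit_mesh)
    assert abs(s.mean_length - 120.9) <= 0.05 * 120.9
    assert abs(s.mean_width - 18.3) <= 0.05 * 18.3
    assert abs(s.mean_neighbors - 6.0) <= 0.5
    # dispersion is realistic even though only the means are pinned
    assert 15.0 < s.sd_length < 35.0
    assert 2.0 < s.sd_width < 5.0


def test_same_cell_faces_are_cytoplasm(unit_mesh):
    unit_mesh.validate()
    same_e = unit_mesh.cell_id[:, :-1] == unit_mesh.cell_id[:, 1:]
    assert np.array_equal(unit_mesh.face_e[:, :-1] == FaceType.CYTOPLASM, same_e)


def test_intercell_faces_use_all_three_junction_types(unit_mesh):
    types = set(np.unique(unit_mesh.face_e)) | set(np.unique(unit_mesh.face_n))
    assert {FaceType.PLICATE, FaceType.INTERPLICATE, FaceType.COMBINED_PLICATE} <= types


def test_template_spec_validation():
    with pytest.raises(ValueError):
        TemplateSpec(n_cells=33)
    with pytest.raises(ValueError):
        TemplateSpec(h=-1.0)
    with pytest.raises(ValueError):
        build_template(TemplateSpec(h=10.0))  # frozen unit is an 8 um grid


def test_identity_tiling_returns_unit(unit_mesh):
    t = tile_template(unit_mesh, 1, 1)
    assert np.array_equal(t.cell_id, unit_mesh.cell_id)
    assert np.array_equal(t.face_e, unit_mesh.face_e)


def test_tiling_counts_and_dimensions(unit_mesh):
    t = tile_template(unit_mesh, 2, 1)
    assert t.nx == 2 * unit_mesh.nx and t.ny == unit_mesh.ny
    # 64 translated cells: the 7 wrap-around cells merge across the
    # interior seam (-7) and leave 14 clipped fragments at the two
    # vertical tissue edges (+14)
    assert t.n_cells == 71


def test_tiled_cells_are_4_connected(unit_mesh):
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    t = tile_template(unit_mesh, 3, 2)
    idx = np.arange(t.ny * t.nx).reshape(t.ny, t.nx)
    cyto_e = t.face_e[:, :-1] == FaceType.CYTOPLASM
    cyto_n = t.face_n[:-1, :] == FaceType.CYTOPLASM
    ei = np.concatenate([idx[:, :-1][cyto_e], idx[:-1, :][cyto_n]])
    ej = np.concatenate([idx[:, 1:][cyto_e], idx[1:, :][cyto_n]])
    g = coo_matrix((np.ones(ei.size), (ei, ej)), shape=(idx.size, idx.size))
    n_comp, comp = connected_components(g, directed=False)
    # each cell is exactly one planar component
    assert n_comp == t.n_cells
    assert np.array_equal(np.unique(comp.reshape(t.ny, t.nx) * 0 + t.cell_id),
                          np.arange(t.n_cells))


def test_tiling_preserves_interior_statistics(unit_mesh):
    s0 = cell_geometry_stats(unit_mesh)
    s = cell_geometry_stats(tile_template(unit_mesh, 3, 3), wrap=False, interior_only=True)
    # exactly 6 in the infinite tiling; clipped boundary fragments
    # perturb the finite interior mean at the per-mille level
    assert s.mean_neighbors == pytest.approx(6.0, abs=0.05)
    assert s.mean_length == pytest.approx(s0.mean_length, rel=0.05)
    assert s.mean_width == pytest.approx(s0.mean_width, rel=0.05)


def test_tile_to_one_centimetre(unit_mesh):
    t = tile_to_extent(unit_mesh, 1e4, 1e4)
    assert t.nx * t.h >= 1e4 and t.ny * t.h >= 1e4
    # smallest such tiling
    assert (t.nx - unit_mesh.nx) * t.h < 1e4 or (t.ny - unit_mesh.ny) * t.h < 1e4
    assert 4e4 <= t.n_cells <= 5e4


def test_rectangular_cell_bounding_box_oracle():
    mesh = two_cell_mesh(width=2, length=15)
    s = cell_geometry_stats(mesh)
    assert s.mean_length == 15 * 8.0
    assert s.mean_width == 2 * 8.0


def test_membrane_only_mesh_has_no_neighbors():
    mesh = two_cell_mesh()
    mesh.face_e[mesh.face_e == FaceType.PLICATE] = FaceType.MEMBRANE
    assert gap_junction_pairs(mesh).size == 0
    assert cell_geometry_stats(mesh).mean_neighbors == 0.0


@pytest.mark.parametrize("ftype,expected", [
    (FaceType.MEMBRANE, 0.0),
    (FaceType.CYTOPLASM, 0.4),
    (FaceType.PLICATE, 0.05),        # G_p / d = 0.5 / 10
    (FaceType.INTERPLICATE, 0.033),
    (FaceType.COMBINED_PLICATE, 0.0062),
])
def test_face_coefficient_values(ftype, expected):
    assert face_coefficient(ftype, ConductanceTable(), 10.0) == pytest.approx(expected)


def test_face_coefficient_errors():
    with pytest.raises(ValueError):
        face_coefficient(FaceType.PLICATE, ConductanceTable(), 0.0)
    with pytest.raises(ValueError):
        face_coefficient(99, ConductanceTable(), 10.0)  # type: ignore[arg-type]


def test_conductance_table_invariants():
    with pytest.raises(ValueError):
        ConductanceTable(sigma_m=0.1)
    with pytest.raises(ValueError):
        ConductanceTable(G_c=-1.0)


def test_face_coefficient_lut_matches_scalar():
    lut = face_coefficients(ConductanceTable(), 10.0)
    for v in range(5):
        assert lut[v] == face_coefficient(FaceType(v), ConductanceTable(), 10.0)


def test_mesh_h5_roundtrip(tmp_path, unit_mesh):
    p = str(tmp_path / "unit.h5")
    save_mesh_h5(unit_mesh, p)
    back = load_mesh_h5(p)
    assert np.array_equal(back.cell_id, unit_mesh.cell_id)
    assert np.array_equal(back.face_n, unit_mesh.face_n)
    assert back.h == unit_mesh.h and back.periodic == unit_mesh.periodic
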