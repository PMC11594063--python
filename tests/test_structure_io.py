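import numpy as np
import pytest

import surfdelta as sd
from surfdelta.structure_io import (ParseError, TopologyError,
                                    UnsupportedFormatError, model_from_atoms,
                                    parse_pqr_text, pqr_text)

PQR_TWO_ATOMS = """\
REMARK toy
ATOM      1 N    ASP A   1    1.000 2.000 3.000 -0.5000 1.5500
ATOM      2 CA   ASP A   1    2.400 2.000 3.000  0.5000 1.7000
END
"""


class TestReadPqr:
    def test_two_atom_fixture_net_charge_zero(self):
        m = parse_pqr_text(PQR_TWO_ATOMS)
        assert m.n_atoms == 2
        assert m.net_charge() == pytest.approx(0.0)
        assert m.charge[0] == -0.5
        assert m.radius[1] == 1.7
        assert m.chain_id[0] == "A" and m.res_id[0] == 1

    def test_windows_line_endings_give_identical_model(self, tmp_path):
        crlf = tmp_path / "crlf.pqr"
        crlf.write_bytes(PQR_TWO_ATOMS.replace("\n", "\r\n").encode())
        a = sd.read_pqr(crlf)
        b = parse_pqr_text(PQR_TWO_ATOMS)
        assert np.array_equal(a.coord, b.coord)
        assert np.array_equal(a.charge, b.charge)

    def test_non_numeric_charge_reports_line_number(self):
        bad = PQR_TWO_ATOMS.replace("-0.5000", "oops")
        with pytest.raises(ParseError, match="line 2"):
            parse_pqr_text(bad)

    def test_empty_atom_set_is_an_error(self):
        with pytest.raises(ParseError, match="no ATOM"):
            parse_pqr_text("REMARK nothing here\nEND\n")

    def test_chainless_dialect_accepted(self):
        text = "ATOM 1 CA GLY 1 0.0 0.0 0.0 0.1 1.7\n"
        m = parse_pqr_text(text)
        assert m.chain_id[0] == "" and m.res_id[0] == 1

    def test_round_trip_preserves_all_fields(self, toy_pair):
        wt, _, _ = toy_pair
        again = parse_pqr_text(pqr_text(wt))
        assert np.array_equal(again.serial, wt.serial)
        assert np.array_equal(again.name, wt.name)
        assert np.array_equal(again.coord, wt.coord)
        assert np.allclose(again.charge, wt.charge)
        assert np.allclose(again.radius, wt.radius)


class TestReadPdbModels:
    def test_three_identical_models(self, toy_files):
        d, _ = toy_files
        ens = sd.read_pdb_models(d / "wt.pdb")
        assert ens.n_models == 3
        assert np.array_equal(ens.models[0].coord, ens.models[2].coord)

    def test_file_without_model_records_is_one_model(self, tmp_path, toy_pair):
        wt, _, _ = toy_pair
        from surfdelta.synth import write_ensemble_pdb
        path = tmp_path / "single.pdb"
        ens1 = sd.make_wobble_ensemble(wt, 1, 0.0)
        write_ensemble_pdb(ens1, path)
        # strip MODEL/ENDMDL records
        lines = [l for l in path.read_text().splitlines()
                 if not l.startswith(("MODEL", "ENDMDL"))]
        path.write_text("\n".join(lines) + "\n")
        ens = sd.read_pdb_models(path)
        assert ens.n_models == 1
        assert ens.models[0].n_atoms == wt.n_atoms

    def test_missing_atom_in_second_model_is_topology_error(self, toy_files, tmp_path):
        d, _ = toy_files
        lines = (d / "wt.pdb").read_text().splitlines()
        # drop the first ATOM line of the second MODEL block
        second = [i for i, l in enumerate(lines) if l.startswith("MODEL")][1]
        atom = next(i for i in range(second, len(lines))
                    if lines[i].startswith("ATOM"))
        bad = tmp_path / "bad.pdb"
        bad.write_text("\n".join(lines[:atom] + lines[atom + 1:]) + "\n")
        with pytest.raises(TopologyError):
            sd.read_pdb_models(bad)

    def test_charges_joined_from_pqr_template(self, toy_files, toy_pair):
        d, _ = toy_files
        wt, _, _ = toy_pair
        ens = sd.apply_pqr_charges(sd.read_pdb_models(d / "wt.pdb"), wt)
        assert np.allclose(ens.models[0].charge, wt.charge)
        assert np.allclose(ens.models[1].radius, wt.radius)

    def test_unmatched_atoms_get_element_radius_and_warning(self, toy_files, toy_pair):
        d, _ = toy_files
        wt, _, _ = toy_pair
        truncated = wt.select(np.arange(wt.n_atoms) < wt.n_atoms - 3)
        with pytest.warns(UserWarning, match="not found in PQR template"):
            ens = sd.apply_pqr_charges(sd.read_pdb_models(d / "wt.pdb"), truncated)
        assert ens.models[0].charge[-1] == 0.0
        assert ens.models[0].radius[-1] == 1.70  # carbon fallback


DX_2x2x2 = """\
# toy grid
object 1 class gridpositions counts 2 2 2
origin 0.0 0.0 0.0
delta 0.5 0.0 0.0
delta 0.0 0.5 0.0
delta 0.0 0.0 0.5
object 2 class gridconnections counts 2 2 2
object 3 class array type double rank 0 items 8 data follows
0.0 1.0 2.0
3.0 4.0 5.0
6.0 7.0
attribute "dep" string "positions"
object "regular positions regular connections" class field
"""


class TestReadDxGrid:
    def test_z_fastest_ordering(self, tmp_path):
        p = tmp_path / "g.dx"
        p.write_text(DX_2x2x2)
        grid = sd.read_dx_grid(p)
        assert grid.values[0, 0, 1] == 1.0
        assert grid.values[0, 1, 0] == 2.0
        assert grid.values[1, 0, 0] == 4.0

    def test_flat_index_convention(self, tmp_path):
        p = tmp_path / "g.dx"
        p.write_text(DX_2x2x2)
        grid = sd.read_dx_grid(p)
        flat = grid.values.reshape(-1)
        nx, ny, nz = grid.counts
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    assert grid.values[i, j, k] == flat[i * ny * nz + j * nz + k]

    def test_spacing_parsed_from_delta_lines(self, tmp_path):
        p = tmp_path / "g.dx"
        p.write_text(DX_2x2x2)
        assert np.allclose(sd.read_dx_grid(p).spacing, 0.5)

    def test_count_mismatch_is_error(self, tmp_path):
        p = tmp_path / "bad.dx"
        p.write_text(DX_2x2x2.replace("counts 2 2 2", "counts 3 3 3")
                     .replace("items 8", "items 27"))
        with pytest.raises(ParseError, match="27"):
            sd.read_dx_grid(p)

    def test_non_orthogonal_delta_unsupported(self, tmp_path):
        p = tmp_path / "skew.dx"
        p.write_text(DX_2x2x2.replace("delta 0.5 0.0 0.0", "delta 0.5 0.1 0.0"))
        with pytest.raises(UnsupportedFormatError):
            sd.read_dx_grid(p)

    def test_dx_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = sd.PotentialGrid(origin=(-1, 0, 2), spacing=(0.4, 0.5, 0.6),
                                counts=(3, 4, 5),
                                values=rng.normal(size=(3, 4, 5)))
        p = tmp_path / "rt.dx"
        sd.write_dx_grid(grid, p)
        back = sd.read_dx_grid(p)
        assert np.allclose(back.values, grid.values, atol=1e-5)
        assert np.allclose(back.origin, grid.origin)


class TestWriteMesh:
    @staticmethod
    def _tetra():
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        faces = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
        mesh = sd.SurfaceMesh(vertices=verts, faces=faces,
                              grid_spacing=0.5, probe_radius=1.4)
        return mesh.with_potential(np.array([0.1, -0.2, 0.3, 0.0]))

    def test_tetrahedron_counts(self, tmp_path):
        p = tmp_path / "t.ply"
        sd.write_mesh(self._tetra(), p, scalar="potential")
        v, f, s = sd.read_mesh(p)
        assert len(v) == 4 and len(f) == 4

    def test_round_trip_scalar_values(self, tmp_path):
        mesh = self._tetra()
        p = tmp_path / "t.ply"
        sd.write_mesh(mesh, p, scalar="potential")
        v, f, s = sd.read_mesh(p)
        assert np.allclose(s, mesh.vertex_potential)
        assert np.array_equal(f, mesh.faces)

    def test_trimesh_reads_our_ply(self, tmp_path):
        trimesh = pytest.importorskip("trimesh")
        p = tmp_path / "t.ply"
        sd.write_mesh(self._tetra(), p, scalar="potential")
        tm = trimesh.load(str(p), process=False)
        assert len(tm.vertices) == 4 and len(tm.faces) == 4

    def test_unknown_scalar_is_error(self, tmp_path):
        with pytest.raises(ValueError, match="shape_index"):
            sd.write_mesh(self._tetra(), tmp_path / "x.ply", scalar="shape_index")


def test_duplicate_serials_rejected():
    with pytest.raises(ValueError, match="unique"):
        model_from_atoms([
            dict(serial=1, name="CA", res_name="GLY", chain_id="A", res_id=1,
                 coord=(0, 0, 0), charge=0, radius=1.7),
            dict(serial=1, name="CB", res_name="GLY", chain_id="A", res_id=1,
                 coord=(1, 0, 0), charge=0, radius=1.7),
        ])
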