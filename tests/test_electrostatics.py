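import numpy as np
import pytest

import surfdelta as sd
from surfdelta.electrostatics import (PointOnAtomError, coulomb_prefactor,
                                      debye_kappa)
from surfdelta.structure_io import model_from_atoms


def _charges(specs):
    """specs: list of (pos, q)"""
    return model_from_atoms([
        dict(serial=i + 1, name="CA", res_name="GLY", chain_id="A", res_id=i + 1,
             coord=p, charge=q, radius=1.5)
        for i, (p, q) in enumerate(specs)
    ])


def brute_force_screened_coulomb(model, points, cfg):
    """Independent pairwise double loop (no vectorization, no sharing)."""
    pref = coulomb_prefactor(cfg.temperature) / cfg.solvent_dielectric
    kappa = debye_kappa(cfg.ionic_strength, cfg.solvent_dielectric, cfg.temperature)
    out = []
    for p in points:
        total = 0.0
        for i in range(model.n_atoms):
            d = float(np.sqrt(sum((p[k] - model.coord[i, k]) ** 2 for k in range(3))))
            total += model.charge[i] * np.exp(-kappa * d) / d
        out.append(pref * total)
    return np.array(out)


class TestScreenedCoulomb:
    def test_unit_charge_closed_form(self):
        # +1e at 3 A in eps_r = 78.5, no screening: prefactor/(78.5*3).
        m = _charges([((0, 0, 0), 1.0)])
        cfg = sd.ElectrostaticsConfig(ionic_strength=0.0, temperature=300.0)
        phi = sd.screened_coulomb_potential(m, [(3.0, 0, 0)], cfg)
        assert phi[0] == pytest.approx(557.0 / (78.5 * 3.0), rel=1e-4)
        assert phi[0] == pytest.approx(2.365, abs=5e-3)

    def test_zero_charges_give_zero(self):
        m = _charges([((0, 0, 0), 0.0), ((2, 0, 0), 0.0)])
        phi = sd.screened_coulomb_potential(m, [(5, 5, 5), (1, 1, 1)])
        assert np.all(phi == 0.0)

    def test_superposition_in_charges(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-5, 5, (6, 3))
        q1, q2 = rng.normal(size=6), rng.normal(size=6)
        pts = rng.uniform(6, 9, (10, 3))
        cfg = sd.ElectrostaticsConfig()
        a = sd.screened_coulomb_potential(_charges(list(zip(pos, q1))), pts, cfg)
        b = sd.screened_coulomb_potential(_charges(list(zip(pos, q2))), pts, cfg)
        ab = sd.screened_coulomb_potential(_charges(list(zip(pos, q1 + q2))), pts, cfg)
        assert np.allclose(a + b, ab, rtol=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        model = _charges([(p, q) for p, q in
                          zip(rng.uniform(-6, 6, (20, 3)), rng.normal(size=20))])
        pts = rng.uniform(8, 12, (15, 3))
        cfg = sd.ElectrostaticsConfig(ionic_strength=0.1)
        mine = sd.screened_coulomb_potential(model, pts, cfg)
        ref = brute_force_screened_coulomb(model, pts, cfg)
        assert np.allclose(mine, ref, rtol=1e-12)

    def test_screening_monotone_in_ionic_strength(self):
        m = _charges([((0, 0, 0), 1.0)])
        values = [
            sd.screened_coulomb_potential(
                m, [(4.0, 0, 0)], sd.ElectrostaticsConfig(ionic_strength=i)
            )[0]
            for i in (0.0, 0.05, 0.15, 0.5)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_kappa_zero_at_zero_ionic_strength(self):
        assert debye_kappa(0.0, 78.5, 300.0) == 0.0
        # ~0.1 /A around physiological salt in water (Debye length ~8 A)
        assert debye_kappa(0.15, 78.5, 300.0) == pytest.approx(0.127, abs=0.01)

    def test_point_on_atom_is_error(self):
        m = _charges([((1.0, 2.0, 3.0), 1.0)])
        with pytest.raises(PointOnAtomError, match="serial 1"):
            sd.screened_coulomb_potential(m, [(1.0, 2.0, 3.0)])


class TestGridMapping:
    @staticmethod
    def _mesh_in_box():
        rng = np.random.default_rng(3)
        verts = rng.uniform(0.5, 3.5, (40, 3))
        return sd.SurfaceMesh(vertices=verts, faces=np.zeros((0, 3), dtype=int),
                              grid_spacing=0.5, probe_radius=1.4)

    @staticmethod
    def _grid(fn, lo=0.0, hi=4.0, n=9):
        ax = np.linspace(lo, hi, n)
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        return sd.PotentialGrid(origin=(lo,) * 3,
                                spacing=((hi - lo) / (n - 1),) * 3,
                                counts=(n, n, n), values=fn(xx, yy, zz))

    def test_constant_grid_maps_constant(self):
        grid = self._grid(lambda x, y, z: np.full_like(x, 2.5))
        mesh = sd.map_grid_to_mesh(grid, self._mesh_in_box())
        assert np.allclose(mesh.vertex_potential, 2.5)

    def test_trilinear_exact_on_affine_field(self):
        grid = self._grid(lambda x, y, z: 2 * x - y + 0.5 * z)
        mesh = sd.map_grid_to_mesh(grid, self._mesh_in_box())
        v = mesh.vertices
        expected = 2 * v[:, 0] - v[:, 1] + 0.5 * v[:, 2]
        assert np.allclose(mesh.vertex_potential, expected, atol=1e-10)

    def test_vertex_on_grid_node_gets_stored_value(self):
        grid = self._grid(lambda x, y, z: x * y + z)
        mesh = sd.SurfaceMesh(vertices=np.array([[2.0, 2.0, 1.5]]),
                              faces=np.zeros((0, 3), dtype=int),
                              grid_spacing=0.5, probe_radius=1.4)
        mapped = sd.map_grid_to_mesh(grid, mesh)
        i, j, k = 4, 4, 3  # node (2.0, 2.0, 1.5) at 0.5 A spacing
        assert mapped.vertex_potential[0] == pytest.approx(grid.values[i, j, k])

    def test_vertex_outside_grid_reports_count_and_overshoot(self):
        grid = self._grid(lambda x, y, z: x)
        mesh = sd.SurfaceMesh(vertices=np.array([[2.0, 2.0, 2.0], [9.0, 2.0, 2.0]]),
                              faces=np.zeros((0, 3), dtype=int),
                              grid_spacing=0.5, probe_radius=1.4)
        with pytest.raises(ValueError, match=r"1 of 2 vertices.*5\.0"):
            sd.map_grid_to_mesh(grid, mesh)
        with pytest.warns(UserWarning, match="clamping"):
            clamped = sd.map_grid_to_mesh(grid, mesh, clamp=True)
        assert clamped.vertex_potential[1] == pytest.approx(4.0)

    def test_grid_self_consistency_with_direct_model_potential(self, toy_pair):
        # Sampling the screened-Coulomb field on a fine grid and
        # interpolating back onto the surface reproduces direct evaluation.
        wt, _, _ = toy_pair
        cfg = sd.ElectrostaticsConfig()
        mesh = sd.compute_ses(wt)
        direct = sd.screened_coulomb_potential(wt, mesh.vertices, cfg)
        grid = sd.potential_grid_from_model(wt, cfg, spacing=0.25, padding=4.0)
        mapped = sd.map_grid_to_mesh(grid, mesh).vertex_potential
        rel = np.abs(mapped - direct) / np.maximum(np.abs(direct), 1e-3)
        assert np.median(rel) < 0.02


class TestPotentialDistribution:
    @staticmethod
    def _mesh():
        mesh = sd.SurfaceMesh(vertices=np.zeros((4, 3)),
                              faces=np.zeros((0, 3), dtype=int),
                              grid_spacing=0.5, probe_radius=1.4)
        return mesh.with_potential(np.array([1.0, 2.0, 3.0, 4.0]))

    def test_subset_in_vertex_order(self):
        assert np.array_equal(
            sd.potential_distribution(self._mesh(), [0, 2]), [1.0, 3.0]
        )

    def test_whole_mesh_length(self):
        assert len(sd.potential_distribution(self._mesh())) == 4

    def test_out_of_range_subset_is_error(self):
        with pytest.raises(IndexError):
            sd.potential_distribution(self._mesh(), [0, 7])

    def test_empty_subset_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            sd.potential_distribution(self._mesh(), [])
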