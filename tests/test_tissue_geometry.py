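import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vertexpulse as vp
from vertexpulse.tissue_geometry import HEX_EDGE_LENGTH, _TopologyCache


class TestPeriodicBox:
    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            vp.PeriodicBox(0.0, 1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_minimum_image_is_shortest_representative(self, dx, dy):
        box = vp.PeriodicBox(10.0, 7.0)
        d = box.minimum_image(np.array([dx, dy]))
        assert abs(d[0]) <= 5.0 + 1e-9 and abs(d[1]) <= 3.5 + 1e-9
        # shifting by whole periods leaves the minimum image unchanged
        d2 = box.minimum_image(np.array([dx + 30.0, dy - 21.0]))
        np.testing.assert_allclose(d, d2, atol=1e-9)

    def test_wrap_reduces_into_box(self):
        box = vp.PeriodicBox(10.0, 7.0)
        pts = box.wrap(np.array([[12.0, -1.0], [-0.5, 7.0]]))
        assert np.all(pts >= 0) and np.all(pts < box.dims)


class TestHexagonalTissue:
    def test_counts_match_torus_topology(self, hex260):
        # 260 hexagons on a torus: 520 vertices, 780 junctions, V-E+C = 0
        assert hex260.n_cells == 260
        assert hex260.n_junctions == 780
        assert hex260.n_vertices == 520
        assert hex260.n_vertices - hex260.n_junctions + hex260.n_cells == 0

    def test_unit_area_regular_hexagons(self, hex260):
        np.testing.assert_allclose(hex260.cell_areas(), 1.0, atol=1e-12)
        np.testing.assert_allclose(hex260.edge_lengths(), HEX_EDGE_LENGTH,
                                   atol=1e-12)
        assert abs((3 * np.sqrt(3) / 2) * HEX_EDGE_LENGTH ** 2 - 1.0) < 1e-14

    def test_box_adjusted_to_commensurate_dimensions(self, hex260):
        # requested ~14 x 18.6 realizes the 13 x 20 grid of the same aspect
        assert hex260.grid_shape == (13, 20)
        assert abs(hex260.box.lx - 14.0) < 0.1
        assert abs(hex260.box.ly - 18.6) < 0.1
        assert hex260.requested_box == vp.PeriodicBox(14.0, 18.6)

    def test_construction_is_mechanical_equilibrium(self, hex260):
        f = vp.net_vertex_forces(hex260, vp.MechParams())
        assert np.abs(f).max() < 1e-12

    def test_zero_initial_strain_all_inactive(self, hex260):
        np.testing.assert_allclose(vp.junction_strains(hex260), 0.0, atol=1e-12)
        assert np.all(hex260.state == vp.INACTIVE)

    @pytest.mark.parametrize("bad_n", [7, 2, 13])
    def test_rejects_incommensurate_cell_counts(self, bad_n):
        with pytest.raises(ValueError, match="factored"):
            vp.make_hexagonal_tissue(bad_n)

    def test_validates(self, hex260):
        assert vp.validate_tissue(hex260).ok


class TestDisorderedTissue:
    def test_deterministic_given_seed(self):
        box = vp.PeriodicBox(6.0, 6.0)
        t1 = vp.make_disordered_tissue(36, box, seed=5)
        t2 = vp.make_disordered_tissue(36, box, seed=5)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.edges, t2.edges)
        assert np.array_equal(t1.rest_length, t2.rest_length)

    def test_mean_sidedness_is_six(self, disordered100):
        sides = np.array([len(c) for c in disordered100.cells])
        assert sides.mean() == pytest.approx(6.0, abs=1e-12)

    def test_heterogeneous_geometry(self, disordered100):
        sides = {len(c) for c in disordered100.cells}
        assert len(sides) >= 2  # mixed polygon classes
        lens = disordered100.edge_lengths()
        assert lens.std() / lens.mean() > 0.1  # varying junction lengths

    def test_equilibrated_with_zero_strain(self, disordered100):
        f = vp.net_vertex_forces(disordered100, vp.MechParams())
        assert np.abs(f).max() < 1e-6
        np.testing.assert_allclose(vp.junction_strains(disordered100), 0.0,
                                   atol=1e-12)

    def test_validates_and_partitions_box(self, disordered100):
        assert vp.validate_tissue(disordered100).ok
        assert disordered100.cell_areas().sum() == pytest.approx(
            disordered100.box.area, abs=1e-9)

    def test_rejects_too_few_cells(self):
        with pytest.raises(ValueError):
            vp.make_disordered_tissue(2, vp.PeriodicBox(5, 5), seed=1)


class TestGeometricPrimitives:
    def test_junction_geometry_direct_and_wrapped(self):
        box = vp.PeriodicBox(10.0, 10.0)
        pos = np.array([[0.0, 0.0], [0.5, 0.0], [0.2, 0.0], [9.9, 0.0]])
        t = vp.Tissue(box, pos, np.array([[0, 1], [2, 3]]), cells=[])
        d, l = vp.junction_geometry(t, 0)
        assert l == pytest.approx(0.5)
        d, l = vp.junction_geometry(t, 1)
        assert l == pytest.approx(0.3)  # wraps across the boundary
        assert l == pytest.approx(np.linalg.norm(d))

    def test_cell_area_unit_square(self):
        box = vp.PeriodicBox(10.0, 10.0)
        pos = np.array([[1.0, 1.0], [2.0, 1.0], [2.0, 2.0], [1.0, 2.0]])
        edges = np.array([[0, 1], [1, 2], [2, 3], [3, 0]])
        t = vp.Tissue(box, pos, edges, cells=[np.array([0, 1, 2, 3])])
        assert vp.cell_area(t, 0) == pytest.approx(1.0)

    def test_cell_area_rejects_clockwise_loop(self):
        box = vp.PeriodicBox(10.0, 10.0)
        pos = np.array([[1.0, 1.0], [2.0, 1.0], [2.0, 2.0], [1.0, 2.0]])
        edges = np.array([[0, 1], [1, 2], [2, 3], [3, 0]])
        t = vp.Tissue(box, pos, edges, cells=[np.array([3, 2, 1, 0])])
        with pytest.raises(ValueError, match="counterclockwise"):
            vp.cell_area(t, 0)

    def test_areas_partition_box(self, hex64, disordered100):
        for t in (hex64, disordered100):
            assert t.cell_areas().sum() == pytest.approx(t.box.area, abs=1e-9)


class TestValidation:
    def test_detects_dangling_junction(self, hex64):
        t = hex64.copy()
        t.edges = np.vstack([t.edges, [0, 7]])  # edge bordered by no cell
        t.rest_length = np.append(t.rest_length, 1.0)
        t.gamma = np.append(t.gamma, 0.0)
        t.state = np.append(t.state, vp.INACTIVE).astype(np.int8)
        t.timer = np.append(t.timer, 0.0)
        rep = vp.validate_tissue(t)
        assert not rep.ok
        assert any("junction" in f or "degree" in f or "Euler" in f
                   for f in rep.failures)

    def test_detects_negative_rest_length(self, hex64):
        t = hex64.copy()
        t.rest_length[0] = -0.1
        rep = vp.validate_tissue(t)
        assert not rep.ok
        assert any("rest length" in f for f in rep.failures)

    def test_passes_after_t1_heavy_run(self, disordered208):
        # a disordered wave run crosses several T1 events and stays valid
        excit = vp.ExcitParams(eps_on=0.1, tau_act=1.6, tau_ref=1.6, gamma0=0.5)
        t = disordered208.copy()
        vp.seed_activation(t, "single", excit)
        res = vp.run_simulation(t, vp.MechParams(k_l=0.7), excit,
                                t_end=20.0, copy=False)
        assert res.n_t1_events > 0
        assert vp.validate_tissue(res.final_tissue).ok


def test_topology_cache_slot_structure(hex64):
    top = _TopologyCache(hex64.cells)
    # every slot's next/prev stay within the same cell and invert each other
    assert np.array_equal(top.slot_cell[top.slot_next], top.slot_cell)
    assert np.array_equal(top.slot_prev[top.slot_next], np.arange(len(top.slot_vertex)))
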