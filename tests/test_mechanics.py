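import dataclasses

import numpy as np
import pytest

import vertexpulse as vp
from vertexpulse import mechanics


def jittered(tissue, scale=0.02, seed=0):
    t = tissue.copy()
    rng = np.random.default_rng(seed)
    t.positions = t.box.wrap(t.positions + rng.normal(0, scale, t.positions.shape))
    return t


class TestEnergy:
    def test_zero_for_unit_areas_without_tension(self, hex64):
        p = vp.MechParams(lam=0.0)
        assert vp.total_energy(hex64, p) == pytest.approx(0.0, abs=1e-12)

    def test_tension_term_scales_with_total_length(self, hex64):
        e0 = vp.total_energy(hex64, vp.MechParams(lam=0.0))
        e1 = vp.total_energy(hex64, vp.MechParams(lam=0.1))
        assert e1 - e0 == pytest.approx(0.1 * hex64.edge_lengths().sum())

    def test_area_term_is_quadratic(self, hex64):
        # shrink the box contents uniformly: every area drops by the same
        # factor and the elastic term follows (K/2) sum (A - A0)^2
        t = hex64.copy()
        s = 0.95
        t.positions *= s
        box = vp.PeriodicBox(hex64.box.lx * s, hex64.box.ly * s)
        t = vp.Tissue(box, t.positions, t.edges, t.cells)
        p = vp.MechParams(lam=0.0)
        expect = 0.5 * t.n_cells * (s * s - 1.0) ** 2
        assert vp.total_energy(t, p) == pytest.approx(expect, rel=1e-9)


class TestForces:
    def test_equilibrium_forces_vanish(self, hex64, disordered100):
        p = vp.MechParams()
        for t in (hex64, disordered100):
            assert np.abs(vp.net_vertex_forces(t, p)).max() < 1e-6

    def test_forces_are_minus_energy_gradient(self, hex64):
        # central differences on a deformed tissue, passive terms only
        t = jittered(hex64)
        p = vp.MechParams()
        f = vp.net_vertex_forces(t, p)
        h = 1e-6
        rng = np.random.default_rng(1)
        for v in rng.choice(t.n_vertices, 5, replace=False):
            for axis in (0, 1):
                tp = t.copy()
                tp.positions[v, axis] += h
                tm = t.copy()
                tm.positions[v, axis] -= h
                grad = (vp.total_energy(tp, p) - vp.total_energy(tm, p)) / (2 * h)
                assert -grad == pytest.approx(f[v, axis], abs=1e-5)

    def test_active_force_pair_equal_and_opposite(self, hex64):
        p = vp.MechParams()
        t = hex64.copy()
        f0 = vp.net_vertex_forces(t, p)
        j = 17
        t.gamma[j] = p.gamma0
        df = vp.net_vertex_forces(t, p) - f0
        i1, i2 = t.edges[j]
        d, l = vp.junction_geometry(t, j)
        np.testing.assert_allclose(df[i1], p.gamma0 * d, atol=1e-12)
        np.testing.assert_allclose(df[i2], -p.gamma0 * d, atol=1e-12)
        assert np.linalg.norm(df[i1]) == pytest.approx(p.gamma0 * l)
        others = np.delete(np.arange(t.n_vertices), [i1, i2])
        assert np.abs(df[others]).max() < 1e-12

    def test_total_force_is_zero(self, hex64):
        t = jittered(hex64)
        rng = np.random.default_rng(2)
        t.gamma = rng.uniform(0, 0.5, t.n_junctions)
        f = vp.net_vertex_forces(t, vp.MechParams())
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)


class TestStep:
    def test_equilibrium_is_stationary(self, hex64):
        t = hex64.copy()
        before = t.positions.copy()
        vp.step(t, vp.MechParams())
        assert np.abs(t.positions - before).max() < 1e-8

    def test_passive_relaxation_decreases_energy(self, hex64):
        t = jittered(hex64, scale=0.05)
        p = vp.MechParams(k_l=0.0)
        energies = [vp.total_energy(t, p)]
        for _ in range(200):
            vp.step(t, p)
            energies.append(vp.total_energy(t, p))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-12)

    def test_rest_length_relaxes_exponentially(self):
        # junction held at fixed length: after time 1/kL the gap l0 - l
        # shrinks by a factor e (up to Euler error O(dt))
        p = vp.MechParams(k_l=1.0, dt=0.01)
        l, l0 = 1.0, 1.5
        gap0 = l0 - l
        n = int(round((1.0 / p.k_l) / p.dt))
        for _ in range(n):
            l0 += -p.dt * p.k_l * (l0 - l)
        assert (l0 - l) / gap0 == pytest.approx(np.exp(-1.0), rel=2 * p.dt)

    def test_dt_halving_leaves_observable_unchanged(self, hex64):
        # first-order convergence: halving dt moves the strain transient
        # by far less than its own scale
        vals = []
        for dt in (0.01, 0.005):
            mech = vp.MechParams(k_l=0.7, dt=dt)
            e = vp.ExcitParams(eps_on=0.1, tau_act=1.6, tau_ref=1.6, gamma0=0.5)
            t = hex64.copy()
            vp.seed_activation(t, "single", e)
            res = vp.run_simulation(t, mech, e, t_end=2.0, copy=False)
            vals.append(res.total_strain[-1])
        assert abs(vals[0] - vals[1]) < 0.05 * abs(vals[1])


class TestT1Transitions:
    @staticmethod
    def shrink_edge(t, j, length=0.004):
        i1, i2 = t.edges[j]
        d, l = vp.junction_geometry(t, j)
        mid = t.positions[i1] + 0.5 * d
        t.positions[i1] = t.box.wrap(mid - 0.5 * length * d / l)
        t.positions[i2] = t.box.wrap(mid + 0.5 * length * d / l)

    def test_swap_resets_junction_and_conserves_topology(self, hex64):
        t = hex64.copy()
        p = vp.MechParams()
        self.shrink_edge(t, 10)
        counts = (t.n_vertices, t.n_junctions, t.n_cells)
        swapped = vp.t1_transitions(t, p)
        assert swapped == [10]
        _, l_new = vp.junction_geometry(t, 10)
        assert l_new == pytest.approx(1.5 * p.l_t1)
        assert t.rest_length[10] == pytest.approx(1.5 * p.l_t1)
        assert t.state[10] == vp.INACTIVE and t.gamma[10] == 0.0
        assert (t.n_vertices, t.n_junctions, t.n_cells) == counts
        assert vp.validate_tissue(t).ok

    def test_swap_redistributes_cell_sides(self, hex64):
        t = hex64.copy()
        self.shrink_edge(t, 10)
        vp.t1_transitions(t, vp.MechParams())
        sides = sorted(len(c) for c in t.cells)
        # the two cells sharing the old junction lose a side, the two at
        # its endpoints gain one
        assert sides.count(5) == 2 and sides.count(7) == 2
        assert sides.count(6) == t.n_cells - 4

    def test_no_short_junction_is_a_noop(self, hex64):
        t = hex64.copy()
        before = t.positions.copy()
        assert vp.t1_transitions(t, vp.MechParams()) == []
        assert np.array_equal(t.positions, before)

    def test_skips_swap_that_would_create_two_sided_cell(self, hex64):
        t = hex64.copy()
        p = vp.MechParams()
        # shrink an edge of a triangle: first make a triangle via two T1s is
        # involved, so emulate by shrinking after manually making cell 0 a
        # triangle is not possible on a hexagonal lattice; instead check the
        # guard directly on a doctored cell list
        self.shrink_edge(t, 10)
        a, b = t.edges[10]
        for ci, loop in enumerate(t.cells):
            if a in loop and b in loop:
                keep = [v for v in loop if v in (a, b)] + \
                    [v for v in loop if v not in (a, b)][:1]
                t.cells[ci] = np.array(keep)
                break
        t.invalidate_topology()
        assert vp.t1_transitions(t, p) == []  # guarded, logged as skipped


class TestEquilibrate:
    def test_restores_jittered_hexagonal_lattice(self, hex64):
        ref = hex64.positions
        t = jittered(hex64, scale=0.01)
        vp.equilibrate(t, vp.MechParams())
        d = t.box.minimum_image(t.positions - ref)
        d -= d.mean(axis=0)  # global translation is a zero mode
        assert np.abs(d).max() < 1e-4

    def test_contract_and_idempotence(self, disordered100):
        p = vp.MechParams()
        t = disordered100.copy()
        before = t.positions.copy()
        vp.equilibrate(t, p)
        assert np.abs(vp.net_vertex_forces(t, p)).max() < 1e-6
        assert np.abs(t.positions - before).max() < 1e-4  # already relaxed
        np.testing.assert_allclose(vp.junction_strains(t), 0.0, atol=1e-12)

    def test_rejects_active_tissue(self, hex64):
        t = hex64.copy()
        t.gamma[0] = 0.5
        with pytest.raises(ValueError):
            vp.equilibrate(t, vp.MechParams())

    def test_euler_method_converges_on_small_jitter(self, hex64):
        t = jittered(hex64, scale=0.001)
        vp.equilibrate(t, vp.MechParams(), method="euler")
        assert np.abs(vp.net_vertex_forces(t, vp.MechParams())).max() < 1e-6


def test_params_validation():
    with pytest.raises(ValueError):
        vp.MechParams(dt=-0.01)
    with pytest.raises(ValueError):
        vp.MechParams(lam=-0.1)
    p = dataclasses.replace(vp.MechParams(), k_l=0.0)
    assert p.k_l == 0.0  # kL = 0 (no remodeling) is legal
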