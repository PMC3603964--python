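"""Mesh geometry, finite-volume transport, moving boundary, sampling."""

import numpy as np
import pytest
from scipy.special import erf

from cryonet import params as P
from cryonet.mesh import Mesh
from cryonet.transport import (apply_iif_source, apply_membrane_source,
                               build_mesh, diffusion_step, initial_state,
                               mass_inventory, move_boundary,
                               sample_at_points)


class TestMeshGeometry:
    def test_ellipsoid_volume_oracle(self, geom, rp, mp):
        m = Mesh.axisymmetric(geom, 32, 32)
        analytic = 4.0 / 3.0 * np.pi * geom.l_maj * geom.l_min ** 2 * 1e-18
        assert m.total_volume() == pytest.approx(analytic, rel=0.01)
        nuc = m.vol[m.region == 1].sum()
        nuc_analytic = 4.0 / 3.0 * np.pi * geom.s_maj * geom.s_min ** 2 * 1e-18
        assert nuc == pytest.approx(nuc_analytic, rel=0.01)

    def test_nucleus_contained(self, geom):
        m = Mesh.axisymmetric(geom, 16, 16)
        pts = m.centroid[m.region == 1] * 1e6
        chk = (((pts[:, 1] - geom.d_nlr) / geom.s_maj) ** 2
               + (pts[:, 0] / geom.s_min) ** 2)
        assert np.all(chk < 1.0)

    def test_refinement_convergence(self, geom):
        analytic = 4.0 / 3.0 * np.pi * geom.l_maj * geom.l_min ** 2 * 1e-18
        errs = [abs(Mesh.axisymmetric(geom, n, n).total_volume() - analytic)
                for n in (8, 16, 32)]
        assert errs[2] < errs[1] < errs[0]

    def test_resolution_floor(self, geom):
        with pytest.raises(P.ConfigurationError):
            Mesh.axisymmetric(geom, 4, 4)


class TestDiffusion:
    def test_uniform_field_is_fixed_point(self, oocyte_state, rp, wp, cpa):
        st = oocyte_state
        before = st.c_w.copy()
        diffusion_step(st, 1.0, np.full(st.mesh.n_cells, 1e-11), rp, wp, cpa)
        assert np.allclose(st.c_w, before, rtol=1e-12)

    def test_zero_diffusivity_is_identity(self, oocyte_state):
        st = oocyte_state
        n_before = st.n_s.copy()
        diffusion_step(st, 1.0, np.zeros(st.mesh.n_cells))
        assert np.array_equal(st.n_s, n_before)

    def test_species_conservation(self, oocyte_state, rp, wp, cpa):
        st = oocyte_state
        st.n_s = st.n_s * (1 + 0.3 * np.random.default_rng(0).random(st.mesh.n_cells))
        totals = [st.n_w.sum(), st.n_g.sum(), st.n_s.sum()]
        for _ in range(5):
            diffusion_step(st, 0.5, np.full(st.mesh.n_cells, 2e-11), rp, wp, cpa)
        for tot, new in zip(totals, [st.n_w.sum(), st.n_g.sum(), st.n_s.sum()]):
            assert new == pytest.approx(tot, rel=1e-10)

    def test_slab_against_erf_solution(self, mp, rp):
        # salt tracer with a step profile in a uniform-water slab; compare
        # with the closed-form solution of the half-space diffusion problem
        L, n, D = 400e-6, 240, 1e-10
        mesh = Mesh.slab(L, n, section_area=1e-9)
        st = initial_state_slab(mesh, mp)
        x = mesh.centroid[:, 0]

        def analytic(t):
            return 0.5 * (1 - erf((x - L / 2) / (2 * np.sqrt(D * t))))

        t0, t1, dt = 5.0, 20.0, 0.1
        st.n_s = analytic(t0) * st.V_liq
        for _ in range(int(round((t1 - t0) / dt))):
            diffusion_step(st, dt, np.full(n, D))
        l2 = (np.linalg.norm(st.c_s - analytic(t1))
              / np.linalg.norm(analytic(t1)))
        assert l2 < 0.01


def initial_state_slab(mesh, mp):
    """Uniform water-filled slab carrying a salt tracer."""
    from cryonet.transport import FieldState

    v_liq = mesh.vol.copy()
    n_w = v_liq * (1.0 / mp.nu_w)
    return FieldState(mesh=mesh, n_w=n_w, n_g=np.zeros(mesh.n_cells),
                      n_s=np.zeros(mesh.n_cells), V_b=np.zeros(mesh.n_cells),
                      V_ice=np.zeros(mesh.n_cells), mp=mp,
                      initial_water_mol=float(n_w.sum()))


class TestMembraneSource:
    def test_zero_flux_no_change(self, sphere_state):
        st = sphere_state
        before = st.n_w.copy()
        apply_membrane_source(st, np.zeros(st.mesh.n_t), 1.0)
        assert np.array_equal(st.n_w, before)
        assert st.efflux_mol == 0.0

    def test_sphere_area_oracle(self, sphere_state):
        # uniform flux on a sphere: total loss = 4 pi r^2 J dt
        st = sphere_state
        J, dt = 1e-9, 1.0
        w0 = st.n_w.sum()
        apply_membrane_source(st, np.full(st.mesh.n_t, J), dt)
        lost_vol = (w0 - st.n_w.sum()) * st.mp.nu_w
        assert lost_vol == pytest.approx(4 * np.pi * (20e-6) ** 2 * J * dt,
                                         rel=0.01)

    def test_solutes_never_cross(self, sphere_state):
        st = sphere_state
        g0, s0 = st.n_g.sum(), st.n_s.sum()
        apply_membrane_source(st, np.full(st.mesh.n_t, 5e-9), 2.0)
        assert st.n_g.sum() == g0 and st.n_s.sum() == s0


class TestIifSource:
    def test_zero_is_identity(self, sphere_state):
        st = sphere_state
        before = st.n_w.copy()
        apply_iif_source(st, np.zeros(st.mesh.n_cells))
        assert np.array_equal(st.n_w, before)

    def test_mole_bookkeeping_oracle(self, sphere_state):
        # a 10% ice increment removes d_ice/nu_w moles of water locally
        st = sphere_state
        c = 7
        d = np.zeros(st.mesh.n_cells)
        d[c] = 0.1 * st.mesh.vol[c] * st.phi_liq[c] * st.x_vw[c]
        n_before = st.n_w[c]
        apply_iif_source(st, d)
        assert n_before - st.n_w[c] == pytest.approx(d[c] / st.mp.nu_w)
        assert st.V_ice[c] == pytest.approx(d[c])

    def test_exhaustion_bound(self, sphere_state):
        st = sphere_state
        d = st.n_w * st.mp.nu_w * 1.5
        with pytest.raises(ValueError):
            apply_iif_source(st, d)


class TestMovingBoundary:
    def test_zero_speed_identity(self, sphere_state):
        st = sphere_state
        r_before = st.mesh.R.copy()
        move_boundary(st, np.zeros(st.mesh.n_t), 1.0)
        assert np.allclose(st.mesh.R, r_before)

    def test_sphere_kinematics(self, sphere_state):
        # uniform inward speed: R(t) = R0 - v t
        st = sphere_state
        v, dt, steps = 1e-8, 1.0, 50
        r0 = st.mesh.R.mean()
        for _ in range(steps):
            move_boundary(st, np.full(st.mesh.n_t, v), dt)
        assert st.mesh.R.mean() == pytest.approx(r0 - v * dt * steps, rel=1e-6)

    def test_remap_conserves_solutes(self, oocyte_state):
        st = oocyte_state
        rng = np.random.default_rng(1)
        st.n_s = st.n_s * (1 + 0.5 * rng.random(st.mesh.n_cells))
        totals = (st.n_w.sum(), st.n_g.sum(), st.n_s.sum())
        for _ in range(20):
            move_boundary(st, np.full(st.mesh.n_t, 5e-9), 1.0)
        new = (st.n_w.sum(), st.n_g.sum(), st.n_s.sum())
        for a, b in zip(totals, new):
            assert abs(b / a - 1) < 1e-8


class TestSampling:
    def test_order0_returns_cell_values(self, oocyte_state):
        st = oocyte_state
        pts = st.mesh.centroid[[3, 50, 120]]
        out = sample_at_points(st, pts, order=0)
        assert np.allclose(out["c_w"], st.c_w[[3, 50, 120]])

    def test_linear_field_exact_order1(self, sphere_state):
        st = sphere_state
        z = st.mesh.centroid[:, 1]
        st.extra_fields = {"lin": 2.0 + 3e4 * z}
        pts = st.mesh.centroid[[10, 60, 100]] * 0.6
        out = sample_at_points(st, pts, order=1, fields=("lin",))
        expected = 2.0 + 3e4 * pts[:, 1]
        assert np.allclose(out["lin"], expected, rtol=1e-8, atol=1e-8)

    def test_quadratic_field_exact_order3(self, sphere_state):
        # axisymmetric quadratic field (even in rho) reproduced exactly
        st = sphere_state
        rho, z = st.mesh.centroid[:, 0], st.mesh.centroid[:, 1]
        f = 1.0 + 0.5e9 * rho ** 2 + 2e4 * z + 0.3e9 * z ** 2
        st.extra_fields = {"quad": f}
        rng = np.random.default_rng(7)
        pts = rng.uniform(-8e-6, 8e-6, size=(12, 2))
        out = sample_at_points(st, pts, order=3, fields=("quad",))
        expected = (1.0 + 0.5e9 * pts[:, 0] ** 2 + 2e4 * pts[:, 1]
                    + 0.3e9 * pts[:, 1] ** 2)
        assert np.max(np.abs(out["quad"] / expected - 1)) < 1e-6

    def test_outside_point_rejected(self, sphere_state):
        with pytest.raises(LookupError):
            sample_at_points(sphere_state, [[0.0, 30e-6]], order=1)


class TestMassInventory:
    def test_fresh_state(self, oocyte_state):
        inv = mass_inventory(oocyte_state)
        assert inv["ice_mol"] == 0.0
        assert inv["efflux_mol"] == 0.0
        assert inv["ledger_residual"] == pytest.approx(0.0, abs=1e-12)

    def test_closes_after_mixed_operations(self, oocyte_state, rp, wp, cpa):
        st = oocyte_state
        for _ in range(10):
            apply_membrane_source(st, np.full(st.mesh.n_t, 2e-9), 1.0)
            move_boundary(st, np.full(st.mesh.n_t, 2e-9), 1.0)
            d = np.zeros(st.mesh.n_cells)
            d[40] = 1e-4 * st.mesh.vol[40]
            apply_iif_source(st, d)
            diffusion_step(st, 1.0, np.full(st.mesh.n_cells, 1e-11), rp, wp, cpa)
        assert abs(mass_inventory(st)["ledger_residual"]) < 1e-6
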