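"""Nucleation/growth kinetics: oracles, limits, RK4 accuracy."""

import numpy as np
import pytest

from cryonet import params as P
from cryonet.iif_kinetics import (CrystalCohort, KineticNodeComposition,
                                  NodeKinetics, advance_node, c_liq,
                                  crystal_count_rate, crystal_growth_rate,
                                  ice_fraction, impingement_correction,
                                  nucleation_rates, supersaturation)
from cryonet.membrane import melting_point


def comp_fixture(**kw):
    base = dict(c_w=30000.0, c_s=150.0, c_g=5000.0, X_vice=0.0, X_vb=0.55,
                D_eff=2e-12, gamma_local=0.45)
    base.update(kw)
    return KineticNodeComposition(**base)


class TestNucleationRates:
    def test_zero_undercooling(self, nucl, mp):
        comp = comp_fixture()
        t_m = float(melting_point(comp.c_s, comp.c_g, mp))
        assert nucleation_rates(t_m, comp, 1e4, nucl, mp) == (0.0, 0.0)
        assert nucleation_rates(t_m + 5.0, comp, 1e4, nucl, mp) == (0.0, 0.0)

    def test_no_area_no_het(self, nucl, mp):
        _, j_het = nucleation_rates(250.0, comp_fixture(), 0.0, nucl, mp)
        assert j_het == 0.0

    def test_table_coefficient_oracle(self, nucl, mp):
        # independent evaluation at T = 250 K, Ae = 1e4 m^2/m^3
        j_hom, j_het = nucleation_rates(250.0, comp_fixture(), 1e4, nucl, mp)
        assert j_hom == pytest.approx(0.0, abs=1e-280)
        assert j_het == pytest.approx(8218166708.707372, rel=1e-9)

    def test_linear_in_area(self, nucl, mp):
        _, j1 = nucleation_rates(250.0, comp_fixture(), 1e4, nucl, mp)
        _, j2 = nucleation_rates(250.0, comp_fixture(), 2e4, nucl, mp)
        assert j2 == pytest.approx(2 * j1)


class TestCrystalCountRate:
    def test_no_free_volume(self, nucl, mp):
        comp = comp_fixture(X_vice=0.45, X_vb=0.55)
        assert crystal_count_rate(250.0, comp, 1e4, nucl, mp) == 0.0

    def test_free_volume_throttle(self, nucl, mp):
        full = crystal_count_rate(250.0, comp_fixture(), 1e4, nucl, mp)
        half = crystal_count_rate(
            250.0, comp_fixture(X_vice=0.225), 1e4, nucl, mp)
        # free volume falls from 0.45 to 0.225 -> rate halves
        assert half == pytest.approx(full * 0.5)


class TestGrowthRate:
    def test_diffusion_arrest(self, nucl, mp):
        comp = comp_fixture(D_eff=0.0)
        assert crystal_growth_rate(1e-6, comp, 250.0, nucl, mp) == 0.0

    def test_alpha_zero(self, mp):
        p0 = P.NucleationParams(alpha_growth=1e-300)
        assert crystal_growth_rate(1e-6, comp_fixture(), 250.0, p0, mp) == \
            pytest.approx(0.0, abs=1e-290)

    def test_rate_oracle(self, nucl, mp):
        # alpha * D_eff * S / r with the independently computed S at 250 K
        r = crystal_growth_rate(1e-6, comp_fixture(), 250.0, nucl, mp)
        assert r == pytest.approx(2.1537261911849724e-07, rel=1e-9)


class TestIceFraction:
    def test_empty(self):
        assert ice_fraction([]) == 0.0

    def test_sphere_volume_oracle(self):
        cohorts = [CrystalCohort(t_i=0.0, r_c=1e-6, n=1e15)]
        assert ice_fraction(cohorts) == pytest.approx(4.188790204786391e-3)

    def test_cubic_scaling(self):
        a = ice_fraction([CrystalCohort(0.0, 1e-6, 1e15)])
        b = ice_fraction([CrystalCohort(0.0, 2e-6, 1e15)])
        assert b == pytest.approx(8 * a)


class TestImpingement:
    def test_zero(self):
        assert impingement_correction(0.0, 0.5) == 0.0

    def test_saturation_limit(self):
        assert impingement_correction(1e6, 0.5) == pytest.approx(0.5 / 1.5)

    def test_monotone(self):
        xs = [impingement_correction(x, 0.5) for x in np.linspace(0, 3, 30)]
        assert np.all(np.diff(xs) > 0)

    def test_fixed_pair_oracle(self):
        assert impingement_correction(0.3, 0.5) == pytest.approx(
            0.1978101134198003, rel=1e-12)


class TestSupersaturation:
    def test_degenerate_no_driving_force(self, mp):
        comp = comp_fixture()
        comp.c_w = c_liq(250.0, comp, mp)
        assert supersaturation(comp, 250.0, mp) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_bulk_concentration(self, mp):
        vals = [supersaturation(comp_fixture(c_w=c), 250.0, mp)
                for c in (28000.0, 30000.0, 32000.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_oracle(self, mp):
        comp = comp_fixture()
        assert c_liq(250.0, comp, mp) == pytest.approx(26769.410713222544,
                                                       rel=1e-9)
        assert supersaturation(comp, 250.0, mp) == pytest.approx(
            0.12068212189600924, rel=1e-9)

    def test_undefined_above_melting(self, mp):
        with pytest.raises(ValueError):
            c_liq(274.0, comp_fixture(), mp)


class TestCohortIntegration:
    def test_rk4_matches_tiny_step_euler(self, nucl, mp):
        # 50 s of isothermal cohort evolution (the undercooled hold that a
        # 1 K protocol window spans at 0.02 K/s)
        def integrate(method, dt):
            node = NodeKinetics()
            t = 0.0
            while t < 50.0 - 1e-9:
                comp = comp_fixture()
                advance_node(node, comp, 251.0, 1e4, dt, nucl, mp, t_now=t,
                             method=method)
                t += dt
            return ice_fraction(node), node.C_j

        # RK4 at the production step vs brute-force explicit Euler at dt/50
        x_rk, c_rk = integrate("rk4", 0.2)
        x_eu, c_eu = integrate("euler", 0.004)
        assert x_rk == pytest.approx(x_eu, rel=5e-3)
        assert c_rk == pytest.approx(c_eu, rel=5e-3)

    def test_zero_undercooling_null(self, nucl, mp):
        node = NodeKinetics()
        comp = comp_fixture()
        t_m = float(melting_point(comp.c_s, comp.c_g, mp))
        for k in range(50):
            advance_node(node, comp, t_m + 0.5, 1e5, 1.0, nucl, mp, t_now=k)
        assert ice_fraction(node) == 0.0 and node.C_j == 0.0

    def test_cohort_merge_conserves_volume(self):
        node = NodeKinetics(r=np.linspace(1e-7, 2e-6, 40),
                            n=np.full(40, 1e12), t_i=np.arange(40.0))
        before = ice_fraction(node)
        node.merge(10)
        assert node.r.size <= 21
        assert ice_fraction(node) == pytest.approx(before, rel=1e-12)
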