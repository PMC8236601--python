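"""Three-pore endothelial transport: correlations, conductivities, fluxes."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plaquesim.endothelium import (LDLTransportParams, PoreModelParams,
                                   build_pore_state, ldl_apparent_permeability,
                                   ldl_influx, leaky_count, leaky_fraction,
                                   lj_conductivity, mitotic_count,
                                   monocyte_influx, plasma_flux, pressure_drop,
                                   single_lj_conductivity,
                                   stokes_einstein_diffusivity)
from plaquesim.errors import InvalidParameterError
from plaquesim.units import MMHG


class TestPoreStatistics:
    def test_mitotic_count_printed_values(self):
        assert mitotic_count(0.0) == pytest.approx(0.003797, rel=1e-12)
        assert mitotic_count(0.5) == pytest.approx(6.058, rel=1e-3)
        assert mitotic_count(1.0) == pytest.approx(9.667e3, rel=1e-3)

    def test_leaky_count_printed_values(self):
        assert leaky_count(0.0) == pytest.approx(0.307, rel=1e-12)
        assert leaky_count(1.0) == pytest.approx(1.112, rel=1e-12)
        assert leaky_count(6.058) == pytest.approx(2.128, rel=1e-3)

    def test_leaky_fraction_unit_value_and_linearity(self):
        # pi * (15 um)^2 / 0.64 mm^2
        assert leaky_fraction(1.0) == pytest.approx(1.1045e-3, rel=1e-4)
        assert leaky_fraction(2.0) == pytest.approx(2 * leaky_fraction(1.0))

    def test_out_of_range_inputs(self):
        with pytest.raises(InvalidParameterError):
            mitotic_count(1.5)
        with pytest.raises(InvalidParameterError):
            leaky_count(-1.0)


class TestPressureDrop:
    def test_printed_anchors_and_reference(self):
        assert pressure_drop(70.0) == pytest.approx(18.0, abs=1e-12)
        assert pressure_drop(180.0) == pytest.approx(28.0, abs=1e-12)
        assert pressure_drop(100.0) == pytest.approx(20.727, abs=1e-3)

    def test_linear_between_knots(self):
        a, b = pressure_drop(90.0), pressure_drop(110.0)
        assert pressure_drop(100.0) == pytest.approx((a + b) / 2, rel=1e-12)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="extrapolating"):
            pressure_drop(60.0)


class TestConductivities:
    def test_single_junction_value(self):
        # (20 nm)^2 / (3 * 1 mPa s * 2 um)
        assert single_lj_conductivity() == pytest.approx(6.6667e-8, rel=1e-4)

    def test_geometric_scalings(self):
        base = single_lj_conductivity()
        assert single_lj_conductivity(
            PoreModelParams(w_l=40e-9)) == pytest.approx(4 * base)
        assert single_lj_conductivity(
            PoreModelParams(l_lj=4e-6)) == pytest.approx(base / 2)

    def test_lj_conductivity_values(self):
        lp, ap_s = lj_conductivity(0.0)
        assert lp == 0.0 and ap_s == 0.0
        lp, ap_s = lj_conductivity(1.0)
        assert ap_s == pytest.approx(5.3333e-3, rel=1e-4)
        assert lp == pytest.approx(3.5556e-10, rel=1e-4)


class TestPlasmaFlux:
    def test_zero_pressure_drop_zeroes_fluxes(self):
        p = PoreModelParams(dp_table=((70.0, 0.0), (180.0, 0.0)))
        jv_nj, jv_lj, jv_v, jv = plasma_flux(1e-12, p, 100.0)
        assert jv_nj == 0.0 and jv_lj == 0.0 and jv == 0.0

    def test_normal_junction_flux_at_reference_pressure(self):
        jv_nj, jv_lj, _, jv = plasma_flux(0.0, None, 100.0)
        assert jv == pytest.approx(1.984e-12 * 20.727 * MMHG, rel=1e-4)
        assert jv == pytest.approx(5.482e-9, rel=1e-3)

    @given(st.floats(0.0, 1.0))
    def test_flux_additivity(self, si):
        pore = build_pore_state(np.array([si]))
        assert pore.jv[0] == pytest.approx(
            pore.jv_nj[0] + pore.jv_lj[0], abs=1e-15
        )
        assert pore.jv_v[0] == 0.0

    def test_chain_monotone_in_shape_index(self):
        si = np.linspace(0.0, 1.0, 100)
        pore = build_pore_state(si)
        for arr in (pore.mc, pore.lc, pore.phi_lj, pore.lp_lj, pore.jv):
            assert np.all(np.diff(arr) >= 0)
        assert np.all(pore.jv >= 0) and np.all(pore.lp_lj >= 0)


class TestLDLPermeability:
    def test_geometric_ratios(self):
        pore = build_pore_state(np.array([0.5]))
        perm = ldl_apparent_permeability(pore)
        assert perm.alpha_lj == pytest.approx(0.55)
        assert perm.chi == pytest.approx(0.45)

    @given(st.floats(0.0, 1.0))
    def test_pathway_ratios_exact(self, si):
        pore = build_pore_state(np.array([si]))
        perm = ldl_apparent_permeability(pore)
        assert perm.p_app_v == pytest.approx(0.1 * perm.p_app_lj, rel=1e-14)
        assert perm.p_app == pytest.approx(1.1 * perm.p_app_lj, rel=1e-14)

    def test_molecule_larger_than_pore_flagged(self):
        params = LDLTransportParams(a_m=25e-9)
        pore = build_pore_state(np.array([0.5]))
        with pytest.raises(InvalidParameterError, match="half-width"):
            ldl_apparent_permeability(pore, params)

    def test_stokes_einstein_default(self):
        # kT/(6 pi mu a) at 310 K for an 11 nm sphere
        assert stokes_einstein_diffusivity(11e-9) == pytest.approx(
            2.06e-11, rel=1e-2
        )
        assert LDLTransportParams().d_free == pytest.approx(2.06e-11, rel=1e-2)


class TestLDLInflux:
    def test_zero_lumen_concentration(self):
        pore = build_pore_state(np.array([0.5]))
        perm = ldl_apparent_permeability(pore)
        assert ldl_influx(0.0, perm) == pytest.approx(0.0)

    def test_linearity_in_lumen_concentration(self):
        pore = build_pore_state(np.array([0.5]))
        perm = ldl_apparent_permeability(pore)
        j1 = ldl_influx(1.0, perm)
        j2 = ldl_influx(2.0, perm)
        assert j2 == pytest.approx(2 * j1, rel=1e-14)

    def test_against_spreadsheet_style_oracle(self):
        """Re-derive the full permeability chain from raw parameters."""
        si = 0.62
        pp, lp = PoreModelParams(), LDLTransportParams()
        pore = build_pore_state(np.array([si]), pp, 100.0)
        perm = ldl_apparent_permeability(pore, lp, pp)
        j = ldl_influx(lp.c_ldl_lumen, perm, lp)

        # independent evaluation, term by term
        mc = 0.003797 * np.exp(14.75 * si)
        lc = 0.307 + 0.805 * mc**0.453
        phi = lc * np.pi * pp.r_cell**2 / pp.a_unit
        ap_s = 4 * pp.w_l / pp.r_cell * phi
        lp_slj = pp.w_l**2 / (3 * pp.mu_p * pp.l_lj)
        dp = (18.0 + (28.0 - 18.0) * (100.0 - 70.0) / 110.0) * MMHG
        jv_lj = ap_s * lp_slj * dp
        alpha = lp.a_m / pp.w_l
        chi = 1 - alpha
        hind = (1 - 1.004 * alpha + 0.418 * alpha**3 + 0.21 * alpha**4
                - 0.169 * alpha**5)
        p_slj = chi * hind * lp.d_free / pp.l_lj
        sigma = 1 - chi * (3 - chi**2) / 2
        p_app_lj = (ap_s / chi) * p_slj + jv_lj * (1 - sigma)
        expected = 1.1 * lp.c_ldl_lumen * 1e-2 * p_app_lj
        assert j[0] == pytest.approx(expected, rel=1e-10)

    def test_closure_overrides_are_honored(self):
        lp = LDLTransportParams(p_slj_override=1e-6, z_lj_override=2.0,
                                sigma_f_lj_override=1.0)
        pore = build_pore_state(np.array([0.5]))
        perm = ldl_apparent_permeability(pore, lp)
        # with sigma = 1 the solvent-drag term vanishes
        assert perm.p_app_lj == pytest.approx(perm.p_lj / 2.0, rel=1e-12)


class TestMonocyteInflux:
    def test_no_oxidized_ldl_no_recruitment(self):
        assert monocyte_influx(0.7449, 0.0) == 0.0

    def test_factor_scales_flux(self):
        lp = LDLTransportParams()
        j = monocyte_influx(0.7449, 1.0, lp)
        assert j == pytest.approx(lp.m_r * 0.7449 * lp.c_m_lumen, rel=1e-12)

    def test_linear_in_wall_oxldl(self):
        j1 = monocyte_influx(1.0, 1.0)
        j2 = monocyte_influx(1.0, 3.0)
        assert j2 == pytest.approx(3 * j1, rel=1e-14)

    def test_saturation_clamped_at_zero(self):
        assert monocyte_influx(1.0, 1.0, saturation=-0.5) == 0.0
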