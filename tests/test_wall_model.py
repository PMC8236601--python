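"""Darcy flow, the reaction network, the stiff integrator and transport."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from plaquesim.endothelium import PoreModelParams
from plaquesim.errors import ConfigurationError, InvalidParameterError, SolverError
from plaquesim.stimulus import StimulusField
from plaquesim.units import DAY, YEAR
from plaquesim.wall_model import (SPECIES, ReactionParams, SolverOptions,
                                  SpeciesFields, SpeciesTransport,
                                  advance_species, darcy_solve,
                                  integrate_reactions, make_wall_mesh,
                                  reaction_jacobian, reaction_sources,
                                  run_inflammation)

IDX = {name: k for k, name in enumerate(SPECIES)}


# --------------------------------------------------------------------------
# Darcy
# --------------------------------------------------------------------------

class TestDarcy:
    def test_uniform_influx_gives_linear_pressure_and_uniform_velocity(self):
        mesh = make_wall_mesh(0.01, 5, 30)
        pp = PoreModelParams()
        jv = np.full(5, 1e-9)
        st = darcy_solve(mesh, jv, pp, 100.0)
        # velocity equals the imposed influx everywhere (1D continuity)
        assert st.u_r == pytest.approx(1e-9, rel=1e-10)
        # pressure profile linear in the transmural direction
        second_diff = np.diff(st.p, n=2, axis=1)
        assert np.abs(second_diff).max() < 1e-8 * np.abs(st.p).max()
        # Darcy relation holds at interior faces
        kappa = pp.k_w / pp.mu_p
        grad = (st.p[:, 1:] - st.p[:, :-1]) / mesh.dr
        assert st.u_r[:, 1:-1] == pytest.approx(-kappa * grad, rel=1e-10)

    def test_slab_velocity_from_table_parameters(self):
        # u = (k_w/mu_p) * dp/h with dp = 1000 Pa over h = 0.7 mm
        pp = PoreModelParams()
        u_expected = pp.k_w / pp.mu_p * 1000.0 / 0.7e-3
        assert u_expected == pytest.approx(1.714e-9, rel=1e-3)
        mesh = make_wall_mesh(0.01, 3, 40)
        st = darcy_solve(mesh, np.full(3, u_expected), pp, 100.0)
        drop = st.p[0, 0] - pp.p_adv * 133.322
        # half-cell offset at both boundaries: drop over (nr-... ) cells
        assert drop == pytest.approx(1000.0 * (1 - 0.5 / 40), rel=1e-6)

    def test_refinement_reduces_boundary_discretization_error(self):
        pp = PoreModelParams()
        u = 1.714e-9
        errs = []
        for nr in (10, 20):
            mesh = make_wall_mesh(0.01, 3, nr)
            st = darcy_solve(mesh, np.full(3, u), pp, 100.0)
            drop = st.p[0, 0] - pp.p_adv * 133.322
            errs.append(abs(drop - 1000.0))
        assert errs[1] <= 0.55 * errs[0]

    def test_missing_anchor_is_configuration_error(self):
        mesh = make_wall_mesh(0.01, 3, 5)
        with pytest.raises(ConfigurationError):
            darcy_solve(mesh, np.zeros(3), None, 100.0, adventitia_anchor=False)


# --------------------------------------------------------------------------
# reaction network
# --------------------------------------------------------------------------

class TestReactionSources:
    def test_all_zero_state_is_stationary(self):
        p = ReactionParams()
        assert np.all(reaction_sources(np.zeros(9), p) == 0.0)

    def test_jacobian_matches_finite_differences(self):
        p = ReactionParams()
        rng = np.random.default_rng(7)
        y = rng.uniform(0.1, 1.0, 9) * p.reference_scales()
        jac = reaction_jacobian(y, p)
        for j in range(9):
            h = 1e-6 * max(abs(y[j]), 1e-30)
            yp, ym = y.copy(), y.copy()
            yp[j] += h
            ym[j] -= h
            fd = (reaction_sources(yp, p) - reaction_sources(ym, p)) / (2 * h)
            tol = 1e-5 * np.abs(fd).max() + 1e-12
            assert jac[:, j] == pytest.approx(fd, rel=1e-4, abs=tol)

    def test_collagen_steady_state(self):
        """Frozen SSMC population drives collagen to g_r*c_ssmc/d_g."""
        p = replace(ReactionParams(), s_r=0.0, p_ss=0.0, r_apop=0.0)
        ssmc = 1e13
        y0 = np.zeros((1, 9))
        y0[0, IDX["ssmc"]] = ssmc
        y = integrate_reactions(y0, 10.0 / p.d_g, p, rtol=1e-7)
        expected = p.g_r * ssmc / p.d_g
        assert y[0, IDX["g"]] == pytest.approx(expected, rel=1e-2)
        assert y[0, IDX["ssmc"]] == pytest.approx(ssmc, rel=1e-9)

    def test_csmc_saturated_cytokine_decay(self):
        """With saturating cytokines CSMCs decay as exp(-s_r*t)."""
        p = replace(ReactionParams(), d_c=0.0, c_r=0.0)
        c = 1e4 * p.k_c * p.c_c_th  # deep saturation, s1 ~ 1
        y0 = np.zeros((1, 9))
        y0[0, IDX["csmc"]] = p.c_csmc0
        y0[0, IDX["c"]] = c
        t_end = 2.0 / p.s_r
        y = integrate_reactions(y0, t_end, p, rtol=1e-7)
        s1 = c / (p.k_c * p.c_c_th + c)
        assert y[0, IDX["csmc"]] == pytest.approx(
            p.c_csmc0 * np.exp(-p.s_r * s1 * t_end), rel=1e-3
        )


class TestStiffIntegrator:
    def test_logistic_growth_against_closed_form(self):
        """TR-BDF2 resolves the nonlinear SSMC logistic to tolerance."""
        p = replace(ReactionParams(), s_r=0.0, r_apop=0.0, g_r=0.0)
        c = 1e4 * p.c_c_th  # s2 ~ 1
        y0 = np.zeros((1, 9))
        y0[0, IDX["ssmc"]] = 0.01 * p.c_ssmc_th
        y0[0, IDX["c"]] = c
        p = replace(p, d_c=0.0, c_r=0.0)
        t_end = 30.0 * DAY
        y = integrate_reactions(y0, t_end, p, rtol=1e-7)
        s2 = c / (p.c_c_th / 2 + c)
        r = p.p_ss * s2
        k = p.c_ssmc_th
        x0 = 0.01 * k
        expected = k / (1 + (k / x0 - 1) * np.exp(-r * t_end))
        assert y[0, IDX["ssmc"]] == pytest.approx(expected, rel=1e-3)

    def test_stiff_relaxation_with_large_horizon(self):
        """The fast SSMC apoptosis (tau ~ 11 s) over a 1-year span."""
        p = ReactionParams()
        y0 = np.zeros((2, 9))
        y0[:, IDX["ssmc"]] = 1e12
        y = integrate_reactions(y0, YEAR, p, rtol=1e-6)
        assert np.all(y[:, IDX["ssmc"]] < 1.0)
        assert np.all(y >= 0.0)

    def test_matches_scipy_bdf_on_full_network(self):
        p = ReactionParams()
        y0 = np.zeros(9)
        y0[IDX["ldl"]] = 0.02
        y0[IDX["ldlox"]] = 0.01
        y0[IDX["m"]] = 1e11
        y0[IDX["M"]] = 1e10
        y0[IDX["csmc"]] = p.c_csmc0
        t_end = 2.0 * YEAR
        mine = integrate_reactions(y0[None, :].copy(), t_end, p, rtol=1e-7)[0]
        ref = solve_ivp(lambda t, y: reaction_sources(y, p), (0, t_end), y0,
                        method="BDF", rtol=1e-9,
                        atol=1e-12 * p.reference_scales(),
                        jac=lambda t, y: reaction_jacobian(y, p)).y[:, -1]
        scale = p.reference_scales()
        assert np.all(np.abs(mine - ref) / (np.abs(ref) + 1e-8 * scale) < 1e-2)


# --------------------------------------------------------------------------
# transport
# --------------------------------------------------------------------------

class TestTransport:
    def test_mass_conserved_without_sources_or_fluxes(self):
        """Zero-source, zero-flux step conserves every diffusing species."""
        mesh = make_wall_mesh(0.01, 8, 10)
        p = ReactionParams()
        tr = SpeciesTransport(mesh, None, p, linear_reactions_in_transport=False)
        state = SpeciesFields.initial(mesh, p)
        rng = np.random.default_rng(0)
        for name in ("ldl", "ldlox", "m", "M"):
            state[name][...] = rng.uniform(0.5, 1.5, (mesh.nx, mesh.nr))
        before = state.total_mass(mesh)
        tr.step(state, {}, 5.0 * DAY)
        after = state.total_mass(mesh)
        for name in ("ldl", "ldlox", "m", "M"):
            k = IDX[name]
            assert abs(after[k] - before[k]) / before[k] < 1e-6

    def test_gaussian_profile_matches_heat_kernel(self):
        """Free diffusion of oxidized LDL follows the analytic spread."""
        nr = 200
        mesh = make_wall_mesh(0.01, 3, nr, thickness=0.7e-3)
        p = ReactionParams()
        tr = SpeciesTransport(mesh, None, p, linear_reactions_in_transport=False)
        state = SpeciesFields.initial(mesh, p)
        d = p.d_ldlox_w
        x = mesh.r
        x0, sig0 = 0.35e-3, 50e-6
        state["ldlox"][...] = np.exp(-((x - x0) ** 2) / (2 * sig0**2))[None, :]
        t_end, n_steps = 1500.0, 150
        for _ in range(n_steps):
            tr.step(state, {}, t_end / n_steps)
        sig = np.sqrt(sig0**2 + 2 * d * t_end)
        expected = sig0 / sig * np.exp(-((x - x0) ** 2) / (2 * sig**2))
        err = np.abs(state["ldlox"][0] - expected).max()
        assert err < 0.01 * expected.max()

    def test_endothelial_influx_adds_expected_mass(self):
        mesh = make_wall_mesh(0.01, 4, 10)
        p = ReactionParams()
        tr = SpeciesTransport(mesh, None, p, linear_reactions_in_transport=False)
        state = SpeciesFields.initial(mesh, p)
        j = np.full(4, 1e-9)
        dt = DAY
        audit = tr.step(state, {"ldl": j}, dt)
        expected = float(np.sum(j) * mesh.ds * dt)
        assert audit["influx_ldl"] == pytest.approx(expected, rel=1e-12)
        assert state.total_mass(mesh)[IDX["ldl"]] == pytest.approx(
            expected, rel=1e-10
        )

    def test_implicit_monocyte_saturation_bounds_wall_concentration(self):
        """A huge recruitment flux cannot push c_m beyond its threshold."""
        mesh = make_wall_mesh(0.01, 4, 10)
        p = ReactionParams()
        tr = SpeciesTransport(mesh, None, p, linear_reactions_in_transport=False)
        state = SpeciesFields.initial(mesh, p)
        j0 = np.full(4, 1e9)  # ~1000x the saturation-limited level
        for _ in range(5):
            tr.step(state, {}, 10 * DAY,
                    saturated_influx={"m": (j0, p.c_m_th)})
        assert state["m"].max() <= p.c_m_th * (1 + 1e-9)


# --------------------------------------------------------------------------
# full runs (scaled down)
# --------------------------------------------------------------------------

def _uniform_stimulus(mesh, tawss, osi, mode="combined"):
    from plaquesim.stimulus import (CorrelationParams, atheroprone_mask,
                                    shape_index)
    n = mesh.nx
    tawss = np.full(n, tawss)
    osi = np.full(n, osi)
    si = shape_index(mode, tawss, osi, CorrelationParams())
    mask = atheroprone_mask(tawss, osi, mode, CorrelationParams())
    return StimulusField(mesh.s.copy(), tawss, osi, si, mask, mode)


class TestInflammationRun:
    def test_trajectory_invariants_on_patch_run(self, small_patch_run):
        """Non-negativity, monotone CSMC decay and FC growth, SMC bound."""
        result, _ = small_patch_run
        p = ReactionParams()
        prev = None
        for state in result.states:
            assert np.all(state.data >= 0.0)
            smc_sum = state["csmc"] + state["ssmc"]
            assert np.all(smc_sum <= 1.05 * max(p.c_csmc0, p.c_ssmc_th))
            if prev is not None:
                assert np.all(state["csmc"] <= prev["csmc"] + 1e-6 * p.c_csmc0)
                assert np.all(state["fc"] >= prev["fc"] - 1e-12)
            prev = state

    def test_atheroprotective_stimulus_keeps_wall_quiescent(self):
        mesh = make_wall_mesh(0.01, 4, 5)
        stim = _uniform_stimulus(mesh, 3.0, 0.01)
        res = run_inflammation(mesh, stim, horizon=2 * YEAR,
                               options=SolverOptions(dt_init=DAY))
        p = ReactionParams()
        assert res.final["fc"].max() < 1e-3 * p.c_ssmc_th
        assert res.final["M"].max() == 0.0

    def test_ldl_ledger_closes_on_short_run(self):
        mesh = make_wall_mesh(0.01, 6, 8)
        stim = _uniform_stimulus(mesh, 0.5, 0.35)
        res = run_inflammation(mesh, stim, horizon=1 * YEAR)
        led = res.ledger
        lhs = led["final_ldl"] - led["initial_ldl"] + led["oxidized_ldl"]
        rhs = led["influx_ldl"] - led["outflux_adv_ldl"]
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_solver_tolerance_robustness(self):
        """Halving the macro step and tightening rtol moves 30-y FC < 0.5 %."""
        mesh = make_wall_mesh(0.01, 6, 8)
        stim = _uniform_stimulus(mesh, 0.5, 0.35)
        base = run_inflammation(
            mesh, stim, horizon=30 * YEAR,
            options=SolverOptions(rtol=1e-5, dt_max=30 * DAY))
        tight = run_inflammation(
            mesh, stim, horizon=30 * YEAR,
            options=SolverOptions(rtol=5e-6, dt_max=15 * DAY))
        fc0 = base.final["fc"]
        fc1 = tight.final["fc"]
        assert np.abs(fc1 - fc0).max() < 5e-3 * fc0.max()

    def test_blowup_guard_aborts_with_diagnostics(self):
        mesh = make_wall_mesh(0.01, 4, 5)
        stim = _uniform_stimulus(mesh, 3.0, 0.01)
        p = ReactionParams()
        bad = SpeciesFields.initial(mesh, p)
        bad["ldlox"][...] = 1e5  # far beyond 1e3 x reference
        with pytest.raises(SolverError, match="blow-up"):
            run_inflammation(mesh, stim, horizon=YEAR, initial_state=bad)

    def test_determinism_of_repeated_runs(self):
        mesh = make_wall_mesh(0.01, 4, 5)
        stim = _uniform_stimulus(mesh, 0.5, 0.35)
        a = run_inflammation(mesh, stim, horizon=0.5 * YEAR)
        b = run_inflammation(mesh, stim, horizon=0.5 * YEAR)
        assert np.array_equal(a.final.data, b.final.data)


class TestMeshValidation:
    def test_minimum_transmural_resolution(self):
        with pytest.raises(InvalidParameterError):
            make_wall_mesh(0.01, 4, 2)

    def test_negative_rates_rejected(self):
        with pytest.raises(InvalidParameterError):
            ReactionParams(d_ldl=-1.0)
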