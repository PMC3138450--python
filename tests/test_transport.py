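"""Transport-solver tests: conservation, steady states, and the radial oracle."""

import numpy as np
import pytest

import isletsim as isl
import isletsim.fem as fem
import isletsim.kinetics as kin
from isletsim.flow import VelocityField
from isletsim.geometry import INLET, OUTLET, TISSUE, radial_grid
from isletsim.radial import RadialSystem
from isletsim.transport import (Protocol, TransportSystem, glucose_inflow,
                                initial_state, outflow_insulin_flux, simulate)


class TestGlucoseInflow:
    def test_staircase_levels_at_plateaus(self):
        proto = Protocol(c_low=1.0, steps=((600.0, 2.0), (1200.0, 4.0)), tau=30.0,
                         duration=1800.0)
        assert glucose_inflow(0.0, proto) == pytest.approx(1.0)
        assert glucose_inflow(900.0, proto) == pytest.approx(3.0)
        assert glucose_inflow(1700.0, proto) == pytest.approx(7.0)

    def test_half_step_at_event_time(self):
        proto = Protocol(c_low=1.0, steps=((600.0, 14.0),), tau=30.0, duration=1200.0)
        assert glucose_inflow(600.0, proto) == pytest.approx(8.0)

    def test_bad_protocols_rejected(self):
        with pytest.raises(ValueError):
            Protocol(steps=((60.0, 1.0), (30.0, 1.0)))
        with pytest.raises(ValueError):
            Protocol(c_low=-1.0)


def test_mass_conservation_with_reactions_off(empty_chamber_mesh):
    """With all reactions off, inventory change balances net boundary flux.

    Plug flow (exactly divergence-free), a smoothed glucose pulse, and the
    backward-Euler quadrature of the boundary fluxes: the discrete balance
    must close to well under 0.1% of the inventory swing.
    """
    mesh = empty_chamber_mesh
    n = mesh.n_nodes
    u = np.zeros((n, 2))
    u[:, 0] = 1e-4
    vel = VelocityField(u=u, p=np.zeros(n), reynolds=0.57)
    system = TransportSystem(mesh, vel)
    proto = Protocol(c_low=1.0, steps=((50.0, 10.0), (200.0, -10.0)), tau=20.0,
                     duration=350.0)
    inlet_e = mesh.boundary_edges[mesh.boundary_tag == INLET]
    outlet_e = mesh.boundary_edges[mesh.boundary_tag == OUTLET]
    ones_times_ux = vel.u[:, 0]

    state = system.steady_state(1.0, proto.c_oxy_in)
    inv0 = float(np.sum(system.Ml * state.c_gluc))
    net = 0.0
    invs = [inv0]
    t, dt = 0.0, 0.5
    while t < proto.duration - 1e-9:
        t += dt
        state = system.step(state, dt, t, proto, reactions=False)
        out = fem.boundary_product_integral(mesh.points, outlet_e, state.c_gluc,
                                            ones_times_ux)
        inn = fem.boundary_product_integral(mesh.points, inlet_e, state.c_gluc,
                                            ones_times_ux)
        net += dt * (out - inn)
        invs.append(float(np.sum(system.Ml * state.c_gluc)))
    drift = abs(invs[-1] - inv0 + net)
    swing = max(invs) - min(invs)
    assert drift < 1e-3 * swing


class TestInitialState:
    def test_no_islets_uniform_fields(self, empty_chamber_mesh):
        """Inflow values propagate as (near-)uniform fields: constants are
        preserved up to the discrete-divergence consistency error of the
        stabilized flow field, O(h^2) at this resolution."""
        vel = isl.solve_steady_flow(empty_chamber_mesh)
        system = TransportSystem(empty_chamber_mesh, vel)
        proto = Protocol(c_low=3.0, duration=60.0)
        st = initial_state(system, proto)
        assert np.allclose(st.c_gluc, 3.0, rtol=1.5e-2)
        assert np.allclose(st.c_oxy, 0.200, rtol=1.5e-2)
        assert np.allclose(st.c_ins, 0.0, atol=1e-15)

    def test_low_glucose_secretion_under_one_percent_of_high(self, two_islet_system):
        s1 = two_islet_system.steady_state(1.0, 0.200)
        s15 = two_islet_system.steady_state(15.0, 0.200)
        assert (two_islet_system.total_secretion(s1)
                < 0.01 * two_islet_system.total_secretion(s15))

    def test_center_oxygen_deficit_scale(self, single_islet_mesh):
        """Interior oxygen minimum at the islet center, deficit of the
        zeroth-order magnitude (R0 a^2 / 4 D_t for a planar disk section)."""
        vel = isl.solve_steady_flow(single_islet_mesh)
        system = TransportSystem(single_islet_mesh, vel)
        st = system.steady_state(1.0, 0.200)
        tn = system.tissue_nodes
        isp = single_islet_mesh.chamber.islets[0]
        pts = single_islet_mesh.points[tn]
        r = np.hypot(pts[:, 0] - isp.center[0], pts[:, 1] - isp.center[1])
        surface = float(st.c_oxy[tn][np.abs(r - isp.radius) < 1e-9].mean())
        center = st.c_oxy[tn].min()
        r0 = 0.034 * float(kin.glucose_metabolic_factor(1.0))
        deficit = r0 * isp.radius ** 2 / (4 * 2.0e-9)
        assert surface - center == pytest.approx(deficit, rel=0.15)


class TestOutflowFlux:
    def test_zero_field_zero_flux(self, two_islet_system):
        st = two_islet_system.steady_state(1.0, 0.2)
        zero = st.copy()
        zero.c_ins = np.zeros_like(zero.c_ins)
        assert outflow_insulin_flux(zero, two_islet_system) == 0.0

    def test_uniform_field_times_outflow_rate(self, two_islet_system):
        st = two_islet_system.steady_state(1.0, 0.2)
        uni = st.copy()
        uni.c_ins = np.full_like(uni.c_ins, 2.5)
        assert outflow_insulin_flux(uni, two_islet_system) == pytest.approx(
            2.5 * two_islet_system.outflow_rate, rel=1e-9)

    def test_steady_outflux_equals_total_secretion(self, two_islet_system):
        st = two_islet_system.steady_state(15.0, 0.200)
        assert outflow_insulin_flux(st, two_islet_system) == pytest.approx(
            two_islet_system.total_secretion(st), rel=0.02)


class TestSteadyProperties:
    def test_secretion_monotone_in_po2(self, two_islet_system):
        sec = [two_islet_system.total_secretion(
            two_islet_system.steady_state(15.0, p / 700.0))
            for p in (20.0, 45.0, 90.0, 140.0)]
        assert all(a <= b * (1 + 1e-9) for a, b in zip(sec, sec[1:]))

    def test_oxygen_minimum_inside_islets(self, two_islet_system):
        st = two_islet_system.steady_state(15.0, 0.200)
        mesh = two_islet_system.mesh
        interior = st.c_oxy[two_islet_system.tissue_nodes].min()
        assert interior == st.c_oxy.min()

    def test_enriched_oxygen_changes_nothing(self, two_islet_system):
        """Inflow at 720 mmHg vs atmospheric 140 mmHg: identical secretion."""
        s140 = two_islet_system.steady_state(15.0, 140 / 700.0)
        s720 = two_islet_system.steady_state(15.0, 720 / 700.0)
        a = two_islet_system.total_secretion(s140)
        b = two_islet_system.total_secretion(s720)
        assert abs(b / a - 1) < 0.01


class TestRadialOracle:
    def test_zeroth_order_oxygen_profile_matches_closed_form(self):
        """Constant consumption in the islet, Dirichlet surface: the steady
        profile must match c(r) = c_s − (R0/6D)(a² − r²) inside the islet."""
        a, r0, cs = 75e-6, 0.034, 0.200
        grid = radial_grid(2 * a, medium_shell=1e-6, n_nodes=200)
        system = RadialSystem(grid, oxygen_rate=lambda co, cg: np.full_like(co, -r0),
                              glucose_rate=lambda cg, co: np.zeros_like(cg))
        res = system.steady_state(cs, 3.0)
        r = grid.radii
        inside = r <= a
        d_tis = 2.0e-9
        exact = cs - r0 / (6 * d_tis) * (a ** 2 - r[inside] ** 2)
        # surface value from the solver (tiny medium shell) anchors the profile
        offset = res.c_oxy[np.argmin(np.abs(r - a))] - cs
        assert np.max(np.abs(res.c_oxy[inside] - offset - exact)) < 0.01 * cs

    def test_small_islet_dose_response_recovers_local_hill(self):
        """A 50-um islet at ample oxygen has negligible internal gradients, so
        its normalized dose-response equals the local sigmoid rate law."""
        grid = radial_grid(50e-6, medium_shell=200e-6, n_nodes=100)
        system = RadialSystem(grid)
        for c in (3.0, 7.0, 15.0):
            res = system.steady_state(0.200, c)
            v_tis = system.v_tissue.sum()
            frac = res.total_secretion / (v_tis * 3.0e-5)
            assert frac == pytest.approx(float(kin.hill_fraction(c, 7.0, 2.5)),
                                         rel=0.02)

    def test_radial_vs_2d_center_oxygen(self):
        """Cross-solver check: matched islet-surface oxygen, compare centers.

        A 120-um islet keeps the planar-section/spherical geometric
        difference in the interior profile small relative to the center
        value, so the two solvers must agree closely there."""
        spec = isl.ChamberSpec(islets=(isl.IsletSpec((6e-3, 2e-3), 120e-6),))
        mesh = isl.mesh_geometry(isl.build_chamber(spec), resolution=300e-6, seed=0)
        system2d = TransportSystem(mesh, isl.solve_steady_flow(mesh))
        st = system2d.steady_state(3.0, 0.200)
        isp = mesh.chamber.islets[0]
        pts = mesh.points[system2d.tissue_nodes]
        r = np.hypot(pts[:, 0] - isp.center[0], pts[:, 1] - isp.center[1])
        on_surface = np.abs(r - isp.radius) < 1e-9
        c_surface = float(st.c_oxy[system2d.tissue_nodes][on_surface].mean())
        grid = radial_grid(isp.diameter, medium_shell=1e-6, n_nodes=150)
        res = RadialSystem(grid).steady_state(c_surface, 3.0)
        center_2d = float(st.c_oxy[system2d.tissue_nodes].min())
        center_radial = float(res.c_oxy[0])
        assert center_2d == pytest.approx(center_radial, rel=0.05)

    def test_local_insulin_decays_with_k_insL(self):
        """Zero secretion: the local compartment empties exponentially with a
        half-life of ln2 / k_insL ≈ 4 min."""
        grid = radial_grid(150e-6, medium_shell=200e-6, n_nodes=80)
        system = RadialSystem(grid, diffusion=isl.DiffusionSet(ins=(3e-9, 3e-9, 3e-9)))
        st0 = system.steady_state(0.200, 1.0)       # essentially no secretion
        base = float(st0.c_insL[0])
        st0.c_insL[system.v_tissue > 0] += 1.0e-3   # load the local pool
        res = system.simulate(lambda t: (0.200, 1.0), duration=300.0, state0=st0)
        # decay of the excess over the steady level, at the islet center
        ratio = (res.c_insL[0] - base) / 1.0e-3
        k_fit = -np.log(ratio) / 300.0
        assert k_fit == pytest.approx(0.003, rel=0.1)
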