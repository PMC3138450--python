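"""Perifusion drivers and the analysis layer (biphasic traces, sweeps, fits)."""

import numpy as np
import pytest

import isletsim as isl
import isletsim.kinetics as kin
from isletsim.protocols import (DoseResponsePoint, encapsulation_compare,
                                extract_dose_response, fit_hill, oxygen_sweep,
                                run_staircase, run_single_step,
                                cross_section_profiles)
from isletsim.transport import Protocol, TransportSystem


@pytest.fixture(scope="session")
def staircase_result(two_islet_system):
    """Reduced staircase G1 -> G5 -> G10 -> G15 with 12-min plateaus."""
    proto = Protocol(c_low=1.0, steps=((120.0, 4.0), (840.0, 5.0), (1560.0, 5.0)),
                     tau=30.0, c_oxy_in=0.200, duration=2280.0)
    return run_staircase(two_islet_system, proto)


class TestBiphasicStaircase:
    def test_every_upward_step_peaks_above_plateau(self, staircase_result):
        for s in staircase_result.steps:
            assert s.peak > s.plateau, f"no first-phase peak at step to {s.level} mM"

    def test_plateaus_monotone_in_glucose(self, staircase_result):
        plats = [s.plateau for s in staircase_result.steps]
        assert all(a < b for a, b in zip(plats, plats[1:]))

    def test_insulin_bookkeeping_closes(self, two_islet_system, staircase_result):
        """Cumulative outflow = cumulative secretion − inventory change (1%)."""
        d = staircase_result.trace.diagnostics
        st0 = two_islet_system.steady_state(1.0, 0.200)
        st1 = staircase_result.trace.final_state
        inv0 = float(np.sum(two_islet_system.Ml * (st0.c_ins + st0.c_insL)))
        inv1 = float(np.sum(two_islet_system.Ml * (st1.c_ins + st1.c_insL)))
        lhs = d["cumulative_outflow"] + (inv1 - inv0)
        assert lhs == pytest.approx(d["cumulative_secretion"], rel=0.01)

    def test_flux_nonnegative(self, staircase_result):
        assert staircase_result.trace.outflow_flux.min() >= 0.0


@pytest.fixture(scope="module")
def step_result(two_islet_system):
    return run_single_step(two_islet_system, c_low=1.0, c_high=15.0,
                           t_up=120.0, t_down=720.0, duration=2100.0)


class TestSingleStep:
    def test_returns_toward_baseline_after_step_down(self, step_result):
        t, f = step_result.trace.t, step_result.trace.outflow_flux
        base = f[t < 100].mean()
        peak = f.max()
        assert f[-1] < base + 0.15 * (peak - base)

    def test_larger_step_gives_larger_first_phase_peak(self, two_islet_system,
                                                       step_result):
        """G1 -> G15 beats G10 -> G15 (same final level, smaller gradient)."""
        small = run_staircase(two_islet_system, Protocol(
            c_low=10.0, steps=((120.0, 5.0),), tau=30.0, duration=900.0))
        t, f = step_result.trace.t, step_result.trace.outflow_flux
        big_peak_rise = f[(t > 120) & (t < 720)].max() - f[t < 100].mean()
        s = small.trace
        small_peak_rise = (s.outflow_flux[(s.t > 120) & (s.t < 720)].max()
                           - s.outflow_flux[s.t < 100].mean())
        assert big_peak_rise > small_peak_rise


@pytest.fixture(scope="module")
def sweep(two_islet_system):
    return oxygen_sweep(two_islet_system, po2_list=(140, 80, 60, 45, 30, 20, 10))


class TestOxygenSweep:
    def test_reference_fraction_is_one(self, sweep):
        i = np.where(sweep.po2_mmHg == 140.0)[0][0]
        assert sweep.fraction_of_normoxic[i] == pytest.approx(1.0)

    def test_monotone_nonincreasing_with_hypoxia(self, sweep):
        f = sweep.fraction_of_normoxic  # ordered by increasing pO2
        assert np.all(np.diff(f) >= -1e-9)

    def test_half_max_po2_in_band(self, sweep):
        assert 15.0 <= sweep.half_max_po2_mmHg <= 60.0

    def test_larger_islet_more_affected_by_hypoxia(self, two_islet_system):
        import isletsim.fem as fem
        from isletsim.geometry import TISSUE
        mesh = two_islet_system.mesh
        masses = [fem.mass(mesh.points, mesh.triangles, lumped=True,
                           element_mask=(mesh.subdomain == TISSUE)
                           & (mesh.islet_index == i)) for i in range(2)]
        fr = []
        s140 = two_islet_system.steady_state(15.0, 140 / 700)
        s30 = two_islet_system.steady_state(15.0, 30 / 700)
        for m in masses:
            hi = float(np.sum(m * two_islet_system.secretion_field(s140)))
            lo = float(np.sum(m * two_islet_system.secretion_field(s30)))
            fr.append(lo / hi)
        # islet 0 is the 100-um islet, islet 1 the 150-um islet
        assert fr[1] < fr[0]


class TestEncapsulation:
    def test_encapsulated_never_exceeds_free(self, two_islet_system,
                                             encapsulated_system):
        res = encapsulation_compare(two_islet_system, encapsulated_system,
                                    po2_values=(140.0, 45.0))
        assert np.all(res.ratio_encapsulated_over_free <= 1.0 + 1e-6)

    def test_hypoxia_hits_encapsulated_harder(self, two_islet_system,
                                              encapsulated_system):
        res = encapsulation_compare(two_islet_system, encapsulated_system,
                                    po2_values=(140.0, 45.0))
        assert (res.encapsulated_fraction_of_normoxic[1]
                < res.free_fraction_of_normoxic[1])


class TestDoseResponse:
    def test_extract_monotone_and_normalized(self, staircase_result):
        pts = extract_dose_response(staircase_result, normalize=True)
        sec = [p.secretion for p in pts]
        assert sec == sorted(sec)
        assert max(sec) == 1.0
        assert pts[0].secretion < 0.02   # G1 point essentially zero


class TestFitHill:
    def _synthetic(self, n=2.5, c_half=7.0, r_max=3e-5):
        c = np.array([1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0, 30.0])
        y = r_max * c ** n / (c ** n + c_half ** n)
        return c, y

    def test_exact_recovery(self):
        c, y = self._synthetic()
        fit = fit_hill((c, y))
        assert fit.n == pytest.approx(2.5, rel=0.01)
        assert fit.c_half == pytest.approx(7.0, rel=0.01)
        assert fit.r_max == pytest.approx(3e-5, rel=0.01)

    def test_restricted_fit_has_larger_residual(self):
        c, y = self._synthetic()
        free = fit_hill((c, y))
        mm = fit_hill((c, y), fix_n=1.0)
        assert mm.n_fixed and mm.n == 1.0
        assert mm.residual > free.residual

    def test_noisy_recovery_median_over_seeds(self):
        """1% multiplicative noise: median recovered n within ±0.2, c_half ±5%."""
        c, y = self._synthetic()
        ns, chs = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            fit = fit_hill((c, y * (1 + 0.01 * rng.standard_normal(len(c)))))
            ns.append(fit.n)
            chs.append(fit.c_half)
        assert abs(np.median(ns) - 2.5) < 0.2
        assert abs(np.median(chs) / 7.0 - 1) < 0.05

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            fit_hill((np.array([1.0, 2, 3]), np.array([1.0, 1, 1])))

    def test_simulated_small_islet_dose_response(self):
        """Dose-response of a small normoxic islet recovers the local Hill law."""
        from isletsim.radial import RadialSystem
        grid = isl.radial_grid(50e-6, medium_shell=200e-6, n_nodes=80)
        system = RadialSystem(grid)
        c = np.array([1.0, 3.0, 5.0, 7.0, 10.0, 15.0, 30.0])
        y = np.array([system.steady_state(0.200, g).total_secretion for g in c])
        fit = fit_hill((c, y))
        assert fit.n == pytest.approx(2.5, rel=0.10)
        assert fit.c_half == pytest.approx(7.0, rel=0.10)


class TestCrossSection:
    def test_profiles_through_islets(self, two_islet_system):
        st = two_islet_system.steady_state(10.0, 45 / 700)
        mesh = two_islet_system.mesh
        isp = mesh.chamber.islets[1]          # the 150-um islet
        x = isp.center[0]
        s, c_oxy, r_ins = cross_section_profiles(
            two_islet_system, st, (x, 0.5e-3), (x, 3.5e-3), n=400)
        # oxygen dips at the islet; minimum well inside the islet band
        i_min = np.argmin(c_oxy)
        assert abs(s[i_min] - (isp.center[1] - 0.5e-3)) < isp.radius * 1.5
        # glucose relative deficit far smaller than oxygen's
        gi = st.c_gluc[two_islet_system.tissue_nodes]
        oi = st.c_oxy[two_islet_system.tissue_nodes]
        assert (1 - gi.min() / gi.max()) < 0.2 * (1 - oi.min() / oi.max())

    def test_line_outside_domain_rejected(self, two_islet_system):
        st = two_islet_system.steady_state(3.0, 0.2)
        with pytest.raises(ValueError):
            cross_section_profiles(two_islet_system, st, (-1e-3, 2e-3),
                                   (5e-3, 2e-3))
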