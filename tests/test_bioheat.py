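"""Pennes bioheat solver: equilibria, analytic oracles, scheme agreement,
energy accounting, and linearity."""

import numpy as np
import pytest

from pttsim.bioheat import (
    ThermalScenario,
    _HeatSystem,
    _ftcs_steps,
    perfusion_source,
    run_transient,
    step_heat,
)
from pttsim.domain import TissueLayer, build_domain, hazard_shell
from pttsim.optics.mixing import MediumOpticalProperties
from conftest import make_uniform_domain

OPTICS = MediumOpticalProperties(mu_abs=0.047, mu_sca=0.883, g=0.8)


class TestPerfusionSource:
    def test_vanishes_at_arterial_temperature(self):
        layer = TissueLayer.from_table("tumor")
        sc = ThermalScenario()
        assert perfusion_source(37.0, layer, sc) == 0.0

    def test_avascular_layer_never_contributes(self):
        epi = TissueLayer.from_table("epidermis")
        sc = ThermalScenario()
        assert perfusion_source(80.0, epi, sc) == 0.0

    def test_tumor_magnitude(self):
        """rho_b w_b c_b (T_b - T) with the default blood constants:
        1050 * 0.0063 * 3617 * (-1) = -23,926 W/m^3 per kelvin above T_b."""
        tumor = TissueLayer.from_table("tumor")
        sc = ThermalScenario()
        assert perfusion_source(38.0, tumor, sc) == pytest.approx(-23926.4, abs=0.5)
        assert perfusion_source(36.0, tumor, sc) == pytest.approx(23926.4, abs=0.5)


class TestStepHeat:
    def test_equilibrium_preserved(self):
        """Zero source, uniform T = T_b, insulated: nothing moves."""
        dom = make_uniform_domain((8, 8, 8), 0.4, OPTICS)
        sc = ThermalScenario()
        T = np.full(dom.shape, 37.0)
        q = np.zeros(dom.shape)
        Tn = step_heat(T, q, dom, sc, clamp=np.zeros(dom.shape, bool))
        np.testing.assert_allclose(Tn, 37.0, atol=1e-12)

    def test_energy_balance_per_step(self):
        """Insulated box: heat-content change equals (source + perfusion) dt
        to round-off (conduction telescopes exactly)."""
        rng = np.random.default_rng(0)
        dom = make_uniform_domain((10, 10, 10), 0.4, OPTICS)
        sc = ThermalScenario()
        T = 37.0 + rng.random(dom.shape)
        q = 1e5 * rng.random(dom.shape)
        sys_ = _HeatSystem(dom, q, sc, clamp=np.zeros(dom.shape, bool))
        dt = sys_.dt_stable * 0.5
        Tn = step_heat(T, q, dom, sc, dt=dt, clamp=np.zeros(dom.shape, bool))
        k3, rc3, wb3 = dom.thermal_volumes()
        dx3 = (dom.voxel_size * 1e-3) ** 3
        dE = np.sum(rc3 * (Tn - T)) * dx3
        perf = sc.rho_b * sc.c_b * wb3 * (sc.T_b - T)
        expected = dt * np.sum(q + perf) * dx3
        assert dE == pytest.approx(expected, rel=1e-10)

    def test_stability_limit_enforced(self):
        dom = make_uniform_domain((6, 6, 6), 0.4, OPTICS)
        sc = ThermalScenario()
        T = np.full(dom.shape, 37.0)
        with pytest.raises(ValueError, match="stability"):
            step_heat(T, np.zeros(dom.shape), dom, sc, dt=10.0)

    def test_maximum_principle(self, coarse_domain, coarse_transport):
        """Non-negative source with T_b-clamped walls: the field never drops
        below the initial/arterial temperature."""
        sc = ThermalScenario()
        q = coarse_transport.volumetric_power(0.05)
        T = np.full(coarse_domain.shape, 37.0)
        for _ in range(20):
            T = step_heat(T, q, coarse_domain, sc)
        assert T.min() >= 37.0 - 1e-9

    def test_production_kernel_matches_reference(self, coarse_domain, coarse_transport):
        """One step of the compiled kernel equals the vectorized reference."""
        sc = ThermalScenario()
        q = coarse_transport.volumetric_power(0.1)
        sys_ = _HeatSystem(coarse_domain, q, sc)
        dt = sys_.dt_stable * 0.9
        coef, decay, src = sys_.coefficients(dt)
        rng = np.random.default_rng(1)
        T0 = 37.0 + rng.random(coarse_domain.shape)
        T0.flat[sys_.clamp_idx] = sc.boundary_temperature
        ref = step_heat(T0, q, coarse_domain, sc, dt=dt)
        prod = T0.copy()
        _ftcs_steps(
            prod, sys_.Gx, sys_.Gy, sys_.Gz, coef, decay, src,
            sys_.clamp_idx, sc.boundary_temperature, 1,
        )
        np.testing.assert_allclose(prod, ref, atol=1e-10)


class TestAnalyticOracles:
    def test_slab_fourier_series(self):
        """1-D homogeneous slab, faces clamped, no source/perfusion: matches
        the Fourier-series solution within 1% at three checkpoints."""
        nz = 41
        dx = 0.4
        dom = make_uniform_domain((5, 5, nz), dx, OPTICS, w_b=0.0)
        sc = ThermalScenario(perfusion_enabled=False)
        T0, Tf = 37.0, 45.0
        clamp = np.zeros(dom.shape, bool)
        clamp[:, :, 0] = True
        clamp[:, :, -1] = True
        sc = ThermalScenario(perfusion_enabled=False, boundary_temperature=Tf)
        T = np.full(dom.shape, T0)
        T[clamp] = Tf

        layer = dom.layers[max(dom.layers)]
        alpha = layer.k_m / (layer.rho * layer.c_v)
        L = (nz - 1) * dx * 1e-3  # clamped planes sit at the end voxel centers
        sys_ = _HeatSystem(dom, np.zeros(dom.shape), sc, clamp=clamp)
        dt = sys_.dt_stable * 0.9

        def analytic(z, t):
            s = 0.0
            for n_ in range(1, 200, 2):
                s += 4 / (np.pi * n_) * np.sin(n_ * np.pi * z / L) * np.exp(
                    -((n_ * np.pi / L) ** 2) * alpha * t
                )
            return Tf + (T0 - Tf) * s

        t = 0.0
        checkpoints = {60.0: None, 180.0: None, 420.0: None}
        n_steps = int(round(420.0 / dt))
        dt = 420.0 / n_steps
        for i in range(n_steps):
            T = step_heat(T, np.zeros(dom.shape), dom, sc, dt=dt, clamp=clamp)
            t += dt
            for cp in checkpoints:
                if abs(t - cp) < dt / 2 and checkpoints[cp] is None:
                    checkpoints[cp] = T[2, 2, nz // 2]
        z_mid = (nz // 2) * dx * 1e-3
        for cp, got in checkpoints.items():
            want = analytic(z_mid, cp)
            assert abs(got - want) / abs(want - Tf + 1e-30) < 0.01 or abs(
                got - want
            ) < 0.01 * abs(T0 - Tf)

    def test_perfusion_steady_state(self):
        """Uniform source in an insulated perfused block approaches
        T_b + q / (rho_b w_b c_b), through the exact exponential transient."""
        dom = make_uniform_domain((6, 6, 6), 0.4, OPTICS)  # tumor w_b
        sc = ThermalScenario()
        layer = dom.layers[max(dom.layers)]
        coeff = sc.rho_b * layer.w_b * sc.c_b          # W/m^3 K
        q0 = 5.0 * coeff                                # -> +5 K rise
        q = np.full(dom.shape, q0)
        clamp = np.zeros(dom.shape, bool)
        T = np.full(dom.shape, 37.0)
        sys_ = _HeatSystem(dom, q, sc, clamp=clamp)
        dt = sys_.dt_stable * 0.9
        tau = layer.rho * layer.c_v / coeff
        t = 0.0
        while t < 4 * tau:
            T = step_heat(T, q, dom, sc, dt=dt, clamp=clamp)
            t += dt
        expected = 37.0 + 5.0 * (1 - np.exp(-t / tau))
        np.testing.assert_allclose(T, expected, atol=5e-3)


class TestTransient:
    def test_zero_power_is_identity(self, coarse_domain):
        sc = ThermalScenario(duration=60.0)
        hist = run_transient(coarse_domain, np.zeros(coarse_domain.shape), sc)
        np.testing.assert_allclose(hist.final_field, 37.0, atol=1e-12)
        np.testing.assert_allclose(hist.tumor_temps, 37.0, atol=1e-12)

    def test_linearity_in_power(self, coarse_domain, coarse_transport):
        """Doubling the beam power doubles the temperature rise everywhere
        (fixed-T_b boundaries keep the problem linear)."""
        sc = ThermalScenario(duration=60.0)
        h1 = run_transient(coarse_domain, coarse_transport.volumetric_power(0.02), sc)
        h2 = run_transient(coarse_domain, coarse_transport.volumetric_power(0.04), sc)
        np.testing.assert_allclose(
            h2.final_field - 37.0, 2.0 * (h1.final_field - 37.0), atol=1e-8
        )

    def test_perfusion_cools(self, coarse_domain, coarse_transport):
        """The perfusion sink lowers late-time temperatures at both probes."""
        q = coarse_transport.volumetric_power(0.1)
        on = run_transient(coarse_domain, q, ThermalScenario(duration=120.0))
        off = run_transient(
            coarse_domain, q, ThermalScenario(duration=120.0, perfusion_enabled=False)
        )
        assert np.all(off.probe_temps[-1] > on.probe_temps[-1])

    def test_explicit_implicit_agree(self):
        """Backward Euler at 0.5 s and FTCS at the stability limit agree to
        0.1 C on a coarse version of the default case."""
        dom = build_domain(voxel_size=0.8, f_v=1e-6)
        from pttsim.transport import BeamSpec, run_transport
        q = run_transport(dom, BeamSpec(), 30_000, seed=5).volumetric_power(0.042)
        shell = hazard_shell(dom)
        exp = run_transient(dom, q, ThermalScenario(duration=120.0), shell_mask=shell)
        imp = run_transient(
            dom, q,
            ThermalScenario(duration=120.0, scheme="implicit", dt=0.5),
            shell_mask=shell,
        )
        assert np.max(np.abs(exp.final_field - imp.final_field)) < 0.1

    def test_grid_refinement_converges(self):
        """Halving the voxel changes the treatment-scale observables by < 2%:
        the deep axial probe (2 mm) and the apoptosis retention ratio.  (The
        single hottest voxel does not converge this fast — the AuNP-sphere
        apex at the surface is a near-singular heat source that sharpens
        under refinement — so the robust quantities are checked.)"""
        from pttsim.metrics import compute_metrics
        from pttsim.transport import BeamSpec, run_transport
        probes, thetas = [], []
        for dx in (0.5, 0.25):
            dom = build_domain(voxel_size=dx, f_v=1e-6)
            q = run_transport(dom, BeamSpec(), 120_000, seed=8).volumetric_power(0.042)
            hist = run_transient(dom, q)
            probes.append(hist.probe_temps[-1][1])
            thetas.append(compute_metrics(hist).theta_A)
        assert abs(probes[1] - probes[0]) / (probes[0] - 37.0) < 0.02
        assert abs(thetas[1] - thetas[0]) / thetas[0] < 0.02

    def test_probe_locations(self, coarse_domain, coarse_transport):
        hist = run_transient(
            coarse_domain,
            coarse_transport.volumetric_power(0.042),
            ThermalScenario(duration=60.0),
        )
        assert hist.probes_mm == ((0.0, 0.0, 0.0), (0.0, 0.0, 2.0))
        assert hist.probe_temps.shape == (7, 2)
        assert np.all(np.isfinite(hist.probe_temps))
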