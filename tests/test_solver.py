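"""Coupled solver: initial conditions, fixed points, conservation, flow."""

import numpy as np
import pytest

from cryophase import (
    FieldState,
    MaterialParams,
    SeedSpec,
    Simulation,
    SpectralGrid,
    compute_diagnostics,
    init_fields,
)
from cryophase.solver import SolverBlowupError

from fd_reference import fd_rhs, smooth_fields

N = 64


@pytest.fixture()
def sim(grid64):
    return Simulation(grid64, flow=False, omega_tilde=0.0)


def uniform_state(n, phi, c, T):
    z = np.zeros((n, n))
    return FieldState(np.full((n, n), float(phi)), np.full((n, n), float(c)),
                      np.full((n, n), float(T)), z.copy(), z.copy(), z.copy())


class TestInitFields:
    def test_no_seeds_gives_uniform_liquid(self, grid64):
        st = init_fields(grid64, SeedSpec(count=0), 0.05, -1.0)
        assert np.allclose(st.phi_sl, -1.0)
        assert np.allclose(st.phi_c, 0.05)
        assert np.allclose(st.T_tilde, -1.0)
        assert np.allclose(st.vx, 0.0) and np.allclose(st.vy, 0.0)

    def test_base_scenario_fixture(self, grid64):
        from cryophase import base_config

        cfg = base_config()
        st = init_fields(grid64, cfg.seeds, cfg.phi_c0, cfg.T_tilde0)
        assert cfg.phi_c0 == 0.05 and cfg.T_tilde0 == -1.0
        assert st.phi_sl.max() > 0.95          # seeds are solid (tanh core)
        assert st.phi_c.max() == pytest.approx(0.05, abs=1e-6)
        d = compute_diagnostics(st, grid64)
        assert d.max_phi_c == pytest.approx(0.05, abs=1e-9)

    def test_mean_solute_matches_area_weighted_integral(self, grid64):
        seeds = SeedSpec(count=5, positions=((1.5, 1.5), (4.5, 1.5), (1.5, 4.5),
                                             (4.5, 4.5), (np.pi, np.pi)))
        st = init_fields(grid64, seeds, 0.05, -1.0)
        solid_fraction = np.mean(0.5 * (1 + st.phi_sl))
        # smooth tanh measure ~ disc area, up to O((w/r)^2) profile corrections
        assert solid_fraction == pytest.approx(5 * np.pi * 0.3**2 / (4 * np.pi**2),
                                               rel=0.25)
        assert st.phi_c.mean() == pytest.approx(0.05 * (1 - solid_fraction), rel=1e-9)

    def test_overlapping_seeds_rejected(self, grid64):
        with pytest.raises(ValueError, match="separation"):
            init_fields(grid64, SeedSpec(count=2, positions=((1.0, 1.0), (1.1, 1.0))),
                        0.05, -1.0)

    def test_unresolvable_radius_rejected(self, grid64):
        with pytest.raises(ValueError, match="unresolvable"):
            init_fields(grid64, SeedSpec(count=1, positions=((1.0, 1.0),),
                                         radius=0.05), 0.05, -1.0)

    def test_random_placement_is_reproducible(self, grid64):
        a = SeedSpec(count=4, rng_seed=3).resolve(0.1)[0]
        b = SeedSpec(count=4, rng_seed=3).resolve(0.1)[0]
        assert np.array_equal(a, b)


class TestPropertyEvaluation:
    def test_inlined_fast_path_matches_reference_functions(self, grid64, rng):
        """The solver's single-pass property evaluation agrees to round-off
        with the module-level correlation functions."""
        from cryophase import (
            density_scaled,
            diffusivity_scaled,
            specific_heat_scaled,
            thermal_conductivity_scaled,
            viscosity_scaled,
        )

        sim = Simulation(grid64, flow=False)
        st = FieldState(
            rng.uniform(-1.02, 1.02, (N, N)),
            rng.uniform(0.0, 0.4, (N, N)),
            rng.uniform(-1.5, 0.0, (N, N)),
            np.zeros((N, N)), np.zeros((N, N)), np.zeros((N, N)),
        )
        pf = sim.evaluate_properties(st)
        p = sim.params
        T = p.T0 + p.dT * st.T_tilde
        c = np.clip(st.phi_c, 0, 1)
        for got, ref in [
            (pf.rho, density_scaled(T, st.phi_sl, c, p)),
            (pf.cp, specific_heat_scaled(T, st.phi_sl, c, p)),
            (pf.kT, thermal_conductivity_scaled(T, st.phi_sl, c, p)),
            (pf.eta, viscosity_scaled(T, st.phi_sl, c, p)),
            (pf.D, diffusivity_scaled(T, st.phi_sl, c, p)),
        ]:
            assert np.allclose(got, ref, rtol=1e-9, atol=1e-12)


class TestFixedPoints:
    @pytest.mark.parametrize("phi", [-1.0, 1.0])
    def test_uniform_pure_phases_are_stationary(self, sim, phi):
        """Both pure phases at their equilibrium temperature are fixed points."""
        st = uniform_state(N, phi, 0.05, -55 * 0.05**2 / 10.0)
        pf = sim.evaluate_properties(st)
        r_phi, _ = sim.rhs_phase(st, pf)
        r_c, _ = sim.rhs_solute(st, pf)
        r_T = sim.rhs_thermal(st, pf)
        assert np.abs(r_phi).max() == 0.0
        assert np.abs(r_c).max() < 1e-12
        assert np.abs(r_T).max() < 1e-12

    def test_uniform_state_unchanged_after_100_steps(self, sim):
        st = uniform_state(N, -1.0, 0.05, -55 * 0.05**2 / 10.0)
        out, _ = sim.advance(st.copy(), 2e-4, 100)
        assert np.array_equal(out.phi_sl, st.phi_sl)
        assert np.array_equal(out.phi_c, st.phi_c)
        assert np.array_equal(out.T_tilde, st.T_tilde)

    def test_uniform_liquid_cools_at_omega(self, grid64):
        """With no phase change the energy balance is pure cooling at -4.762."""
        sim = Simulation(grid64, flow=False)
        st = uniform_state(N, -1.0, 0.0, -1.0)
        r_T = sim.rhs_thermal(st, sim.evaluate_properties(st))
        assert np.allclose(r_T, -sim.groups.Omega_tilde)
        assert sim.groups.Omega_tilde == pytest.approx(4.762, rel=5e-3)

    def test_mobility_kills_transport_at_bounds(self, sim):
        """phi_c = 0 or 1 zeroes the degenerate Cahn-Hilliard mobility."""
        for c in (0.0, 1.0):
            st = uniform_state(N, 0.0, c, -1.0)
            st.phi_sl[:] = np.tanh((2.0 - np.abs(SpectralGrid(N).x - np.pi)) / 0.14)
            r_c, _ = sim.rhs_solute(st)
            assert np.abs(r_c).max() < 1e-6


class TestSoluteConservation:
    def test_rhs_integral_vanishes(self, sim, grid64):
        """The conservative form integrates to zero for arbitrary fields."""
        phi, c, T = smooth_fields(N)
        st = FieldState(phi, np.clip(c, 0.01, 0.99), T,
                        np.zeros((N, N)), np.zeros((N, N)), np.zeros((N, N)))
        r_c, _ = sim.rhs_solute(st)
        assert abs(r_c.mean()) < 1e-10

    def test_mean_solute_constant_over_1000_steps(self, grid64):
        sim = Simulation(grid64, flow=False)
        st = init_fields(grid64, SeedSpec(count=3, positions=((1.5, 1.5), (4.5, 2.0),
                                                              (3.0, 4.8))), 0.05, -1.0)
        m0 = st.phi_c.mean()
        out, _ = sim.advance(st, 2e-4, 1000)
        assert abs(out.phi_c.mean() - m0) < 1e-8


class TestThermalSources:
    def test_latent_heat_released_at_advancing_front(self, sim, grid64):
        """A freezing interface (D phi/Dt > 0 where P' < 0) heats locally."""
        x = grid64.x
        phi = np.tanh((1.5 - np.abs(x - np.pi)) / 0.14)
        st = FieldState(phi, np.zeros((N, N)), np.full((N, N), -1.0),
                        np.zeros((N, N)), np.zeros((N, N)), np.zeros((N, N)))
        pf = sim.evaluate_properties(st)
        dphi, _ = sim.rhs_phase(st, pf)
        interface = np.abs(phi) < 0.9
        assert dphi[interface].max() > 0  # supercooled -> freezing
        r_T = sim.rhs_thermal(st, pf, dphi, np.zeros((N, N)))
        assert r_T[interface].max() > 0  # exothermic

    def test_thermal_rhs_matches_finite_differences(self, sim):
        phi, c, T = smooth_fields(N)
        st = FieldState(phi, c, T, np.zeros((N, N)), np.zeros((N, N)),
                        np.zeros((N, N)))
        pf = sim.evaluate_properties(st)
        r_T = sim.rhs_thermal(st, pf)
        _, _, fd_T = fd_rhs(phi, c, T, omega_tilde=0.0)
        # FD is O(dx^2); at n=64 the stiff conduction term dominates the error
        scale = np.abs(fd_T).max()
        assert np.abs(r_T - fd_T).max() / scale < 0.05


class TestSpectralVsFiniteDifferenceConvergence:
    def test_rhs_converges_at_second_order(self):
        """FD evaluations approach the spectral RHS at O(dx^2)."""
        errs = {"phi": [], "c": [], "T": []}
        for n in (32, 64, 128):
            grid = SpectralGrid(n)
            sim = Simulation(grid, flow=False, omega_tilde=0.0)
            phi, c, T = smooth_fields(n)
            st = FieldState(phi, c, T, np.zeros((n, n)), np.zeros((n, n)),
                            np.zeros((n, n)))
            pf = sim.evaluate_properties(st)
            r_phi, _ = sim.rhs_phase(st, pf)
            r_c, _ = sim.rhs_solute(st, pf)
            r_T = sim.rhs_thermal(st, pf)
            fd_phi, fd_c, fd_T = fd_rhs(phi, c, T, omega_tilde=0.0)
            errs["phi"].append(np.abs(r_phi - fd_phi).max() / np.abs(fd_phi).max())
            errs["c"].append(np.abs(r_c - fd_c).max() / np.abs(fd_c).max())
            errs["T"].append(np.abs(r_T - fd_T).max() / np.abs(fd_T).max())
        for key, (e32, e64, e128) in errs.items():
            rate1 = np.log2(e32 / e64)
            rate2 = np.log2(e64 / e128)
            assert rate2 > 1.5, f"{key}: rates {rate1:.2f}, {rate2:.2f}, errs {errs[key]}"


class TestVelocity:
    def test_no_forcing_no_flow(self, grid64):
        """Uniform density and no phase change leave the fluid at rest."""
        sim = Simulation(grid64, flow=True)
        # uniform liquid at T0 (rho_tilde = 1): no buoyancy, no blowing
        st = uniform_state(N, -1.0, 0.0, 0.0)
        vx, vy, p, _, _ = sim.update_velocity(st, dphi_sl_dt=np.zeros((N, N)))
        assert np.abs(vx).max() < 1e-12
        assert np.abs(vy).max() < 1e-12
        assert np.abs(p).max() < 1e-10

    def test_blowing_divergence_matches_continuity_source(self, grid64):
        """div(v) reproduces the density-change source of the continuity eq."""
        sim = Simulation(grid64, flow=True)
        st = init_fields(grid64, SeedSpec(count=1, positions=((np.pi, np.pi),)),
                         0.0, -1.0)
        pf = sim.evaluate_properties(st)
        dphi, _ = sim.rhs_phase(st, pf)
        vx, vy, _, _, _ = sim.update_velocity(st, pf, dphi)
        S = -(1.0 / (sim.groups.Pe * pf.rho)) * pf.drho_dphi * dphi
        S = grid64.ifft(grid64.dealias(grid64.fft(S)))  # solver's dealias policy
        S = S - S.mean()
        div_v = grid64.div(vx, vy)
        assert np.abs(div_v - S).max() < 1e-8

    def test_growing_crystal_blows_outward(self, grid64):
        """Ice is lighter than water: freezing expels mass toward the liquid."""
        sim = Simulation(grid64, flow=True, gravity=False)
        st = init_fields(grid64, SeedSpec(count=1, positions=((np.pi, np.pi),)),
                         0.0, -1.0)
        pf = sim.evaluate_properties(st)
        dphi, _ = sim.rhs_phase(st, pf)
        vx, vy, _, _, _ = sim.update_velocity(st, pf, dphi)
        # radial component just outside the seed is positive (outflow)
        x, y = grid64.x - np.pi, grid64.y - np.pi
        r = np.hypot(x, y)
        ring = (r > 0.45) & (r < 0.7)
        v_rad = (vx * x + vy * y) / np.maximum(r, 1e-12)
        assert v_rad[ring].mean() > 0
        # net outflow through the ring equals the enclosed divergence source
        div_v = grid64.div(vx, vy)
        inside = r < 0.55
        assert div_v[inside].sum() > 0


class TestAdvanceRobustness:
    def test_blowup_raises_with_last_state(self, grid64):
        sim = Simulation(grid64, flow=False, omega_tilde=0.0)
        st = uniform_state(N, -1.0, 0.05, -0.01375)
        st.T_tilde[0, 0] = np.inf
        with pytest.raises((SolverBlowupError, ValueError)):
            sim.step(st, 2e-4)

    def test_negative_dt_rejected(self, sim):
        st = uniform_state(N, -1.0, 0.05, 0.0)
        with pytest.raises(ValueError):
            sim.advance(st, -1e-4, 10)

    def test_deterministic_given_config(self, grid64):
        sim1 = Simulation(grid64, flow=True)
        sim2 = Simulation(grid64, flow=True)
        seeds = SeedSpec(count=2, positions=((2.0, 2.0), (4.5, 4.0)))
        a, _ = sim1.advance(init_fields(grid64, seeds, 0.05, -1.0), 2e-4, 50)
        b, _ = sim2.advance(init_fields(grid64, seeds, 0.05, -1.0), 2e-4, 50)
        assert np.array_equal(a.phi_sl, b.phi_sl)
        assert np.array_equal(a.vx, b.vx)


class TestDiagnostics:
    def test_uniform_liquid(self, grid64):
        st = uniform_state(N, -1.0, 0.05, -1.0)
        d = compute_diagnostics(st, grid64)
        assert d.crystal_area_fraction == 0.0
        assert d.max_speed == 0.0
        assert d.max_vorticity == 0.0

    def test_total_solute_is_quadrature(self, grid64, rng):
        c = np.clip(0.05 + 0.01 * rng.normal(size=(N, N)), 0, 1)
        st = uniform_state(N, -1.0, 0.0, -1.0)
        st.phi_c[:] = c
        d = compute_diagnostics(st, grid64)
        assert d.total_solute == pytest.approx(c.sum() * (2 * np.pi / N) ** 2)
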