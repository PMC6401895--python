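"""Coupled phase-field / solute / thermal / flow evolution in scaled form.

The state is four coupled fields on the periodic square: the
non-conserved phase field ``phi_sl`` (Allen-Cahn type, +1 ice / -1
liquid), the conserved solute volume fraction ``phi_c`` (Cahn-Hilliard
type with Flory-Huggins mixing and a degenerate mobility), the scaled
temperature ``T_tilde = (T - T0)/dT`` (conduction, latent-heat and mixing
sources, uniform volumetric cooling), and the scaled velocity.  The
velocity is split into a potential part driven by the density jump across
the moving front (the "blowing" flux of the quasi-incompressible
continuity equation) and a solenoidal part relaxed explicitly toward the
inertialess momentum balance with variable viscosity and Boussinesq
buoyancy.

Time stepping is forward Euler at a uniform scaled step (default 2e-4)
with semi-implicit (backward-Euler, constant-coefficient split)
treatment of the stiff linear diffusion operators, evaluated pseudo-
spectrally with 2/3-rule dealiasing of the nonlinear terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import properties as props_mod
from .properties import MaterialParams, PHI_C_EPS
from .scaling import (
    DimensionlessGroups,
    ReferenceScales,
    characteristic_times,
    dimensionless_groups,
)
from .spectral import SpectralGrid

__all__ = [
    "FieldState",
    "SeedSpec",
    "Diagnostics",
    "PropertyFields",
    "Simulation",
    "SolverBlowupError",
    "init_fields",
    "compute_diagnostics",
]

log = logging.getLogger(__name__)


class SolverBlowupError(RuntimeError):
    """Raised when a field goes non-finite; carries the last good state."""

    def __init__(self, message: str, state: "FieldState"):
        super().__init__(message)
        self.state = state


@dataclass
class FieldState:
    """The evolving scaled fields plus the scaled time.

    ``vsx``/``vsy`` hold the solenoidal velocity component, which carries
    memory between steps (the potential part is re-derived every step from
    the instantaneous phase-change rate).
    """

    phi_sl: np.ndarray
    phi_c: np.ndarray
    T_tilde: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    p_tilde: np.ndarray
    t_tilde: float = 0.0
    vsx: np.ndarray | None = None
    vsy: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = self.phi_sl.shape
        for name in ("phi_c", "T_tilde", "vx", "vy", "p_tilde"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"field {name} shape mismatch")
        if self.vsx is None:
            self.vsx = np.zeros(shape)
        if self.vsy is None:
            self.vsy = np.zeros(shape)

    def copy(self) -> "FieldState":
        return FieldState(
            self.phi_sl.copy(), self.phi_c.copy(), self.T_tilde.copy(),
            self.vx.copy(), self.vy.copy(), self.p_tilde.copy(),
            self.t_tilde, self.vsx.copy(), self.vsy.copy(),
        )

    def is_finite(self) -> bool:
        return all(
            np.all(np.isfinite(a))
            for a in (self.phi_sl, self.phi_c, self.T_tilde, self.vx, self.vy)
        )


@dataclass(frozen=True)
class SeedSpec:
    """Prescribed nucleation sites: crystal seeds placed at t = 0.

    ``positions`` are scaled coordinates in ``[0, 2*pi)^2``; when omitted,
    seeds are placed uniformly at random (recorded RNG seed) subject to a
    minimum pairwise separation.  ``radius`` defaults to three interface
    widths (3 Ch) — resolvable yet small against the domain.
    """

    count: int = 5
    positions: tuple | None = None
    radius: float | None = None
    min_separation: float | None = None
    rng_seed: int = 0

    def resolve(self, ch: float) -> tuple[np.ndarray, float]:
        """Return (positions array (count, 2), radius), validated."""
        radius = 3.0 * ch if self.radius is None else float(self.radius)
        if radius < 2.0 * ch:
            raise ValueError(f"seed radius {radius} < 2 Ch = {2 * ch}: interface unresolvable")
        sep = 2.0 * radius if self.min_separation is None else float(self.min_separation)
        if self.count == 0:
            return np.zeros((0, 2)), radius
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float).reshape(-1, 2)
            if pos.shape[0] != self.count:
                raise ValueError("positions count does not match SeedSpec.count")
        else:
            pos = self._random_positions(sep)
        if np.any(pos < 0) or np.any(pos >= 2 * np.pi):
            raise ValueError("seed positions must lie in [0, 2*pi)")
        d = _pairwise_periodic_dist(pos)
        if d.size and d.min() < sep:
            raise ValueError(
                f"seeds closer than min_separation ({d.min():.3f} < {sep:.3f})"
            )
        return pos, radius

    def _random_positions(self, sep: float) -> np.ndarray:
        rng = np.random.default_rng(self.rng_seed)
        pos: list[np.ndarray] = []
        for _ in range(20000):
            cand = rng.uniform(0.0, 2 * np.pi, size=2)
            if all(_periodic_dist(cand, q) >= sep for q in pos):
                pos.append(cand)
                if len(pos) == self.count:
                    return np.array(pos)
        raise ValueError(f"could not place {self.count} seeds with separation {sep}")


def _periodic_dist(a, b, length: float = 2 * np.pi) -> float:
    d = np.abs(np.asarray(a) - np.asarray(b))
    d = np.minimum(d, length - d)
    return float(np.hypot(*d))


def _pairwise_periodic_dist(pos: np.ndarray) -> np.ndarray:
    n = len(pos)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append(_periodic_dist(pos[i], pos[j]))
    return np.asarray(out)


@dataclass(frozen=True)
class Diagnostics:
    """Scalar observables extracted from a state at one output time."""

    t_tilde: float
    max_phi_c: float
    min_T_tilde: float
    max_T_tilde: float
    mean_T_tilde: float
    crystal_area_fraction: float
    total_solute: float
    max_speed: float
    max_vorticity: float


@dataclass
class PropertyFields:
    """All property/auxiliary fields evaluated on the current state."""

    P: np.ndarray
    Pp: np.ndarray
    G: np.ndarray
    Gp: np.ndarray
    Gpp: np.ndarray
    chi: np.ndarray
    chip: np.ndarray
    rho: np.ndarray
    cp: np.ndarray
    kT: np.ndarray
    eta: np.ndarray
    D: np.ndarray
    Teq_tilde: np.ndarray
    drho_dphi: np.ndarray
    one_minus_c: np.ndarray
    mobility: np.ndarray


def init_fields(
    grid: SpectralGrid,
    seeds: SeedSpec,
    phi_c0: float,
    T_tilde0: float,
    ch: float = 0.1,
) -> FieldState:
    """Initial condition: tanh-profile crystal discs in supercooled solution.

    ``phi_sl`` is +1 inside each seed disc and -1 outside with a tanh
    transition of equilibrium width ``sqrt(2) Ch``; the solute is uniform
    at ``phi_c0`` in the liquid and zero inside the seeds; temperature is
    uniform at the supercooled onset value; the fluid starts at rest.
    """
    pos, radius = seeds.resolve(ch)
    n = grid.n
    phi = np.full((n, n), -1.0)
    width = math.sqrt(2.0) * ch
    for (px, py) in pos:
        dx = np.abs(grid.x - px)
        dx = np.minimum(dx, 2 * np.pi - dx)
        dy = np.abs(grid.y - py)
        dy = np.minimum(dy, 2 * np.pi - dy)
        d = np.hypot(dx, dy)
        phi = np.maximum(phi, np.tanh((radius - d) / width))
    solid = 0.5 * (1.0 + phi)
    phi_c = phi_c0 * (1.0 - solid)
    return FieldState(
        phi_sl=phi,
        phi_c=phi_c,
        T_tilde=np.full((n, n), float(T_tilde0)),
        vx=np.zeros((n, n)),
        vy=np.zeros((n, n)),
        p_tilde=np.zeros((n, n)),
        t_tilde=0.0,
    )


def compute_diagnostics(state: FieldState, grid: SpectralGrid) -> Diagnostics:
    """Scalar diagnostics; vorticity via the spectral curl."""
    speed = np.hypot(state.vx, state.vy)
    vort = grid.curl(state.vx, state.vy)
    dA = grid.dx**2
    return Diagnostics(
        t_tilde=float(state.t_tilde),
        max_phi_c=float(state.phi_c.max()),
        min_T_tilde=float(state.T_tilde.min()),
        max_T_tilde=float(state.T_tilde.max()),
        mean_T_tilde=float(state.T_tilde.mean()),
        crystal_area_fraction=float(np.mean(state.phi_sl > 0.0)),
        total_solute=float(state.phi_c.sum() * dA),
        max_speed=float(speed.max()),
        max_vorticity=float(np.abs(vort).max()),
    )


class Simulation:
    """Advances the coupled scaled system on a :class:`SpectralGrid`.

    Parameters
    ----------
    grid : SpectralGrid
    params : MaterialParams, optional
    flow, gravity : bool
        Disable the velocity solve or only the buoyancy force.
    omega_tilde : float, optional
        Override of the scaled cooling rate (0 switches cooling off);
        defaults to the value implied by ``params.beta_f``.
    """

    def __init__(
        self,
        grid: SpectralGrid,
        params: MaterialParams | None = None,
        scales: ReferenceScales | None = None,
        groups: DimensionlessGroups | None = None,
        flow: bool = True,
        gravity: bool = True,
        omega_tilde: float | None = None,
        evolve_temperature: bool = True,
        solute_regularization: bool = True,
    ):
        self.grid = grid
        self.params = params or MaterialParams()
        self.scales = scales or characteristic_times(self.params)
        self.groups = groups or dimensionless_groups(self.scales, self.params)
        self.flow = flow
        self.gravity = gravity
        g = self.groups
        self.omega_tilde = g.Omega_tilde if omega_tilde is None else float(omega_tilde)
        p = self.params
        self.eps_T = p.dT / p.T0            # dT/T0, relative subcooling
        self.T_ratio = p.T0 / p.dT          # T0/dT, appears in mixing sources
        self.r_phic = self.scales.tau_sl / self.scales.tau_phic
        self.R_over_h = p.R_specific / p.h_sl
        self.h_over_R = p.h_sl / p.R_specific
        self.ch2 = g.Ch**2
        self.evolve_temperature = evolve_temperature
        # Solute gradient-energy coefficient.  The physical value implies a
        # spinodal interface width sqrt(Ch^2 h_sl/R) ~ 2e-3 that no feasible
        # grid resolves; where trapped solute makes the composite diffusion
        # coefficient negative (chi G'' < 0, which requires the crystal-side
        # chi), unresolved backward diffusion blows up at the grid scale.
        # The regularisation augments the coefficient by a grid-scale term
        # weighted by the solid fraction (1 - P): it caps the fastest-
        # growing spinodal mode at ~n/4 inside crystals, leaves the
        # (parabolically stable) liquid untouched, and vanishes under grid
        # refinement.
        self.kappa_phys = self.r_phic * self.ch2 * self.h_over_R
        if solute_regularization:
            self.kappa_grid = self.r_phic * 4.0 * p.chi_s * (4.0 / grid.n) ** 2
        else:
            self.kappa_grid = 0.0
        # rate of phase change from the previous step, feeds the continuity
        # source of the velocity solve (zero at step 0: fluid starts at rest)
        self._Dphi_prev = np.zeros((grid.n, grid.n))

    # -- property evaluation -------------------------------------------------

    def evaluate_properties(self, state: FieldState) -> PropertyFields:
        """Evaluate every property field once per step.

        Inlines the correlations of :mod:`cryophase.properties` (single
        evaluation of the interpolation polynomial, shared by all
        interpolated properties); the module-level functions remain the
        reference implementations and the two are cross-checked in tests.
        """
        if not state.is_finite():
            raise SolverBlowupError("non-finite field in state", state.copy())
        p = self.params
        phi = np.clip(state.phi_sl, -1.0, 1.0)
        c_raw = np.clip(state.phi_c, 0.0, 1.0)
        c = np.clip(state.phi_c, PHI_C_EPS, 1.0 - PHI_C_EPS)
        T = p.T0 + p.dT * state.T_tilde
        dT0 = T - p.T0
        phi2 = phi * phi
        P = 0.5 - 0.9375 * phi * (0.2 * phi2 * phi2 - (2.0 / 3.0) * phi2 + 1.0)
        omp2 = 1.0 - phi2
        Pp = -0.9375 * omp2 * omp2
        omc = 1.0 - c
        G = 4.0 * c * c * omc * omc
        Gp = 8.0 * c * omc * (1.0 - 2.0 * c)
        Gpp = 8.0 * (1.0 - 6.0 * c + 6.0 * c * c)
        chi = P * p.chi_l + (1.0 - P) * p.chi_s
        chip = Pp * (p.chi_l - p.chi_s)
        Teq_t = -(55.0 / p.dT) * c_raw * c_raw
        rho_l = (p.rho0 - 0.017 * dT0 * dT0) / p.rho0
        rho_s = (0.917 * p.rho0 - 0.15 * dT0) / p.rho0
        rho = c_raw * (p.rho_c / p.rho0) + (1.0 - c_raw) * (P * rho_l + (1.0 - P) * rho_s)
        mooney = c_raw * (1.0 - 0.588 * c_raw)
        cp_l = 4180.0 * (1.0 - 0.953 * mooney + 1e-3 * dT0)
        cp_s = p.cp0 + 8.0 * dT0
        cp = (P * cp_l + (1.0 - P) * cp_s) / p.cp0
        k_l = 0.58 * (1.0 - 0.905 * mooney + 2.6e-3 * dT0)
        k_s = p.kT0 - 0.013 * dT0
        kT = (P * k_l + (1.0 - P) * k_s) / p.kT0
        if np.any(T <= props_mod.VTF_SINGULAR_T):
            raise SolverBlowupError("temperature below the VTF singularity",
                                    state.copy())
        eta_l = (4.442e-5 / p.eta0) * np.exp(
            2.288 * props_mod.VTF_SINGULAR_T / (T - props_mod.VTF_SINGULAR_T)
            + 6.3 * c_raw / (1.0 - 0.85 * c_raw)
        )
        eta = P * eta_l + (1.0 - P) * p.eta_s_ratio
        D_l = T / (p.T0 * eta_l)
        D = P * D_l + (1.0 - P) * p.D_s_ratio
        return PropertyFields(
            P=P, Pp=Pp, G=G, Gp=Gp, Gpp=Gpp, chi=chi, chip=chip,
            rho=rho, cp=cp, kT=kT, eta=eta, D=D, Teq_tilde=Teq_t,
            drho_dphi=(1.0 - c_raw) * Pp * (rho_l - rho_s),
            one_minus_c=1.0 - c_raw,
            mobility=c * (1.0 - c),
        )

    # -- right-hand sides ------------------------------------------------------

    def _shared_derivs(self, state: FieldState) -> dict:
        """All spectral derivatives of the scalar fields, computed once."""
        g = self.grid
        phi_hat = g.fft(state.phi_sl)
        c_hat = g.fft(state.phi_c)
        T_hat = g.fft(state.T_tilde)
        ikx, iky = 1j * g.dkx, 1j * g.dky
        lap_c_hat = -g.k2 * c_hat
        return dict(
            phi_hat=phi_hat,
            c_hat=c_hat,
            T_hat=T_hat,
            lap_phi=g.ifft(-g.k2 * phi_hat),
            dphix=g.ifft(ikx * phi_hat),
            dphiy=g.ifft(iky * phi_hat),
            dcx=g.ifft(ikx * c_hat),
            dcy=g.ifft(iky * c_hat),
            dlx=g.ifft(ikx * lap_c_hat),
            dly=g.ifft(iky * lap_c_hat),
            dTx=g.ifft(ikx * T_hat),
            dTy=g.ifft(iky * T_hat),
        )

    def _phase_parts(self, state: FieldState, pf: PropertyFields, dv: dict | None = None):
        """Return (full right side F, its Ch^2 lap(phi) piece, advection)."""
        dv = dv or self._shared_derivs(state)
        phi = state.phi_sl
        lap_phi = dv["lap_phi"]
        # local temperature factor (T - Teq) / (T Teq) in scaled variables
        Tt = state.T_tilde
        thermo = (Tt - pf.Teq_tilde) / (
            (1.0 + self.eps_T * Tt) * (1.0 + self.eps_T * pf.Teq_tilde)
        )
        F = (
            self.ch2 * lap_phi
            + self.groups.Lambda_sl * pf.one_minus_c * pf.Pp * thermo
            + pf.one_minus_c * (phi - phi**3)
            - self.R_over_h * pf.chip * pf.G
        )
        adv = self.groups.Pe * (state.vx * dv["dphix"] + state.vy * dv["dphiy"])
        return F, lap_phi, adv

    def rhs_phase(self, state: FieldState, pf: PropertyFields | None = None):
        """Explicit d(phi_sl)/dt_tilde and the implicit coefficient Ch^2.

        The returned field is the complete instantaneous rate (including
        the interfacial diffusion term and advection); the coefficient is
        the constant that the time stepper treats backward-Euler.
        """
        pf = pf or self.evaluate_properties(state)
        F, _, adv = self._phase_parts(state, pf)
        rhs = F - adv
        self._check_finite(rhs, state, "phase")
        return rhs, self.ch2

    def _solute_parts(self, state: FieldState, pf: PropertyFields, dv: dict | None = None):
        """Return (spectral F_hat of the conservative terms, advection, c2max, c4max)."""
        g = self.grid
        dv = dv or self._shared_derivs(state)
        c = np.clip(state.phi_c, 0.0, 1.0)
        # composite 2nd-order diffusion coefficient: ideal mixing, solvent
        # entropy and the chi G'' mixing curvature
        A = pf.D * ((1.0 - c) / self.params.N + c + pf.mobility * pf.chi * pf.Gpp)
        # drift of solute down the chi gradient (exclusion from the crystal)
        drift = pf.D * pf.mobility * pf.Gp * pf.chip
        fx = A * dv["dcx"] + drift * dv["dphix"]
        fy = A * dv["dcy"] + drift * dv["dphiy"]
        F_hat = self.r_phic * g.div_hat(fx, fy)
        # Cahn-Hilliard gradient-energy flux (4th order); grid-scale
        # regularisation active only on the crystal side
        kappa = self.kappa_phys + self.kappa_grid * (1.0 - pf.P)
        mk = pf.D * pf.mobility * kappa
        F_hat -= g.div_hat(mk * dv["dlx"], mk * dv["dly"])
        adv = self.groups.Pe * (state.vx * dv["dcx"] + state.vy * dv["dcy"])
        c2max = self.r_phic * max(float(A.max()), 0.0)
        c4max = float(mk.max())
        return F_hat, adv, c2max, c4max

    def rhs_solute(self, state: FieldState, pf: PropertyFields | None = None):
        """Explicit d(phi_c)/dt_tilde and the 4th-order implicit coefficient.

        Both transport terms are in divergence (conservative) form, so the
        domain mean of the returned field is zero whenever the velocity
        vanishes.
        """
        pf = pf or self.evaluate_properties(state)
        F_hat, adv, _, c4max = self._solute_parts(state, pf)
        rhs = self.grid.ifft(self.grid.dealias(F_hat)) - adv
        self._check_finite(rhs, state, "solute")
        return rhs, c4max

    def rhs_thermal(
        self,
        state: FieldState,
        pf: PropertyFields | None = None,
        dphi_sl_dt: np.ndarray | None = None,
        dphi_c_dt: np.ndarray | None = None,
    ):
        """Explicit d(T_tilde)/dt_tilde.

        ``dphi_sl_dt`` / ``dphi_c_dt`` are the *material* rates of the two
        phase fields from the current step (latent-heat and mixing
        sources); when omitted they are recomputed from the state.
        """
        pf = pf or self.evaluate_properties(state)
        if dphi_sl_dt is None:
            F, _, _ = self._phase_parts(state, pf)
            dphi_sl_dt = F
        if dphi_c_dt is None:
            F_hat, _, _, _ = self._solute_parts(state, pf)
            dphi_c_dt = self.grid.ifft(self.grid.dealias(F_hat))
        F_T, adv = self._thermal_parts(state, pf, dphi_sl_dt, dphi_c_dt)
        rhs = F_T - adv
        self._check_finite(rhs, state, "thermal")
        return rhs

    def _thermal_parts(self, state, pf, Dphi, Dphic, dv: dict | None = None):
        g = self.grid
        gr = self.groups
        dv = dv or self._shared_derivs(state)
        Tt = state.T_tilde
        a = pf.kT / (pf.rho * pf.cp)
        dTx, dTy = dv["dTx"], dv["dTy"]
        conduction = gr.Le * g.div(a * dTx, a * dTy)
        T_abs = Tt + self.T_ratio
        latent = -(1.0 / (pf.cp * gr.Ste1)) * (
            pf.Pp + gr.Ste2 * T_abs * pf.chip * pf.G
        ) * Dphi
        mixing = -(gr.Ste2 / (pf.cp * gr.Ste1)) * T_abs * pf.chi * pf.Gp * Dphic
        F = conduction + latent + mixing - self.omega_tilde
        adv = gr.Pe * (state.vx * dTx + state.vy * dTy)
        return F, adv

    # -- velocity ---------------------------------------------------------------

    def update_velocity(
        self,
        state: FieldState,
        pf: PropertyFields | None = None,
        dphi_sl_dt: np.ndarray | None = None,
    ):
        """One velocity update: Helmholtz split of the scaled flow problem.

        The potential part satisfies the quasi-incompressible continuity
        equation: ``lap(psi) = -(1/(Pe rho)) (d rho/d phi) D(phi)/Dt`` (the
        blowing source; any nonzero mean is removed by the periodic
        gauge).  The solenoidal part is relaxed one explicit step of the
        inertialess momentum equation (variable viscosity, buoyancy
        ``+Gr (1 - rho) y_hat``), stabilised by a backward-Euler split at
        the domain-maximum viscosity, then Leray-projected.  Pressure is
        the projection multiplier from the corresponding Poisson equation.

        Returns ``(vx, vy, p, vsx, vsy)``.
        """
        g = self.grid
        gr = self.groups
        pf = pf or self.evaluate_properties(state)
        if dphi_sl_dt is None:
            dphi_sl_dt = self._Dphi_prev
        n = g.n
        # potential (blowing) part; the source is a nonlinear product and is
        # dealiased like every other one, which also makes div(v) reproduce
        # it exactly on the retained modes
        S = -(1.0 / (gr.Pe * pf.rho)) * pf.drho_dphi * dphi_sl_dt
        S_hat = g.dealias(g.fft(S))
        S_hat[0, 0] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            psi_hat = np.where(g.k2 > 0, -S_hat / g.k2, 0.0)
        vpx = g.ifft(1j * g.dkx * psi_hat)
        vpy = g.ifft(1j * g.dky * psi_hat)
        # solenoidal part: explicit relaxation of the momentum balance
        ux_x, ux_y = g.grad(state.vx)
        uy_x, uy_y = g.grad(state.vy)
        txx = 2.0 * pf.eta * ux_x
        tyy = 2.0 * pf.eta * uy_y
        txy = pf.eta * (ux_y + uy_x)
        fx_hat = g.div_hat(txx, txy)
        fy_hat = g.div_hat(txy, tyy)
        if self.gravity:
            buoy = gr.Gr_coefficient * (1.0 - pf.rho)
            fy_hat = fy_hat + g.fft(buoy)
        fx_hat = g.dealias(fx_hat)
        fy_hat = g.dealias(fy_hat)
        dt_sc = self._dt_sc
        eta_max = float(pf.eta.max())
        denom = 1.0 + dt_sc * eta_max * g.k2
        vsx_hat = g.fft(state.vsx) + dt_sc * fx_hat / denom
        vsy_hat = g.fft(state.vsy) + dt_sc * fy_hat / denom
        # Leray projection (zero-mean gauge)
        with np.errstate(divide="ignore", invalid="ignore"):
            k2 = np.where(g.k2 > 0, g.k2, 1.0)
            kdotv = (g.dkx * vsx_hat + g.dky * vsy_hat) / k2
        vsx_hat = vsx_hat - g.dkx * kdotv
        vsy_hat = vsy_hat - g.dky * kdotv
        vsx_hat[0, 0] = 0.0
        vsy_hat[0, 0] = 0.0
        vsx = g.ifft(vsx_hat)
        vsy = g.ifft(vsy_hat)
        p = g.solve_poisson(g.ifft(1j * g.dkx * fx_hat + 1j * g.dky * fy_hat))
        vx = vpx + vsx
        vy = vpy + vsy
        for arr, name in ((vx, "vx"), (vy, "vy")):
            if not np.all(np.isfinite(arr)):
                raise SolverBlowupError(f"non-finite velocity ({name})", state.copy())
        return vx, vy, p, vsx, vsy

    # -- time stepping ------------------------------------------------------------

    _dt_sc = 0.0  # dt * Sc, set by advance()

    def step(self, state: FieldState, dt: float) -> FieldState:
        """Advance the state by one forward-Euler / semi-implicit step."""
        g = self.grid
        gr = self.groups
        self._dt_sc = dt * gr.Sc
        pf = self.evaluate_properties(state)
        if self.flow:
            vx, vy, p, vsx, vsy = self.update_velocity(state, pf, self._Dphi_prev)
            state = FieldState(state.phi_sl, state.phi_c, state.T_tilde,
                               vx, vy, p, state.t_tilde, vsx, vsy)
        # explicit right-hand sides (material rates feed the thermal sources);
        # all shared spectral derivatives are evaluated once
        dv = self._shared_derivs(state)
        F_phi, lap_phi, adv_phi = self._phase_parts(state, pf, dv)
        Fc_hat, adv_c, c2max, c4max = self._solute_parts(state, pf, dv)
        Dphic = g.ifft(g.dealias(Fc_hat))
        if self.evolve_temperature:
            F_T, adv_T = self._thermal_parts(state, pf, F_phi, Dphic, dv)

        # phase: exact implicit on Ch^2 lap
        E_phi = g.dealias(g.fft(F_phi - self.ch2 * lap_phi - adv_phi))
        phi_hat = (dv["phi_hat"] + dt * E_phi) / (1.0 + dt * self.ch2 * g.k2)
        # solute: add-subtract stabilisation at the domain-max coefficients
        L_c = dt * (c2max * g.k2 + c4max * g.k2**2)
        E_c = g.dealias(g.fft(-adv_c)) + Fc_hat * g.dealias_mask
        c_hat = (dv["c_hat"] + dt * E_c + L_c * dv["c_hat"]) / (1.0 + L_c)
        if self.evolve_temperature:
            # thermal: add-subtract stabilisation at the max diffusivity
            a_max = float((pf.kT / (pf.rho * pf.cp)).max())
            L_T = dt * gr.Le * a_max * g.k2
            E_T = g.dealias(g.fft(F_T - adv_T))
            T_hat = dv["T_hat"]
            T_new = g.ifft((T_hat + dt * E_T + L_T * T_hat) / (1.0 + L_T))
        else:
            # benchmark mode: temperature held fixed (isolates interface
            # kinetics from recalescence feedback)
            T_new = state.T_tilde

        new = FieldState(
            phi_sl=g.ifft(phi_hat),
            phi_c=g.ifft(c_hat),
            T_tilde=T_new,
            vx=state.vx, vy=state.vy, p_tilde=state.p_tilde,
            t_tilde=state.t_tilde + dt,
            vsx=state.vsx, vsy=state.vsy,
        )
        if not new.is_finite():
            raise SolverBlowupError(
                f"non-finite field at t_tilde = {new.t_tilde:.4f}", state.copy()
            )
        self._Dphi_prev = F_phi
        return new

    def advance(
        self,
        state: FieldState,
        dt: float,
        n_steps: int,
        diag_every: int = 0,
        on_diagnostics=None,
    ):
        """Advance ``n_steps`` steps of size ``dt``.

        Returns ``(state, diagnostics)`` where diagnostics are sampled
        every ``diag_every`` steps (0 samples only the final state).
        A CFL-style advection sanity check is logged when violated.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        diags: list[Diagnostics] = []
        for i in range(1, n_steps + 1):
            state = self.step(state, dt)
            if diag_every and (i % diag_every == 0 or i == n_steps):
                d = compute_diagnostics(state, self.grid)
                cfl = self.groups.Pe * d.max_speed * dt / self.grid.dx
                if cfl >= 1.0:
                    log.warning("advective CFL %.2f >= 1 at t_tilde=%.4f", cfl, d.t_tilde)
                diags.append(d)
                if on_diagnostics is not None:
                    on_diagnostics(d)
        if not diags:
            diags.append(compute_diagnostics(state, self.grid))
        return state, diags

    def _check_finite(self, arr: np.ndarray, state: FieldState, what: str) -> None:
        if not np.all(np.isfinite(arr)):
            raise SolverBlowupError(f"non-finite {what} right-hand side", state.copy())
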