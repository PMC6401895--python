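"""Thermophysical correlations for supercooled aqueous sugar/protein solutions.

This module holds the material description of the binary system (water +
excluded solute, parameterised with sucrose data): temperature- and
concentration-dependent density, specific heat, thermal conductivity,
viscosity (Vogel–Fulcher–Tammann with a Mooney concentration correction),
solute diffusivity (Stokes–Einstein), the sucrose–water liquidus, and the
ingredients of the Flory–Huggins mixing energy used by the phase-field
solver: the fifth-order solid/liquid interpolation polynomial ``P``, the
double-well potential ``G`` and the phase-interpolated interaction
parameter ``chi``.

Conventions
-----------
The phase field ``phi_sl`` is +1 in the ice crystal and -1 in the liquid
solution.  ``P(phi_sl)`` is the *liquid* weight: ``P(-1) = 1`` (liquid),
``P(+1) = 0`` (solid).  Scaled ("tilde") properties divide by the
reference values stored in :class:`MaterialParams`; note that the
reference specific heat and conductivity are the *ice* values at the
reference freezing temperature ``T0`` (the convention under which the
published dimensionless groups are recovered), while the reference
density, viscosity and diffusivity are liquid values at ``T0``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

__all__ = [
    "MaterialParams",
    "interp_P",
    "doublewell_G",
    "chi_mix",
    "density_scaled",
    "specific_heat_scaled",
    "thermal_conductivity_scaled",
    "viscosity_scaled",
    "diffusivity_scaled",
    "liquidus_temperature",
    "interfacial_energy",
    "property_table",
    "VTF_SINGULAR_T",
]

log = logging.getLogger(__name__)

#: Singular temperature of the VTF viscosity correlation for supercooled
#: water; the liquid viscosity diverges as T -> VTF_SINGULAR_T from above.
VTF_SINGULAR_T = 168.9  # K

# Validity window of the supercooled-water correlations.  Outside it the
# fits are extrapolated; we warn (once per call site) instead of failing.
_CORR_T_MIN = 230.0
_CORR_T_MAX = 280.0

# The phase field is clamped to [-1, 1] before evaluating P and P'.  Small
# spectral overshoots beyond the wells are tolerated in the field itself,
# but the interpolation weight saturates and, critically, its derivative
# vanishes there: P'(phi) as a raw polynomial is nonzero again beyond
# +-1, and the mixing force (R/h_sl ~ 3e3) chi' G would otherwise exert a
# spurious bulk force that drags both pure phases off +-1.
_PHI_SL_OVERSHOOT = 1.0
# phi_c is clipped into [EPS, 1-EPS] before mobility/mixing terms to keep
# the degenerate mobility phi_c (1 - phi_c) non-negative under ringing.
PHI_C_EPS = 1e-6


@dataclass(frozen=True)
class MaterialParams:
    """Dimensional material constants and correlation coefficients.

    Defaults describe a dilute sucrose solution freezing around
    ``T0 = 273.15 K`` on a 10 micrometre mesoscale domain.
    """

    rho0: float = 999.8        #: reference (liquid water at T0) density, kg/m^3
    cp0: float = 2110.0        #: reference specific heat (ice at T0), J/(kg K)
    kT0: float = 2.14          #: reference thermal conductivity (ice at T0), W/(m K)
    D0: float = 2.1e-10        #: reference solute diffusivity (liquid, T0), m^2/s
    eta0: float = 1.8e-3       #: reference dynamic viscosity (liquid, T0), Pa s
    La: float = 3.4e5          #: latent heat of fusion, J/kg
    h_sl: float = 0.1456       #: solid/liquid energy-barrier coefficient, J/(kg K)
    W_sl: float = 1e-6         #: characteristic interfacial thickness, m
    chi_s: float = 2.5         #: Flory interaction parameter, crystal phase
    chi_l: float = 0.5         #: Flory interaction parameter, liquid phase
    N: float = 11.5            #: solute-to-water partial molar volume ratio
    T0: float = 273.15         #: equilibrium freezing temperature of pure water, K
    dT: float = 10.0           #: characteristic subcooled temperature, K
    beta_f: float = 100.0      #: bulk cooling rate, K/s
    g: float = 9.8             #: gravitational acceleration, m/s^2
    R_specific: float = 461.5  #: specific gas constant of water, J/(kg K)
    rho_c: float = 1587.0      #: solute (sucrose) density, kg/m^3
    eta_s_ratio: float = 1e4   #: crystal-to-reference viscosity ratio
    D_s_ratio: float = 1e-4    #: crystal-to-reference diffusivity ratio
    L: float = 1e-5            #: mesoscale length scale, m

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"MaterialParams.{f.name} must be positive and finite, got {v!r}")
        if not self.chi_s > self.chi_l:
            raise ValueError(
                f"solute exclusion requires chi_s > chi_l, got {self.chi_s} <= {self.chi_l}"
            )
        if self.eta_s_ratio < 1e4:
            raise ValueError("crystal viscosity must be >= 1e4 times the reference")
        if self.D_s_ratio >= 1e-2:
            raise ValueError("crystal diffusivity ratio D_s_ratio must be << 1")

    def with_overrides(self, **kwargs: float) -> "MaterialParams":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)

    @property
    def xi_sl_sq(self) -> float:
        """Gradient-energy coefficient rho0 * h_sl * W_sl**2 (phase field)."""
        return self.rho0 * self.h_sl * self.W_sl**2


def _check_finite(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite values in {name}: field is corrupted")
    return x


def _warn_range(T: np.ndarray) -> None:
    if np.any(T < _CORR_T_MIN) or np.any(T > _CORR_T_MAX):
        log.warning(
            "temperature outside the %g-%g K correlation range; extrapolating",
            _CORR_T_MIN,
            _CORR_T_MAX,
        )


def interp_P(phi_sl, deriv: bool = False):
    """Fifth-order solid/liquid interpolation polynomial.

    ``P = 1/2 - (15/16) (phi^5/5 - 2 phi^3/3 + phi)`` maps the phase field
    onto a liquid-fraction weight with ``P(-1) = 1``, ``P(+1) = 0`` and
    vanishing first and second derivatives at both pure phases, so every
    interpolated property is exactly its pure-phase branch there.

    The input is clamped to [-1, 1]: spectral overshoot beyond the wells
    maps onto the saturated weight with exactly zero derivative.

    Parameters
    ----------
    phi_sl : scalar or array
    deriv : bool
        When True, return ``(P, dP/dphi)``.
    """
    phi = _check_finite(phi_sl, "phi_sl")
    phi = np.clip(phi, -_PHI_SL_OVERSHOOT, _PHI_SL_OVERSHOOT)
    P = 0.5 - (15.0 / 16.0) * (phi**5 / 5.0 - 2.0 * phi**3 / 3.0 + phi)
    if not deriv:
        return P
    Pp = -(15.0 / 16.0) * (1.0 - phi**2) ** 2
    return P, Pp


def doublewell_G(phi_c):
    """Double-well mixing potential ``G = 4 phi_c^2 (1 - phi_c)^2``.

    Stands in for the ideal-mixing term phi_c (1 - phi_c) while keeping the
    solute volume fraction inside [0, 1].  Returns ``(G, G', G'')``.
    """
    c = _check_finite(phi_c, "phi_c")
    G = 4.0 * c**2 * (1.0 - c) ** 2
    Gp = 8.0 * c * (1.0 - c) * (1.0 - 2.0 * c)
    Gpp = 8.0 * (1.0 - 6.0 * c + 6.0 * c**2)
    return G, Gp, Gpp


def chi_mix(phi_sl, params: MaterialParams | None = None):
    """Phase-interpolated Flory parameter ``chi = P chi_l + (1-P) chi_s``.

    ``chi_s > chi_l`` makes mixing costlier in the crystal, which is what
    expels solute from the growing ice.  Returns ``(chi, dchi/dphi_sl)``.
    """
    p = params or MaterialParams()
    P, Pp = interp_P(phi_sl, deriv=True)
    chi = P * p.chi_l + (1.0 - P) * p.chi_s
    chip = Pp * (p.chi_l - p.chi_s)
    return chi, chip


# -- dimensional single-phase correlations (SI units) -----------------------

def rho_liquid(T, params: MaterialParams):
    """Supercooled liquid water density, kg/m^3."""
    return params.rho0 - 0.017 * (np.asarray(T) - params.T0) ** 2


def rho_ice(T, params: MaterialParams):
    """Ice density, kg/m^3 (ice is ~8% lighter than liquid at T0)."""
    return 0.917 * params.rho0 + 0.15 * (params.T0 - np.asarray(T))


def cp_liquid(T, phi_c, params: MaterialParams):
    """Supercooled sucrose-solution specific heat, J/(kg K)."""
    c = np.asarray(phi_c)
    return 4180.0 * (1.0 - 0.953 * c * (1.0 - 0.588 * c) + 1e-3 * (np.asarray(T) - params.T0))


def cp_ice(T, params: MaterialParams):
    """Ice specific heat, J/(kg K); solute-independent (strong exclusion)."""
    return params.cp0 + 8.0 * (np.asarray(T) - params.T0)


def k_liquid(T, phi_c, params: MaterialParams):
    """Supercooled sucrose-solution thermal conductivity, W/(m K)."""
    c = np.asarray(phi_c)
    return 0.58 * (1.0 - 0.905 * c * (1.0 - 0.588 * c) + 2.6e-3 * (np.asarray(T) - params.T0))


def k_ice(T, params: MaterialParams):
    """Ice thermal conductivity, W/(m K); increases on cooling."""
    return params.kT0 + 0.013 * (params.T0 - np.asarray(T))


def eta_liquid(T, phi_c=0.0, params: MaterialParams | None = None):
    """Liquid viscosity, Pa s: VTF temperature law x Mooney concentration law.

    ``eta = 4.442e-5 exp(2.288 * 168.9 / (T - 168.9)) * exp(6.3 phi_c / (1 - 0.85 phi_c))``

    The VTF prefactor is the viscosity at the singular temperature 168.9 K;
    evaluation at or below it raises.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= VTF_SINGULAR_T):
        raise ValueError(
            f"viscosity correlation is singular at T <= {VTF_SINGULAR_T} K"
        )
    c = np.clip(np.asarray(phi_c, dtype=float), 0.0, 1.0 - PHI_C_EPS)
    vtf = 4.442e-5 * np.exp(2.288 * VTF_SINGULAR_T / (T - VTF_SINGULAR_T))
    mooney = np.exp(6.3 * c / (1.0 - 0.85 * c))
    return vtf * mooney


# -- scaled, phase-interpolated properties ----------------------------------

def density_scaled(T, phi_sl, phi_c, params: MaterialParams | None = None):
    """Scaled local density rho/rho0.

    ``rho = phi_c rho_c + (1 - phi_c) [P rho_l(T) + (1-P) rho_s(T)]``.
    Water expands on freezing, so a moving front expels mass toward the
    liquid ("blowing" flux); that density contrast lives here.
    """
    p = params or MaterialParams()
    T = _check_finite(T, "T")
    _warn_range(T)
    P = interp_P(phi_sl)
    c = np.clip(np.asarray(phi_c, dtype=float), 0.0, 1.0)
    rho = c * p.rho_c + (1.0 - c) * (P * rho_liquid(T, p) + (1.0 - P) * rho_ice(T, p))
    rho_t = rho / p.rho0
    if np.any(rho_t <= 0):
        raise ValueError("non-physical (<= 0) density")
    return rho_t


def specific_heat_scaled(T, phi_sl, phi_c, params: MaterialParams | None = None):
    """Scaled specific heat cp/cp0, interpolated between ice and liquid."""
    p = params or MaterialParams()
    T = _check_finite(T, "T")
    _warn_range(T)
    P = interp_P(phi_sl)
    cp = P * cp_liquid(T, phi_c, p) + (1.0 - P) * cp_ice(T, p)
    cp_t = cp / p.cp0
    if np.any(cp_t <= 0):
        raise ValueError("non-physical (<= 0) specific heat")
    return cp_t


def thermal_conductivity_scaled(T, phi_sl, phi_c, params: MaterialParams | None = None):
    """Scaled thermal conductivity kT/kT0, interpolated between phases."""
    p = params or MaterialParams()
    T = _check_finite(T, "T")
    _warn_range(T)
    P = interp_P(phi_sl)
    kT = P * k_liquid(T, phi_c, p) + (1.0 - P) * k_ice(T, p)
    kT_t = kT / p.kT0
    if np.any(kT_t <= 0):
        raise ValueError("non-physical (<= 0) thermal conductivity")
    return kT_t


def viscosity_scaled(T, phi_sl, phi_c, params: MaterialParams | None = None):
    """Scaled dynamic viscosity eta/eta0.

    The crystal is treated as a highly viscous fluid with a constant
    scaled viscosity ``eta_s_ratio`` (>= 1e4); rigid-body behaviour of the
    crystals is emergent rather than imposed.
    """
    p = params or MaterialParams()
    T = _check_finite(T, "T")
    _warn_range(T)
    P = interp_P(phi_sl)
    eta_l_t = eta_liquid(T, phi_c, p) / p.eta0
    return P * eta_l_t + (1.0 - P) * p.eta_s_ratio


def diffusivity_scaled(T, phi_sl, phi_c, params: MaterialParams | None = None):
    """Scaled solute diffusivity D/D0 from the Stokes-Einstein relation.

    ``D_l/D0 = (T eta0) / (T0 eta_l(T, phi_c))``; in the crystal the
    diffusivity collapses to the small constant ``D_s_ratio``.
    """
    p = params or MaterialParams()
    T = _check_finite(T, "T")
    P = interp_P(phi_sl)
    D_l_t = (np.asarray(T, dtype=float) * p.eta0) / (p.T0 * eta_liquid(T, phi_c, p))
    return P * D_l_t + (1.0 - P) * p.D_s_ratio


def liquidus_temperature(phi_c, params: MaterialParams | None = None):
    """Liquidus of the sucrose-water system: ``Teq = T0 - 55 phi_c^2``.

    Returns ``(Teq, Teq_tilde)`` with ``Teq_tilde = (Teq - T0)/dT`` the
    scaled freezing-point depression.
    """
    p = params or MaterialParams()
    c = _check_finite(phi_c, "phi_c")
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("phi_c must lie in [0, 1] for the liquidus correlation")
    Teq = p.T0 - 55.0 * c**2
    return Teq, (Teq - p.T0) / p.dT


def interfacial_energy(params: MaterialParams | None = None) -> float:
    """Solid/liquid interfacial energy, J/m^2.

    One-dimensional equilibrium (tanh) profile gives
    ``gamma_sl = (2 sqrt(2)/3) rho0 h_sl W_sl T0``; with the defaults this
    is about half the free-surface tension of water at T0.
    """
    p = params or MaterialParams()
    return (2.0 * math.sqrt(2.0) / 3.0) * p.rho0 * p.h_sl * p.W_sl * p.T0


def property_table(
    T_values=None,
    phi_c_values=None,
    params: MaterialParams | None = None,
) -> pd.DataFrame:
    """Tabulate the dimensional correlations for plotting / QA.

    Produces the cross product of ``T_values`` and ``phi_c_values`` with
    columns T, phi_c, rho_l, rho_s, cp_l, cp_s, kT_l, kT_s, eta_l, D_l, Teq.
    """
    p = params or MaterialParams()
    if T_values is None:
        T_values = np.arange(233.15, 278.15 + 1e-9, 5.0)
    if phi_c_values is None:
        phi_c_values = np.array([0.0, 0.05, 0.1, 0.2, 0.35])
    rows = []
    for c in np.atleast_1d(phi_c_values):
        Teq, _ = liquidus_temperature(c, p)
        for T in np.atleast_1d(T_values):
            eta = eta_liquid(T, c, p)
            rows.append(
                dict(
                    T=float(T),
                    phi_c=float(c),
                    rho_l=float(rho_liquid(T, p)),
                    rho_s=float(rho_ice(T, p)),
                    cp_l=float(cp_liquid(T, c, p)),
                    cp_s=float(cp_ice(T, p)),
                    kT_l=float(k_liquid(T, c, p)),
                    kT_s=float(k_ice(T, p)),
                    eta_l=float(eta),
                    D_l=float(p.D0 * T * p.eta0 / (p.T0 * eta)),
                    Teq=float(Teq),
                )
            )
    return pd.DataFrame(rows)
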