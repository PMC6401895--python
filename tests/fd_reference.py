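"""Independent finite-difference reference for the coupled right-hand sides.

Second-order central differences on the periodic grid, written directly
from the governing equations with no shared machinery with the spectral
solver (numpy.roll stencils only).  Used as the convergence oracle: the
spectral RHS is treated as exact, and the FD evaluation must approach it
at O(dx^2) under grid refinement for smooth fields.
"""

from __future__ import annotations

import numpy as np

from cryophase.properties import (
    MaterialParams,
    chi_mix,
    diffusivity_scaled,
    doublewell_G,
    interp_P,
    liquidus_temperature,
    specific_heat_scaled,
    thermal_conductivity_scaled,
)
from cryophase.properties import rho_ice, rho_liquid
from cryophase.scaling import characteristic_times, dimensionless_groups


def _dx(f, h):
    return (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / (2 * h)


def _dy(f, h):
    return (np.roll(f, -1, axis=0) - np.roll(f, 1, axis=0)) / (2 * h)


def _lap(f, h):
    return (
        np.roll(f, -1, axis=0) + np.roll(f, 1, axis=0)
        + np.roll(f, -1, axis=1) + np.roll(f, 1, axis=1) - 4 * f
    ) / h**2


def _div(fx, fy, h):
    return _dx(fx, h) + _dy(fy, h)


def fd_rhs(phi, c, T_t, params: MaterialParams | None = None, omega_tilde=None):
    """FD evaluation of the three explicit right-hand sides (v = 0).

    Returns ``(rhs_phase, rhs_solute, rhs_thermal)`` on the same grid.
    """
    p = params or MaterialParams()
    scales = characteristic_times(p)
    g = dimensionless_groups(scales, p)
    n = phi.shape[0]
    h = 2 * np.pi / n
    eps = p.dT / p.T0
    T = p.T0 + p.dT * T_t
    P, Pp = interp_P(phi, deriv=True)
    G, Gp, Gpp = doublewell_G(c)
    chi, chip = chi_mix(phi, p)
    _, Teq_t = liquidus_temperature(np.clip(c, 0, 1), p)
    D = diffusivity_scaled(T, phi, c, p)

    thermo = (T_t - Teq_t) / ((1 + eps * T_t) * (1 + eps * Teq_t))
    rhs_phi = (
        g.Ch**2 * _lap(phi, h)
        + g.Lambda_sl * (1 - c) * Pp * thermo
        + (1 - c) * (phi - phi**3)
        - (p.R_specific / p.h_sl) * chip * G
    )

    r = scales.tau_sl / scales.tau_phic
    mob = c * (1 - c)
    A = D * ((1 - c) / p.N + c + mob * chi * Gpp)
    drift = D * mob * Gp * chip
    fx = A * _dx(c, h) + drift * _dx(phi, h)
    fy = A * _dy(c, h) + drift * _dy(phi, h)
    lap_c = _lap(c, h)
    bx = D * mob * _dx(lap_c, h)
    by = D * mob * _dy(lap_c, h)
    kappa = r * g.Ch**2 * p.h_sl / p.R_specific
    rhs_c = r * _div(fx, fy, h) - kappa * _div(bx, by, h)

    rho_l = rho_liquid(T, p) / p.rho0
    rho_s = rho_ice(T, p) / p.rho0
    rho = c * (p.rho_c / p.rho0) + (1 - c) * (P * rho_l + (1 - P) * rho_s)
    cp = specific_heat_scaled(T, phi, c, p)
    kT = thermal_conductivity_scaled(T, phi, c, p)
    a = kT / (rho * cp)
    T_abs = T_t + p.T0 / p.dT
    om = g.Omega_tilde if omega_tilde is None else omega_tilde
    rhs_T = (
        g.Le * _div(a * _dx(T_t, h), a * _dy(T_t, h), h)
        - (1 / (cp * g.Ste1)) * (Pp + g.Ste2 * T_abs * chip * G) * rhs_phi
        - (g.Ste2 / (cp * g.Ste1)) * T_abs * chi * Gp * rhs_c
        - om
    )
    return rhs_phi, rhs_c, rhs_T


def smooth_fields(n: int):
    """Deterministic smooth test fields fully resolved at n >= 32."""
    x = np.arange(n) * 2 * np.pi / n
    X, Y = np.meshgrid(x, x)
    phi = 0.6 * np.sin(X) * np.cos(Y) + 0.2 * np.cos(2 * X)
    c = 0.06 + 0.03 * np.cos(X) * np.cos(Y) + 0.01 * np.sin(2 * Y)
    T_t = -1.0 + 0.2 * np.sin(X + Y) + 0.1 * np.cos(2 * X - Y)
    return phi, c, T_t
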