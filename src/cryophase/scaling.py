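"""Characteristic scales and dimensionless groups of the freezing problem.

The governing equations are advanced in scaled form: lengths by the
mesoscale domain scale ``L``, time by the interfacial (phase-transition)
time ``tau_sl``, temperature by the characteristic subcooling ``dT``
through ``T_tilde = (T - T0)/dT``.  This module is the single source of
truth for the six characteristic times and for every dimensionless
coefficient that appears in the scaled PDEs, so the solver never
re-derives a prefactor.

Conventions
-----------
``tau_sl`` is an *input* (the interfacial mobility ``M_sl`` is
back-computed from it as ``1/(rho0 h_sl tau_sl)``); by default it is tied
to the solute diffusion time ``L^2/D0`` and the convective velocity is
``U = L/tau_sl``, which pins the Peclet number at 1.  The viscous time is
computed from its defining formula ``rho0 L^2 / eta0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .properties import MaterialParams

__all__ = ["ReferenceScales", "DimensionlessGroups", "characteristic_times",
           "dimensionless_groups", "groups_report"]


@dataclass(frozen=True)
class ReferenceScales:
    """Reference length/velocity/mobility and the six characteristic times."""

    L: float        #: length scale, m
    U: float        #: convective velocity scale, m/s
    M_sl: float     #: interfacial mobility, (J s / kg / K)^-1 scaled units
    tau_sl: float   #: solid/liquid phase-transition time, s
    tau_phic: float #: solute diffusion time L^2/D0, s
    tau_T: float    #: thermal diffusion time rho0 cp0 L^2 / kT0, s
    tau_vis: float  #: viscous diffusion time rho0 L^2 / eta0, s
    tau_conv: float #: convective time L/U, s
    tau_f: float    #: freezing (cooling) time dT/beta_f, s


@dataclass(frozen=True)
class DimensionlessGroups:
    """The ten dimensionless groups of the scaled system.

    ``Gr_coefficient`` is the prefactor multiplying the local density
    deficit ``(1 - rho_tilde)`` in the buoyancy term.
    """

    Pe: float             #: Peclet, convective vs diffusive solute transport
    Re: float             #: Reynolds, inertial vs viscous
    Lambda_sl: float      #: phase-change number La dT / (h_sl T0^2)
    Ch: float             #: Cahn-Hilliard number W_sl / L
    Le: float             #: interfacial Lewis number tau_sl / tau_T
    Ste1: float           #: Stefan number cp0 dT / La (sensible vs latent)
    Ste2: float           #: Stefan number R dT / La (partition vs latent)
    Omega_tilde: float    #: scaled uniform cooling rate tau_sl / tau_f
    Sc: float             #: Schmidt number tau_sl / tau_vis
    Gr_coefficient: float #: rho0 L^2 g / (eta0 U), times (1 - rho_tilde)


def characteristic_times(
    params: MaterialParams | None = None,
    tau_sl: float | None = None,
    U: float | None = None,
) -> ReferenceScales:
    """Compute all characteristic times from the material parameters.

    Parameters
    ----------
    tau_sl : float, optional
        Phase-transition time in seconds.  Defaults to the solute
        diffusion time ``L^2/D0`` (the published convention, giving
        tau_sl = tau_phic = tau_conv).
    U : float, optional
        Velocity scale; defaults to ``L/tau_sl`` (Pe = 1).
    """
    p = params or MaterialParams()
    tau_phic = p.L**2 / p.D0
    if tau_sl is None:
        tau_sl = tau_phic
    if tau_sl <= 0:
        raise ValueError("tau_sl must be positive")
    if U is None:
        U = p.L / tau_sl
    if U <= 0:
        raise ValueError("U must be positive")
    return ReferenceScales(
        L=p.L,
        U=U,
        M_sl=1.0 / (p.rho0 * p.h_sl * tau_sl),
        tau_sl=tau_sl,
        tau_phic=tau_phic,
        tau_T=p.rho0 * p.cp0 * p.L**2 / p.kT0,
        tau_vis=p.rho0 * p.L**2 / p.eta0,
        tau_conv=p.L / U,
        tau_f=p.dT / p.beta_f,
    )


def dimensionless_groups(
    scales: ReferenceScales | None = None,
    params: MaterialParams | None = None,
) -> DimensionlessGroups:
    """Assemble the dimensionless groups from the scales and parameters."""
    p = params or MaterialParams()
    s = scales or characteristic_times(p)
    return DimensionlessGroups(
        Pe=s.tau_sl / s.tau_conv,
        Re=s.tau_vis / s.tau_conv,
        Lambda_sl=p.La * p.dT / (p.h_sl * p.T0**2),
        Ch=p.W_sl / p.L,
        Le=s.tau_sl / s.tau_T,
        Ste1=p.cp0 * p.dT / p.La,
        Ste2=p.R_specific * p.dT / p.La,
        Omega_tilde=s.tau_sl / s.tau_f,
        Sc=s.tau_sl / s.tau_vis,
        Gr_coefficient=p.rho0 * p.L**2 * p.g / (p.eta0 * s.U),
    )


def groups_report(params: MaterialParams | None = None) -> pd.DataFrame:
    """Tabular report of scales and groups (for the ``groups`` CLI command)."""
    p = params or MaterialParams()
    s = characteristic_times(p)
    g = dimensionless_groups(s, p)
    from .properties import interfacial_energy

    rows = [
        ("length scale L [m]", p.L),
        ("interfacial thickness W_sl [m]", p.W_sl),
        ("interfacial energy gamma_sl [J/m^2]", interfacial_energy(p)),
        ("velocity scale U [m/s]", s.U),
        ("tau_sl [s]", s.tau_sl),
        ("tau_phic [s]", s.tau_phic),
        ("tau_T [s]", s.tau_T),
        ("tau_vis [s]", s.tau_vis),
        ("tau_conv [s]", s.tau_conv),
        ("tau_f [s]", s.tau_f),
        ("Pe", g.Pe),
        ("Re", g.Re),
        ("Lambda_sl", g.Lambda_sl),
        ("Ch", g.Ch),
        ("Le", g.Le),
        ("Ste1", g.Ste1),
        ("Ste2", g.Ste2),
        ("Omega_tilde", g.Omega_tilde),
        ("Sc", g.Sc),
        ("Gr coefficient (x (1 - rho_tilde))", g.Gr_coefficient),
    ]
    return pd.DataFrame(rows, columns=["quantity", "value"])
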