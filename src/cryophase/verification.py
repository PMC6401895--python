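"""Benchmarks turning published reference numbers and limits into checks.

Three tiers:

* :func:`table_regression` — desk-scale identities: the tabulated
  characteristic times, interfacial energy and dimensionless groups must
  be reproduced from the raw material constants alone.
* :func:`planar_front_benchmark` — a quasi-1-D two-phase slab: at the
  liquidus the front must be stationary and the interface must relax to
  the closed-form tanh profile of width ``sqrt(2) Ch``; under supercooling
  the front advances, and solute loading slows it.
* :func:`base_scenario` — the base 5-seed freeze-concentration run,
  tracked through scalar diagnostics (peak solute fraction, temperature
  range, crystal area fraction).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig, base_config
from .properties import MaterialParams, eta_liquid, interfacial_energy
from .scaling import characteristic_times, dimensionless_groups
from .solver import Diagnostics, FieldState, SeedSpec, Simulation, init_fields
from .spectral import SpectralGrid

__all__ = [
    "BenchmarkResult",
    "table_regression",
    "planar_front_benchmark",
    "base_scenario",
    "run_scenario",
    "fit_tanh_width",
]


@dataclass(frozen=True)
class BenchmarkResult:
    name: str
    computed: float
    reference: float
    tolerance: float  #: relative where reference != 0
    passed: bool
    runtime_s: float

    @staticmethod
    def compare(name, computed, reference, tolerance, runtime_s=0.0):
        if reference != 0:
            ok = abs(computed - reference) <= tolerance * abs(reference)
        else:
            ok = abs(computed) <= tolerance
        return BenchmarkResult(name, float(computed), float(reference),
                               tolerance, bool(ok), runtime_s)


#: Published reference values (Table-level anchors) with the tolerance at
#: which this implementation is expected to agree.  Sc and the viscous
#: time are recomputed from their defining formulas, which differ at the
#: sub-percent level from the rounded tabulated entries.
_TABLE_REFERENCES = (
    ("gamma_sl [J/m^2]", 0.0375, 0.005),
    ("tau_T [s]", 9.86e-5, 0.005),
    ("tau_phic [s]", 0.4762, 0.005),
    ("tau_f [s]", 0.1, 0.005),
    ("Lambda_sl", 312.88, 0.001),
    ("Le", 4830.6, 0.005),
    ("Ste1", 0.0621, 0.005),
    ("Ste2", 0.0136, 0.005),
    ("Ch", 0.1, 1e-9),
    ("Pe", 1.0, 1e-9),
    ("Omega_tilde", 4.762, 0.005),
    ("Re", 1.16e-4, 0.01),
    ("Sc", 8620.8, 0.01),
    ("Gr_coefficient", 25.92, 0.01),
    ("eta0 [Pa s]", 1.8e-3, 0.01),
    ("heat sink [J/m^3 s]", 2e8, 0.06),
)


def table_regression(params: MaterialParams | None = None) -> list[BenchmarkResult]:
    """Recompute every tabulated scale/group and compare with its reference."""
    p = params or MaterialParams()
    s = characteristic_times(p)
    g = dimensionless_groups(s, p)
    computed = {
        "gamma_sl [J/m^2]": interfacial_energy(p),
        "tau_T [s]": s.tau_T,
        "tau_phic [s]": s.tau_phic,
        "tau_f [s]": s.tau_f,
        "Lambda_sl": g.Lambda_sl,
        "Le": g.Le,
        "Ste1": g.Ste1,
        "Ste2": g.Ste2,
        "Ch": g.Ch,
        "Pe": g.Pe,
        "Omega_tilde": g.Omega_tilde,
        "Re": g.Re,
        "Sc": g.Sc,
        "Gr_coefficient": g.Gr_coefficient,
        "eta0 [Pa s]": float(eta_liquid(p.T0, 0.0, p)),
        "heat sink [J/m^3 s]": p.rho0 * p.cp0 * p.beta_f,
    }
    out = []
    for name, ref, tol in _TABLE_REFERENCES:
        t0 = time.perf_counter()
        out.append(BenchmarkResult.compare(name, computed[name], ref, tol,
                                           time.perf_counter() - t0))
    return out


def benchmarks_frame(results: list[BenchmarkResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def _slab_state(grid: SpectralGrid, ch: float, T_tilde: float, phi_c0: float,
                half_width: float = np.pi / 2, width_scale: float = 1.0) -> FieldState:
    """Quasi-1-D two-phase slab: solid band centred at x = pi."""
    n = grid.n
    w = width_scale * np.sqrt(2.0) * ch
    x = grid.x
    # distance to the slab centre along x, periodic
    d = np.abs(x - np.pi)
    phi = np.tanh((half_width - d) / w)
    solid = 0.5 * (1.0 + phi)
    return FieldState(
        phi_sl=phi,
        phi_c=phi_c0 * (1.0 - solid),
        T_tilde=np.full((n, n), float(T_tilde)),
        vx=np.zeros((n, n)),
        vy=np.zeros((n, n)),
        p_tilde=np.zeros((n, n)),
    )


def front_position(phi_line: np.ndarray, x_line: np.ndarray) -> float:
    """Right-hand zero crossing of a 1-D slab profile, by linear interpolation."""
    half = len(phi_line) // 2
    seg = phi_line[half:]
    xs = x_line[half:]
    idx = np.nonzero((seg[:-1] > 0) & (seg[1:] <= 0))[0]
    if len(idx) == 0:
        return float("nan")
    i = idx[0]
    f = seg[i] / (seg[i] - seg[i + 1])
    return float(xs[i] + f * (xs[i + 1] - xs[i]))


def fit_tanh_width(phi_line: np.ndarray, x_line: np.ndarray) -> float:
    """Least-squares tanh interface width of the right-hand front."""
    from scipy.optimize import curve_fit

    x0 = front_position(phi_line, x_line)
    if not np.isfinite(x0):
        return float("nan")
    sel = np.abs(x_line - x0) < 1.0
    def model(x, xc, w):
        return -np.tanh((x - xc) / w)
    popt, _ = curve_fit(model, x_line[sel], phi_line[sel], p0=(x0, 0.15))
    return float(abs(popt[1]))


def planar_front_benchmark(
    n: int = 128,
    T_tilde: float = 0.0,
    phi_c0: float = 0.0,
    t_end: float = 1.0,
    dt: float = 2e-4,
    params: MaterialParams | None = None,
    width_scale: float = 1.0,
):
    """Relax/advance a planar front; return positions, velocity and width.

    With ``T_tilde`` at the liquidus the front must be stationary and the
    profile relaxes to the equilibrium tanh of width ``sqrt(2) Ch``; a
    supercooled slab front advances into the liquid.  The temperature is
    held at the prescribed value (no recalescence feedback): the benchmark
    isolates the interface kinetics of the phase-field equation, whose
    driving term amplifies micro-Kelvin temperature drift by the
    phase-change number ~313.
    """
    p = params or MaterialParams()
    grid = SpectralGrid(n)
    sim = Simulation(grid, p, flow=False, omega_tilde=0.0,
                     evolve_temperature=False)
    ch = sim.groups.Ch
    state = _slab_state(grid, ch, T_tilde, phi_c0, width_scale=width_scale)
    n_steps = int(round(t_end / dt))
    sample = max(n_steps // 20, 1)
    times, positions = [], []
    x_line = grid.x[0]
    for i in range(0, n_steps, sample):
        state, _ = sim.advance(state, dt, min(sample, n_steps - i))
        times.append(state.t_tilde)
        positions.append(front_position(state.phi_sl[0], x_line))
    times = np.asarray(times)
    positions = np.asarray(positions)
    # front velocity from the second half of the trajectory
    half = len(times) // 2
    vel = np.polyfit(times[half:], positions[half:], 1)[0] if len(times) > 2 else np.nan
    width = fit_tanh_width(state.phi_sl[0], x_line)
    return {
        "times": times,
        "positions": positions,
        "front_velocity": float(vel),
        "fitted_width": width,
        "expected_width": float(np.sqrt(2.0) * ch),
        "state": state,
    }


def run_scenario(cfg: RunConfig, diag_every: int = 250, on_diagnostics=None):
    """Run a configured scenario; returns (final state, diagnostics list)."""
    import dataclasses

    params = cfg.material_params()
    grid = SpectralGrid(cfg.n)
    sim = Simulation(grid, params, flow=cfg.flow, gravity=cfg.gravity)
    seeds = cfg.seeds
    if seeds.positions is None:
        # random placement draws from the run-level RNG seed
        seeds = dataclasses.replace(seeds, rng_seed=cfg.rng_seed)
    state = init_fields(grid, seeds, cfg.phi_c0, cfg.T_tilde0, sim.groups.Ch)
    n_steps = int(round(cfg.t_end_tilde / cfg.dt_tilde))
    return sim.advance(state, cfg.dt_tilde, n_steps, diag_every=diag_every,
                       on_diagnostics=on_diagnostics)


def base_scenario(n: int = 128, t_end: float = 2.5, diag_every: int = 250,
                  on_diagnostics=None, **overrides) -> tuple[FieldState, list[Diagnostics]]:
    """The base 5-seed freeze-concentration run (reduced-resolution grid)."""
    if n < 128:
        raise ValueError("the base scenario requires n >= 128")
    cfg = base_config(n=n, t_end_tilde=t_end, **overrides)
    return run_scenario(cfg, diag_every=diag_every, on_diagnostics=on_diagnostics)
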