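"""Run configuration: TOML loading, validation, scenario presets.

A run is fully described by a :class:`RunConfig`: material-parameter
overrides (SI units), grid resolution, scaled time step and end time,
initial supercooling and solute loading, the seed specification, and the
flow/gravity toggles.  Unknown keys are rejected so that typos fail
loudly, and a config round-trips losslessly through its TOML form.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field, fields

import numpy as np

from .properties import MaterialParams
from .solver import SeedSpec

__all__ = ["RunConfig", "load_config", "base_config", "dense_seeding_config", "dumps_toml"]

_MATERIAL_KEYS = {f.name for f in fields(MaterialParams)}
_SEED_KEYS = {f.name for f in fields(SeedSpec)}


@dataclass(frozen=True)
class RunConfig:
    """Validated simulation configuration (scaled quantities carry _tilde)."""

    n: int = 128                    #: grid points per side
    dt_tilde: float = 2e-4          #: scaled time step
    t_end_tilde: float = 2.5        #: scaled end time
    output_interval_tilde: float = 0.1  #: diagnostics/snapshot cadence
    phi_c0: float = 0.05            #: initial solute volume fraction (liquid)
    T_tilde0: float = -1.0          #: initial scaled supercooling
    gravity: bool = True
    flow: bool = True
    outdir: str = "cryophase_out"
    rng_seed: int = 0
    material: dict = field(default_factory=dict)  #: MaterialParams overrides
    seeds: SeedSpec = field(default_factory=SeedSpec)

    def __post_init__(self) -> None:
        if self.dt_tilde <= 0:
            raise ValueError("dt_tilde must be positive")
        if self.t_end_tilde <= 0:
            raise ValueError("t_end_tilde must be positive")
        if self.output_interval_tilde <= 0:
            raise ValueError("output_interval_tilde must be positive")
        if not 0.0 <= self.phi_c0 < 1.0:
            raise ValueError("phi_c0 must lie in [0, 1)")
        unknown = set(self.material) - _MATERIAL_KEYS
        if unknown:
            raise ValueError(f"unknown material parameter(s): {sorted(unknown)}")

    def material_params(self) -> MaterialParams:
        return MaterialParams(**self.material)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        seeds = {k: v for k, v in d["seeds"].items() if v is not None}
        if "positions" in seeds:
            seeds["positions"] = [list(p) for p in np.asarray(seeds["positions"]).reshape(-1, 2)]
        d["seeds"] = seeds
        return d


def _from_dict(data: dict) -> RunConfig:
    data = dict(data)
    top_keys = {f.name for f in fields(RunConfig)}
    unknown = set(data) - top_keys
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    if "seeds" in data:
        seeds = dict(data["seeds"])
        bad = set(seeds) - _SEED_KEYS
        if bad:
            raise ValueError(f"unknown seeds key(s): {sorted(bad)}")
        if seeds.get("positions") is not None:
            seeds["positions"] = tuple(tuple(map(float, p)) for p in seeds["positions"])
        data["seeds"] = SeedSpec(**seeds)
    return RunConfig(**data)


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration; empty file -> defaults."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return _from_dict(data)


def _toml_value(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return repr(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)}")


def dumps_toml(cfg: RunConfig) -> str:
    """Serialise a RunConfig to TOML (lossless round-trip with load_config)."""
    d = cfg.to_dict()
    material = d.pop("material")
    seeds = d.pop("seeds")
    lines = [f"{k} = {_toml_value(v)}" for k, v in d.items()]
    if material:
        lines += ["", "[material]"] + [f"{k} = {_toml_value(v)}" for k, v in material.items()]
    lines += ["", "[seeds]"] + [f"{k} = {_toml_value(v)}" for k, v in seeds.items()]
    return "\n".join(lines) + "\n"


def _quincunx() -> tuple:
    """Five symmetric seed sites: four half-diagonal corners plus the centre."""
    h = np.pi / 2
    return ((h, h), (3 * h, h), (h, 3 * h), (3 * h, 3 * h), (np.pi, np.pi))


def base_config(n: int = 128, **overrides) -> RunConfig:
    """Base freeze-concentration scenario: 5 seeds, phi_c0 = 0.05, T_tilde0 = -1.

    Rapid uniform cooling at 100 K/s from 10 K of supercooling; runs to
    scaled time 2.5 by default.
    """
    kw = dict(
        n=n,
        phi_c0=0.05,
        T_tilde0=-1.0,
        t_end_tilde=2.5,
        seeds=SeedSpec(count=5, positions=_quincunx()),
    )
    kw.update(overrides)
    return RunConfig(**kw)


def dense_seeding_config(n: int = 128, **overrides) -> RunConfig:
    """Dense-seeding scenario: 25 seeds (denser on the left), phi_c0 = 0.02."""
    rng = np.random.default_rng(7)
    pos: list[tuple[float, float]] = []
    # 16 seeds on the left half, 9 on the right, jittered lattices
    for (nx, ny, x0, x1) in ((4, 4, 0.0, np.pi), (3, 3, np.pi, 2 * np.pi)):
        xs = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
        ys = (np.arange(ny) + 0.5) * 2 * np.pi / ny
        for x in xs:
            for y in ys:
                jit = rng.uniform(-0.08, 0.08, 2)
                pos.append((float(x + jit[0]), float(y + jit[1])))
    kw = dict(
        n=n,
        phi_c0=0.02,
        T_tilde0=-1.0,
        t_end_tilde=2.8,
        seeds=SeedSpec(count=25, positions=tuple(pos), min_separation=0.6),
    )
    kw.update(overrides)
    return RunConfig(**kw)
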