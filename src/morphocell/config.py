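"""Scenario configuration: defaults mirroring the published parameter
tables, YAML loading with strict validation, and deterministic seeding.

The default values reproduce the model's parameter tables verbatim
(kg–μm–min unit system): substrate stiffness 100, cell stiffness 5,
Poisson ratios 0.49/0.32, secretion rate 2.5, Robin coefficient 100,
viscosities 33.783/22.523, mobility 10, N = 40 membrane nodes, random-walk
weight 1, plasticity 0.1, and per-scenario radii/time steps/diffusivities.
Any override is logged.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields, replace
from math import sqrt
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = ["ScenarioConfig", "load_config", "dump_config", "default_config",
           "spawn_rngs", "TABLE6_MC_ERRORS"]

#: published Monte Carlo sample counts and phase-3 occurrence errors per
#: active-displacement mechanism
TABLE6_MC_ERRORS = {
    "chemotaxis": (1400, 9.2171e-3),
    "fixed-10": (1390, 9.7022e-3),
    "uniform-6-15": (1360, 1.2102e-2),
    "uniform-6-20": (1378, 1.0621e-2),
}

_SCENARIOS = ("chemotaxis", "differentiation", "collision", "microtube")


@dataclass
class ScenarioConfig:
    """All tunable parameters of one scenario run (kg–μm–min units)."""

    scenario: str = "chemotaxis"
    # shared material/cell parameters
    E_s: float = 100.0          # substrate elasticity, kg/(μm·min²)
    E_c: float = 5.0            # cell spring rate (min⁻¹ in the node law)
    E_c_elastic: float = 5.0    # cell elasticity for Hertz contact
    mu_f: float = 0.03          # wall friction coefficient
    nu_s: float = 0.49
    nu_c: float = 0.32
    k: float = 2.5              # secretion rate, kg/(μm³·min)
    kappa_s: float = 100.0      # Robin boundary coefficient
    mu1: float = 33.783         # shear viscosity
    mu2: float = 22.523         # bulk viscosity
    beta0: float = 10.0         # maximal membrane-point mobility, min⁻¹
    N: int = 40                 # membrane nodes per cell
    mu_m: float = 1.0           # mobility reduction coefficient
    sigma_rw: float = 1.0       # random-walk weight
    alpha: float = 0.1          # plasticity rate
    P: float = 10.0             # traction per unit membrane length, kg/min²
    #   (≈ 100 nN total over a 30 μm perimeter, the measured scale of
    #    cellular traction on soft gels)
    gamma: float = 1e-6         # chemotaxis gradient regulariser
    # scenario geometry / numerics
    R: float = 5.0              # cell radius, μm
    dt: float = 0.1             # time step, min
    D: float = 200.0            # signal diffusivity, μm²/min
    domain_x: float = 120.0
    domain_y: float = 120.0
    sub_x: float = 40.0         # central subdomain (initial cell placement)
    sub_y: float = 40.0
    mesh_h: float = 6.0         # coarse mesh size
    mesh_h_fine: float = 2.5    # refined mesh size near sources/channels
    t_end: float = 35.0         # simulated time, min
    n_cells: int = 4
    seed: int = 0
    quasi_static: bool = True
    # differentiation
    a_e: float = 6.25
    b_e: float = 4.0
    a_h: float = 20.0 / sqrt(6.0)
    b_h: float = 5.0 / sqrt(6.0)
    lambda_w: float = 10.0
    c_diff: float = 1e-3        # differentiation concentration threshold
    traction_factor: float = 2.0  # myofibroblast traction multiplier
    # microtube
    lc_width: float = 15.0
    snb_width: float = 3.3
    snb_length: float = 10.0
    lc_length: float = 50.0
    mechanism: str = "chemotaxis"
    signal_warmup: bool = True  # start from the steady source field
    runup: float = 10.0         # free distance before the channel mouth, μm

    def validate(self) -> "ScenarioConfig":
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        positive = ("E_s", "E_c", "E_c_elastic", "k", "beta0", "R", "dt",
                    "D", "domain_x", "domain_y", "mesh_h", "mesh_h_fine",
                    "t_end", "gamma", "lc_width", "snb_width", "snb_length",
                    "lc_length")
        bad = [n for n in positive if getattr(self, n) <= 0]
        nonneg = ("mu_f", "kappa_s", "mu1", "mu2", "mu_m", "sigma_rw",
                  "alpha", "P")
        bad += [n for n in nonneg if getattr(self, n) < 0]
        if self.N < 4:
            bad.append("N")
        if bad:
            raise ValueError(f"out-of-range configuration values: {bad}")
        return self


def default_config(scenario: str = "chemotaxis") -> ScenarioConfig:
    """Table-default configuration for one of the four scenarios."""
    base = ScenarioConfig(scenario=scenario)
    if scenario == "differentiation":
        return replace(base, D=233.2, t_end=8.0)
    if scenario == "collision":
        return replace(base, n_cells=2)
    if scenario == "microtube":
        return replace(base, R=9.0, dt=0.07, D=874.5,
                       domain_x=400.0, domain_y=400.0,
                       mesh_h=25.0, mesh_h_fine=3.0, t_end=60.0, n_cells=1)
    return base


def load_config(path_or_dict, scenario: str | None = None) -> ScenarioConfig:
    """Load a YAML configuration; missing keys fall back to the table
    defaults, unknown keys are rejected with a listing."""
    if isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    else:
        text = Path(path_or_dict).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration file must contain a mapping")
    scenario = data.pop("scenario", scenario or "chemotaxis")
    cfg = default_config(scenario)
    known = {f.name for f in fields(ScenarioConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown configuration keys: {unknown}")
    for key, value in data.items():
        if value != getattr(cfg, key):
            logger.info("config override: %s = %r (default %r)", key, value,
                        getattr(cfg, key))
        setattr(cfg, key, value)
    return cfg.validate()


def dump_config(cfg: ScenarioConfig, path=None) -> str:
    """Serialise a configuration to YAML (round-trips losslessly)."""
    text = yaml.safe_dump(asdict(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def spawn_rngs(seed: int, n: int, stream: str = "") -> list:
    """Independent child generators from one global seed.

    A counter-based spawn (SeedSequence) keyed additionally on the stream
    name, so adding a subsystem never perturbs the draws of another.
    """
    key = [seed] + [ord(c) for c in stream]
    ss = np.random.SeedSequence(key)
    return [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(n)]
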