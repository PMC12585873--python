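"""Run configuration: every model constant and protocol toggle in one place.

The defaults reproduce the reference parameterization of the allometric
bioenergetic model (ectotherm metabolic constant 0.88, quarter-power
allometry, basal mortality 0.4, Holling type-III functional response) and
the simulation protocol (extinction threshold 1e-6, 2000 time units at
step 0.1, last 500 recorded time units analysed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

SCHEMA_VERSION = "webstab-results-v1"


@dataclass
class RunConfig:
    # --- bioenergetic rates -------------------------------------------------
    ax: float = 0.88              # ectotherm metabolic constant, x_i = ax * M^b
    allometric_exponent: float = -0.25   # b in x_i = ax * M^b
    d0: float = 0.4               # basal natural mortality rate
    max_consumption: float = 4.0  # y_i, multiple of metabolic rate
    growth_rate: float = 1.0      # r_i of primary producers
    half_saturation: float = 0.5  # B0 of the functional response
    hill_exponent: float = 2.0    # h; 2 -> Holling type III
    alpha_intra: float = 1.0      # producer self-competition
    alpha_inter: float = 0.5      # producer cross-competition
    k_global: float = 10.0        # K', community-level producer capacity
    e_herbivory: float = 0.45     # assimilation efficiency, producer resource
    e_carnivory: float = 0.85     # assimilation efficiency, animal resource

    # --- simulation protocol ------------------------------------------------
    extinction_threshold: float = 1e-6
    dt: float = 0.1
    dt_fallback: float = 0.05     # used when instability is detected
    t_initial: float = 2000.0     # time units of the first integration pass
    t_extension: float = 1000.0   # added after extinctions / disconnections
    window: int = 500             # recorded points analysed (unit spacing)
    record_every: float = 1.0
    noise_burn_in: float = 10.0   # time units of noise discarded up front
    max_extensions: int = 10
    initial_biomass_low: float = 0.5
    initial_biomass_high: float = 1.0
    max_web_tries: int = 200      # niche-model rejection budget per (S, C)

    # --- protocol toggles ---------------------------------------------------
    equal_mortality: bool = False           # d_i = d0 for every species
    standardize_k: bool = True              # K_i scaled by producer number
    rebuild_web: bool = False               # reset omega/TL/mass after removals
    remove_unconsumed_producers: bool = True
    literal_covariance_mixing: bool = False  # mix noise by rho*sigma_e^2 matrix
    literal_assimilation: bool = False       # predation loss multiplied by e
    literal_wtl: bool = False                # wTL as sum of TL_i / B_i
    literal_ou_diffusion: bool = False       # OU diffusion sigma_e (sd != sigma_e)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        path.write_text(text)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt_fallback <= 0:
            raise ValueError("time steps must be positive")
        if self.extinction_threshold <= 0:
            raise ValueError("extinction threshold must be positive")
        if self.hill_exponent not in (1.0, 2.0):
            raise ValueError("hill exponent must be 1 or 2")
        if not (0 < self.e_herbivory <= 1 and 0 < self.e_carnivory <= 1):
            raise ValueError("assimilation efficiencies must lie in (0, 1]")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON) config; missing keys fall back to defaults."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else None
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    config.save(path)


def results_header() -> str:
    """Comment line prepended to every results CSV."""
    return f"# {SCHEMA_VERSION}"


def check_results_header(path: str | Path) -> None:
    with open(path) as fh:
        first = fh.readline().strip()
    if first != results_header():
        raise ValueError(
            f"results table at {path} has schema marker {first!r}; "
            f"expected {results_header()!r}"
        )
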