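"""Factorial in-silico experiment: build the design, run the ensemble,
assemble the results table that feeds the statistical stage.

Design factors follow the study ranges: initial richness S uniform on
[10, 60], target connectance C uniform on [0.02, 0.38] (re-drawn when the
niche model cannot produce an acceptable web there), environmental
stochasticity sigma_e on the 6-level grid 0.1..0.6, interspecific noise
correlation rho on the 5-level grid 0..1 (response diversity 1 - rho),
predator-prey mass ratio Z log-uniform on [1, 100] (it spans two decades)
and interference c uniform on [0, 1]. Each web is crossed with all five rho
levels under common random numbers: the web, the initial biomass and the
underlying OU noise draws are shared across the rho treatments, so the
response-diversity contrast is not confounded with sampling noise.

The default ensemble is 200 webs x 5 rho levels = 1000 runs (about a minute
on one CPU); the statistical stage estimates fifteen partially collinear
interaction coefficients, and a few hundred usable runs leave their signs
unstable run-to-run, so the default is sized for coefficient stability
rather than raw speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioenergetics import build_params
from .config import RunConfig, results_header
from .metrics import compute_metrics
from .niche import WebGenerationError, body_masses, generate_niche_web, trophic_levels
from .simulator import run_protocol
from .stability import full_partition

SIGMA_E_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
RHO_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class DesignRow:
    web_id: int
    s_init: int
    c_target: float
    sigma_e: float
    rho: float
    ppmr: float              # Z
    interference: float      # c
    web_seed: np.random.SeedSequence
    run_seed: np.random.SeedSequence

    @property
    def response_diversity(self) -> float:
        return 1.0 - self.rho


def _sample_feasible_web(rng: np.random.Generator, web_ss, config: RunConfig,
                         s_range=(10, 60), c_range=(0.02, 0.38),
                         max_outer: int = 50):
    """Draw (S, C) and build a niche web, re-drawing the combination when the
    rejection filters make it infeasible (high S x C webs rarely avoid
    cannibal links)."""
    web_rng = np.random.default_rng(web_ss)
    for _ in range(max_outer):
        S = int(rng.integers(s_range[0], s_range[1] + 1))
        C = float(rng.uniform(*c_range))
        try:
            web = generate_niche_web(S, C, web_rng, max_tries=config.max_web_tries)
        except WebGenerationError:
            continue
        return web, S, C
    raise WebGenerationError("could not build any acceptable web")


def build_design(n_webs: int = 200, seed: int | np.random.SeedSequence = 0,
                 rho_levels=RHO_LEVELS, sigma_levels=SIGMA_E_LEVELS,
                 config: RunConfig | None = None,
                 s_range=(10, 60), c_range=(0.02, 0.38),
                 z_range=(1.0, 100.0)):
    """Design rows plus their generated webs.

    Returns ``(rows, webs)`` where ``webs[web_id]`` is the FoodWeb shared by
    the ``len(rho_levels)`` rows of that web.
    """
    config = config or RunConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rows: list[DesignRow] = []
    webs: dict[int, object] = {}
    for web_id in range(n_webs):
        web_ss, run_ss = ss.spawn(2)
        web, S, C = _sample_feasible_web(rng, web_ss, config, s_range, c_range)
        webs[web_id] = web
        sigma_e = float(rng.choice(sigma_levels))
        Z = float(np.exp(rng.uniform(np.log(z_range[0]), np.log(z_range[1]))))
        c = float(rng.uniform(0.0, 1.0))
        for rho in rho_levels:
            rows.append(DesignRow(web_id, S, C, sigma_e, float(rho), Z, c,
                                  web_ss, run_ss))
    return rows, webs


def design_grid_sds() -> tuple[float, float]:
    """Population sds of the sigma_e and response-diversity design grids."""
    return (float(np.std(SIGMA_E_LEVELS)),
            float(np.std([1.0 - r for r in RHO_LEVELS])))


def run_one(row: DesignRow, web, config: RunConfig) -> dict:
    """Simulate one design row and return its results-table record."""
    tl = trophic_levels(web)
    masses = body_masses(tl, row.ppmr)
    params = build_params(web, tl, masses, row.interference, config)
    result = run_protocol(params, row.sigma_e, row.rho, row.run_seed, config)
    record = {
        "web_id": row.web_id,
        "s_init": row.s_init,
        "c_target": row.c_target,
        "sigma_e": row.sigma_e,
        "rho": row.rho,
        "response_diversity": row.response_diversity,
        "ppmr": row.ppmr,
        "interference": row.interference,
        "converged": result.converged,
        "degenerate": result.degenerate,
        "n_extensions": result.n_extensions,
        "dt_used": result.dt_used,
    }
    if result.converged and result.n_survivors > 0:
        m = compute_metrics(result, web, tl, params,
                            literal_wtl=config.literal_wtl)
        p = full_partition(result)
        record.update({
            "richness": m.richness_final,
            "connectance": m.connectance,
            "wtl": m.weighted_trophic_level,
            "max_tl": m.max_trophic_level,
            "omnivory": m.mean_omnivory,
            "interaction_strength": m.mean_interaction_strength,
            "total_biomass": m.total_biomass,
            "single_survivor": p.single_survivor,
            "undefined_partition": p.undefined,
        })
        record.update(p.as_dict())
        if not p.undefined:
            record.update(p.as_dict(log=True))
    return record


def run_ensemble(design, webs, config: RunConfig | None = None,
                 progress: bool = False) -> pd.DataFrame:
    """Execute every design row; per-row failures never abort the ensemble."""
    config = config or RunConfig()
    records = []
    iterator = design
    if progress:
        from tqdm import tqdm
        iterator = tqdm(design, desc="ensemble")
    for row in iterator:
        try:
            records.append(run_one(row, webs[row.web_id], config))
        except Exception as err:  # noqa: BLE001 - logged, not fatal
            records.append({
                "web_id": row.web_id, "s_init": row.s_init,
                "c_target": row.c_target, "sigma_e": row.sigma_e,
                "rho": row.rho, "response_diversity": row.response_diversity,
                "ppmr": row.ppmr, "interference": row.interference,
                "converged": False, "degenerate": True,
                "error": repr(err),
            })
    return pd.DataFrame.from_records(records)


def modelled_subset(table: pd.DataFrame) -> pd.DataFrame:
    """Converged, non-degenerate runs with finite log stability components."""
    ok = table["converged"].astype(bool) & ~table["degenerate"].astype(bool)
    for flag in ("undefined_partition", "single_survivor"):
        if flag in table:
            vals = table[flag].astype(object).where(table[flag].notna(), True)
            ok &= ~vals.astype(bool)
    sub = table[ok].copy()
    log_cols = [c for c in sub.columns if c.startswith("log_")]
    finite = np.isfinite(sub[log_cols].to_numpy(float)).all(axis=1)
    return sub[finite]


def save_results(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(results_header() + "\n")
        table.to_csv(fh, index=False)


def load_results(path) -> pd.DataFrame:
    from .config import check_results_header

    check_results_header(path)
    return pd.read_csv(path, comment="#")
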