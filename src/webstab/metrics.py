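"""Food-web covariates measured on a simulation: connectance, biomass-weighted
trophic level, omnivory, and time-averaged interaction strengths.

Dynamic quantities (biomass, interaction strengths, weighted trophic level)
are averaged over the 500 recorded time units; connectance and the trophic
levels themselves are static properties of the initial web.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bioenergetics import CommunityParams, functional_response
from .niche import FoodWeb
from .simulator import SimulationResult


@dataclass
class WebMetrics:
    total_biomass: float
    richness_final: int
    connectance: float
    weighted_trophic_level: float
    max_trophic_level: float
    mean_omnivory: float
    mean_interaction_strength: float


def connectance(web: FoodWeb) -> float:
    """Directed connectance C = L / (S (S - 1))."""
    S = web.n_species
    if S < 2:
        raise ValueError("connectance needs at least two species")
    return web.n_links / (S * (S - 1))


def weighted_trophic_level(tl: np.ndarray, mean_biomass: np.ndarray,
                           literal: bool = False) -> float:
    """Biomass-weighted mean trophic level over surviving species.

    ``literal=True`` evaluates the inverse-biomass-weighted sum
    sum_i TL_i / B_i instead (not an average; kept for comparison).
    """
    tl = np.asarray(tl, float)
    b = np.asarray(mean_biomass, float)
    alive = b > 0
    if not alive.any():
        raise ValueError("no surviving species")
    if literal:
        return float(np.sum(tl[alive] / b[alive]))
    return float(np.sum(b[alive] * tl[alive]) / b[alive].sum())


def omnivory(web: FoodWeb, tl: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Per-consumer omnivory: preference-weighted variance of resource
    trophic levels. Single-resource consumers and strict herbivores get 0."""
    S = web.n_species
    out = np.zeros(S)
    tl = np.asarray(tl, float)
    for i in range(S):
        res = np.nonzero(web.adjacency[i])[0]
        if res.size == 0:
            continue
        w = omega[i, res]
        w = w / w.sum()
        mean_tl = np.sum(w * tl[res])
        out[i] = np.sum(w * (tl[res] - mean_tl) ** 2)
    return out


def interaction_strengths(result: SimulationResult,
                          params: CommunityParams | None = None) -> np.ndarray:
    """Time-averaged biomass-flux matrix I_ij = <x_i y_i B_i F_ij>_t over the
    recorded window."""
    params = params or result.params
    B = result.recorded_biomass
    n_t, S = B.shape
    Bh = B ** params.h
    denom = params.B0 ** params.h + params.c * B + Bh @ params.omega.T
    F = params.omega[None, :, :] * Bh[:, None, :] / denom[:, :, None]
    I = (params.x * params.y * B)[:, :, None] * F
    return I.mean(axis=0)


def compute_metrics(result: SimulationResult, web: FoodWeb,
                    tl: np.ndarray, params: CommunityParams,
                    literal_wtl: bool = False) -> WebMetrics:
    """All covariates of one simulation, on the shared recorded window."""
    B = result.recorded_biomass
    mean_b = B.mean(axis=0)
    alive = result.alive
    I = interaction_strengths(result, params)
    nonzero = I[I > 0]
    omn = omnivory(web, tl, params.omega)
    consumers_alive = alive & ~web.is_producer
    return WebMetrics(
        total_biomass=float(B.sum(axis=1).mean()),
        richness_final=int(alive.sum()),
        connectance=connectance(web),
        weighted_trophic_level=weighted_trophic_level(tl, mean_b, literal_wtl),
        max_trophic_level=float(np.max(tl[alive])) if alive.any() else np.nan,
        mean_omnivory=float(omn[consumers_alive].mean())
        if consumers_alive.any() else 0.0,
        mean_interaction_strength=float(nonzero.mean()) if nonzero.size else 0.0,
    )
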