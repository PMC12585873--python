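"""Allometric bioenergetic rates and the deterministic biomass dynamics.

Consumer dynamics:

    dB_i/dt = sum_j x_i y_i B_i F_ij            (consumption gain)
            - sum_j x_j y_j B_j F_ji / e_ij     (predation loss)
            - x_i B_i                           (metabolic loss)
            - d_{i,t} B_i                       (natural mortality)

Producer dynamics:

    dB_i/dt = r_i B_i G_i - sum_j x_j y_j B_j F_ji / e_ij - d_{i,t} B_i

with logistic producer growth G_i = 1 - sum_{j in producers} alpha_ij B_j / K_i
and the multi-resource functional response

    F_ij = omega_ij B_j^h / (B0^h + c_i B_i + sum_k omega_ik B_k^h).

All physiological rates scale with body mass: x_i = ax M_i^(-1/4) and
d_i = d0 M_i^(-1/4). Dividing the predation loss by the assimilation
efficiency e makes the consumer's realized gain e times the biomass removed
from the resource, the standard bioenergetic bookkeeping; the
``literal_assimilation`` toggle multiplies by e instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .niche import FoodWeb


@dataclass
class CommunityParams:
    """Per-species and per-link rates for one community realization."""

    web: FoodWeb
    trophic_level: np.ndarray
    body_mass: np.ndarray
    x: np.ndarray                 # mass-specific metabolic rate
    y: float                      # maximum consumption, multiple of x
    d: np.ndarray                 # baseline natural mortality
    r: float                      # producer growth rate
    K: float                      # per-producer carrying capacity
    alpha_intra: float
    alpha_inter: float
    B0: float
    c: float                      # consumer interference
    h: float
    omega: np.ndarray             # (S, S) preferences, rows sum to 1 over diets
    e_mat: np.ndarray             # (S, S) efficiency of consumer i on resource j
    literal_assimilation: bool = False

    @property
    def is_producer(self) -> np.ndarray:
        return self.web.is_producer


def standardized_capacity(n_producers: int, alpha_offdiag: float, k_total: float,
                          standardize: bool = True) -> float:
    """Per-producer carrying capacity K_i = (1 + a (Sp - 1)) / Sp * K'.

    Keeps the joint producer equilibrium (hence basal energy input) constant
    as the number of producers varies; without standardization K_i = K'.
    """
    if n_producers < 1:
        raise ValueError("need at least one producer")
    if not standardize:
        return float(k_total)
    return (1.0 + alpha_offdiag * (n_producers - 1)) / n_producers * k_total


def build_params(web: FoodWeb, tl: np.ndarray, masses: np.ndarray,
                 c: float, config: RunConfig) -> CommunityParams:
    """Assemble every rate of the community from structure, masses and config."""
    S = web.n_species
    masses = np.asarray(masses, dtype=float)
    x = config.ax * masses ** config.allometric_exponent
    if config.equal_mortality:
        d = np.full(S, config.d0)
    else:
        d = config.d0 * masses ** config.allometric_exponent
    is_prod = web.is_producer
    n_res = web.adjacency.sum(axis=1)
    omega = np.zeros((S, S))
    consumers = n_res > 0
    omega[consumers] = web.adjacency[consumers] / n_res[consumers, None]
    # efficiency depends on the resource type: herbivory vs carnivory
    e_mat = np.where(is_prod[None, :], config.e_herbivory, config.e_carnivory)
    e_mat = np.where(web.adjacency, e_mat, 1.0)  # only defined on links
    K = standardized_capacity(int(is_prod.sum()), config.alpha_inter,
                              config.k_global, config.standardize_k)
    return CommunityParams(
        web=web, trophic_level=np.asarray(tl, float), body_mass=masses,
        x=x, y=config.max_consumption, d=d, r=config.growth_rate, K=K,
        alpha_intra=config.alpha_intra, alpha_inter=config.alpha_inter,
        B0=config.half_saturation, c=float(c), h=config.hill_exponent,
        omega=omega, e_mat=e_mat,
        literal_assimilation=config.literal_assimilation,
    )


def functional_response(B: np.ndarray, params: CommunityParams) -> np.ndarray:
    """Multi-resource functional response matrix F (consumer x resource).

    Each F_ij lies in [0, 1) and each consumer's row sums to < 1 because the
    half-saturation term keeps the denominator above the summed numerators.
    """
    B = np.asarray(B, dtype=float)
    Bh = B ** params.h
    denom = params.B0 ** params.h + params.c * B + params.omega @ Bh
    return params.omega * Bh[None, :] / denom[:, None]


def producer_growth(B: np.ndarray, params: CommunityParams) -> np.ndarray:
    """Logistic growth fraction G_i for producers (0 for consumers)."""
    B = np.asarray(B, dtype=float)
    is_prod = params.is_producer
    s_prod = B[is_prod].sum()
    G = np.zeros_like(B)
    comp = params.alpha_intra * B + params.alpha_inter * (s_prod - B)
    G[is_prod] = 1.0 - comp[is_prod] / params.K
    return G


def rhs(B: np.ndarray, d_t: np.ndarray, params: CommunityParams) -> np.ndarray:
    """Deterministic time derivative of biomass at realized mortality d_t.

    Reference (pure numpy) evaluation; the simulator uses a compiled kernel
    checked against this function.
    """
    B = np.asarray(B, dtype=float)
    d_t = np.asarray(d_t, dtype=float)
    F = functional_response(B, params)
    xyB = params.x * params.y * B
    gain = xyB * F.sum(axis=1)
    if params.literal_assimilation:
        loss = (xyB[:, None] * F * params.e_mat).sum(axis=0)
    else:
        loss = (xyB[:, None] * F / params.e_mat).sum(axis=0)
    is_prod = params.is_producer
    G = producer_growth(B, params)
    dB = np.where(
        is_prod,
        params.r * B * G - loss - d_t * B,
        gain - loss - params.x * B - d_t * B,
    )
    return dB
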