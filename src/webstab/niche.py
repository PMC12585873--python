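"""Niche-model food-web generation, trophic levels and allometric body masses.

Webs are drawn from the Williams–Martinez niche model: each species gets a
niche value n_i ~ U(0,1), a diet range r_i = n_i * x_i with
x_i ~ Beta(1, (1-2C)/(2C)) (expected connectance C), and a diet centre
c_i ~ U(r_i/2, min(n_i, 1-r_i/2)). Species i consumes every species whose
niche value falls inside [c_i - r_i/2, c_i + r_i/2]. Whole webs are
rejection-sampled until they contain no cannibalistic link and form a single
connected component; the species with the lowest niche value is forced to be
a producer so a basal resource always exists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


class WebGenerationError(RuntimeError):
    """Raised when no acceptable web is found within the rejection budget."""


@dataclass
class FoodWeb:
    """Directed consumer -> resource feeding structure.

    ``adjacency[i, j] = True`` means species i consumes species j.
    Producers are species without outgoing feeding links.
    """

    n_species: int
    adjacency: np.ndarray            # (S, S) boolean, consumer x resource
    niche_values: np.ndarray         # (S,) floats in [0, 1]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if self.adjacency.shape != (self.n_species, self.n_species):
            raise ValueError("adjacency shape does not match n_species")

    @property
    def links(self) -> set[tuple[int, int]]:
        cons, res = np.nonzero(self.adjacency)
        return {(int(i), int(j)) for i, j in zip(cons, res)}

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum())

    @property
    def is_producer(self) -> np.ndarray:
        return ~self.adjacency.any(axis=1)

    def connectance(self) -> float:
        s = self.n_species
        return self.n_links / (s * (s - 1)) if s > 1 else 0.0


def _draw_niche_web(S: int, C: float, rng: np.random.Generator) -> FoodWeb:
    n = rng.uniform(0.0, 1.0, S)
    beta_b = (1.0 - 2.0 * C) / (2.0 * C)
    ranges = n * rng.beta(1.0, beta_b, S)
    ranges[np.argmin(n)] = 0.0  # guarantee a basal producer
    lo = ranges / 2.0
    hi = np.minimum(n, 1.0 - ranges / 2.0)
    centres = rng.uniform(lo, hi)
    low = centres - ranges / 2.0
    high = centres + ranges / 2.0
    adjacency = (n[None, :] >= low[:, None]) & (n[None, :] <= high[:, None])
    adjacency &= ranges[:, None] > 0.0
    return FoodWeb(S, adjacency, n)


def _acceptable(web: FoodWeb) -> bool:
    if web.adjacency.diagonal().any():      # cannibalism
        return False
    if not web.is_producer.any():
        return False
    und = web.adjacency | web.adjacency.T
    if not und.any(axis=1).all():           # isolated species
        return False
    n_comp, _ = connected_components(csr_matrix(und), directed=False)
    return n_comp == 1


def generate_niche_web(
    S: int,
    C: float,
    seed: int | np.random.Generator,
    max_tries: int = 1000,
) -> FoodWeb:
    """Rejection-sample a niche-model web passing all structural filters.

    Parameters
    ----------
    S : initial species richness (>= 2).
    C : target directed connectance, 0 < C < 0.5.
    seed : integer seed or numpy Generator.
    max_tries : webs drawn before declaring the (S, C) combination infeasible.

    Raises
    ------
    WebGenerationError
        If no web passes the filters within ``max_tries`` draws; this signals
        an (S, C) combination where cannibal-free connected webs are too rare.
    """
    if S < 2:
        raise ValueError("need at least two species")
    if not 0.0 < C < 0.5:
        raise ValueError("target connectance must lie in (0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_tries):
        web = _draw_niche_web(S, C, rng)
        if _acceptable(web):
            return web
    raise WebGenerationError(
        f"no acceptable niche web for S={S}, C={C:.3f} in {max_tries} tries"
    )


def trophic_levels(web: FoodWeb) -> np.ndarray:
    """Prey-averaged trophic levels: TL_i = 1 + mean(TL of resources of i).

    Solved as the linear system (I - A_norm) TL = 1 where A_norm is the
    row-normalized diet matrix, which also handles feeding loops. Producers
    get exactly 1.
    """
    S = web.n_species
    counts = web.adjacency.sum(axis=1)
    a_norm = np.zeros((S, S))
    consumers = counts > 0
    a_norm[consumers] = web.adjacency[consumers] / counts[consumers, None]
    try:
        tl = np.linalg.solve(np.eye(S) - a_norm, np.ones(S))
    except np.linalg.LinAlgError as err:  # pragma: no cover - loops make it rare
        raise np.linalg.LinAlgError(
            "trophic-level system is singular (pathological feeding loops)"
        ) from err
    return tl


def body_masses(tl: np.ndarray, Z: float) -> np.ndarray:
    """Allometric body masses M_i = Z**(TL_i - 1) from the predator-prey
    mass ratio Z >= 1; producers (TL 1) have mass 1."""
    if Z < 1:
        raise ValueError("predator-prey mass ratio must be >= 1")
    return np.power(float(Z), np.asarray(tl) - 1.0)


# --------------------------------------------------------------------------
# serialization: edge-list text + JSON sidecar


def save_web(web: FoodWeb, path: str | Path, *, tl=None, masses=None, seed=None) -> None:
    path = Path(path)
    lines = [f"{i}\t{j}" for i, j in sorted(web.links)]
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "n_species": web.n_species,
        "niche_values": web.niche_values.tolist(),
        "trophic_level": None if tl is None else np.asarray(tl).tolist(),
        "body_mass": None if masses is None else np.asarray(masses).tolist(),
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_web(path: str | Path) -> FoodWeb:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    S = sidecar["n_species"]
    adjacency = np.zeros((S, S), dtype=bool)
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        i, j = map(int, line.split("\t"))
        adjacency[i, j] = True
    return FoodWeb(S, adjacency, np.asarray(sidecar["niche_values"], dtype=float))
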