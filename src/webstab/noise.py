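"""Correlated Ornstein-Uhlenbeck mortality noise: environmental stochasticity
(sigma_e) and response diversity (1 - rho).

Each species carries a stochastic mortality exponent eps_{i,t}; the realized
mortality rate is d_{i,t} = d_i * exp(eps_{i,t}), which keeps mortality
positive. eps is built in two steps:

1. independent mean-reverting OU processes a_i with unit reversion rate,
   da_i = -a_i dt + sqrt(2) sigma_e dW_i, so the stationary law is
   N(0, sigma_e^2) and the autocorrelation over a lag u is exp(-u);
2. cross-species mixing by the lower Cholesky factor of the equicorrelation
   matrix R (R_ii = 1, R_ij = rho), which preserves the marginal sd sigma_e
   and gives every species pair correlation rho. rho = 1 degenerates to a
   single shared process; rho = 0 leaves the columns independent.

The sqrt(2) diffusion scaling makes the stationary sd equal sigma_e; the
``literal_ou_diffusion`` toggle drops it (stationary sd sigma_e/sqrt(2)).
The ``literal_covariance_mixing`` toggle replaces the Cholesky factor by the
covariance matrix rho_ij * sigma_e^2 itself.
"""

from __future__ import annotations

import numpy as np


def equicorrelation_cholesky(n: int, rho: float) -> np.ndarray:
    """Lower Cholesky factor of the n x n equicorrelation matrix."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    R = np.full((n, n), rho)
    np.fill_diagonal(R, 1.0)
    return np.linalg.cholesky(R)


def simulate_ou(
    n_species: int,
    n_steps: int,
    dt: float,
    sigma_e: float,
    seed: int | np.random.Generator,
    scaled: bool = True,
) -> np.ndarray:
    """Exact-discretization OU sample paths, one independent column per species.

    Update: a_{t+dt} = a_t e^{-dt} + N(0, s^2 (1 - e^{-2 dt})) with stationary
    sd s = sigma_e (scaled=True) or s = sigma_e/sqrt(2) (literal diffusion).
    Columns start at stationarity.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = sigma_e if scaled else sigma_e / np.sqrt(2.0)
    out = np.empty((n_steps, n_species))
    decay = np.exp(-dt)
    innov_sd = s * np.sqrt(1.0 - decay * decay)
    a = rng.normal(0.0, s, n_species) if s > 0 else np.zeros(n_species)
    for t in range(n_steps):
        a = a * decay + (rng.normal(0.0, innov_sd, n_species) if s > 0
                         else 0.0)
        out[t] = a
    return out


def correlate(a: np.ndarray, rho: float, literal: bool = False,
              sigma_e: float | None = None) -> np.ndarray:
    """Mix independent OU columns into equicorrelated mortality exponents.

    rho = 0 returns ``a`` unchanged; rho = 1 replicates the first column
    (rank-1 construction, the Cholesky factor being singular there).
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[1]
    if literal:
        if sigma_e is None:
            raise ValueError("literal mixing needs sigma_e")
        R = np.full((n, n), rho * sigma_e**2)
        np.fill_diagonal(R, sigma_e**2)
        return a @ R.T
    if rho == 0.0:
        return a.copy()
    if rho == 1.0:
        return np.repeat(a[:, :1], n, axis=1)
    L = equicorrelation_cholesky(n, rho)
    return a @ L.T


def realized_mortality(epsilon: np.ndarray, d_baseline: np.ndarray) -> np.ndarray:
    """d_{i,t} = d_i exp(eps_{i,t}); strictly positive."""
    d = np.asarray(d_baseline, dtype=float)
    if np.any(d <= 0):
        raise ValueError("baseline mortality must be positive")
    return d[None, :] * np.exp(np.asarray(epsilon, dtype=float))


class NoiseGenerator:
    """Stateful stream of correlated OU mortality exponents.

    The stream can be extended chunk by chunk without breaking temporal
    continuity, which the simulation protocol needs when a run is prolonged
    after extinctions. A burn-in (default 10 time units) is discarded before
    the first chunk so the process starts at stationarity regardless of the
    (already stationary) initial draw.
    """

    def __init__(self, n_species: int, sigma_e: float, rho: float, dt: float,
                 seed: int | np.random.SeedSequence,
                 burn_in: float = 10.0,
                 scaled: bool = True, literal_mixing: bool = False) -> None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.n_species = n_species
        self.sigma_e = float(sigma_e)
        self.rho = float(rho)
        self.dt = float(dt)
        self.scaled = scaled
        self.literal_mixing = literal_mixing
        self._rng = np.random.default_rng(seed)
        self._s = self.sigma_e if scaled else self.sigma_e / np.sqrt(2.0)
        self._decay = np.exp(-self.dt)
        self._innov_sd = self._s * np.sqrt(1.0 - self._decay**2)
        self._a = (self._rng.normal(0.0, self._s, n_species)
                   if self._s > 0 else np.zeros(n_species))
        if not literal_mixing and 0.0 < rho < 1.0:
            self._L = equicorrelation_cholesky(n_species, rho)
        else:
            self._L = None
        n_burn = int(round(burn_in / dt))
        if n_burn:
            self._advance(n_burn)

    def _advance(self, n_steps: int) -> np.ndarray:
        out = np.empty((n_steps, self.n_species))
        a = self._a
        if self._s > 0:
            innov = self._rng.normal(0.0, self._innov_sd,
                                     (n_steps, self.n_species))
        else:
            innov = np.zeros((n_steps, self.n_species))
        for t in range(n_steps):
            a = a * self._decay + innov[t]
            out[t] = a
        self._a = a
        return out

    def steps(self, n_steps: int) -> np.ndarray:
        """Next ``n_steps`` rows of the mortality-exponent matrix eps."""
        a = self._advance(n_steps)
        if self.literal_mixing:
            return correlate(a, self.rho, literal=True, sigma_e=self.sigma_e)
        if self.rho == 0.0:
            return a
        if self.rho == 1.0:
            return np.repeat(a[:, :1], self.n_species, axis=1)
        return a @ self._L.T


def response_diversity(rho: float) -> float:
    """Response diversity is 1 - rho: 1 = independent responses, 0 = identical."""
    return 1.0 - rho
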