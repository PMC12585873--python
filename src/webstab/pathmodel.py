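"""Piecewise path analysis and the stability-richness slope model.

The path model is a directed acyclic graph fitted as one ordinary
least-squares regression per endogenous node (the piecewise formulation of a
structural equation model). Reported coefficients are standardized,
r_delta = b * sd(x) / sd(y), so a direct coefficient is a partial
correlation-scale quantity and the total effect of a source on a target is
the sum over all directed paths of the products of direct standardized
coefficients.

Default arrangement (right to left): environmental stochasticity sigma_e and
response diversity 1 - rho act on every species; realized richness, weighted
trophic level, connectance and mean interaction strength describe food-web
structure; these drive the asynchrony components (portfolio effects log PFE
and interaction-driven compensation log CPE_int) and population stability
log S_pop; asynchrony log phi collects its two components; community
stability log S_com collects population stability and asynchrony. The
predator-prey mass ratio and interference enter every node regression as
controls; omnivory is excluded (collinear with trophic level).

The slope model regresses log S_com on structure, sigma_e and response
diversity with the two-way interactions of richness with each structure
variable, with response diversity and with sigma_e, and the three-way
interactions of richness x structure x response diversity and
richness x structure x sigma_e; the web identifier enters as a random
intercept. Predictors are centred so the interaction terms stay
interpretable and multicollinearity stays low. The stability-richness slope
at a covariate setting is the sum of every richness-bearing coefficient
times the product of the (centred) values of its other variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

STRUCTURE_VARS = ["richness", "wtl", "connectance", "interaction_strength"]
CONTROL_VARS = ["ppmr", "interference"]
EXOGENOUS_DRIVERS = ["sigma_e", "response_diversity"]

DEFAULT_EQUATIONS: dict[str, list[str]] = {
    "log_s_com": ["log_s_pop", "log_phi"],
    "log_phi": ["log_pfe", "log_cpe_int"],
    "log_s_pop": STRUCTURE_VARS + EXOGENOUS_DRIVERS + CONTROL_VARS,
    "log_pfe": STRUCTURE_VARS + EXOGENOUS_DRIVERS + CONTROL_VARS,
    "log_cpe_int": STRUCTURE_VARS + EXOGENOUS_DRIVERS + CONTROL_VARS,
}

REPORTING_THRESHOLD = 0.05  # |r_delta| below this is not displayed


@dataclass
class PathModelFit:
    equations: dict[str, list[str]]
    coefficients: dict[tuple[str, str], float]   # raw b, keyed (response, predictor)
    rdelta: dict[tuple[str, str], float]         # standardized
    sds: dict[str, float]
    n: int

    def reported_edges(self, threshold: float = REPORTING_THRESHOLD):
        return {k: v for k, v in self.rdelta.items() if abs(v) >= threshold}

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"response": resp, "predictor": pred,
             "coefficient": self.coefficients[(resp, pred)],
             "rdelta": self.rdelta[(resp, pred)]}
            for (resp, pred) in self.rdelta
        ]
        return pd.DataFrame(rows)


def _check_dag(equations: dict[str, list[str]]) -> nx.DiGraph:
    g = nx.DiGraph()
    for resp, preds in equations.items():
        for p in preds:
            g.add_edge(p, resp)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("path-model edge set contains a cycle")
    return g


def fit_path_model(table: pd.DataFrame,
                   equations: dict[str, list[str]] | None = None) -> PathModelFit:
    """One OLS fit per endogenous node; standardized coefficients per edge."""
    equations = equations or DEFAULT_EQUATIONS
    _check_dag(equations)
    needed = set(equations) | {p for ps in equations.values() for p in ps}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")
    data = table[sorted(needed)].astype(float)
    sds = data.std(ddof=1).to_dict()
    coefs: dict[tuple[str, str], float] = {}
    rdelta: dict[tuple[str, str], float] = {}
    for resp, preds in equations.items():
        X = sm.add_constant(data[preds])
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(f"rank-deficient design for {resp}: {preds}")
        fit = sm.OLS(data[resp], X).fit()
        for p in preds:
            b = float(fit.params[p])
            coefs[(resp, p)] = b
            rdelta[(resp, p)] = b * sds[p] / sds[resp]
    return PathModelFit(equations, coefs, rdelta, sds, len(data))


def total_effects(model: PathModelFit) -> dict[tuple[str, str], float]:
    """Total standardized effect of every source on every reachable target:
    the path-sum of products of direct standardized coefficients."""
    g = _check_dag(model.equations)
    nodes = list(nx.topological_sort(g))
    idx = {n: i for i, n in enumerate(nodes)}
    M = np.zeros((len(nodes), len(nodes)))
    for (resp, pred), r in model.rdelta.items():
        M[idx[pred], idx[resp]] = r
    # DAG -> M is nilpotent, the geometric series terminates
    total = np.linalg.inv(np.eye(len(nodes)) - M) - np.eye(len(nodes))
    out: dict[tuple[str, str], float] = {}
    for s in nodes:
        for t in nodes:
            if s != t and nx.has_path(g, s, t):
                out[(s, t)] = float(total[idx[s], idx[t]])
    return out


# --------------------------------------------------------------------------
# stability-richness slope model


def _slope_terms() -> list[tuple[str, ...]]:
    struct = ["wtl", "connectance", "interaction_strength"]
    terms: list[tuple[str, ...]] = [("richness",)]
    terms += [(v,) for v in struct]
    terms += [("sigma_e",), ("response_diversity",)]
    terms += [(v,) for v in CONTROL_VARS]
    terms += [("richness", v) for v in struct]
    terms += [("richness", "response_diversity"), ("richness", "sigma_e")]
    terms += [("richness", v, "response_diversity") for v in struct]
    terms += [("richness", v, "sigma_e") for v in struct]
    return terms


@dataclass
class SlopeModelFit:
    coefficients: dict[tuple[str, ...], float]
    centres: dict[str, float]
    vif: dict[str, float]
    method: str
    n: int

    def max_vif(self) -> float:
        return max(self.vif.values())


def fit_slope_model(table: pd.DataFrame, method: str = "mixed") -> SlopeModelFit:
    """Linear model of log community stability with richness interactions and
    a web-level random intercept.

    ``method='mixed'`` fits a two-level mixed model (random intercept per
    web); ``method='demean'`` absorbs the web effect by within-web demeaning.
    A mixed fit that fails to converge falls back to demeaning.
    """
    terms = _slope_terms()
    base_vars = sorted({v for t in terms for v in t})
    data = table[base_vars + ["log_s_com", "web_id"]].astype(
        {v: float for v in base_vars}).copy()
    centres = {v: float(data[v].mean()) for v in base_vars}
    centred = {v: data[v].to_numpy(float) - centres[v] for v in base_vars}
    X = pd.DataFrame({
        ":".join(t): np.prod([centred[v] for v in t], axis=0) for t in terms
    }, index=data.index)
    y = data["log_s_com"].astype(float)

    vif_arr = X.to_numpy()
    vif = {col: float(variance_inflation_factor(vif_arr, i))
           for i, col in enumerate(X.columns)}
    bad = {k: v for k, v in vif.items() if v >= 3}
    if bad:
        import warnings

        warnings.warn(f"variance inflation factor >= 3 for {sorted(bad)}",
                      stacklevel=2)

    used = method
    params = None
    if method == "mixed":
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mixed = sm.MixedLM(y, sm.add_constant(X),
                                   groups=data["web_id"]).fit(reml=True)
            if np.all(np.isfinite(mixed.params.to_numpy())):
                params = mixed.params
            else:
                used = "demean"
        except Exception:  # noqa: BLE001 - singular fits fall back
            used = "demean"
    if params is None and used != "mixed":
        groups = data["web_id"]
        Xd = X - X.groupby(groups).transform("mean")
        yd = y - y.groupby(groups).transform("mean")
        params = sm.OLS(yd, Xd).fit().params
    elif params is None:
        params = sm.OLS(y, sm.add_constant(X)).fit().params
        used = "ols"

    coefs = {t: float(params[":".join(t)]) for t in terms}
    return SlopeModelFit(coefs, centres, vif, used, len(data))


def richness_slope(model: SlopeModelFit, covariates: dict[str, float]) -> float:
    """d log S_com / d richness at the given covariate values: the sum over
    every model term containing richness of its coefficient times the product
    of the other (centred) covariate values in that term."""
    slope = 0.0
    for term, coef in model.coefficients.items():
        if "richness" not in term:
            continue
        others = [v for v in term if v != "richness"]
        for v in others:
            if v not in covariates:
                raise KeyError(f"missing covariate {v!r} for term {term}")
        prod = np.prod([covariates[v] - model.centres[v] for v in others]) \
            if others else 1.0
        slope += coef * float(prod)
    return slope


def slope_surface(model: SlopeModelFit, base: dict[str, float],
                  rd_grid, var: str, var_grid) -> pd.DataFrame:
    """Richness-slope over a response-diversity x structure grid."""
    rows = []
    for rd in rd_grid:
        for v in var_grid:
            cov = dict(base)
            cov["response_diversity"] = float(rd)
            cov[var] = float(v)
            rows.append({"response_diversity": float(rd), var: float(v),
                         "slope": richness_slope(model, cov)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# synthetic results-table generator (oracle for the statistical stage)

DEFAULT_TRUE_COEFFICIENTS: dict[str, dict[str, float]] = {
    "log_s_pop": {"sigma_e": -3.2, "response_diversity": -0.12,
                  "richness": -0.004, "wtl": 0.25, "connectance": -0.3,
                  "interaction_strength": -2.0, "ppmr": 0.0004,
                  "interference": 0.05},
    "log_pfe": {"response_diversity": 1.1, "richness": 0.012, "wtl": -0.05,
                "connectance": -0.2, "interaction_strength": -1.5,
                "sigma_e": 0.05, "ppmr": 0.0, "interference": 0.0},
    "log_cpe_int": {"response_diversity": -0.15, "richness": 0.01,
                    "wtl": -0.2, "connectance": -1.0,
                    "interaction_strength": -0.5, "sigma_e": 0.02,
                    "ppmr": 0.0, "interference": 0.02},
    "log_phi": {"log_pfe": 1.0, "log_cpe_int": 1.0},
    "log_s_com": {"log_s_pop": 1.0, "log_phi": 1.0},
}


def generate_synthetic_table(
    path_coefficients: dict[str, dict[str, float]] | None = None,
    n: int = 5000,
    noise_sd: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Linear-Gaussian results table with known path coefficients.

    Exogenous columns follow the experiment design grids (sigma_e 6-level
    grid, rho 5-level grid) and plausible ranges for the structural
    covariates; endogenous columns follow the given acyclic linear system
    plus N(0, noise_sd) residuals. Returns the table and the ground-truth
    coefficients for recovery tests.
    """
    from .experiment import RHO_LEVELS, SIGMA_E_LEVELS

    coeffs = path_coefficients or DEFAULT_TRUE_COEFFICIENTS
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rho = rng.choice(RHO_LEVELS, n)
    table = pd.DataFrame({
        "web_id": np.arange(n) // max(len(RHO_LEVELS), 1),
        "sigma_e": rng.choice(SIGMA_E_LEVELS, n),
        "rho": rho,
        "response_diversity": 1.0 - rho,
        "richness": rng.integers(3, 31, n).astype(float),
        "wtl": rng.uniform(1.0, 3.0, n),
        "connectance": rng.uniform(0.02, 0.38, n),
        "interaction_strength": rng.uniform(0.001, 0.08, n),
        "ppmr": np.exp(rng.uniform(0.0, np.log(100.0), n)),
        "interference": rng.uniform(0.0, 1.0, n),
    })
    g = _check_dag({r: list(p) for r, p in coeffs.items()})
    for node in nx.topological_sort(g):
        if node not in coeffs:
            continue  # exogenous
        value = np.zeros(n)
        for pred, b in coeffs[node].items():
            value += b * table[pred].to_numpy(float)
        value += rng.normal(0.0, noise_sd, n)
        table[node] = value
    return table, coeffs
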