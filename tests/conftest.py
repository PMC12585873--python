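import numpy as np
import pytest

import webstab
from webstab.niche import FoodWeb


def make_web(S: int, links: list[tuple[int, int]],
             niche=None) -> FoodWeb:
    """Hand-built web: links are (consumer, resource) pairs."""
    adjacency = np.zeros((S, S), dtype=bool)
    for i, j in links:
        adjacency[i, j] = True
    niche = np.linspace(0.0, 1.0, S) if niche is None else np.asarray(niche)
    return FoodWeb(S, adjacency, niche)


@pytest.fixture(scope="session")
def sample_web():
    return webstab.generate_niche_web(15, 0.15, seed=11)


@pytest.fixture(scope="session")
def sample_result(sample_web):
    """One converged stochastic run, shared by metric and stability tests."""
    return webstab.simulate_community(sample_web, Z=10.0, c=0.5,
                                      sigma_e=0.3, rho=0.5, seed=42)


@pytest.fixture(scope="session")
def ensemble():
    """The default reduced ensemble (200 webs x 5 rho levels) used by the
    ensemble-level acceptance checks, plus its modelled subset."""
    design, webs = webstab.build_design(seed=1)
    table = webstab.run_ensemble(design, webs)
    return table, webstab.modelled_subset(table)
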