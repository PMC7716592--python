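"""Shared fixtures: small graphs and a reusable tiny model fit."""

import numpy as np
import pytest

import podsmooth as ps
from podsmooth.simulate import default_mu_profile


@pytest.fixture(scope="session")
def path_graph():
    return ps.build_graph([("a", "b"), ("b", "c")], ["a", "b", "c"])

@pytest.fixture(scope="session")
def lattice_4x4():
    return ps.make_lattice(4, 4)


@pytest.fixture(scope="session")
def tiny_truth(lattice_4x4):
    """Sparse synthetic dataset on a 4x4 lattice, 3 age groups."""
    return ps.simulate_dataset(
        lattice_4x4,
        A=3,
        mu_profile=default_mu_profile(3, p_first=5e-3, p_last=0.2),
        rho=0.6,
        sigma=0.5,
        gamma=0.8,
        populations=(100.0, 5000.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_fit(tiny_truth, lattice_4x4):
    """A short but real MCMC fit of the tiny dataset, reused across tests."""
    draws = ps.run_mcmc(
        tiny_truth.table,
        lattice_4x4,
        ps.PriorConfig(),
        ps.McmcConfig(n_chains=2, n_iter=1200, burn_in=400, thin=4, seed=21),
    )
    return draws


def random_connected_graph(rng: np.random.Generator, n: int) -> ps.SpatialGraph:
    """Random connected graph on n nodes: a random spanning tree plus extras."""
    ids = [f"v{i}" for i in range(n)]
    edges = []
    order = rng.permutation(n)
    for k in range(1, n):
        parent = order[rng.integers(0, k)]
        edges.append((ids[order[k]], ids[parent]))
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            edges.append((ids[i], ids[j]))
    return ps.build_graph(edges, ids)
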