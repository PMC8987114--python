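import numpy as np
import pytest

import coexdiff as cd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    """4 genes x 10 samples of random log-expression."""
    return cd.ExpressionMatrix(
        ("G1", "G2", "G3", "G4"),
        tuple(f"S{i}" for i in range(1, 11)),
        rng.standard_normal((4, 10)),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default simulation shared across read-only tests."""
    return cd.simulate(cd.SimulationParams(seed=7))


@pytest.fixture(scope="session")
def switch_sim():
    """A 50-gene module with 10 planted sign-switch pairs."""
    params = cd.SimulationParams(
        n_genes=50, module_sizes=(50,), rho=0.6, n_samples=(150, 80),
        trait_linked_modules=(), n_switch_pairs=10, switch_module=1, seed=11,
    )
    return cd.simulate(params)


def brute_force_tom(adj: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap, the independent oracle for tom()."""
    n = adj.shape[0]
    out = np.zeros_like(adj)
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
                continue
            l_ij = sum(adj[i, u] * adj[j, u] for u in range(n) if u not in (i, j))
            k_i = sum(adj[i, u] for u in range(n) if u != i)
            k_j = sum(adj[j, u] for u in range(n) if u != j)
            out[i, j] = (l_ij + adj[i, j]) / (min(k_i, k_j) + 1.0 - adj[i, j])
    return out


def random_adjacency(rng: np.random.Generator, n: int) -> cd.AdjacencyMatrix:
    raw = rng.uniform(0.0, 1.0, size=(n, n))
    sym = (raw + raw.T) / 2.0
    np.fill_diagonal(sym, 1.0)
    genes = tuple(f"g{i}" for i in range(n))
    return cd.AdjacencyMatrix(genes, sym, power=1)
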