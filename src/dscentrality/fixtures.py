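"""Deterministic toy graphs and seeded random-network generators.

Everything the test surface needs runs offline: canonical hand-analyzable
graphs (paths, stars, cycles, cliques) plus seeded Erdos-Renyi,
Barabasi-Albert and Watts-Strogatz generators that guarantee connectivity.

`EMPIRICAL_NETWORK_STATS` records the published headline statistics of four
widely used empirical benchmark networks (Erdos collaboration, URV email,
router-level Internet, human protein-protein interaction) so consistency
checks need no download; the networks themselves are optional external
inputs fetched by the user.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .network import Network

TOY_FAMILIES = ("path", "star", "cycle", "complete", "triangle_pendant")
RANDOM_MODELS = ("er", "ba", "ws")

# Published (n, e, <k>, 1/lambda1) of the four empirical benchmark networks.
EMPIRICAL_NETWORK_STATS = {
    "erdos": {"n": 454, "e": 1313, "avg_degree": 5.784, "inv_lambda1": 0.079},
    "email": {"n": 1133, "e": 5451, "avg_degree": 9.622, "inv_lambda1": 0.048},
    "router": {"n": 2114, "e": 6632, "avg_degree": 6.274, "inv_lambda1": 0.036},
    "protein": {"n": 2783, "e": 6007, "avg_degree": 4.317, "inv_lambda1": 0.063},
}


def toy_graph(family: str, n: int = 3) -> Network:
    """Canonical labeled toy graph.

    ``path``/``cycle``/``complete`` take the node count n; ``star`` takes the
    number of leaves (center is node 0); ``triangle_pendant`` is fixed: a
    triangle {0,1,2} with pendant node 3 attached to node 0.
    """
    if family == "path":
        edges = [(i, i + 1) for i in range(n - 1)]
    elif family == "star":
        edges = [(0, i) for i in range(1, n + 1)]
    elif family == "cycle":
        if n < 3:
            raise ValueError("cycle needs n >= 3")
        edges = [(i, (i + 1) % n) for i in range(n)]
    elif family == "complete":
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    elif family == "triangle_pendant":
        edges = [(0, 1), (0, 2), (1, 2), (0, 3)]
    else:
        raise ValueError(f"unknown toy family {family!r}; expected one of {TOY_FAMILIES}")
    return Network.from_edges(edges)


def _from_nx(g: nx.Graph) -> Network:
    return Network.from_edges(list(g.edges()), nodes=list(g.nodes()))


def random_graph(model: str, rng_seed: int, *, n: int, p: float | None = None,
                 m: int | None = None, k: int | None = None,
                 max_retries: int = 100) -> Network:
    """Seeded connected random graph: 'er' (G(n,p)), 'ba', or 'ws'.

    ER and WS draws are resampled (bounded retries, deterministic retry
    seeds) until connected; BA graphs are connected by construction.
    """
    seed_stream = np.random.default_rng(rng_seed)
    if model == "ba":
        if m is None:
            raise ValueError("ba model requires m (edges per new node)")
        g = nx.barabasi_albert_graph(n, m, seed=int(seed_stream.integers(2**31)))
        return _from_nx(g)
    if model == "er":
        if p is None:
            raise ValueError("er model requires p (edge probability)")
        make = lambda s: nx.gnp_random_graph(n, p, seed=s)  # noqa: E731
    elif model == "ws":
        if k is None or p is None:
            raise ValueError("ws model requires k (ring neighbors) and p (rewiring prob)")
        make = lambda s: nx.watts_strogatz_graph(n, k, p, seed=s)  # noqa: E731
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {RANDOM_MODELS}")
    for _ in range(max_retries):
        g = make(int(seed_stream.integers(2**31)))
        if nx.is_connected(g):
            return _from_nx(g)
    raise RuntimeError(
        f"could not generate a connected {model} graph in {max_retries} tries"
    )
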