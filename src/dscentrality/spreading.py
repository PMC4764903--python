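"""Discrete-time SIR/SI epidemic simulation and an exact enumeration oracle.

The Monte-Carlo simulator produces the ground-truth spreading influence that
centrality rankings are scored against: the expected number of non-susceptible
(infected + recovered) nodes at time t, starting from a single infected seed.

Dynamics per synchronous step: every node infected at the start of the step
contacts each susceptible neighbor independently, infecting it with
probability beta (so a susceptible node with m infected neighbors becomes
infected with probability 1-(1-beta)^m); then each node infected at the
start of the step recovers with probability mu. Newly infected nodes neither
transmit nor recover until the next step. mu = 0 is the SI model.

For tiny systems (n <= 8, t <= 4) `exact_expected_influence` and
`exact_infection_probabilities` enumerate the full outcome space exactly,
serving as the oracle the simulator and the linearized centrality are
validated against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .centrality import SpreadingParams
from .network import Network

SUSCEPTIBLE, INFECTED, RECOVERED = 0, 1, 2


class EnumerationGuardError(ValueError):
    """Raised when exact enumeration would be intractable; use Monte Carlo."""


@dataclass(frozen=True)
class EpidemicTrajectory:
    """Per-step compartment counts of one realization, including step 0."""

    counts: np.ndarray  # shape (t+1, 3): columns S, I, R

    @property
    def n_steps(self) -> int:
        return self.counts.shape[0] - 1

    def influence(self) -> int:
        """Non-susceptible count (#I + #R) at the final step."""
        return int(self.counts[-1, 1] + self.counts[-1, 2])

    def to_dict(self) -> dict:
        return {
            "steps": list(range(self.counts.shape[0])),
            "S": self.counts[:, 0].tolist(),
            "I": self.counts[:, 1].tolist(),
            "R": self.counts[:, 2].tolist(),
        }


@dataclass(frozen=True)
class InfluenceEstimate:
    """Monte-Carlo estimate of one node's spreading influence at horizon t."""

    node: int
    t: int
    mean_influence: float
    n_runs: int
    std_error: float

    def to_dict(self) -> dict:
        return {
            "node": self.node,
            "t": self.t,
            "mean_influence": self.mean_influence,
            "n_runs": self.n_runs,
            "std_error": self.std_error,
        }


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _dense_adjacency32(net: Network) -> np.ndarray:
    return net.adjacency(sparse=False).astype(np.float32)


def step(
    status: np.ndarray,
    net: Network,
    beta: float,
    mu: float,
    rng,
    _A: np.ndarray | None = None,
) -> np.ndarray:
    """Advance one epidemic state by a single synchronous step.

    ``status`` is a length-n int array over {0: S, 1: I, 2: R}. Infections
    are resolved before recoveries, both using the infected set from the
    start of the step; the input array is not modified.
    """
    rng = _as_rng(rng)
    status = np.asarray(status)
    A = _dense_adjacency32(net) if _A is None else _A
    infected = status == INFECTED
    m = infected.astype(np.float32) @ A
    p_inf = 1.0 - (1.0 - beta) ** m
    new_status = status.copy()
    susceptible = status == SUSCEPTIBLE
    newly_infected = susceptible & (rng.random(status.shape[0]) < p_inf)
    recovered = infected & (rng.random(status.shape[0]) < mu)
    new_status[newly_infected] = INFECTED
    new_status[recovered] = RECOVERED
    return new_status


def simulate(net: Network, seed_node: int, params: SpreadingParams, rng) -> EpidemicTrajectory:
    """One stochastic trajectory: per-step S/I/R counts from step 0 to t."""
    if not 0 <= seed_node < net.n:
        raise IndexError(f"seed node {seed_node} out of range for n={net.n}")
    rng = _as_rng(rng)
    A = _dense_adjacency32(net)
    status = np.zeros(net.n, dtype=np.int8)
    status[seed_node] = INFECTED
    counts = np.zeros((params.t + 1, 3), dtype=np.int64)
    counts[0] = [net.n - 1, 1, 0]
    for k in range(1, params.t + 1):
        status = step(status, net, params.beta, params.mu, rng, _A=A)
        counts[k] = [
            int(np.sum(status == SUSCEPTIBLE)),
            int(np.sum(status == INFECTED)),
            int(np.sum(status == RECOVERED)),
        ]
    return EpidemicTrajectory(counts=counts)


def _batch_influences(
    A32: np.ndarray,
    seed_node: int,
    beta: float,
    mu: float,
    t: int,
    n_runs: int,
    rng: np.random.Generator,
    batch_size: int = 20000,
) -> np.ndarray:
    """Final (#I + #R) of ``n_runs`` replicates, vectorized across replicates.

    Replicates are advanced jointly as rows of a status matrix; one RNG
    stream drives the whole batch, so results are deterministic given the
    stream but not attributable to individual replicates.
    """
    n = A32.shape[0]
    out = np.empty(n_runs, dtype=np.int64)
    done = 0
    while done < n_runs:
        b = min(batch_size, n_runs - done)
        status = np.zeros((b, n), dtype=np.int8)
        status[:, seed_node] = INFECTED
        for _ in range(t):
            infected = status == INFECTED
            if not infected.any():
                break
            m = infected.astype(np.float32) @ A32
            p_inf = 1.0 - (1.0 - np.float32(beta)) ** m
            newly = (status == SUSCEPTIBLE) & (
                rng.random((b, n), dtype=np.float32) < p_inf
            )
            if mu > 0:
                recov = infected & (rng.random((b, n), dtype=np.float32) < mu)
                status[recov] = RECOVERED
            status[newly] = INFECTED
        out[done : done + b] = (status != SUSCEPTIBLE).sum(axis=1)
        done += b
    return out


def spreading_influence(
    net: Network,
    node: int,
    params: SpreadingParams,
    n_runs: int,
    rng,
) -> InfluenceEstimate:
    """Monte-Carlo mean of (#I + #R) at step t with ``node`` as the seed.

    The seed counts toward the total, so the estimate is at least 1.
    Reproducible given the same seed or Generator.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 0 <= node < net.n:
        raise IndexError(f"seed node {node} out of range for n={net.n}")
    rng = _as_rng(rng)
    finals = _batch_influences(
        _dense_adjacency32(net), node, params.beta, params.mu, params.t, n_runs, rng
    )
    mean = float(finals.mean())
    se = float(finals.std(ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else 0.0
    return InfluenceEstimate(
        node=node, t=params.t, mean_influence=mean, n_runs=n_runs, std_error=se
    )


def _exact_state_distribution(net: Network, seed: int, params: SpreadingParams) -> dict:
    """Exact distribution over joint S/I/R states at step t by enumeration.

    Every per-contact infection and per-node recovery Bernoulli outcome is
    enumerated step by step. Guarded to n <= 8 and t <= 4.
    """
    if net.n > 8 or params.t > 4:
        raise EnumerationGuardError(
            f"exact enumeration guarded to n <= 8 and t <= 4 "
            f"(got n={net.n}, t={params.t}); use Monte Carlo instead"
        )
    neighbors = [[] for _ in range(net.n)]
    for i, j in net.edges:
        neighbors[i].append(j)
        neighbors[j].append(i)
    beta, mu = params.beta, params.mu
    init = tuple(
        INFECTED if i == seed else SUSCEPTIBLE for i in range(net.n)
    )
    dist = {init: 1.0}
    for _ in range(params.t):
        new_dist: dict = {}
        for state, prob in dist.items():
            options = []
            for node, s in enumerate(state):
                if s == SUSCEPTIBLE:
                    m = sum(1 for nb in neighbors[node] if state[nb] == INFECTED)
                    if m == 0:
                        options.append(((SUSCEPTIBLE, 1.0),))
                    else:
                        p = 1.0 - (1.0 - beta) ** m
                        opts = []
                        if p > 0:
                            opts.append((INFECTED, p))
                        if p < 1:
                            opts.append((SUSCEPTIBLE, 1.0 - p))
                        options.append(tuple(opts))
                elif s == INFECTED:
                    opts = []
                    if mu > 0:
                        opts.append((RECOVERED, mu))
                    if mu < 1:
                        opts.append((INFECTED, 1.0 - mu))
                    options.append(tuple(opts))
                else:
                    options.append(((RECOVERED, 1.0),))
            for combo in itertools.product(*options):
                new_state = tuple(c[0] for c in combo)
                p = prob
                for c in combo:
                    p *= c[1]
                new_dist[new_state] = new_dist.get(new_state, 0.0) + p
        dist = new_dist
    return dist


def exact_expected_influence(net: Network, node: int, params: SpreadingParams) -> float:
    """Exact expectation of (#I + #R) at step t by full enumeration (n<=8, t<=4)."""
    dist = _exact_state_distribution(net, node, params)
    return float(
        sum(p * sum(1 for s in state if s != SUSCEPTIBLE) for state, p in dist.items())
    )


def exact_infection_probabilities(net: Network, node: int, params: SpreadingParams) -> np.ndarray:
    """Exact per-node probability of being infected during steps 1..t.

    Because recovered nodes are never re-infected, a node other than the seed
    has been infected by step t iff it is non-susceptible at step t. The seed
    itself is infected at step 0 and can never be infected again, so its
    entry is 0. This is the quantity the linearized
    `centrality.infection_probabilities` overestimates entrywise.
    """
    dist = _exact_state_distribution(net, node, params)
    probs = np.zeros(net.n)
    for state, p in dist.items():
        for i, s in enumerate(state):
            if s != SUSCEPTIBLE:
                probs[i] += p
    probs[node] = 0.0
    return probs
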