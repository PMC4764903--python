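# dscentrality

Locating influential spreaders in a network requires more than topology:
which node seeds the largest epidemic depends on the spreading rate and on
how long the process runs. `dscentrality` implements the
**dynamics-sensitive (DS) centrality**, a spreading-rate- and time-aware
node-influence score for discrete-time SIR/SI epidemics on undirected
networks, together with the Monte-Carlo simulator and Kendall-tau protocol
used to validate it. It is aimed at network scientists and computational
epidemiologists who need node rankings that track a *specific* dynamical
regime rather than a purely structural index.

## The model

For a simple undirected connected network with adjacency matrix **A**
(largest eigenvalue λ₁), spreading rate β, recovery rate μ and time horizon
t, define the propagation matrix

    H = βA + (1 − μ)I.

The DS score of node *i* is the *i*-th entry of

    S(t) = Σ_{r=1..t} βA · H^{r−1} · 1,

the linearized expected outbreak size at time t when *i* is the single
initial seed (the exact per-contact probability 1 − (1−β)^m is approximated
by mβ, so entries may exceed 1 by design). Useful special cases:

- **t = 1:** S(1) = β·degree — the DS ranking is the degree ranking.
- **μ = 1 (one-shot SIR):** S(t) = Σ_{r=1..t} β^r A^r 1, a walk count with
  walks of length r weighted by β^r.
- **βλ₁ + 1 − μ < 1:** S(t) converges; the limit solves (I − H)y = 1,
  S(∞) = βAy (`ds_centrality_limit`). Above this epidemic threshold S(t)
  diverges and, as t grows, its ranking approaches the eigenvector
  centrality (leading eigenvector **q₁**).

Ground truth comes from the discrete-time simulator: each infected node
infects each susceptible neighbor with probability β per step, then recovers
with probability μ (μ = 0 is the SI model). A node's spreading influence is
the expected number of non-susceptible nodes at step t from a single seed.
Rankings are compared with Kendall's tau-a.

## Worked example

```python
import numpy as np
from dscentrality import toy_graph, ds_centrality
from dscentrality.centrality import SpreadingParams

path3 = toy_graph("path", 3)            # a - b - c
S = ds_centrality(path3.adjacency(), SpreadingParams(beta=0.1, mu=1.0, t=2))
print(S)                                 # [0.12 0.22 0.12]
```

The middle node scores 0.22 = β·2 + β²·2 (two walks of length 1 and two of
length 2 start there), the ends 0.12 = β·1 + β²·2: with a short horizon and
small β the center of the path is roughly twice as influential as its ends.

From the shell, the same pipeline at experiment scale:

```sh
dsc fixtures --family ba --n 200 --m 3 --rng-seed 1 -o ba.edgelist
dsc summary ba.edgelist
dsc centrality --method ds --beta 0.05 --mu 1 --t 5 ba.edgelist -o scores.csv
dsc evaluate --beta-grid 0.01:0.10:0.01 --mu 1 --t 5 --runs 500 \
    --methods ds,degree,kshell,eigenvector --rng-seed 1 ba.edgelist -o table.csv
```

`table.csv` holds one Kendall-tau row per (β, method) against the same
simulated influence vector; on this Barabási–Albert fixture the DS column
dominates degree, k-shell and eigenvector centrality across the grid
(k-shell is uniform on BA graphs, so its tau is 0).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch: it generates a seeded BA(200, 3)
network, prints its summary statistics and the top-ranked node under each
centrality, simulates spreading influence for every node over
β ∈ {0.01, …, 0.10} (μ = 1, t = 5, 500 runs per seed node), and prints the
mean Kendall tau of each method over the grid, e.g.

```
network: n=200 e=591 <k>=5.910 1/lambda1=0.0894
mean Kendall tau over the beta grid:
  ds           0.8050
  eigenvector  0.6671
  degree       0.5883
  kshell       0.0000
```

See `docs/methods.md` for assumptions, numerical choices and limitations.
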