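# Methods

## Model and assumptions

The dynamics-sensitive (DS) centrality scores node *i* by the linearized
expected outbreak size of a discrete-time SIR/SI epidemic seeded at *i*:

    S(t) = Σ_{r=1..t} βA · H^{r−1} · 1,    H = βA + (1 − μ)I,

on a simple undirected network with binary, symmetric, zero-diagonal
adjacency matrix A. Two deliberate approximations are inherited from the
underlying linear recursion for the per-node cumulative infection
probabilities x(t):

1. **Linear coupling.** A susceptible node with m infected neighbors is
   treated as infected with probability mβ instead of the exact
   1 − (1 − β)^m. Scores (and x(t) entries) may therefore exceed 1; they are
   *not* capped, because the ranking, not the probability scale, is the
   object of interest.
2. **No depletion.** Nodes are treated as still susceptible at every step,
   so every infection probability is overestimated. The exact rule lives
   only in the simulator; the enumeration oracle verifies the entrywise
   overestimation property on all tractable fixtures.

Equivalent computational routes, each exposed and cross-checked against the
others: the iterated matrix–vector recursion (`ds_centrality`,
O(t·e) with sparse products, never dense matrix powers), the spectral
assembly (`ds_spectral`, dense eigendecomposition, mode *i* weighted by
βλᵢ·Σ_{r=1..t}(βλᵢ+1−μ)^{r−1}; intended for n ≲ 3000), and the closed-form
limit (`ds_centrality_limit`, solving (I − H)y = 1 then S = βAy, valid only
below the epidemic threshold βλ₁ + 1 − μ < 1; above it the series diverges
and the function raises).

## Parameters

| parameter | meaning | range | default |
|---|---|---|---|
| β | per-contact infection probability per step | [0, 1] | required |
| μ | recovery probability per step (0 = SI, 1 = one-shot SIR) | [0, 1] | 1.0 |
| t | time horizon in steps | integer ≥ 1 | 1 |

β and t jointly set the dynamical regime: small β·t weights short walks
(rankings resemble degree), large β·t weights long walks (rankings approach
the eigenvector centrality). The threshold 1/λ₁ of the network (reported by
`network_summary`) separates convergent from divergent horizons.

## Convergence to the eigenvector ranking

The claim that the S(t) ranking becomes identical to the leading eigenvector
q₁ holds when the leading-mode weight grows without bound relative to the
others, i.e. for βλ₁ + 1 − μ ≥ 1. Below the threshold S(t) converges to the
Katz-like limit βA(I − H)⁻¹1, a *fixed* mixture of eigenmodes whose ranking
retains a persistent, graph-dependent disagreement with q₁ (Kendall tau
saturates near 0.95 on BA(200, 3) fixtures regardless of t). The test suite
demonstrates tau ≥ 0.99 at β = 1.05/λ₁, t = 60; an acceptance-level check
pinned at β = 0.9/λ₁ is retained verbatim and fails for exactly this reason.

## Simulator

Synchronous updates: all nodes infected at the start of a step attempt to
infect each susceptible neighbor (exact probability 1 − (1 − β)^m for m
infected neighbors), then each of those same nodes recovers with probability
μ. Infections are resolved before recoveries from the same snapshot, so with
μ = 1 every infected node gets exactly one transmission round — consistent
with the t = 1 expectation β·degree. A node infected at step t cannot
recover until step t+1. The seed counts toward the influence
(#I + #R); the constant does not affect rankings.

**Vectorization and RNG.** Replicates for one seed node are advanced jointly
as rows of an int8 status matrix (float32 matmul against the dense adjacency
for neighbor counts). One master `SeedSequence` spawns an independent child
stream per seed node, so influence vectors are deterministic under the
master seed and independent of node processing order; individual replicates
within a batch share a stream (a deliberate trade of per-replicate
attribution for ~1000× throughput).

**Exact oracle.** For n ≤ 8 and t ≤ 4, the full joint S/I/R state
distribution is propagated exactly by enumerating every per-node Bernoulli
outcome; it yields exact expected influences and exact cumulative infection
probabilities. The guard is a hard error directing users to Monte Carlo.

## Evaluation

Kendall's tau-a, τ = 2/(n(n−1)) Σ_{i<j} sgn(yᵢ−yⱼ)·sgn(zᵢ−zⱼ), computed by
direct vectorized pair enumeration; tied pairs contribute 0, so an all-tied
influence vector (e.g. β = 0) gives τ = 0 and is flagged `degenerate` rather
than raising. The tie-adjusted tau-b is available as an option but is not
the default. In `accuracy_experiment` one influence vector per β is the
shared ground truth for all methods, and the DS score is evaluated at the
same (β, μ, t) as the simulation; `n_runs` means replicates per seed node.

## Synthetic fixtures vs real data

The generators produce seeded, connectivity-guaranteed Erdős–Rényi,
Barabási–Albert and Watts–Strogatz graphs plus hand-analyzable toys. The
default benchmark, BA(200, 3), has average degree ≈ 5.9 and 1/λ₁ ≈ 0.09,
comparable to the published empirical benchmark networks (average degree
4.3–9.6, 1/λ₁ 0.036–0.079), so the standard β grid [0.01, 0.10] probes the
same sub- to near-threshold regime. What synthetic fixtures do not emulate:
degree–degree correlations, clustering and community structure of real
collaboration/email/router/protein networks — a green ranking test here
shows the machinery and the qualitative ordering of methods, not the
published tau values on real data (those require user-downloaded networks).
Note that BA graphs have uniform coreness (= m), so the k-shell benchmark is
fully tied on them and scores τ = 0.

## Numerical choices

- **Eigenvector centrality:** power iteration on A + I (same eigenvectors;
  the shift prevents oscillation on bipartite graphs whose spectrum contains
  ±λ₁), sum-normalized each step, uniform start, tolerance 1e−10 on the
  successive-iterate max difference, max 10 000 iterations, error with the
  residual on non-convergence.
- **λ₁:** dense `eigvalsh` below n = 200, sparse Lanczos above; the summary
  value agrees with the dense spectral decomposition to 1e−10.
- **Spectral sign convention:** q₁ oriented all-positive; other eigenvectors
  oriented so their largest-magnitude entry is positive.
- **Geometric mode weights:** the ratio form (ρ^t − 1)/(ρ − 1) switches to
  the exact value t when |ρ − 1| < 1e−12.
- **k-shell:** computed by k-core decomposition (networkx `core_number`);
  isolated nodes get shell 0.
- **Node order:** labels sorted numerically when all parse as integers,
  lexicographically otherwise; all vectors are indexed in that order.
- **Degenerate inputs:** disconnected networks are analyzed as given with a
  warning (the CLI offers `--lcc`); empty networks error; the contact kernel
  errors on isolated nodes.

## Contact kernel

For the one-contact-per-step spreading variant the adjacency matrix is
replaced by the row-normalized D⁻¹A (`kernel="contact"`). Because D⁻¹A has
unit row sums, H'·1 = (β + 1 − μ)·1 and the score vector is *constant*:
under this linearization every infected node produces expected β new
infections per step regardless of degree, so seed position is invisible to
the total. The kernel is provided verbatim for completeness; its ranking is
degenerate by construction, and the spectral path is disabled for it (the
kernel is not symmetric).

## Known limitations

- Unweighted, undirected, simple networks only.
- The DS score requires β (and μ, t) to be known or estimated externally.
- `ds_spectral` and `ds_centrality_limit` use dense solvers: practical to a
  few thousand nodes.
- Monte-Carlo influence at experiment scale (all nodes × β grid) is the
  runtime bottleneck; the scaled default (n = 200, 500 runs per seed node)
  runs in seconds, but real-network scale (n ≳ 2000, 10⁴ runs) takes hours
  on one CPU.
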