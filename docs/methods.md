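# Methods

## Model

The package operates on an undirected heterogeneous network G(V, E)
whose nodes are typed (gene, disease, GO/DO/HPO term) and whose edges
carry (i) a type index k ∈ [0, K) and (ii) an initial weight
t₀ ∈ [0, 1].  For networks read from edge lists the type is the
unordered pair of endpoint node types (so a gene–gene interaction and
an HPO-term–gene annotation are distinct types), enumerated in sorted
order; synthetic networks label types freely.  t₀ comes from a source
confidence score when one exists, otherwise from annotation evidence
codes via a code→weight table, taking the maximum over an edge's codes
so experimental evidence dominates computational prediction.

Edge strength is a logistic function of the learnable edge-type
importance vector w through the one-hot feature t(u, v) (t₀ at
position k): f(u, v) = σ(w · t(u, v)).  Because features are one-hot,
f depends only on the edge's type and t₀ — the model has exactly K
degrees of freedom.  Laplacian normalization

a(u, v) = f(u, v) / √(Σ_{i∈N(u)} f(u, i) · Σ_{j∈N(v)} f(v, j))

divides each strength by the geometric mean of the total strength at
its endpoints, damping hub dominance; `mode="none"` sets a = f and is
the unnormalized supervised-random-walk baseline kept for comparison.

The restart walk row-normalizes a into Q′ and teleports to the start
node s with probability α per step.  Stationary probabilities solve
P^T = P^T Q and are computed by power iteration from the uniform
vector.  Isolated nodes get the pure restart row e_s, so Q is
stochastic on any input; the restart matrix itself is never
materialized (rank-one update; memory linear in |E|).

Training minimizes O(w) = ½‖w‖² + λ Σ h(S_n − S_p) over all
(positive, negative) pairs of every training instance, with the
one-sided logistic loss h (0 below the margin, σ(x/b) at or above it).
Gradients are analytic end-to-end: ∂f = f(1−f)t, ∂a by the quotient
rule through the endpoint sums, ∂Q by the quotient rule through the
row sums, and ∂S as the fixed point of the recursion obtained by
differentiating the stationary equation, iterated jointly with S.  The
recursion propagates along incoming transitions (the left-eigenvector
orientation); the finite-difference oracle in the test suite pins the
orientation and every rule to rtol ≤ 1e−3 on random graphs.  Note the
regularizer gradient is w, the exact derivative of ½‖w‖² — objective
and gradient are kept mutually consistent, which the
finite-difference checks require.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| α (restart) | 0.2 | teleport probability; controls locality. Grid-searched over {0.1,…,0.9} on training AUC by `select_restart`; 0.2 is where the normalized model peaks on this kind of benchmark. |
| b (loss sharpness) | 0.03 | scale of the margin S_n − S_p inside h; stationary-probability differences are small, so a small b keeps the loss responsive. Used in every experiment. |
| λ (penalty weight) | 1.0 (LossConfig) / 10.0 (synthetic benchmark) | trades margin violations against ‖w‖ shrinkage. The pairwise loss scales with the number of supervision pairs times the size of stationary-probability gradients (O(1/|V|)); on the 1000-node benchmark with ~2·10⁴ pairs, λ = 10 makes the data term dominate while leaving the regularizer as tie-breaker. λ = 1 over-shrinks w toward 0 there (recovery error ≈ ‖w′‖₁ for any method); λ = 100 lets ‖w‖ overshoot. |
| w₀ | all ones | a zero start would set every strength to ½ and erase the initial weights; ones keep strengths monotone in t₀. |
| learning rate | 0.1, halved ≤ 20× per step | plain gradient descent; a step is accepted only if the objective does not increase, so the trace is non-increasing. |
| outer stop | rel. ΔO ≤ 1e−6, ≤ 200 iterations | h jumps by ½ whenever a pair's margin crosses zero, so the objective is piecewise smooth; when no halved step improves it, the iterate sits at a kink bottom and the fit stops there, returning the best-seen w. |
| inner stop | L1 change < 1e−10, ≤ 1000 sweeps | both S and ∂S/∂w contract geometrically at rate ≤ (1−α). |

## Synthetic benchmark

The generator emulates the *structural* situation of an integrated
network — scale-free topology with typed edges of unequal usefulness —
without any biological content.  A copying-model graph grows from a
triangle; each new node attaches by one edge, uniformly with
probability 0.8, degree-proportionally otherwise (n nodes, n edges,
connected, heavy-tailed degrees).  Each edge gets one of K = 2 types
uniformly at random with t₀ = 1, and the gold vector w′ = (1, −1)
fixes "true" strengths σ(±1) ≈ 0.73 / 0.27.

Supervision is built future-link style.  All nodes are ranked by the
gold-weighted normalized walk from one of the three seed nodes v; the
20 best-ranked nodes **not adjacent to v** become the positives, and
every remaining non-adjacent node is a negative.  The positives stand
for edges of v that exist in the complete benchmark but are withheld
from the training network, so only the walk — and hence the edge-type
weights — can separate them from the negatives.  Two alternative
readings were evaluated and rejected as degenerate: taking top-ranked
*direct neighbors* as positives leaves every pair satisfied at any w
(direct neighbors outrank all non-neighbors by orders of magnitude),
so the loss vanishes identically and every method collapses to w = 0;
deleting those neighbors' edges instead isolates v whenever its degree
does not exceed n_pos, which is typical for seed nodes of this
generator.  Under the future-link design the pure pairwise loss of the
normalized model is zero at w′ on generated replicates while the
unnormalized baseline cannot reach zero — which is precisely the
contrast the recovery experiment measures.

Each replicate fits both modes on identical data from w₀ = (1, 1);
recovery error is the L1 distance Σᵢ |w′ᵢ − w*ᵢ|, and the comparison
across replicates is a one-sided *paired* t-test (the two methods see
the same replicates, so pairing is the appropriate design; errors
across replicates are i.i.d.).  Replicates whose fit produces
non-finite values are excluded and counted (none observed in
practice).

What passing does not show: the generator has uniform random types
(real edge types correlate with topology), a single instance per
network (real training pools many diseases), binary gold weights, and
no noise in the supervision.  Recovery here demonstrates the
correctness and discriminative behavior of the machinery, not
real-data performance.

Problem sizes: the test suite runs the recovery comparison at n = 300
with 25 replicates, where the paired difference is already
significant; `scripts/acceptance.py` runs the full n = 1000, 100
replicate benchmark (~1.5 min on one CPU).

## Numerical and design choices

- The row-normalization denominator of Q′ sums a(u, j) over the
  neighbors j of u — the only construction that yields a stochastic row.
- Ties in rankings are broken by node id, everywhere, so runs are
  reproducible byte-for-byte from their seeds.
- h is discontinuous at 0 (jumps 0 → ½); its derivative uses the
  right-branch formula at x = 0.
- AUC is the exact Mann–Whitney pair statistic with half-credit ties,
  not a trapezoidal approximation; candidate sets are small enough for
  exact counting.  The pooled AUC concatenates scores across diseases;
  per-disease AUCs are reported alongside.
- Benchmark construction for real-style networks (`build_benchmark_sets`)
  takes each disease with ≥ 5 gene neighbors, samples an equal number
  of non-adjacent genes as negatives (uniformly, without replacement,
  seeded), splits both sets 50/50 into train/test at random, and
  removes all positive disease–gene edges from the returned pruned
  network, so evaluation cannot read answers off direct edges.
- The direct linear-solve `stationary_oracle` is retained in the
  package as an independent cross-check of the power iteration and is
  used as such by the tests; the power iteration is the production
  path.
- α is held fixed during a fit; the grid search over α happens outside
  the optimization, on training AUC.

## Limitations

- One scalar feature per edge (one-hot by type); arbitrary
  multi-feature edges are out of scope.
- No parsing or identifier unification for real source databases; the
  package starts from a typed TSV edge list.
- The discontinuous loss makes the objective only piecewise smooth;
  gradient descent with step halving finds a kink-bottom stationary
  point, not a certified global minimum.
- λ requires scaling with supervision size and network size (see the
  parameter table); there is no automatic calibration.
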