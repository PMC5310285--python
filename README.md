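# slnsrw

Supervised random walks with Laplacian edge normalization for
disease-gene prioritization on heterogeneous biomedical networks.

## The problem

Integrated biomedical networks mix several kinds of nodes (genes,
diseases, GO/DO/HPO ontology terms) and therefore several kinds of
edges (protein interactions, annotations, ontology relations).  A
random walk with restart (RWR) from a disease node ranks candidate
genes well — but only if the edges are weighted sensibly, and a good
weight for a gene–gene interaction need not be a good weight for a
term–gene annotation.  This package learns one importance weight per
*edge type* from known disease–gene associations, so that the walk
reaches true disease genes before random ones, and then reuses the
fitted walk for prediction.  It is aimed at computational biologists
who already have a typed edge list and supervision, and at anyone who
wants a compact, fully tested reference implementation of
supervised random walks with Laplacian normalization.

## The model

Every edge (u, v) carries a one-hot feature t(u, v): its scalar
initial weight t₀ ∈ [0, 1] (from a source confidence score or from
evidence codes, e.g. EXP → 1.0, IEA → 0.4, maximum over codes) at the
position of its edge type.  With importance vector **w** (one entry
per edge type), the edge strength and its Laplacian normalization are

    f(u,v) = 1 / (1 + exp(−w·t(u,v)))
    a(u,v) = f(u,v) / √( Σ_{i∈N(u)} f(u,i) · Σ_{j∈N(v)} f(v,j) )

(the normalization damps hub nodes; skipping it gives the plain
supervised-random-walk baseline).  Row-normalizing a gives the
transition matrix Q′, and restart at the disease node s with
probability α gives Q = (1−α)Q′ + α·1(v=s), whose stationary
distribution P (solved by power iteration, P^T = P^T Q) scores every
node.  **w** is chosen to minimize

    O(w) = ½‖w‖² + λ Σ_d Σ_{p∈V_p, n∈V_n} h(S_n − S_p),
    h(x) = 0 for x < 0,  1/(1+e^{−x/b}) for x ≥ 0,

by gradient descent with analytic gradients propagated through the
stationary distribution (a joint power iteration for S and ∂S/∂w).

## Worked example

The built-in benchmark grows scale-free copying-model networks, plants
gold edge-type weights w′ = (1, −1) on two random edge types, builds a
training instance from the gold-weighted walk (the 20 top-ranked
non-adjacent nodes are the positives — future links withheld from the
network — and all other non-adjacent nodes the negatives), then fits
**w** back with and without Laplacian normalization:

```sh
slnsrw simulate --n 300 --n-pos 20 --reps 10 --seed 7 --out-dir out/
```

prints

```
mean error: slnsrw=0.8589 srw=1.1128 p=0.05539
```

i.e. across 10 paired replicates the Laplacian-normalized fit lands on
average 0.86 away from the gold parameters in L1 distance
(error = Σᵢ |w′ᵢ − w*ᵢ|), the unnormalized baseline 1.11 away, and a
one-sided paired t-test gives p ≈ 0.055 at this small replicate count.
`out/results.tsv` holds the per-replicate errors, `out/summary.json`
the quartiles and test statistic, and each replicate's edge list and
instance file sit beside them.

The same pieces are available as a library:

```python
import slnsrw

cfg = slnsrw.SyntheticConfig(n=300, seed=7)
res = slnsrw.recovery_experiment(cfg, n_reps=10)
print(res.summary())
```

For real edge lists, `slnsrw train / predict / evaluate / gridsearch`
fit a model from a TSV edge list plus instance file, rank genes for a
disease, report per-disease and pooled AUC with top-k true-pair rates,
and sweep the restart probability α over {0.1, …, 0.9}.

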