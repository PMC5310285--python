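"""Synthetic benchmark: copying-model networks with gold edge-type weights.

The generator emulates the structure of an integrated biomedical
network with a scale-free copying-model graph: growth starts from a
triangle, and every new node attaches by a single edge to an existing
node chosen uniformly at random with probability ``p_uniform`` and
proportionally to degree otherwise, producing a connected graph with
exactly n edges and a heavy-tailed degree distribution.

Each edge is then labeled with one of K edge types uniformly at random
(initial weight t0 = 1), and the gold importance vector w' — default
(1, -1) with K = 2 — fixes the "true" edge strengths.  A training
instance is built future-link style: all nodes are ranked by the
gold-weighted restart walk from one of the three seed nodes v, the
top-ranked nodes *not* adjacent to v become the positives (their edges
to v are the withheld future links, absent from the training network)
and every remaining non-adjacent node is a negative.  Because the
positives are distinguishable from the negatives only through the
walk, supervision carries a genuine signal about the gold weights: if
positives were taken among direct neighbors instead, they would
outrank every non-neighbor at any w and the loss would vanish
identically.

The recovery experiment fits w back from that supervision under both
the Laplacian-normalized model and the unnormalized baseline on
*identical* replicates, scores each fit by the L1 parameter error
sum_i |w'_i - w*_i|, and compares the two methods with a paired
one-sided t-test (normalized error smaller).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hetnet import HeteroNetwork, TrainingInstance
from .edge_model import normalized_strengths
from .walk import build_transition, stationary
from .train import LossConfig, OptimizerSettings, fit, DivergenceError


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic experiment.

    Defaults are the benchmark's standard conditions: 1000-node
    copying-model graphs with uniform-attachment probability 0.8, two
    edge types with gold weights (1, -1), 20 positives per instance,
    loss sharpness b = 0.03.
    """

    n: int = 1000
    p_uniform: float = 0.8
    K: int = 2
    w_gold: tuple[float, ...] = (1.0, -1.0)
    n_pos: int = 20
    alpha: float = 0.2
    b: float = 0.03
    # penalty weight scaled so the ~|V| * n_pos pairwise loss terms,
    # whose margins are O(1/|V|), dominate the l2 shrinkage
    lam: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least the three seed nodes")
        if not 0.0 <= self.p_uniform <= 1.0:
            raise ValueError("p_uniform must be in [0, 1]")
        if len(self.w_gold) != self.K:
            raise ValueError("w_gold length must equal K")


def copying_model(
    n: int, p_uniform: float = 0.8, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Grow a copying-model graph; returns edge endpoint arrays (u, v).

    Seed graph: a triangle on nodes 0, 1, 2.  Each new node attaches by
    one edge, uniformly with probability ``p_uniform`` and
    degree-proportionally otherwise, so the result is connected with
    exactly n edges (3 + (n - 3)).
    """
    if n < 3:
        raise ValueError("copying model needs n >= 3")
    if not 0.0 <= p_uniform <= 1.0:
        raise ValueError("p_uniform must be in [0, 1]")
    rng = np.random.default_rng(seed)
    eu = [0, 0, 1]
    ev = [1, 2, 2]
    deg = np.zeros(n, dtype=np.int64)
    deg[:3] = 2
    total_deg = 6
    for u in range(3, n):
        if rng.random() < p_uniform:
            target = int(rng.integers(u))
        else:
            # degree-proportional choice among existing nodes
            r = rng.random() * total_deg
            target = int(np.searchsorted(np.cumsum(deg[:u]), r, side="right"))
            target = min(target, u - 1)
        eu.append(u)
        ev.append(target)
        deg[u] += 1
        deg[target] += 1
        total_deg += 2
    return np.array(eu, dtype=np.intp), np.array(ev, dtype=np.intp)


def assign_gold_types(
    edges: tuple[np.ndarray, np.ndarray],
    K: int = 2,
    seed=None,
    n_nodes: int | None = None,
) -> HeteroNetwork:
    """Wrap a raw graph as a HeteroNetwork with random edge types, t0 = 1.

    Synthetic edge types are labels of their own ("type_0", ...), drawn
    uniformly per edge; all nodes are typed as genes so the network is
    otherwise homogeneous.
    """
    eu, ev = edges
    if n_nodes is None:
        n_nodes = int(max(eu.max(), ev.max())) + 1 if len(eu) else 0
    rng = np.random.default_rng(seed)
    width = len(str(max(n_nodes - 1, 0)))
    node_ids = [f"n{idx:0{width}d}" for idx in range(n_nodes)]
    etypes = rng.integers(K, size=len(eu))
    return HeteroNetwork(
        node_ids=node_ids,
        node_types=["gene"] * n_nodes,
        edge_u=eu,
        edge_v=ev,
        edge_type=etypes,
        t0=np.ones(len(eu)),
        evidence=[[] for _ in range(len(eu))],
        edge_type_names=[f"type_{k}" for k in range(K)],
    )


def make_synthetic_instance(
    net: HeteroNetwork,
    w_gold,
    alpha: float = 0.2,
    n_pos: int = 20,
    seed=None,
    mode: str = "laplacian",
    n_neg: int | None = None,
) -> TrainingInstance:
    """Build the gold training instance from one of the three seed nodes.

    All nodes are ranked by the gold-weighted restart walk from a
    randomly chosen seed-triangle node v.  The positives are the
    ``n_pos`` best-ranked nodes among those *not* adjacent to v (ties
    broken by node id): they stand for v's future links, whose edges
    are withheld from the training network, so only the walk weights
    can separate them from the negatives.  The negatives default to
    every remaining non-adjacent node; pass ``n_neg`` to subsample
    them uniformly instead.
    """
    rng = np.random.default_rng(seed)
    v = int(rng.integers(3))
    w_gold = np.asarray(w_gold, dtype=float)
    strengths = normalized_strengths(net, w_gold, mode)
    model = build_transition(net, strengths, alpha, v)
    P = stationary(model).P
    nbrs = set(net.neighbors(v).tolist())
    non_adjacent = [i for i in range(net.n_nodes) if i not in nbrs and i != v]
    if len(non_adjacent) <= n_pos:
        raise ValueError("not enough non-adjacent nodes for positives")
    order = sorted(non_adjacent, key=lambda i: (-P[i], net.node_ids[i]))
    positives = tuple(net.node_ids[i] for i in order[:n_pos])
    rest = order[n_pos:]
    if n_neg is None:
        neg_idx = sorted(rest)
    else:
        if len(rest) < n_neg:
            raise ValueError("not enough non-neighbors to sample negatives")
        neg_idx = sorted(
            rng.choice(np.array(rest), size=n_neg, replace=False).tolist()
        )
    negatives = tuple(net.node_ids[i] for i in neg_idx)
    return TrainingInstance(net.node_ids[v], positives, negatives)


def param_error(w_gold, w_est) -> float:
    """L1 parameter-recovery error sum_i |w'_i - w*_i|."""
    w_gold = np.asarray(w_gold, dtype=float)
    w_est = np.asarray(w_est, dtype=float)
    if w_gold.shape != w_est.shape:
        raise ValueError("parameter vectors have different lengths")
    return float(np.abs(w_gold - w_est).sum())


@dataclass
class RecoveryResult:
    """Paired parameter-recovery comparison of the two edge models."""

    errors_slnsrw: np.ndarray
    errors_srw: np.ndarray
    t_stat: float
    p_value: float  # one-sided, H1: error(SLN-SRW) < error(SRW)
    n_failed: int
    replicate_seeds: list[int] = field(default_factory=list)

    def quartiles(self, method: str) -> tuple[float, float, float]:
        errs = self.errors_slnsrw if method == "slnsrw" else self.errors_srw
        q1, q2, q3 = np.percentile(errs, [25, 50, 75])
        return float(q1), float(q2), float(q3)

    def summary(self) -> dict:
        out = {
            "n_replicates": int(len(self.errors_slnsrw)),
            "n_failed": self.n_failed,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
        }
        for name in ("slnsrw", "srw"):
            errs = self.errors_slnsrw if name == "slnsrw" else self.errors_srw
            q1, q2, q3 = self.quartiles(name)
            out[name] = {
                "mean_error": float(errs.mean()),
                "q1": q1,
                "median": q2,
                "q3": q3,
            }
        return out


def run_replicate(
    cfg: SyntheticConfig, seed: int, opt: OptimizerSettings | None = None
) -> tuple[float, float]:
    """One paired replicate: generate, fit both modes, return both errors."""
    ss = np.random.SeedSequence(seed)
    s_graph, s_types, s_inst = ss.spawn(3)
    edges = copying_model(cfg.n, cfg.p_uniform, s_graph)
    net = assign_gold_types(edges, cfg.K, s_types, n_nodes=cfg.n)
    inst = make_synthetic_instance(
        net, cfg.w_gold, cfg.alpha, cfg.n_pos, s_inst
    )
    errors = {}
    for mode in ("laplacian", "none"):
        loss_cfg = LossConfig(lam=cfg.lam, b=cfg.b, alpha=cfg.alpha, mode=mode)
        result = fit(net, [inst], loss_cfg, opt)
        errors[mode] = param_error(cfg.w_gold, result.w)
    return errors["laplacian"], errors["none"]


def recovery_experiment(
    cfg: SyntheticConfig,
    n_reps: int = 100,
    opt: OptimizerSettings | None = None,
) -> RecoveryResult:
    """Run the paired parameter-recovery experiment over n_reps replicates.

    Both methods see identical networks and instances within each
    replicate; only the normalization mode differs.  Replicates whose
    fit diverges are excluded and counted.
    """
    if n_reps < 2:
        raise ValueError("need at least two replicates for a t-test")
    master = np.random.SeedSequence(cfg.seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(n_reps)]
    errs_sln, errs_srw, kept_seeds = [], [], []
    n_failed = 0
    for seed in rep_seeds:
        try:
            e_sln, e_srw = run_replicate(cfg, seed, opt)
        except (DivergenceError, FloatingPointError) as exc:
            warnings.warn(f"replicate seed {seed} failed: {exc}", RuntimeWarning)
            n_failed += 1
            continue
        errs_sln.append(e_sln)
        errs_srw.append(e_srw)
        kept_seeds.append(seed)
    errs_sln = np.array(errs_sln)
    errs_srw = np.array(errs_srw)
    t = stats.ttest_rel(errs_sln, errs_srw, alternative="less")
    return RecoveryResult(
        errors_slnsrw=errs_sln,
        errors_srw=errs_srw,
        t_stat=float(t.statistic),
        p_value=float(t.pvalue),
        n_failed=n_failed,
        replicate_seeds=kept_seeds,
    )
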