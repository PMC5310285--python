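"""Prediction and scoring: ranking genes from a disease node, ROC/AUC.

Prediction runs the restart walk from a disease node on the fitted
network and ranks candidate genes by stationary probability.  AUC is
the exact Mann-Whitney pair statistic — the probability that a random
positive outranks a random negative, ties at half credit — rather than
a trapezoidal curve integral, since candidate sets are small enough
for exact counting.  A top-k true-pair rate and a restart-probability
grid search over the training instances complete the evaluation
surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hetnet import HeteroNetwork, TrainingInstance
from .edge_model import normalized_strengths
from .walk import build_transition, stationary


@dataclass
class RankedPredictions:
    """Candidate genes ranked by association score, descending."""

    disease: str
    alpha: float
    entries: list[tuple[str, float, int]]  # (gene_id, score, rank)

    def genes(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene_id", "score", "rank"])


def predict_rank(
    net: HeteroNetwork,
    w: np.ndarray,
    disease: str,
    candidates=None,
    alpha: float = 0.2,
    mode: str = "laplacian",
) -> RankedPredictions:
    """Rank candidate genes by stationary probability from the disease.

    ``candidates`` defaults to all gene-typed nodes; ties share order
    by gene id.
    """
    di = net.node_index(disease)
    strengths = normalized_strengths(net, w, mode)
    model = build_transition(net, strengths, alpha, di)
    P = stationary(model).P
    if candidates is None:
        candidates = [
            net.node_ids[i]
            for i, t in enumerate(net.node_types)
            if t == "gene"
        ]
    cand = sorted(set(candidates))
    scored = sorted(
        ((g, float(P[net.node_index(g)])) for g in cand),
        key=lambda gs: (-gs[1], gs[0]),
    )
    entries = [(g, s, r) for r, (g, s) in enumerate(scored, start=1)]
    return RankedPredictions(disease=disease, alpha=alpha, entries=entries)


def roc_auc(pos_scores, neg_scores) -> float:
    """Exact pairwise AUC: P(pos > neg) + 0.5 P(pos = neg)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    diff = pos[:, None] - neg[None, :]
    wins = np.count_nonzero(diff > 0)
    ties = np.count_nonzero(diff == 0)
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def roc_points(pos_scores, neg_scores) -> np.ndarray:
    """ROC curve points (fpr, tpr) sweeping score thresholds, descending."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    # collapse tied thresholds
    distinct = np.r_[np.diff(scores) != 0, True]
    tp = np.cumsum(labels)[distinct]
    fp = np.cumsum(1 - labels)[distinct]
    tpr = np.r_[0.0, tp / pos.size]
    fpr = np.r_[0.0, fp / neg.size]
    return np.column_stack([fpr, tpr])


def topk_true_rate(ranked: RankedPredictions, truth, k: int) -> float:
    """Fraction of the top-k ranked genes that are true associations."""
    n = len(ranked.entries)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    truth = set(truth)
    top = ranked.genes()[:k]
    return sum(g in truth for g in top) / k


@dataclass
class EvalReport:
    """Pooled and per-disease ranking quality for one (w, alpha)."""

    alpha: float
    auc: float  # pooled over all instances
    per_disease_auc: dict[str, float]
    topk: dict[int, float]
    roc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"disease_id": d, "auc": a} for d, a in self.per_disease_auc.items()
        ]
        rows.append({"disease_id": "__pooled__", "auc": self.auc})
        return pd.DataFrame(rows)


def evaluate_instances(
    net: HeteroNetwork,
    w: np.ndarray,
    instances: list[TrainingInstance],
    alpha: float = 0.2,
    mode: str = "laplacian",
    ks: tuple[int, ...] = (),
) -> EvalReport:
    """Score every instance's positives vs negatives by the restart walk.

    The pooled AUC concatenates scores across diseases; per-disease
    AUCs are reported alongside.
    """
    if not instances:
        raise ValueError("no instances to evaluate")
    all_pos, all_neg = [], []
    per_disease = {}
    topk_counts = {k: [] for k in ks}
    for inst in instances:
        inst.check_against(net)
        candidates = list(inst.positives) + list(inst.negatives)
        ranked = predict_rank(net, w, inst.disease, candidates, alpha, mode)
        score_of = {g: s for g, s, _ in ranked.entries}
        pos = [score_of[g] for g in inst.positives]
        neg = [score_of[g] for g in inst.negatives]
        per_disease[inst.disease] = roc_auc(pos, neg)
        all_pos.extend(pos)
        all_neg.extend(neg)
        for k in ks:
            if k <= len(ranked.entries):
                topk_counts[k].append(
                    topk_true_rate(ranked, set(inst.positives), k)
                )
    topk = {
        k: float(np.mean(v)) for k, v in topk_counts.items() if v
    }
    return EvalReport(
        alpha=alpha,
        auc=roc_auc(all_pos, all_neg),
        per_disease_auc=per_disease,
        topk=topk,
        roc=roc_points(all_pos, all_neg),
    )


DEFAULT_ALPHA_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))


def select_restart(
    net: HeteroNetwork,
    w: np.ndarray,
    train_instances: list[TrainingInstance],
    grid=DEFAULT_ALPHA_GRID,
    mode: str = "laplacian",
) -> tuple[float, dict[float, float]]:
    """Grid-search the restart probability on training AUC.

    Returns the alpha with the highest pooled training AUC (ties go to
    the smallest alpha) and the full per-alpha AUC table.
    """
    grid = sorted(set(float(a) for a in grid))
    if not grid:
        raise ValueError("empty alpha grid")
    if any(not 0.0 < a < 1.0 for a in grid):
        raise ValueError("alpha grid values must be in (0, 1)")
    table = {
        a: evaluate_instances(net, w, train_instances, a, mode).auc
        for a in grid
    }
    best = max(grid, key=lambda a: (table[a], -a))
    return best, table
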