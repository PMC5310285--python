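"""Random walk with restart: transition structure and stationary vector.

The walk over the weighted network is defined in two layers.  First the
normalized strengths are row-normalized into a stochastic matrix

    Q'_uv = a(u, v) / sum_{j in N(u)} a(u, j)      for edges, else 0.

Then restart at the start node s with probability alpha:

    Q_uv = (1 - alpha) Q'_uv + alpha 1(v = s).

The stationary distribution P solves P^T = P^T Q; its entries S_v score
how reachable v is from s and are the association scores used both for
training supervision and for ranking candidate genes.  The restart
matrix is never materialized: iteration uses the sparse Q' plus a
rank-one restart update, so memory stays linear in the edge count.
Rows of dangling (isolated) nodes are replaced by the pure restart row
e_s, which keeps Q stochastic on any input.

``stationary`` is the production power iteration (initialized uniform
at 1/|V|); ``stationary_oracle`` is an independent direct linear solve
retained as a cross-check for small systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .hetnet import HeteroNetwork
from .edge_model import NormalizedStrengthMap


@dataclass
class TransitionModel:
    """Sparse RWR transition structure Q = (1-alpha) Q' + alpha e_s."""

    Qprime: sparse.csr_array  # row-stochastic on non-dangling rows
    alpha: float
    s: int  # start node index
    dangling: np.ndarray  # bool mask of all-zero rows

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"restart probability must be in (0, 1), got {self.alpha}")
        n = self.Qprime.shape[0]
        if not 0 <= self.s < n:
            raise ValueError("start node outside node range")

    @property
    def n_nodes(self) -> int:
        return self.Qprime.shape[0]

    def apply(self, P: np.ndarray) -> np.ndarray:
        """One step of P^T <- P^T Q without materializing Q.

        Non-dangling rows contribute (1-alpha) Q' + alpha e_s; dangling
        rows send all their mass to s.
        """
        mass_dangling = float(P[self.dangling].sum())
        mass_rest = float(P.sum()) - mass_dangling
        out = (1.0 - self.alpha) * (self.Qprime.T @ P)
        out[self.s] += self.alpha * mass_rest + mass_dangling
        return out


@dataclass
class WalkResult:
    """Stationary probability vector with convergence diagnostics."""

    P: np.ndarray
    iterations: int
    residual: float
    converged: bool

    def scores(self) -> np.ndarray:
        return self.P


def row_normalize(
    strengths: NormalizedStrengthMap,
) -> tuple[sparse.csr_array, np.ndarray]:
    """Row-normalize strengths into the stochastic matrix Q'.

    Returns the sparse Q' and a boolean mask flagging isolated nodes,
    whose rows are all-zero.
    """
    net = strengths.net
    a = strengths.values
    tails, heads, eids = net.directed_edges()
    rowsum = np.zeros(net.n_nodes)
    np.add.at(rowsum, tails, a[eids])
    dangling = rowsum == 0.0
    has_edges = np.zeros(net.n_nodes, dtype=bool)
    has_edges[tails] = True
    if np.any(has_edges & dangling):
        raise FloatingPointError("zero strength sum on a node with edges")
    vals = a[eids] / rowsum[tails]
    Qprime = sparse.csr_array(
        (vals, (tails, heads)), shape=(net.n_nodes, net.n_nodes)
    )
    return Qprime, dangling


def transition_matrix(
    Qprime: sparse.csr_array,
    alpha: float,
    s: int,
    dangling: np.ndarray | None = None,
) -> TransitionModel:
    """Bundle Q', the restart probability and the start node."""
    if dangling is None:
        rowsum = np.asarray(Qprime.sum(axis=1)).ravel()
        dangling = rowsum == 0.0
    return TransitionModel(Qprime=Qprime.tocsr(), alpha=alpha, s=s, dangling=dangling)


def build_transition(
    net: HeteroNetwork, strengths: NormalizedStrengthMap, alpha: float, s: str | int
) -> TransitionModel:
    """Convenience: strengths -> Q' -> TransitionModel for a start node."""
    si = s if isinstance(s, (int, np.integer)) else net.node_index(s)
    Qprime, dangling = row_normalize(strengths)
    return transition_matrix(Qprime, alpha, si, dangling)


def stationary(
    model: TransitionModel, tol: float = 1e-10, max_iter: int = 1000
) -> WalkResult:
    """Power iteration for the stationary vector of the restart walk.

    Starts from the uniform vector 1/|V| and iterates P^T <- P^T Q
    until the L1 change drops below ``tol``.  The restart guarantees an
    aperiodic, irreducible-to-s chain, so convergence is geometric with
    rate at most (1 - alpha).
    """
    n = model.n_nodes
    P = np.full(n, 1.0 / n)
    residual = np.inf
    for it in range(1, max_iter + 1):
        P_new = model.apply(P)
        residual = float(np.abs(P_new - P).sum())
        P = P_new
        if residual < tol:
            return WalkResult(P=P, iterations=it, residual=residual, converged=True)
    warnings.warn(
        f"power iteration did not converge in {max_iter} iterations "
        f"(residual {residual:.3e})",
        RuntimeWarning,
        stacklevel=2,
    )
    return WalkResult(P=P, iterations=max_iter, residual=residual, converged=False)


def stationary_oracle(model: TransitionModel) -> WalkResult:
    """Direct linear solve of P^T (I - Q) = 0 with sum(P) = 1.

    Independent of the power iteration; intended for |V| <= 2000.
    """
    n = model.n_nodes
    if n > 2000:
        raise ValueError("oracle solve limited to 2000 nodes")
    Q = (1.0 - model.alpha) * model.Qprime.toarray()
    Q[model.dangling, :] = 0.0
    Q[~model.dangling, model.s] += model.alpha
    Q[model.dangling, model.s] = 1.0
    A = np.vstack([Q.T - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    P, *_ = np.linalg.lstsq(A, b, rcond=None)
    residual = float(np.abs(A @ P - b).max())
    if residual > 1e-8:
        raise np.linalg.LinAlgError(
            f"stationary system inconsistent (residual {residual:.3e})"
        )
    return WalkResult(P=P, iterations=0, residual=residual, converged=True)


def write_scores(net: HeteroNetwork, P: np.ndarray, path) -> None:
    """Dump scores as TSV ``node_id  score  rank``, descending."""
    order = np.lexsort((np.array(net.node_ids), -P))
    pd.DataFrame(
        {
            "node_id": [net.node_ids[i] for i in order],
            "score": P[order],
            "rank": np.arange(1, net.n_nodes + 1),
        }
    ).to_csv(path, sep="\t", index=False)
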