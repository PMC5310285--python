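"""Supervised learning of the edge-type importance vector w.

Given training instances (a disease node with positive and negative
gene sets), the edge-type weights are chosen to make the restart walk
from each disease reach its known genes with higher stationary
probability than the sampled non-genes.  The objective is

    O(w) = 1/2 ||w||^2
           + lambda * sum_d sum_{p in V_p, n in V_n} h(S_n - S_p)

with the one-sided logistic loss

    h(x) = 0                       for x < 0
    h(x) = 1 / (1 + exp(-x / b))   for x >= 0,

so only pairs where a negative outranks (or ties) a positive are
penalized, with sharpness 1/b.  The loss jumps from 0 to 1/2 at x = 0;
the derivative convention follows the right branch there.

The gradient is analytic throughout the pipeline.  dS/dw is the fixed
point of the recursion obtained by differentiating P^T = P^T Q,

    dS_x = sum_i ( Q_ix dS_i + S_i dQ_ix ),

iterated jointly with S from dS = 0, S = 1/|V| until neither changes.
dQ/dw comes from the quotient rule through the row normalization, and
da/dw from :mod:`slnsrw.edge_model`.  The sum is over *incoming*
transitions i -> x, matching the left-eigenvector orientation of the
stationary equation; the finite-difference oracle in the test suite
pins this orientation down.

Fitting is plain gradient descent with step halving: a fixed base
learning rate, halved within an iteration until the objective does not
increase, which makes the objective trace non-increasing.

Note the regularizer gradient: with the 1/2 ||w||^2 penalty the exact
derivative is w (not 2w); the implementation keeps objective and
gradient mutually consistent, which the finite-difference checks
require.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import expit

from .hetnet import HeteroNetwork, TrainingInstance
from .edge_model import (
    edge_strength_data,
    strength_gradient_data,
    normalized_strengths,
)
from .walk import build_transition, stationary, TransitionModel, WalkResult


@dataclass(frozen=True)
class LossConfig:
    """Loss and walk hyperparameters.

    lam    -- penalty weight trading the margin violations against the
              ||w|| regularizer (> 0).
    b      -- loss sharpness; smaller b penalizes small violations more
              steeply (> 0).
    alpha  -- restart probability of the walk, in (0, 1).
    mode   -- "laplacian" for the normalized model, "none" for the
              unnormalized supervised-random-walk baseline.
    """

    lam: float = 1.0
    b: float = 0.03
    alpha: float = 0.2
    mode: str = "laplacian"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.b <= 0:
            raise ValueError("b must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def loss_h(x, b: float):
    """One-sided logistic loss: 0 for x < 0, sigma(x / b) for x >= 0."""
    if b <= 0:
        raise ValueError("b must be positive")
    x = np.asarray(x, dtype=float)
    out = np.where(x < 0, 0.0, expit(x / b))
    return out if out.ndim else float(out)


def loss_h_prime(x, b: float):
    """Right-branch derivative of the loss: (1/b) sigma(x/b)(1 - sigma(x/b)) for x >= 0."""
    if b <= 0:
        raise ValueError("b must be positive")
    x = np.asarray(x, dtype=float)
    s = expit(x / b)
    out = np.where(x < 0, 0.0, s * (1.0 - s) / b)
    return out if out.ndim else float(out)


# -- walk plumbing shared by objective and gradient ----------------------


def _instance_stationary(
    net: HeteroNetwork,
    w: np.ndarray,
    cfg: LossConfig,
    disease: str,
    tol: float,
    max_iter: int,
) -> WalkResult:
    strengths = normalized_strengths(net, w, cfg.mode)
    model = build_transition(net, strengths, cfg.alpha, disease)
    return stationary(model, tol=tol, max_iter=max_iter)


def objective(
    w: np.ndarray,
    net: HeteroNetwork,
    instances: list[TrainingInstance],
    cfg: LossConfig,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> float:
    """O(w): regularizer plus pairwise margin losses over all instances."""
    w = np.asarray(w, dtype=float)
    total = 0.5 * float(w @ w)
    for inst in instances:
        inst.check_against(net)
        res = _instance_stationary(net, w, cfg, inst.disease, tol, max_iter)
        S = res.P
        sp = S[[net.node_index(p) for p in inst.positives]]
        sn = S[[net.node_index(n) for n in inst.negatives]]
        x = sn[None, :] - sp[:, None]  # pairs (p, n)
        total += cfg.lam * float(loss_h(x, cfg.b).sum())
    return total


# -- transition gradient -------------------------------------------------


def _transition_gradient_matrices(
    net: HeteroNetwork, w: np.ndarray, cfg: LossConfig
) -> tuple[TransitionModel, list[sparse.csr_array], np.ndarray]:
    """Q' (wrapped in a TransitionModel-ready form) and dQ/dw.

    Returns K sparse matrices M_k with (M_k)_{xv} ... laid out
    transposed for the dS recursion: M_k holds dQ_{i x}/dw_k at entry
    (x, i), so that (M_k @ S)_x = sum_i S_i dQ_{i x}/dw_k.
    """
    data = edge_strength_data(net, w, cfg.mode)
    grads = strength_gradient_data(net, w, cfg.mode, data=data)
    tails, heads, eids = net.directed_edges()
    a = data.a
    rowsum = np.zeros(net.n_nodes)
    np.add.at(rowsum, tails, a[eids])
    dR = np.zeros((net.n_nodes, net.K))
    np.add.at(dR, tails, grads.da[eids])
    # quotient rule on Q'_{uv} = a_uv / R_u, then the (1 - alpha) restart scale
    R_t = rowsum[tails]
    dQ = (
        (1.0 - cfg.alpha)
        * (grads.da[eids] * R_t[:, None] - a[eids][:, None] * dR[tails])
        / (R_t[:, None] ** 2)
    )
    matrices = [
        sparse.csr_array(
            (dQ[:, k], (heads, tails)), shape=(net.n_nodes, net.n_nodes)
        )
        for k in range(net.K)
    ]
    return data, matrices, dQ


def grad_transition(
    net: HeteroNetwork,
    w: np.ndarray,
    alpha: float,
    u: str | int,
    v: str | int,
    mode: str = "laplacian",
) -> np.ndarray:
    """dQ_{uv}/dw for the directed transition u -> v; zero for non-edges."""
    ui = u if isinstance(u, (int, np.integer)) else net.node_index(u)
    vi = v if isinstance(v, (int, np.integer)) else net.node_index(v)
    if not net.has_edge(ui, vi):
        return np.zeros(net.K)
    cfg = LossConfig(alpha=alpha, mode=mode)
    _, matrices, _ = _transition_gradient_matrices(net, w, cfg)
    return np.array([m[vi, ui] for m in matrices])


# -- stationary gradient -------------------------------------------------


@dataclass
class GradientState:
    """Converged S and dS/dw for one start node."""

    S: np.ndarray  # |V|
    dS: np.ndarray  # |V| x K
    iterations: int
    converged: bool


def grad_stationary(
    net: HeteroNetwork,
    w: np.ndarray,
    cfg: LossConfig,
    disease: str | int,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> GradientState:
    """Jointly iterate S and dS/dw to their common fixed point.

    S starts uniform at 1/|V| and dS at zero.  Each sweep applies the
    transition to S and the differentiated transition to (S, dS);
    iteration stops when both L1 changes fall below ``tol``.
    """
    w = np.asarray(w, dtype=float)
    si = (
        disease
        if isinstance(disease, (int, np.integer))
        else net.node_index(disease)
    )
    data, dQ_mats, _ = _transition_gradient_matrices(net, w, cfg)
    from .edge_model import NormalizedStrengthMap

    strengths = NormalizedStrengthMap(net=net, mode=cfg.mode, data=data)
    model = build_transition(net, strengths, cfg.alpha, si)
    QT = model.Qprime.T.tocsr()
    n, K = net.n_nodes, net.K
    S = np.full(n, 1.0 / n)
    dS = np.zeros((n, K))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        S_new = model.apply(S)
        # sum_i Q_ix dS_i: (1-alpha) through Q', restart mass to s,
        # dangling rows forward their dS fully to s.
        dS_new = (1.0 - cfg.alpha) * (QT @ dS)
        col_rest = dS[~model.dangling].sum(axis=0)
        col_dang = dS[model.dangling].sum(axis=0)
        dS_new[si] += cfg.alpha * col_rest + col_dang
        # sum_i S_i dQ_ix
        for k in range(K):
            dS_new[:, k] += dQ_mats[k] @ S
        res_S = float(np.abs(S_new - S).sum())
        res_dS = float(np.abs(dS_new - dS).sum())
        S, dS = S_new, dS_new
        if res_S < tol and res_dS < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"joint S/dS iteration did not converge in {max_iter} sweeps",
            RuntimeWarning,
            stacklevel=2,
        )
    return GradientState(S=S, dS=dS, iterations=it, converged=converged)


def grad_objective(
    w: np.ndarray,
    net: HeteroNetwork,
    instances: list[TrainingInstance],
    cfg: LossConfig,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """Analytic gradient of O(w): w + lambda * sum h'(x) (dS_n - dS_p)."""
    w = np.asarray(w, dtype=float)
    g = w.copy()
    for inst in instances:
        inst.check_against(net)
        gs = grad_stationary(net, w, cfg, inst.disease, tol=tol, max_iter=max_iter)
        pos = [net.node_index(p) for p in inst.positives]
        neg = [net.node_index(nn) for nn in inst.negatives]
        x = gs.S[neg][None, :] - gs.S[pos][:, None]  # (p, n) margins
        hp = loss_h_prime(x, cfg.b)
        # sum_{p,n} hp * (dS_n - dS_p) via row/column weights
        wn = hp.sum(axis=0)  # per-negative
        wp = hp.sum(axis=1)  # per-positive
        g += cfg.lam * (wn @ gs.dS[neg] - wp @ gs.dS[pos])
    return g


# -- fitting -------------------------------------------------------------


@dataclass
class OptimizerSettings:
    """Gradient-descent controls.

    w0 defaults to the all-ones vector so the initial strengths are
    monotone in the initial weights t0 (w0 = 0 would flatten every
    strength to 1/2 and erase them).
    """

    w0: np.ndarray | None = None
    learning_rate: float = 0.1
    tol: float = 1e-6  # relative objective change
    max_iter: int = 200
    max_halvings: int = 20
    inner_tol: float = 1e-10
    inner_max_iter: int = 1000


@dataclass
class FitResult:
    """Fitted edge-type importances with the optimization trace."""

    w: np.ndarray
    objective_trace: list[float]
    converged: bool
    iterations: int
    mode: str
    edge_type_names: list[str]
    config: LossConfig


class DivergenceError(RuntimeError):
    """Optimization produced a non-finite objective or gradient."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def fit(
    net: HeteroNetwork,
    instances: list[TrainingInstance],
    cfg: LossConfig,
    opt: OptimizerSettings | None = None,
) -> FitResult:
    """Minimize O(w) by gradient descent with step halving.

    Each outer iteration evaluates the objective, computes the analytic
    gradient through the joint S/dS power iteration, then takes the
    largest step (starting from the base learning rate, halving at most
    ``max_halvings`` times) that does not increase the objective, so
    the objective trace is non-increasing.  The loop stops when the
    relative objective change drops below ``tol``, or when no halved
    step improves the objective — the loss jumps by 1/2 whenever a
    pair's margin crosses zero, so exhausting the halvings normally
    means the iterate sits at a kink bottom of the piecewise-smooth
    objective.  The best-seen w is returned either way; a non-finite
    objective or gradient raises :class:`DivergenceError`.
    """
    if opt is None:
        opt = OptimizerSettings()
    w = (
        np.ones(net.K)
        if opt.w0 is None
        else np.asarray(opt.w0, dtype=float).copy()
    )
    if w.shape != (net.K,):
        raise ValueError(f"w0 has length {w.size}, network has K={net.K}")
    obj = objective(w, net, instances, cfg, opt.inner_tol, opt.inner_max_iter)
    trace = [obj]
    best_w, best_obj = w.copy(), obj
    converged = False
    it = 0
    for it in range(1, opt.max_iter + 1):
        g = grad_objective(
            w, net, instances, cfg, opt.inner_tol, opt.inner_max_iter
        )
        if not np.all(np.isfinite(g)):
            raise DivergenceError("non-finite gradient", trace)
        eta = opt.learning_rate
        accepted = False
        for _ in range(opt.max_halvings + 1):
            w_new = w - eta * g
            obj_new = objective(
                w_new, net, instances, cfg, opt.inner_tol, opt.inner_max_iter
            )
            if not np.isfinite(obj_new):
                raise DivergenceError("non-finite objective", trace)
            if obj_new <= obj:
                accepted = True
                break
            eta *= 0.5
        if not accepted:
            # even the smallest step increases the objective: the
            # iterate sits at a kink bottom of the discontinuous loss
            converged = True
            break
        w, prev_obj, obj = w_new, obj, obj_new
        trace.append(obj)
        if obj < best_obj:
            best_obj, best_w = obj, w.copy()
        if abs(prev_obj - obj) <= opt.tol * max(1.0, abs(prev_obj)):
            converged = True
            break
    return FitResult(
        w=best_w,
        objective_trace=trace,
        converged=converged,
        iterations=it,
        mode=cfg.mode,
        edge_type_names=list(net.edge_type_names),
        config=cfg,
    )


# -- finite differences (test oracle) ------------------------------------


def finite_diff_gradient(fn, w: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite differences (fn(w + h e_k) - fn(w - h e_k)) / 2h."""
    w = np.asarray(w, dtype=float)
    g = np.zeros_like(w)
    for k in range(w.size):
        e = np.zeros_like(w)
        e[k] = h
        g[k] = (fn(w + e) - fn(w - e)) / (2.0 * h)
    return g


# -- model persistence ---------------------------------------------------


def save_model(result: FitResult, path) -> None:
    """Write the fitted model as a JSON document."""
    doc = {
        "edge_type_names": result.edge_type_names,
        "w": [float(x) for x in result.w],
        "mode": result.mode,
        "config": {
            "lambda": result.config.lam,
            "b": result.config.b,
            "alpha": result.config.alpha,
        },
        "optimizer": {
            "iterations": result.iterations,
            "converged": result.converged,
            "final_objective": result.objective_trace[-1],
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_model(path) -> FitResult:
    with open(path) as fh:
        doc = json.load(fh)
    cfg = LossConfig(
        lam=doc["config"]["lambda"],
        b=doc["config"]["b"],
        alpha=doc["config"]["alpha"],
        mode=doc["mode"],
    )
    return FitResult(
        w=np.array(doc["w"], dtype=float),
        objective_trace=[doc["optimizer"]["final_objective"]],
        converged=doc["optimizer"]["converged"],
        iterations=doc["optimizer"]["iterations"],
        mode=doc["mode"],
        edge_type_names=list(doc["edge_type_names"]),
        config=cfg,
    )
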