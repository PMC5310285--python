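"""Loss, objective, analytic gradients and the gradient-descent fit."""

import numpy as np
import pytest

from slnsrw.edge_model import normalized_strengths
from slnsrw.hetnet import TrainingInstance
from slnsrw.train import (
    LossConfig,
    OptimizerSettings,
    fit,
    finite_diff_gradient,
    grad_objective,
    grad_stationary,
    grad_transition,
    load_model,
    loss_h,
    loss_h_prime,
    objective,
    save_model,
)
from slnsrw.walk import build_transition, stationary, stationary_oracle

from conftest import make_net, path_net, random_net


class TestLossH:
    def test_zero_below_margin(self):
        assert loss_h(-0.1, 0.03) == 0.0
        assert loss_h(-1e-12, 1.0) == 0.0

    def test_half_at_zero(self):
        assert loss_h(0.0, 0.03) == 0.5

    def test_logistic_above_zero(self):
        assert loss_h(0.03, 0.03) == pytest.approx(0.731059, abs=1e-6)

    def test_invalid_sharpness_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            loss_h(0.1, 0.0)
        with pytest.raises(ValueError, match="positive"):
            loss_h_prime(0.1, -1.0)

    def test_derivative_matches_right_branch(self):
        for x in (0.0, 0.01, 0.2):
            fd = (loss_h(x + 1e-7, 0.03) - loss_h(x + 1e-7 / 2, 0.03)) / (1e-7 / 2)
            assert loss_h_prime(x, 0.03) == pytest.approx(fd, rel=1e-3)
        assert loss_h_prime(-0.5, 0.03) == 0.0


def loss_instance_net():
    """Symmetric 3-node path: disease center, one gene either side."""
    net = make_net(
        3,
        [(1, 0, 0, 1.0), (1, 2, 0, 1.0)],
        K=2,
        node_types=["gene", "disease", "gene"],
    )
    return net, TrainingInstance("x1", ("x0",), ("x2",))


class TestObjective:
    def test_pure_regularizer_when_pairs_satisfied(self):
        # disease adjacent to positive, negative two hops away
        net = make_net(
            4,
            [(0, 1, 0, 1.0), (1, 2, 1, 1.0), (2, 3, 1, 1.0)],
            K=2,
            node_types=["disease", "gene", "gene", "gene"],
        )
        inst = TrainingInstance("x0", ("x1",), ("x3",))
        w = np.array([1.0, -1.0])
        cfg = LossConfig(lam=1.0)
        assert objective(w, net, [inst], cfg) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_tie_costs_half_lambda(self):
        net, inst = loss_instance_net()
        for lam in (1.0, 3.0):
            cfg = LossConfig(lam=lam)
            assert objective(np.zeros(2), net, [inst], cfg) == pytest.approx(
                0.5 * lam, abs=1e-9
            )

    def test_matches_bruteforce_enumeration(self, rng):
        # independent oracle: explicit pair loops over oracle-solved S
        net = random_net(rng, 5, K=2)
        inst = TrainingInstance("x0", ("x1", "x2"), ("x3", "x4"))
        cfg = LossConfig(lam=2.0, b=0.05, alpha=0.3)
        w = rng.normal(size=2)

        model = build_transition(
            net, normalized_strengths(net, w, cfg.mode), cfg.alpha, 0
        )
        S = stationary_oracle(model).P
        expected = 0.5 * w @ w
        for p in inst.positives:
            for n in inst.negatives:
                x = S[net.node_index(n)] - S[net.node_index(p)]
                expected += cfg.lam * (
                    0.0 if x < 0 else 1.0 / (1.0 + np.exp(-x / cfg.b))
                )
        assert objective(w, net, [inst], cfg) == pytest.approx(expected, rel=1e-8)

    def test_missing_instance_node_raises(self):
        net, _ = loss_instance_net()
        inst = TrainingInstance("x1", ("x0",), ("nope",))
        with pytest.raises(KeyError):
            objective(np.zeros(2), net, [inst], LossConfig())


class TestGradTransition:
    def test_nonedge_is_zero(self, rng):
        net = path_net(3, K=1)
        g = grad_transition(net, np.array([0.5]), 0.2, "x0", "x2")
        np.testing.assert_array_equal(g, np.zeros(1))

    def test_single_edge_constant_rows(self, two_node_net):
        g = grad_transition(two_node_net, np.array([0.7]), 0.2, "x0", "x1")
        np.testing.assert_allclose(g, 0.0, atol=1e-15)

    @pytest.mark.parametrize("mode", ["laplacian", "none"])
    def test_matches_finite_difference_on_every_edge(self, rng, mode):
        net = random_net(rng, 10, K=2)
        w = rng.normal(size=2)
        alpha = 0.25

        for e in range(net.n_edges):
            for u, v in [
                (net.edge_u[e], net.edge_v[e]),
                (net.edge_v[e], net.edge_u[e]),
            ]:

                def q_entry(ww):
                    from slnsrw.walk import row_normalize

                    a = normalized_strengths(net, ww, mode)
                    Qp, _ = row_normalize(a)
                    return (1 - alpha) * Qp[u, v]

                fd = finite_diff_gradient(q_entry, w)
                g = grad_transition(net, w, alpha, int(u), int(v), mode)
                np.testing.assert_allclose(g, fd, rtol=1e-4, atol=1e-8)


class TestGradStationary:
    def test_columns_sum_to_zero(self, rng):
        net = random_net(rng, 12, K=2)
        gs = grad_stationary(net, rng.normal(size=2), LossConfig(), "x0")
        np.testing.assert_allclose(gs.dS.sum(axis=0), 0.0, atol=1e-9)

    def test_two_node_chain_matches_finite_difference(self, two_node_net):
        cfg = LossConfig(alpha=0.2)
        w = np.array([0.4])
        gs = grad_stationary(two_node_net, w, cfg, "x0")

        def stat(ww):
            m = build_transition(
                two_node_net,
                normalized_strengths(two_node_net, ww, cfg.mode),
                cfg.alpha,
                0,
            )
            return stationary(m).P

        fd = np.column_stack(
            [(stat(w + 1e-5) - stat(w - 1e-5)) / 2e-5]
        )
        np.testing.assert_allclose(gs.dS, fd, atol=1e-5)

    @pytest.mark.parametrize("mode", ["laplacian", "none"])
    def test_random_graphs_match_finite_difference(self, rng, mode):
        for _ in range(5):
            K = int(rng.integers(1, 4))
            net = random_net(rng, int(rng.integers(5, 20)), K)
            w = rng.normal(size=K)
            cfg = LossConfig(alpha=float(rng.uniform(0.1, 0.6)), mode=mode)
            s = int(rng.integers(net.n_nodes))
            gs = grad_stationary(net, w, cfg, s)

            def stat(ww):
                m = build_transition(
                    net, normalized_strengths(net, ww, mode), cfg.alpha, s
                )
                return stationary(m).P

            fd = np.zeros_like(gs.dS)
            for k in range(K):
                e = np.zeros(K)
                e[k] = 1e-5
                fd[:, k] = (stat(w + e) - stat(w - e)) / 2e-5
            scale = max(np.abs(fd).max(), 1e-12)
            np.testing.assert_allclose(gs.dS / scale, fd / scale, atol=1e-3)


class TestGradObjective:
    def test_reduces_to_regularizer_when_loss_inactive(self):
        net = make_net(
            4,
            [(0, 1, 0, 1.0), (1, 2, 1, 1.0), (2, 3, 1, 1.0)],
            K=2,
            node_types=["disease", "gene", "gene", "gene"],
        )
        inst = TrainingInstance("x0", ("x1",), ("x3",))
        w = np.array([1.0, -1.0])
        g = grad_objective(w, net, [inst], LossConfig())
        np.testing.assert_allclose(g, w, atol=1e-6)

    def test_symmetric_tie_gradient_is_loss_term_only(self):
        net, inst = loss_instance_net()
        cfg = LossConfig(lam=2.0)
        w = np.zeros(2)
        gs = grad_stationary(net, w, cfg, "x1")
        expected = cfg.lam * loss_h_prime(0.0, cfg.b) * (
            gs.dS[net.node_index("x2")] - gs.dS[net.node_index("x0")]
        )
        np.testing.assert_allclose(
            grad_objective(w, net, [inst], cfg), expected, atol=1e-9
        )

    @pytest.mark.parametrize("mode", ["laplacian", "none"])
    def test_matches_finite_difference_on_toy_networks(self, rng, mode):
        for _ in range(4):
            net = random_net(rng, 8, K=2)
            inst = TrainingInstance("x0", ("x1", "x2"), ("x5", "x6"))
            cfg = LossConfig(lam=3.0, b=0.05, alpha=0.3, mode=mode)
            w = rng.normal(size=2)
            g = grad_objective(w, net, [inst], cfg)
            fd = finite_diff_gradient(
                lambda ww: objective(ww, net, [inst], cfg), w
            )
            np.testing.assert_allclose(g, fd, rtol=1e-3, atol=1e-6)


class TestFit:
    def test_no_instances_shrinks_to_zero(self, two_node_net):
        result = fit(two_node_net, [], LossConfig(lam=1.0))
        assert np.abs(result.w).max() < 0.01
        assert result.converged

    def test_trace_non_increasing(self, rng):
        net = random_net(rng, 10, K=2)
        inst = TrainingInstance("x0", ("x1", "x3"), ("x6", "x8"))
        result = fit(net, [inst], LossConfig(lam=50.0))
        trace = np.array(result.objective_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_recovers_sign_pattern_on_synthetic_network(self):
        from slnsrw.synthetic import (
            assign_gold_types,
            copying_model,
            make_synthetic_instance,
        )

        net = assign_gold_types(copying_model(120, 0.8, 5), 2, 6, n_nodes=120)
        inst = make_synthetic_instance(net, (1.0, -1.0), 0.2, 10, 7)
        result = fit(net, [inst], LossConfig(lam=10.0))
        assert result.w[0] > result.w[1]

    def test_w0_length_checked(self, two_node_net):
        with pytest.raises(ValueError, match="w0"):
            fit(two_node_net, [], LossConfig(), OptimizerSettings(w0=np.ones(3)))

    def test_model_round_trip(self, tmp_path, rng):
        net = random_net(rng, 6, K=2)
        result = fit(net, [], LossConfig(lam=1.0, b=0.1, alpha=0.4))
        p = tmp_path / "model.json"
        save_model(result, p)
        loaded = load_model(p)
        np.testing.assert_allclose(loaded.w, result.w)
        assert loaded.config.b == 0.1
        assert loaded.edge_type_names == result.edge_type_names


class TestFiniteDiff:
    def test_quadratic_recovered_exactly(self):
        w = np.array([0.3, -1.2, 2.0])
        fd = finite_diff_gradient(lambda x: 0.5 * x @ x, w)
        np.testing.assert_allclose(fd, w, atol=1e-9)
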