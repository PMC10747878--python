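"""Network components: layer semantics, architectural invariants, gradients."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connectofuse.network import (
    Adam,
    MultimodalGraphClassifier,
    _attention_forward,
    _softmax,
    attention_fuse,
    cross_entropy_loss,
    global_max_pool,
    graphconv_forward,
)


def random_graph_batch(rng, b=3, r=5, p=6):
    x = rng.standard_normal((b, r, r))
    a = np.abs(rng.standard_normal((b, r, r)))
    a = (a + a.transpose(0, 2, 1)) / 2
    for k in range(b):
        np.fill_diagonal(a[k], 0.0)
    pheno = rng.standard_normal((b, p))
    y = rng.integers(0, 2, b)
    return x, a, pheno, y


class TestGraphConv:
    def test_identity_self_transform(self, rng):
        x = rng.standard_normal((4, 4))
        a = np.zeros((4, 4))
        out = graphconv_forward(x, a, np.eye(4), np.zeros((4, 4)))
        np.testing.assert_allclose(out, x)

    def test_neighbor_aggregation_hand_example(self):
        # two nodes joined by weight 0.5; h1=(1,0), h2=(0,2); W1=0, W2=I
        x = np.array([[1.0, 0.0], [0.0, 2.0]])
        a = np.array([[0.0, 0.5], [0.5, 0.0]])
        out = graphconv_forward(x, a, np.zeros((2, 2)), np.eye(2))
        np.testing.assert_allclose(out, [[0.0, 1.0], [0.5, 0.0]])

    def test_isolated_node_gets_only_self_term(self, rng):
        x = rng.standard_normal((3, 3))
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.7  # node 2 isolated
        w1, w2 = rng.standard_normal((3, 2)), rng.standard_normal((3, 2))
        out = graphconv_forward(x, a, w1, w2)
        np.testing.assert_allclose(out[2], x[2] @ w1)

    def test_zero_weight_edge_equals_deleted_edge(self, rng):
        x = rng.standard_normal((4, 4))
        a = np.abs(rng.standard_normal((4, 4)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        a_zeroed = a.copy()
        a_zeroed[1, 2] = a_zeroed[2, 1] = 0.0
        a_deleted = a_zeroed.copy()  # same structure: zeroing IS deletion
        w1, w2 = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        np.testing.assert_array_equal(
            graphconv_forward(x, a_zeroed, w1, w2), graphconv_forward(x, a_deleted, w1, w2)
        )


class TestPooling:
    def test_elementwise_max(self):
        np.testing.assert_array_equal(
            global_max_pool(np.array([[1.0, 5.0], [3.0, 2.0]])), [3.0, 5.0]
        )

    def test_single_node(self):
        np.testing.assert_array_equal(global_max_pool(np.array([[2.0, -1.0]])), [2.0, -1.0])

    def test_permutation_invariance(self, rng):
        x = rng.standard_normal((6, 4))
        perm = rng.permutation(6)
        np.testing.assert_array_equal(global_max_pool(x), global_max_pool(x[perm]))

    def test_empty_node_set_rejected(self):
        with pytest.raises(ValueError):
            global_max_pool(np.zeros((0, 3)))


class TestAttention:
    def test_uniform_vector_passes_through(self):
        # A=(1,1): scores all 0.5, softmax rows uniform, output = A
        out = attention_fuse(np.array([1.0]), np.array([1.0]))
        np.testing.assert_allclose(out, [[1.0, 1.0]])

    def test_zero_vector_maps_to_zero_with_uniform_rows(self):
        a = np.zeros((1, 6))
        fused, alpha = _attention_forward(a)
        np.testing.assert_allclose(alpha, 1.0 / 6)
        np.testing.assert_allclose(fused, 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=6), st.integers(min_value=0, max_value=2**31 - 1))
    def test_rows_sum_to_one(self, d, seed):
        a = np.random.default_rng(seed).standard_normal((2, 2 * d))
        _, alpha = _attention_forward(a)
        np.testing.assert_allclose(alpha.sum(axis=2), 1.0, atol=1e-12)
        assert (alpha > 0).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention_fuse(np.zeros(3), np.zeros(4))


class TestClassifierAndLoss:
    def test_equal_logits_give_half_half(self):
        np.testing.assert_allclose(_softmax(np.zeros((1, 2))), [[0.5, 0.5]])

    def test_softmax_shift_invariance(self):
        p1 = _softmax(np.array([[1.0, 3.0]]))
        p2 = _softmax(np.array([[11.0, 13.0]]))
        np.testing.assert_allclose(p1, p2)
        assert p1[0, 1] / p1[0, 0] == pytest.approx(np.exp(2.0))

    def test_perfect_predictions_zero_loss(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy_loss(probs, [0, 1]) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_predictions_ln2(self):
        probs = np.full((4, 2), 0.5)
        assert cross_entropy_loss(probs, [0, 1, 1, 0]) == pytest.approx(np.log(2))

    def test_hand_worked_value(self):
        assert cross_entropy_loss(np.array([[0.9, 0.1]]), [0]) == pytest.approx(
            -np.log(0.9), abs=1e-12
        )

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.zeros((0, 2)), [])


class TestModel:
    def test_forward_is_node_permutation_invariant(self, rng):
        x, a, pheno, _ = random_graph_batch(rng)
        model = MultimodalGraphClassifier(n_roi=5, pheno_dim=6, d1=8, d2=4, seed=3)
        logits, _ = model.forward(x, a, pheno, training=False)
        perm = rng.permutation(5)
        xp = x[:, perm, :]
        ap = a[:, perm, :][:, :, perm]
        logits_p, _ = model.forward(xp, ap, pheno, training=False)
        np.testing.assert_allclose(logits, logits_p, atol=1e-10)

    def test_eval_mode_deterministic(self, rng):
        x, a, pheno, _ = random_graph_batch(rng)
        model = MultimodalGraphClassifier(n_roi=5, pheno_dim=6, seed=0)
        p1 = model.predict_proba(x, a, pheno)
        p2 = model.predict_proba(x, a, pheno)
        np.testing.assert_array_equal(p1, p2)

    def test_gradients_match_finite_differences(self, rng):
        """Analytic vs numerical gradients of the composed loss on a 5-node toy."""
        x, a, pheno, y = random_graph_batch(rng, b=4, r=5, p=6)
        model = MultimodalGraphClassifier(n_roi=5, pheno_dim=6, d1=6, d2=4, clf_hidden=5, seed=1)
        _, grads = copy.deepcopy(model).loss_and_grads(x, a, pheno, y, training=True)
        eps = 1e-6
        check_rng = np.random.default_rng(99)
        for name, theta in model.params.items():
            flat = theta.ravel()
            for i in check_rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = copy.deepcopy(model).loss_and_grads(x, a, pheno, y, training=True)
                flat[i] = orig - eps
                lm, _ = copy.deepcopy(model).loss_and_grads(x, a, pheno, y, training=True)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[i]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), f"{name}[{i}]"

    def test_pfe_matches_affine_oracle(self, rng):
        model = MultimodalGraphClassifier(n_roi=4, pheno_dim=5, d1=6, d2=3, seed=2)
        x, a, pheno, _ = random_graph_batch(rng, b=2, r=4, p=5)
        _, cache = model.forward(x, a, pheno, training=False)
        expected = np.maximum(pheno @ model.params["pfe_w0"] + model.params["pfe_b0"], 0.0)
        np.testing.assert_allclose(cache["fused_in"][:, 3:], expected, atol=1e-12)

    def test_imaging_only_variant(self, rng):
        x, a, _, y = random_graph_batch(rng)
        model = MultimodalGraphClassifier(n_roi=5, pheno_dim=0, use_phenotype=False, seed=0)
        probs = model.predict_proba(x, a, None)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)

    def test_state_dict_round_trip(self, rng):
        x, a, pheno, _ = random_graph_batch(rng)
        model = MultimodalGraphClassifier(n_roi=5, pheno_dim=6, seed=4)
        clone = MultimodalGraphClassifier.from_state_dict(model.state_dict())
        np.testing.assert_allclose(
            model.predict_proba(x, a, pheno), clone.predict_proba(x, a, pheno), atol=1e-12
        )

    def test_adam_no_decay_set_respected(self):
        params = {"w": np.ones(2), "bn1_gamma": np.ones(2)}
        opt = Adam(params, lr=0.0, weight_decay=0.5, no_decay={"bn1_gamma"})
        opt.step({"w": np.zeros(2), "bn1_gamma": np.zeros(2)})
        # lr=0 -> parameters unchanged regardless; decay only enters the moments
        assert opt.m["w"][0] != 0.0 and opt.m["bn1_gamma"][0] == 0.0
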