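"""Attention blocks, fusion, classification head and decoders.

The independent oracle is a dense per-row implementation of
softmax(QK^T / sqrt(d)) V written with explicit Python loops, kept free
of the package's vectorized path.
"""

import numpy as np
import pytest

from omicsformer.dataio import MultiOmicsDataset, OmicsMatrix
from omicsformer.model import (
    AttentionBlockParams,
    OmicsformerModel,
    classify,
    concat_representations,
    decode,
    encode_all,
    forward,
    fuse,
    predict_proba,
    self_attention,
)


def brute_force_attention(X, W_Q, W_K, W_V, scale_dim):
    """Loop-based oracle: row i attends over all rows j."""
    Q, K, V = X @ W_Q, X @ W_K, X @ W_V
    n = X.shape[0]
    H = np.zeros((n, V.shape[1]))
    for i in range(n):
        scores = np.array([Q[i] @ K[j] for j in range(n)]) / np.sqrt(scale_dim)
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        for j in range(n):
            H[i] += w[j] * V[j]
    return H


def random_block(rng, d_in, d_out, scale_mode="sqrt"):
    return AttentionBlockParams(
        rng.normal(size=(d_in, d_out)),
        rng.normal(size=(d_in, d_out)),
        rng.normal(size=(d_in, d_out)),
        scale_dim=d_out,
        scale_mode=scale_mode,
    )


class TestSelfAttention:
    def test_matches_brute_force_oracle_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            X = rng.normal(size=(5, 4))
            blk = random_block(rng, 4, 3)
            expected = brute_force_attention(X, blk.W_Q, blk.W_K, blk.W_V, 3)
            assert np.abs(self_attention(X, blk) - expected).max() < 1e-10

    def test_single_sample_reduces_to_value_projection(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(1, 4))
        blk = random_block(rng, 4, 3)
        np.testing.assert_allclose(self_attention(X, blk), X @ blk.W_V, atol=1e-12)

    def test_zero_input_gives_zero_output(self):
        rng = np.random.default_rng(1)
        blk = random_block(rng, 4, 3)
        np.testing.assert_array_equal(self_attention(np.zeros((6, 4)), blk), 0.0)

    def test_two_sample_scalar_example(self):
        # X=[[0],[1]], all weights [1], scale 1: scores [[0,0],[0,1]]
        one = np.array([[1.0]])
        blk = AttentionBlockParams(one, one, one, scale_dim=1)
        H = self_attention(np.array([[0.0], [1.0]]), blk)
        np.testing.assert_allclose(
            H.ravel(), [0.5, np.exp(1) / (1 + np.exp(1))], atol=1e-5
        )

    def test_attention_rows_are_convex_weights(self):
        # output rows lie inside the convex hull of the value rows
        rng = np.random.default_rng(2)
        X = rng.normal(size=(7, 5))
        blk = random_block(rng, 5, 2)
        H = self_attention(X, blk)
        V = X @ blk.W_V
        assert H.min() >= V.min() - 1e-9 and H.max() <= V.max() + 1e-9

    def test_dimension_mismatch_raises(self):
        rng = np.random.default_rng(3)
        blk = random_block(rng, 4, 3)
        with pytest.raises(ValueError, match="width"):
            self_attention(np.zeros((2, 5)), blk)


def make_dataset(rng, dims, n=6, labels=None):
    layers = [
        OmicsMatrix(
            rng.normal(size=(n, d)),
            [f"s{i}" for i in range(n)],
            [f"{name}_{j}" for j in range(d)],
            name,
        )
        for name, d in dims.items()
    ]
    return MultiOmicsDataset(layers, labels)


class TestEncodeFuseClassify:
    def setup_method(self):
        self.rng = np.random.default_rng(10)
        self.dims = {"a": 7, "b": 5}
        self.ds = make_dataset(self.rng, self.dims)
        self.model = OmicsformerModel.initialize(self.dims, 3, d_hidden=4, d_mul=3, seed=0)

    def test_encode_all_shapes(self):
        H_list = encode_all(self.ds, self.model)
        assert [H.shape for H in H_list] == [(6, 4), (6, 4)]

    def test_permutation_equivariance(self):
        perm = self.rng.permutation(6)
        permuted = self.ds.subset_samples(perm)
        H_orig = forward(self.ds, self.model)["H_F"]
        H_perm = forward(permuted, self.model)["H_F"]
        np.testing.assert_allclose(H_perm, H_orig[perm], atol=1e-10)

    def test_concat_widths_and_offsets(self):
        H_list = [np.ones((3, 4)), 2 * np.ones((3, 3)), 3 * np.ones((3, 2))]
        H = concat_representations(H_list)
        assert H.shape == (3, 9)
        assert H[0, 4 + 1] == 2.0  # column j of layer 2 sits at offset d1 + j
        with pytest.raises(ValueError):
            concat_representations([np.ones((3, 2)), np.ones((4, 2))])

    def test_fuse_matches_oracle(self):
        rng = np.random.default_rng(4)
        H_mul = rng.normal(size=(4, 8))
        model = OmicsformerModel.initialize({"a": 5, "b": 5}, 3, d_hidden=4, d_mul=3, seed=1)
        fus = model.fusion
        expected = brute_force_attention(H_mul, fus.W_Q, fus.W_K, fus.W_V, fus.scale_dim)
        assert np.abs(fuse(H_mul, model) - expected).max() < 1e-10

    def test_fuse_zero_and_single_row(self):
        assert np.all(fuse(np.zeros((3, 8)), self.model) == 0)
        h = self.rng.normal(size=(1, 8))
        np.testing.assert_allclose(
            fuse(h, self.model), h @ self.model.fusion.W_V, atol=1e-12
        )

    def test_classify_uniform_for_zero_head(self):
        self.model.head.W[:] = 0
        self.model.head.b[:] = 0
        P = classify(self.rng.normal(size=(5, 3)), self.model)
        np.testing.assert_allclose(P, 1 / 3, atol=1e-12)

    def test_classify_rows_sum_to_one(self):
        P = classify(self.rng.normal(size=(8, 3)) * 5, self.model)
        assert P.min() >= 0
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_logit_boost_wins_argmax(self):
        H = self.rng.normal(size=(4, 3))
        base = H @ self.model.head.W + self.model.head.b
        self.model.head.b[1] += 10.0 + np.abs(base).max() * 2
        P = classify(H, self.model)
        assert (np.argmax(P, axis=1) == 1).all()

    def test_layer_count_mismatch_raises(self):
        ds1 = make_dataset(self.rng, {"a": 7})
        with pytest.raises(ValueError, match="layers"):
            encode_all(ds1, self.model)


class TestDecode:
    def test_shapes_and_zero_case(self):
        model = OmicsformerModel.initialize({"a": 7, "b": 5}, 2, d_hidden=4, seed=0)
        H = np.zeros((3, 4))
        model.decoders[0].W[:] = 0
        model.decoders[0].b[:] = 0
        assert decode(H, model, 0).shape == (3, 7)
        np.testing.assert_array_equal(decode(H, model, 0), 0.0)
        assert decode(np.ones((3, 4)), model, "b").shape == (3, 5)
        with pytest.raises(KeyError):
            decode(H, model, "nope")

    def test_orthogonal_encoder_pseudoinverse_decoder_reconstructs(self):
        # noiseless low-rank data, V an orthonormal basis of its row space:
        # with identity-like attention bypassed (single sample), decoding
        # by the transposed basis restores the input exactly
        rng = np.random.default_rng(5)
        basis, _ = np.linalg.qr(rng.normal(size=(6, 2)))  # 6-dim, rank 2
        X = rng.normal(size=(1, 2)) @ basis.T
        model = OmicsformerModel.initialize({"a": 6}, 2, d_hidden=2, seed=0)
        model.blocks[0].W_V[:] = basis  # encoder = projection onto basis
        model.decoders[0].W[:] = basis.T  # decoder = pseudo-inverse
        model.decoders[0].b[:] = 0
        H = self_attention(X, model.blocks[0])  # n=1: H = X @ W_V
        np.testing.assert_allclose(decode(H, model, 0), X, atol=1e-10)


def test_forward_is_deterministic(tiny_pre, tiny_fit):
    batch = tiny_pre.subset_samples(np.arange(6))
    p1 = predict_proba(batch, tiny_fit.model)
    p2 = predict_proba(batch, tiny_fit.model)
    np.testing.assert_array_equal(p1, p2)


def test_gradients_match_finite_differences(tiny_pre):
    """Backprop through attention, decoders, fusion and head is checked
    against central finite differences of the joint loss."""
    from omicsformer.training import _grads, classification_loss

    ds = tiny_pre.subset_samples(np.arange(8))
    model = OmicsformerModel.initialize(
        {lay.omics_name: lay.n_features for lay in ds.layers},
        int(tiny_pre.labels.max()) + 1,
        d_hidden=4,
        d_mul=3,
        seed=2,
    )
    y = ds.labels

    def loss():
        out = forward(ds, model)
        L_re = sum(
            np.sum((xh - lay.values) ** 2) for xh, lay in zip(out["X_hat"], ds.layers)
        )
        return L_re + classification_loss(y, out["proba"])

    _, _, grads = _grads(ds, model, y, 1.0, "cross_entropy", joint=True)
    params = model.parameters()
    rng = np.random.default_rng(0)
    eps = 1e-6
    for pi in rng.choice(len(params), size=6, replace=False):
        p, g = params[pi], grads[pi]
        idx = tuple(rng.integers(0, s) for s in p.shape)
        p[idx] += eps
        up = loss()
        p[idx] -= 2 * eps
        down = loss()
        p[idx] += eps
        numeric = (up - down) / (2 * eps)
        assert numeric == pytest.approx(g[idx], rel=1e-4, abs=1e-6)


def test_attention_block_validation():
    W = np.zeros((3, 2))
    with pytest.raises(ValueError, match="scale_dim"):
        AttentionBlockParams(W, W, W, scale_dim=3)
    with pytest.raises(ValueError, match="shape"):
        AttentionBlockParams(W, W, np.zeros((3, 4)), scale_dim=2)


def test_linear_scale_mode_divides_by_d():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(4, 3))
    W = rng.normal(size=(3, 4))
    sqrt_blk = AttentionBlockParams(W, W, W, scale_dim=4, scale_mode="sqrt")
    lin_blk = AttentionBlockParams(W, W, W, scale_dim=4, scale_mode="linear")
    assert sqrt_blk.scale == pytest.approx(2.0)
    assert lin_blk.scale == pytest.approx(4.0)
    assert not np.allclose(self_attention(X, sqrt_blk), self_attention(X, lin_blk))
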