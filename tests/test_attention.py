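"""Single-environment attention model: oracles, invariants, gradients."""

import numpy as np
import pytest

from attnmap._core import attention_layer, softmax_rows
from attnmap.attention import AttentionGPModel, count_parameters, init_model


def naive_attention(Z, W_Q, W_K, W_V):
    """Brute-force oracle: explicit three-matrix products and softmax."""
    Q, K, V = Z @ W_Q, Z @ W_K, Z @ W_V
    S = Q @ K.T
    A = np.exp(S - S.max(axis=1, keepdims=True))
    A /= A.sum(axis=1, keepdims=True)
    return A @ V


def materialized_one_hot(x):
    """Explicit signed one-hot matrix: row l has x_l at column l."""
    return np.diag(x.astype(float))


class TestSoftmax:
    def test_uniform_on_equal_scores(self):
        assert np.allclose(softmax_rows(np.array([[0.0, 0.0]])), [[0.5, 0.5]])

    def test_closed_form_log_ratio(self):
        out = softmax_rows(np.array([[0.0, np.log(2.0)]]))
        assert np.allclose(out, [[1 / 3, 2 / 3]])

    def test_shift_invariance_no_overflow(self):
        out = softmax_rows(np.array([[1000.0, 1000.0]]))
        assert np.allclose(out, [[0.5, 0.5]])
        assert np.isfinite(softmax_rows(np.array([[1e4, -1e4]]))).all()

    def test_rows_sum_to_one_across_random_inputs(self, rng):
        # includes extreme-magnitude scores
        for _ in range(100):
            scale = rng.choice([1e-3, 1.0, 1e3])
            M = rng.normal(0, scale, size=(5, 7))
            assert np.allclose(softmax_rows(M).sum(axis=1), 1.0, atol=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            softmax_rows(np.array([[np.nan, 0.0]]))


class TestEmbedding:
    def test_all_plus_one_gives_w_embed(self):
        m = init_model(6, 3, 1, seed=0)
        Z = m.embed(np.ones(6)).Z
        assert np.allclose(Z, m.params["W_embed"])

    def test_all_minus_one_negates(self):
        m = init_model(6, 3, 1, seed=0)
        Z = m.embed(-np.ones(6)).Z
        assert np.allclose(Z, -m.params["W_embed"])

    def test_equals_materialized_one_hot_product(self, rng):
        m = init_model(5, 3, 1, seed=1)
        x = rng.integers(0, 2, size=5) * 2 - 1
        Z = m.embed(x).Z
        oracle = materialized_one_hot(x) @ m.params["W_embed"]
        assert np.allclose(Z, oracle, atol=1e-12)

    def test_allele_flip_negates_one_row(self, rng):
        m = init_model(5, 3, 1, seed=2)
        x = rng.integers(0, 2, size=5) * 2 - 1
        Z0 = m.embed(x).Z
        x2 = np.array(x)
        x2[2] *= -1
        Z1 = m.embed(x2).Z
        assert np.allclose(Z1[2], -Z0[2])
        assert np.allclose(np.delete(Z1, 2, axis=0), np.delete(Z0, 2, axis=0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            init_model(5, 3, 1).embed(np.ones(4))


class TestAttentionLayer:
    def test_zero_projections_give_uniform_attention(self, rng):
        Z = rng.normal(size=(4, 3))
        W_V = rng.normal(size=(3, 3))
        out = attention_layer(Z, np.zeros((3, 3)), np.zeros((3, 3)), W_V)
        expected = np.tile((Z @ W_V).mean(axis=0), (4, 1))
        assert np.allclose(out, expected, atol=1e-12)

    def test_single_token(self, rng):
        Z = rng.normal(size=(1, 3))
        Ws = [rng.normal(size=(3, 3)) for _ in range(3)]
        out = attention_layer(Z, *Ws)
        assert np.allclose(out, Z @ Ws[2], atol=1e-12)

    def test_matches_naive_oracle(self, rng):
        Z = rng.normal(size=(5, 4))
        Ws = [rng.normal(size=(4, 4)) for _ in range(3)]
        assert np.allclose(attention_layer(Z, *Ws), naive_attention(Z, *Ws),
                           atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            attention_layer(rng.normal(size=(5, 4)), np.eye(3), np.eye(3),
                            np.eye(3))


class TestForward:
    def test_zero_regression_weights_give_bias(self, rng):
        m = init_model(8, 4, 3, seed=3)
        m.params["beta0"][()] = 1.7
        for _ in range(3):
            x = rng.integers(0, 2, size=8) * 2 - 1
            assert m.forward(x) == pytest.approx(1.7)

    def test_no_layers_is_linear_in_genotype(self, rng):
        # NL=0: prediction = beta0 + sum_l x_l <reg[l], W_embed[l]>
        m = init_model(6, 3, 0, seed=4)
        m.params["reg_weights"][:] = rng.normal(size=(6, 3))
        m.params["beta0"][()] = 0.5
        betas = np.sum(m.params["reg_weights"] * m.params["W_embed"], axis=1)
        for _ in range(5):
            x = rng.integers(0, 2, size=6) * 2 - 1
            assert m.forward(x) == pytest.approx(0.5 + betas @ x, abs=1e-10)

    def test_matches_layer_by_layer_oracle(self, rng):
        m = init_model(10, 4, 3, seed=5)
        m.params["reg_weights"][:] = rng.normal(size=(10, 4))
        m.params["beta0"][()] = -0.3
        x = rng.integers(0, 2, size=10) * 2 - 1
        Z = materialized_one_hot(x) @ m.params["W_embed"]
        for (W_Q, W_K, W_V) in m.layers:
            Z = naive_attention(Z, W_Q, W_K, W_V)
        oracle = -0.3 + np.sum(m.params["reg_weights"] * Z)
        assert m.forward(x) == pytest.approx(oracle, abs=1e-10)

    def test_batch_prediction_matches_per_individual(self, rng):
        m = init_model(7, 3, 2, seed=6)
        m.params["reg_weights"][:] = rng.normal(size=(7, 3))
        X = rng.integers(0, 2, size=(4, 7)) * 2 - 1
        batch = m.predict(X)
        singles = [m.forward(x) for x in X]
        assert np.allclose(batch, singles, atol=1e-12)

    def test_permutation_covariance(self, rng):
        # permuting loci together with embedding and regression rows is a no-op
        m = init_model(9, 4, 3, seed=7)
        m.params["reg_weights"][:] = rng.normal(size=(9, 4))
        x = rng.integers(0, 2, size=9) * 2 - 1
        perm = rng.permutation(9)
        m2 = init_model(9, 4, 3, seed=7)
        m2.params["W_embed"][:] = m.params["W_embed"][perm]
        m2.params["reg_weights"][:] = m.params["reg_weights"][perm]
        assert m2.forward(x[perm]) == pytest.approx(m.forward(x), abs=1e-10)


class TestParameterCount:
    @pytest.mark.parametrize("L,d,NL,expected", [
        (1000, 12, 3, 25_297),
        (1, 1, 1, 6),
    ])
    def test_closed_form(self, L, d, NL, expected):
        assert count_parameters(L, d, NL) == expected

    def test_formula_matches_enumeration_for_random_triples(self, rng):
        for _ in range(20):
            L = int(rng.integers(1, 200))
            d = int(rng.integers(1, 40))
            NL = int(rng.integers(0, 5))
            m = init_model(L, d, NL, seed=0)
            assert m.n_parameters() == count_parameters(L, d, NL)

    @pytest.mark.parametrize("d", [2, 12, 30, 50])
    def test_standard_embedding_dims_construct(self, d):
        m = init_model(20, d, 3, seed=0)
        assert m.n_parameters() == count_parameters(20, d, 3)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        m = init_model(6, 3, 2, seed=8)
        m.params["reg_weights"][:] = rng.normal(0, 0.3, size=(6, 3))
        m.params["beta0"][()] = 0.2
        X = rng.integers(0, 2, size=(5, 6)) * 2 - 1
        y = rng.normal(size=5)
        _, grads = m.loss_and_grads(X, y)
        eps = 1e-6
        for name, p in m.params.items():
            flat = p.reshape(-1)
            for idx in ([0] if p.size == 1 else [0, p.size // 2, p.size - 1]):
                flat[idx] += eps
                lp, _ = m.loss_and_grads(X, y)
                flat[idx] -= 2 * eps
                lm, _ = m.loss_and_grads(X, y)
                flat[idx] += eps
                fd = (lp - lm) / (2 * eps)
                g = np.asarray(grads[name]).reshape(-1)[idx]
                assert g == pytest.approx(fd, abs=1e-6, rel=1e-5), name


class TestPersistence:
    def test_checkpoint_roundtrip_bit_exact(self, tmp_path, rng):
        m = init_model(8, 4, 3, seed=9)
        m.params["reg_weights"][:] = rng.normal(size=(8, 4))
        path = tmp_path / "model.npz"
        m.save(path)
        back = AttentionGPModel.load(path)
        for k in m.params:
            assert (back.params[k] == m.params[k]).all()
        assert (back.L, back.d, back.NL) == (m.L, m.d, m.NL)

    def test_init_seed_determinism(self):
        a, b = init_model(5, 3, 2, seed=42), init_model(5, 3, 2, seed=42)
        for k in a.params:
            assert (a.params[k] == b.params[k]).all()
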