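"""Network stages against independent brute-force oracles, plus contracts:
masking, padding/batching invariance, gradient correctness, checkpointing."""

import numpy as np
import pytest

from phopt.embed import FixtureEmbedder, embed_batch, embed_sequence
from phopt.exceptions import ContractError
from phopt.network import (AttentionResult, ModelConfig, ModelState, forward,
                           forward_batch, init_state, linear_featuremap,
                           load_checkpoint, mse_loss_and_grads,
                           multi_scale_cnn, predict_batch, predict_ph,
                           residual_dense_block, save_checkpoint,
                           self_attention)

from _oracles import (oracle_attention, oracle_conv, oracle_featuremap,
                      oracle_residual)

# ---------------------------------------------------------------------------


class TestMultiScaleCnn:
    def test_identity_1x1_filter(self, rng):
        cfg = ModelConfig(dim=3, n_head=1, n_rd=1, window_sizes=(1,), seed=0)
        state = init_state(cfg)
        state.params["conv1_W"][0] = np.eye(3)
        state.params["conv1_b"][:] = 0
        x = rng.standard_normal((3, 5))
        assert np.allclose(multi_scale_cnn(state, x), x)

    def test_zero_filters_zero_output(self, rng):
        cfg = ModelConfig(dim=3, n_head=1, n_rd=1, window_sizes=(1, 3), seed=0)
        state = init_state(cfg)
        for w in (1, 3):
            state.params[f"conv{w}_W"][:] = 0
            state.params[f"conv{w}_b"][:] = 0
        assert np.all(multi_scale_cnn(state, rng.standard_normal((3, 4))) == 0)

    @pytest.mark.parametrize("window_sizes", [(1, 3), (2,), (1, 2, 3, 4, 5)])
    def test_matches_sliding_window_oracle(self, window_sizes, rng):
        cfg = ModelConfig(dim=2, n_head=1, n_rd=1, window_sizes=window_sizes,
                          seed=4)
        state = init_state(cfg)
        x = rng.standard_normal((2, 6))
        expected = oracle_conv(state.params, window_sizes, x)
        assert np.allclose(multi_scale_cnn(state, x), expected, atol=1e-6)


class TestLinearFeaturemap:
    def test_matches_per_column_oracle(self, tiny_state, rng):
        x = rng.standard_normal((8, 6))
        got = linear_featuremap(tiny_state, x)
        want = oracle_featuremap(tiny_state.params,
                                 tiny_state.config.leaky_slope, x)
        assert np.allclose(got, want, atol=1e-6)

    def test_zero_input_zero_biases(self, tiny_config):
        state = init_state(tiny_config)
        state.params["fm_b1"][:] = 0
        state.params["fm_b2"][:] = 0
        assert np.all(linear_featuremap(state, np.zeros((8, 4))) == 0)

    def test_position_wise_column_permutation(self, tiny_state, rng):
        x = rng.standard_normal((8, 5))
        perm = rng.permutation(5)
        assert np.allclose(linear_featuremap(tiny_state, x)[:, perm],
                           linear_featuremap(tiny_state, x[:, perm]))


class TestSelfAttention:
    def test_uniform_tie_when_logits_equal(self, tiny_config):
        state = init_state(tiny_config)
        # zero the key/query projections: q*k is constant over positions
        for name in ("att_wk", "att_wq"):
            state.params[name][:] = 0
        state.params["att_bk"][:] = 1.7
        state.params["att_bq"][:] = -0.3
        res = self_attention(state, np.random.default_rng(0)
                             .standard_normal((8, 2)))
        assert np.allclose(res.weights, 0.5)

    def test_matches_brute_force_oracle(self, tiny_state, rng):
        x = rng.standard_normal((8, 3))
        res = self_attention(tiny_state, x)
        w_expect, f_expect = oracle_attention(tiny_state.params, x)
        assert np.allclose(res.weights, w_expect, atol=1e-6)
        assert np.allclose(res.per_head_features, f_expect, atol=1e-6)
        assert np.allclose(res.pooled, f_expect.reshape(-1), atol=1e-6)

    def test_masked_padding_column_is_inert(self, tiny_state, rng):
        x = rng.standard_normal((8, 4))
        res = self_attention(tiny_state, x)
        xp = np.concatenate([x, np.zeros((8, 1))], axis=1)
        mask = np.array([True] * 4 + [False])
        resp = self_attention(tiny_state, xp, mask)
        assert np.allclose(resp.weights[:, :4], res.weights)
        assert np.all(resp.weights[:, 4] == 0)
        assert np.allclose(resp.pooled, res.pooled)

    def test_all_masked_rejected(self, tiny_state):
        with pytest.raises(ContractError):
            self_attention(tiny_state, np.zeros((8, 3)),
                           np.zeros(3, dtype=bool))


class TestResidualDenseBlock:
    def test_zero_weights_pure_identity(self, tiny_config, rng):
        state = init_state(tiny_config)
        state.params["rd0_W"][:] = 0
        state.params["rd0_b"][:] = 0
        x = rng.standard_normal(16)
        assert np.array_equal(residual_dense_block(state, x, 0), x)

    def test_zero_input_positive_bias_gives_bias(self, tiny_config):
        state = init_state(tiny_config)
        state.params["rd1_b"][:] = 0.25
        out = residual_dense_block(state, np.zeros(16), 1)
        assert np.allclose(out, 0.25)

    def test_matches_formula_oracle(self, rng):
        cfg = ModelConfig(dim=4, n_head=2, n_rd=1, window_sizes=(1,), seed=9)
        state = init_state(cfg)
        x = rng.standard_normal(8)
        want = oracle_residual(state.params["rd0_W"], state.params["rd0_b"],
                               cfg.leaky_slope, x)
        assert np.allclose(residual_dense_block(state, x, 0), want, atol=1e-6)


class TestForward:
    def test_deterministic(self, tiny_state, rng):
        x = rng.standard_normal((8, 9))
        y1, a1 = forward(tiny_state, x)
        y2, a2 = forward(tiny_state, x)
        assert y1 == y2
        assert np.array_equal(a1.weights, a2.weights)

    def test_batched_equals_single(self, tiny_state, embedder8, rng):
        seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                   size=rng.integers(5, 40)))
                for _ in range(20)]
        batched = predict_batch(tiny_state, seqs, embedder8, batch_size=7,
                                clamp=False)
        single = np.array([
            14.0 * forward(tiny_state, embed_sequence(embedder8, s))[0]
            for s in seqs])
        assert np.allclose(batched, single, atol=1e-5)

    def test_zeroed_value_projections_give_constant_prediction(
            self, tiny_config, embedder8):
        state = init_state(tiny_config)
        state.params["att_Wv"][:] = 0
        p1 = predict_ph(state, "MKVAC", embedder8, clamp=False)
        p2 = predict_ph(state, "WWWWHHHHEEEE", embedder8, clamp=False)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_attention_simplex(self, tiny_state, embedder8):
        r = embed_sequence(embedder8, "MKVACDEFGH")
        _, attn = forward(tiny_state, r)
        assert np.all(attn.weights >= 0)
        assert np.allclose(attn.weights.sum(axis=-1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("dim", [4, 16, 320])
    @pytest.mark.parametrize("L", [1, 2, 7])
    def test_shape_contract_sweep(self, dim, L, rng):
        cfg = ModelConfig(dim=dim, n_head=3, n_rd=2, seed=1)
        state = init_state(cfg)
        x = rng.standard_normal((dim, L))
        y, attn = forward(state, x)
        assert np.isfinite(y)
        assert attn.weights.shape == (3, L)
        assert attn.pooled.shape == (3 * dim,)
        assert np.allclose(attn.weights.sum(axis=-1), 1.0, atol=1e-6)


class TestGradients:
    def test_gradients_match_finite_differences(self, rng):
        cfg = ModelConfig(dim=4, n_head=1, n_rd=1, window_sizes=(1, 2), seed=5)
        state = init_state(cfg)
        B, L = 2, 5
        r = rng.standard_normal((B, 4, L))
        mask = np.ones((B, L), dtype=bool)
        mask[1, 3:] = False
        r[1][:, 3:] = 0
        t = rng.uniform(0.3, 0.7, B)
        _, grads = mse_loss_and_grads(state, r, mask, t)
        eps = 1e-6
        for name, arr in state.params.items():
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + eps
                lp, _ = mse_loss_and_grads(state, r, mask, t)
                arr[i] = orig - eps
                lm, _ = mse_loss_and_grads(state, r, mask, t)
                arr[i] = orig
                num[i] = (lp - lm) / (2 * eps)
            denom = np.abs(num) + np.abs(grads[name]) + 1e-8
            assert np.max(np.abs(num - grads[name]) / denom) < 1e-4, name

    def test_every_parameter_receives_gradient(self, tiny_state, embedder8,
                                               rng):
        # guards against accidentally detached attention weights
        seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=30))
                for _ in range(8)]
        r, mask = embed_batch(embedder8, seqs)
        t = rng.uniform(0.3, 0.7, len(seqs))
        _, grads = mse_loss_and_grads(tiny_state, r, mask, t)
        for name, g in grads.items():
            assert np.any(g != 0), f"zero gradient for {name}"


class TestPredictPh:
    def _constant_state(self, tiny_config, value):
        state = init_state(tiny_config)
        state.params["head_w"][:] = 0
        state.params["head_b"] = np.asarray(value, dtype=float)
        return state

    def test_scaled_half_maps_to_seven(self, tiny_config, embedder8):
        state = self._constant_state(tiny_config, 0.5)
        assert predict_ph(state, "MKV", embedder8) == pytest.approx(7.0)

    def test_clamp_contract(self, tiny_config, embedder8):
        state = self._constant_state(tiny_config, 1.1)
        assert predict_ph(state, "MKV", embedder8) == pytest.approx(14.0)
        assert predict_ph(state, "MKV", embedder8,
                          clamp=False) == pytest.approx(15.4)

    def test_invariant_to_fasta_line_wrapping(self, tmp_path, tiny_state,
                                              embedder8):
        from phopt.io import read_fasta

        seq = "MKVACDEFGHIKWWHH"
        (tmp_path / "a.fasta").write_text(f">a\n{seq}\n")
        (tmp_path / "b.fasta").write_text(f">a\n{seq[:7]}\n{seq[7:]}\n")
        pa = predict_ph(tiny_state, read_fasta(tmp_path / "a.fasta")[0],
                        embedder8)
        pb = predict_ph(tiny_state, read_fasta(tmp_path / "b.fasta")[0],
                        embedder8)
        assert pa == pb


class TestCheckpoint:
    def test_save_load_bit_exact(self, tiny_state, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_state, path)
        loaded = load_checkpoint(path)
        assert loaded.config == tiny_state.config
        assert loaded.params.keys() == tiny_state.params.keys()
        for k in tiny_state.params:
            assert np.array_equal(loaded.params[k], tiny_state.params[k])

    def test_loaded_model_predicts_identically(self, tiny_state, embedder8,
                                               tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_state, path)
        loaded = load_checkpoint(path)
        assert (predict_ph(loaded, "MKVACD", embedder8)
                == predict_ph(tiny_state, "MKVACD", embedder8))
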