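"""Model building blocks against closed-form and hand-composed oracles,
ablation semantics, and the recurrent baselines."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hutchcast as hc
from hutchcast.model import (
    ModelConfig,
    PatchCrossFormer,
    aggregate_step,
    build_baseline,
    cross_attention,
    gru_cell,
    patchify,
    positional_encoding,
)


class TestPatchify:
    def test_patch_count(self):
        assert patchify(np.arange(48), 12).shape == (4, 12)

    def test_fallback_when_sequence_shorter_than_patch(self):
        assert patchify(np.arange(6), 12).shape == (1, 6)

    def test_concatenation_restores_input(self):
        x = np.random.default_rng(0).normal(size=72)
        assert np.array_equal(patchify(x, 12).ravel(), x)

    def test_indivisible_length_lists_valid_patch_lengths(self):
        with pytest.raises(ValueError, match=r"1.*2.*5.*10"):
            patchify(np.arange(10), 3)


class TestPositionalEncoding:
    def test_position_zero(self):
        pe = positional_encoding(0, 8)
        assert np.allclose(pe[0::2], 0.0)
        assert np.allclose(pe[1::2], 1.0)

    def test_closed_form_values(self):
        pe = positional_encoding(1, 8)
        assert pe[0] == pytest.approx(np.sin(1.0))
        assert pe[0] == pytest.approx(0.841471, abs=1e-6)
        assert pe[2] == pytest.approx(np.sin(1.0 / 10000 ** (2 / 8)))
        assert pe[3] == pytest.approx(np.cos(1.0 / 10000 ** (2 / 8)))

    def test_bounded(self):
        pe = positional_encoding(np.arange(100), 16)
        assert (np.abs(pe) <= 1.0).all()

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(1, 7)


class TestEmbedding:
    def test_environmental_token_count(self, tiny_config):
        model = PatchCrossFormer(tiny_config)
        tokens = model.embed_environmental(np.ones(8))
        assert tokens.shape == (tiny_config.k + 1, tiny_config.d) == (3, 8)

    def test_zero_input_zero_weights_leaves_positional_encoding(self, tiny_config):
        model = PatchCrossFormer(tiny_config)
        for name in ("embed.patch.W", "embed.patch.b", "embed.global.W", "embed.global.b"):
            model.params[name].data[:] = 0.0
        tokens = model.embed_environmental(np.zeros(8))
        expected = positional_encoding(np.arange(1, 4), 8)
        assert np.allclose(tokens, expected)

    def test_projections_shared_across_channels(self, tiny_config):
        model = PatchCrossFormer(tiny_config)
        x = np.random.default_rng(1).normal(size=8)
        a = model.embed_environmental(x)
        b = model.embed_environmental(x)
        assert np.array_equal(a, b)

    def test_auxiliary_token_count_and_channel_maps(self, tiny_config):
        model = PatchCrossFormer(tiny_config)
        S = np.random.default_rng(2).normal(size=(3, 8))
        tokens = model.embed_auxiliary(S)
        assert tokens.shape == (3, 8)
        # per-channel projections: changing one channel changes only its token
        S2 = S.copy()
        S2[1] += 1.0
        tokens2 = model.embed_auxiliary(S2)
        assert np.array_equal(tokens[0], tokens2[0])
        assert np.array_equal(tokens[2], tokens2[2])
        assert not np.array_equal(tokens[1], tokens2[1])

    def test_auxiliary_channel_count_mismatch(self, tiny_config):
        model = PatchCrossFormer(tiny_config)
        with pytest.raises(ValueError, match="auxiliary"):
            model.embed_auxiliary(np.zeros((4, 8)))

    def test_nonfinite_input_rejected(self, tiny_config):
        model = PatchCrossFormer(tiny_config)
        env = np.zeros((1, 8, 3))
        env[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            model.forward(env, np.zeros((1, 8, 3)))


class TestAggregateStep:
    def test_equal_scores_give_uniform_weights(self):
        tokens = np.eye(4)[:3] * 0.0  # three identical tokens
        h = np.zeros(4)
        w_e = np.random.default_rng(0).normal(size=8)
        p_t, alpha = aggregate_step(tokens, h, w_e)
        assert np.allclose(alpha, 1.0 / 3.0)

    def test_single_token_passthrough(self):
        tokens = np.random.default_rng(1).normal(size=(1, 4))
        p_t, alpha = aggregate_step(tokens, np.zeros(4), np.zeros(8))
        assert np.allclose(alpha, [1.0])
        assert np.allclose(p_t, tokens[0])

    def test_weights_sum_to_one_and_shift_invariant(self):
        rng = np.random.default_rng(2)
        tokens = rng.normal(size=(5, 6))
        h = rng.normal(size=6)
        w_e = rng.normal(size=12)
        _, alpha = aggregate_step(tokens, h, w_e)
        assert alpha.sum() == pytest.approx(1.0)
        assert (alpha >= 0).all()
        # softmax shift-invariance on the raw scores
        e = np.tanh(np.concatenate([np.tile(h, (5, 1)), tokens], axis=1) @ w_e)
        for shift in (0.0, 3.7, -1.2):
            s = np.exp(e + shift - (e + shift).max())
            assert np.allclose(s / s.sum(), alpha)


def _gru_params(rng, d_h, d_in, zero=False):
    shape = (d_h + d_in, d_h)
    mk = (lambda s: np.zeros(s)) if zero else (lambda s: rng.normal(size=s) * 0.3)
    return {
        "Wz": mk(shape), "Wr": mk(shape), "Wh": mk(shape),
        "bz": np.zeros(d_h) if zero else rng.normal(size=d_h) * 0.1,
        "br": np.zeros(d_h) if zero else rng.normal(size=d_h) * 0.1,
        "bh": np.zeros(d_h) if zero else rng.normal(size=d_h) * 0.1,
    }


class TestGruCell:
    def test_hand_evaluated_oracle(self):
        rng = np.random.default_rng(3)
        for d in (2, 4, 8):
            params = _gru_params(rng, d, d)
            x, h = rng.normal(size=d), rng.normal(size=d)
            sig = lambda v: 1.0 / (1.0 + np.exp(-v))
            cat = np.concatenate([h, x])
            z = sig(cat @ params["Wz"] + params["bz"])
            r = sig(cat @ params["Wr"] + params["br"])
            h_cand = np.tanh(np.concatenate([r * h, x]) @ params["Wh"] + params["bh"])
            expected = (1 - z) * h + z * h_cand
            assert np.allclose(gru_cell(x, h, params), expected, atol=1e-6)

    def test_all_zero_weights_halve_hidden_state(self):
        d = 4
        params = _gru_params(np.random.default_rng(0), d, d, zero=True)
        h = np.array([1.0, -2.0, 0.5, 3.0])
        out = gru_cell(np.zeros(d), h, params)
        assert np.allclose(out, 0.5 * h)  # z = r = 0.5, candidate = 0

    def test_update_gate_limits(self):
        rng = np.random.default_rng(4)
        d = 4
        params = _gru_params(rng, d, d)
        x, h = rng.normal(size=d), rng.normal(size=d)
        p1 = dict(params, bz=np.full(d, 100.0))   # z -> 1
        sig = 1.0 / (1.0 + np.exp(-(np.concatenate([h, x]) @ p1["Wr"] + p1["br"])))
        h_cand = np.tanh(np.concatenate([sig * h, x]) @ p1["Wh"] + p1["bh"])
        assert np.allclose(gru_cell(x, h, p1), h_cand, atol=1e-8)
        p0 = dict(params, bz=np.full(d, -100.0))  # z -> 0
        assert np.allclose(gru_cell(x, h, p0), h, atol=1e-8)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_output_is_convex_combination(self, seed):
        rng = np.random.default_rng(seed)
        d = 5
        params = _gru_params(rng, d, d)
        x, h = rng.normal(size=d), rng.normal(size=d)
        out = gru_cell(x, h, params)
        cat = np.concatenate([h, x])
        r = 1.0 / (1.0 + np.exp(-(cat @ params["Wr"] + params["br"])))
        h_cand = np.tanh(np.concatenate([r * h, x]) @ params["Wh"] + params["bh"])
        lo, hi = np.minimum(h, h_cand), np.maximum(h, h_cand)
        assert (out >= lo - 1e-12).all() and (out <= hi + 1e-12).all()


class TestEncodeChannel:
    def test_matches_hand_composition(self, tiny_config):
        """The tensor-graph recurrence must equal the step-by-step loop of
        the NumPy aggregator and GRU reference forms."""
        model = PatchCrossFormer(tiny_config)
        d, T = tiny_config.d, tiny_config.n_tokens
        rng = np.random.default_rng(5)
        tokens = rng.normal(size=(T, d))
        hidden = model.encode_channel(tokens, layer=0)
        # hand loop
        p = {k.split(".")[-1]: v.data for k, v in model.params.items()
             if k.startswith("enc0.gru")}
        w_e = model.params["enc0.agg.w"].data
        h = np.zeros(d)
        expected = []
        for _ in range(T):
            p_t, _ = aggregate_step(tokens, h, w_e)
            h = gru_cell(p_t, h, p)
            expected.append(h)
        assert np.allclose(hidden, np.array(expected), atol=1e-6)

    def test_output_length_is_token_count(self, tiny_config):
        model = PatchCrossFormer(tiny_config)
        tokens = np.zeros((tiny_config.n_tokens, tiny_config.d))
        assert model.encode_channel(tokens).shape == tokens.shape

    def test_aggregator_off_consumes_tokens_in_order(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, use_aggregator=False)
        model = PatchCrossFormer(cfg)
        rng = np.random.default_rng(6)
        tokens = rng.normal(size=(cfg.n_tokens, cfg.d))
        hidden = model.encode_channel(tokens, layer=0)
        p = {k.split(".")[-1]: v.data for k, v in model.params.items()
             if k.startswith("enc0.gru")}
        h = np.zeros(cfg.d)
        for t in range(cfg.n_tokens):
            h = gru_cell(tokens[t], h, p)
            assert np.allclose(hidden[t], h, atol=1e-10)


class TestCrossAttention:
    def _params(self, rng, d):
        return {
            "Wq": rng.normal(size=(d, d)), "Wk": rng.normal(size=(d, d)),
            "Wv": rng.normal(size=(d, d)), "Wo": rng.normal(size=(d, d)),
            "ln_g": np.ones(d), "ln_b": np.zeros(d),
        }

    def test_single_key_returns_its_projected_value(self):
        rng = np.random.default_rng(7)
        d = 6
        params = self._params(rng, d)
        q = rng.normal(size=(4, d))
        kv = rng.normal(size=(1, d))
        _, w, pre = cross_attention(q, kv, params)
        expected = np.tile((kv @ params["Wv"]) @ params["Wo"], (4, 1))
        assert np.allclose(pre, expected)
        assert np.allclose(w, 1.0)

    def test_identical_keys_average_projected_values(self):
        rng = np.random.default_rng(8)
        d = 4
        params = self._params(rng, d)
        q = rng.normal(size=(2, d))
        kv = np.tile(rng.normal(size=(1, d)), (3, 1))
        kv_vals = rng.normal(size=(3, d))
        # same keys but distinct values: force K from kv, V from kv_vals
        params2 = dict(params)
        _, w, _ = cross_attention(q, kv, params2)
        assert np.allclose(w, 1.0 / 3.0)

    def test_weights_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        d = 8
        params = self._params(rng, d)
        _, w, _ = cross_attention(rng.normal(size=(5, d)), rng.normal(size=(3, d)),
                                  params, n_heads=2)
        assert w.shape == (2, 5, 3)
        assert np.allclose(w.sum(axis=-1), 1.0)

    def test_model_attention_matches_reference(self, tiny_config):
        model = PatchCrossFormer(tiny_config)
        d, T = tiny_config.d, tiny_config.n_tokens
        rng = np.random.default_rng(10)
        q = rng.normal(size=(T, d))
        kv = rng.normal(size=(3, d))
        from hutchcast._autodiff import Tensor
        out = model._cross_attend(Tensor(q[None]), Tensor(kv[None]), 0).data[0]
        params = {
            "Wq": model.params["enc0.attn.Wq"].data,
            "Wk": model.params["enc0.attn.Wk"].data,
            "Wv": model.params["enc0.attn.Wv"].data,
            "Wo": model.params["enc0.attn.Wo"].data,
            "ln_g": model.params["enc0.ln1.g"].data,
            "ln_b": model.params["enc0.ln1.b"].data,
        }
        expected, _, _ = cross_attention(q, kv, params)
        assert np.allclose(out, expected, atol=1e-8)

    def test_flag_off_layernorms_queries_untouched_by_auxiliaries(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, use_cross_attention=False)
        model = PatchCrossFormer(cfg)
        rng = np.random.default_rng(11)
        env = rng.normal(size=(2, cfg.N, 3))
        aux1 = rng.normal(size=(2, cfg.N, 3))
        aux2 = rng.normal(size=(2, cfg.N, 3))
        assert np.array_equal(model.forward(env, aux1), model.forward(env, aux2))


class TestForward:
    def test_output_shape(self, smoke_config):
        model = PatchCrossFormer(smoke_config)
        rng = np.random.default_rng(0)
        out = model.forward(rng.normal(size=(2, 48, 3)), rng.normal(size=(2, 48, 3)))
        assert out.shape == (2, 12, 3)

    def test_patch_flag_controls_token_count(self, smoke_config):
        assert smoke_config.n_tokens == 48 // 12 + 1
        ablated = dataclasses.replace(smoke_config, use_patch_encoding=False)
        assert ablated.n_tokens == 1

    def test_deterministic(self, tiny_config):
        model = PatchCrossFormer(tiny_config)
        rng = np.random.default_rng(1)
        env, aux = rng.normal(size=(3, 8, 3)), rng.normal(size=(3, 8, 3))
        assert np.array_equal(model.forward(env, aux), model.forward(env, aux))

    def test_batch_permutation_equivariance(self, tiny_config):
        model = PatchCrossFormer(tiny_config)
        rng = np.random.default_rng(2)
        env, aux = rng.normal(size=(4, 8, 3)), rng.normal(size=(4, 8, 3))
        out = model.forward(env, aux)
        perm = [2, 0, 3, 1]
        out_p = model.forward(env[perm], aux[perm])
        assert np.allclose(out[perm], out_p, atol=1e-12)

    def test_shape_mismatch_names_expected_shape(self, tiny_config):
        model = PatchCrossFormer(tiny_config)
        with pytest.raises(ValueError, match=r"\(B, 8, 3\)"):
            model.forward(np.zeros((1, 9, 3)), np.zeros((1, 8, 3)))

    @pytest.mark.parametrize(
        "flag", ["use_patch_encoding", "use_aggregator", "use_cross_attention"]
    )
    def test_each_ablation_strictly_reduces_parameters(self, smoke_config, flag):
        full = PatchCrossFormer(smoke_config).num_params()
        ablated = PatchCrossFormer(
            dataclasses.replace(smoke_config, **{flag: False})
        ).num_params()
        assert ablated < full

    def test_config_validation(self):
        with pytest.raises(ValueError, match="valid lengths"):
            ModelConfig(N=10, L=3)
        with pytest.raises(ValueError, match="even"):
            ModelConfig(d=7)
        with pytest.raises(ValueError):
            ModelConfig(H=0)

    def test_short_input_falls_back_to_single_patch(self):
        cfg = ModelConfig(N=6, H=3, L=12, d=8, n_layers=1, ffn_hidden=16)
        assert cfg.effective_L == 6 and cfg.k == 1


class TestBaselines:
    def test_parameter_count_ordering(self, tiny_config):
        counts = {
            kind: build_baseline(kind, tiny_config, hidden=16).num_params()
            for kind in ("rnn", "gru", "lstm")
        }
        assert counts["rnn"] < counts["gru"] < counts["lstm"]

    def test_forward_shape(self, tiny_config):
        model = build_baseline("gru", tiny_config, hidden=8, n_layers=2)
        rng = np.random.default_rng(3)
        out = model.forward(rng.normal(size=(2, 8, 3)), rng.normal(size=(2, 8, 3)))
        assert out.shape == (2, 3, 3)

    def test_unknown_kind_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="unknown baseline"):
            build_baseline("transformer", tiny_config)

    def test_gru_baseline_cell_matches_gru_cell_oracle(self, tiny_config):
        """Weight-transplant equivalence: one step of the baseline's first
        GRU layer equals the reference cell with the same weights."""
        from hutchcast._autodiff import Tensor
        model = build_baseline("gru", tiny_config, hidden=4, n_layers=1)
        rng = np.random.default_rng(4)
        x, h = rng.normal(size=6), rng.normal(size=4)
        out, _ = model._step(Tensor(x[None]), Tensor(h[None]), None, 0)
        params = {
            "Wz": model.params["l0.Wz"].data, "bz": model.params["l0.bz"].data,
            "Wr": model.params["l0.Wr"].data, "br": model.params["l0.br"].data,
            "Wh": model.params["l0.Wh"].data, "bh": model.params["l0.bh"].data,
        }
        assert np.allclose(out.data[0], gru_cell(x, h, params), atol=1e-10)
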