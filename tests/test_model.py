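"""Architecture oracles: SE gating, CoT block equations, GRU recurrence,
and the multi-task forward contract."""

import numpy as np
import pytest

from ecgmtl.autodiff import Tensor, bce_with_logits
from ecgmtl.model import CoTBlock, ModelConfig, MultiTaskECGNet, SEBlock
from ecgmtl.nn import GRU, Adam, BiGRU


def np_conv1d(x, w, b, padding):
    """Straight-line cross-correlation oracle (no stride)."""
    n, c_in, t = x.shape
    c_out, _, k = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
    out = np.zeros((n, c_out, t))
    for i in range(t):
        window = xp[:, :, i:i + k]
        out[:, :, i] = np.tensordot(window, w, axes=([1, 2], [1, 2]))
    return out + b[None, :, None]


def sigmoid(z):
    return 1 / (1 + np.exp(-z))


class TestSEBlock:
    @pytest.fixture
    def block(self, rng):
        cfg = ModelConfig(in_leads=2, block_channels=(2,), block_strides=(1,),
                          n_main_classes=2, n_aux_classes=2, se_reduction=1,
                          dropout=0.0, gru_hidden=2)
        return SEBlock(2, 2, cfg, stride=1, rng=rng)

    def test_squeeze_of_constant_channels(self, block):
        x = Tensor(np.stack([np.full((2, 10), 3.0)]))
        assert np.allclose(x.mean(axis=2).data, 3.0)

    def test_gate_oracle_with_hand_set_weights(self, block, rng):
        block.fc1.weight.data[...] = rng.normal(size=(2, 2))
        block.fc1.bias.data[...] = [0.1, -0.2]
        block.fc2.weight.data[...] = rng.normal(size=(2, 2))
        block.fc2.bias.data[...] = [0.3, 0.0]
        x = rng.normal(size=(3, 2, 8))
        gate = block.se_gate(Tensor(x)).data
        squeezed = x.mean(axis=2)
        hidden = np.maximum(squeezed @ block.fc1.weight.data + block.fc1.bias.data, 0)
        expected = sigmoid(hidden @ block.fc2.weight.data + block.fc2.bias.data)
        assert np.abs(gate - expected).max() < 1e-12

    def test_gates_forced_open_leave_features_unscaled(self, block, rng):
        block.fc2.weight.data[...] = 0.0
        block.fc2.bias.data[...] = 100.0  # logistic saturates at 1
        x = rng.normal(size=(2, 2, 6))
        gate = block.se_gate(Tensor(x)).data
        assert np.allclose(gate, 1.0)
        assert np.allclose(x * gate[:, :, None], x)

    def test_channel_mismatch_raises_before_compute(self, block, rng):
        with pytest.raises(ValueError, match="channel mismatch"):
            block(Tensor(rng.normal(size=(1, 5, 8))))

    def test_output_finite(self, block, rng):
        block.eval()
        out = block(Tensor(rng.normal(size=(2, 2, 12))))
        assert np.isfinite(out.data).all()


class TestCoTBlock:
    def test_oracle_equivalence_on_tiny_tensors(self, rng):
        """Block output matches a straight-line evaluation of
        K1 = conv(K); A = W_theta(relu(W_sigma([K1, Q]))); K2 = V * A;
        D = proj([K1, K2]) on random <=3-channel, <=8-step inputs."""
        for channels, t_len in [(1, 4), (2, 6), (3, 8)]:
            block = CoTBlock(channels, 3, rng)
            e = rng.normal(size=(2, channels, t_len))
            out, state = block(Tensor(e), return_state=True)

            k1 = np_conv1d(e, block.key_conv.weight.data,
                           block.key_conv.bias.data, padding=1)
            v = np_conv1d(e, block.value_embed.weight.data,
                          block.value_embed.bias.data, padding=0)
            cat = np.concatenate([k1, e], axis=1)
            a = np_conv1d(np.maximum(np_conv1d(cat, block.attn1.weight.data,
                                               block.attn1.bias.data, 0), 0),
                          block.attn2.weight.data, block.attn2.bias.data, 0)
            k2 = v * a
            d = np_conv1d(np.concatenate([k1, k2], axis=1),
                          block.proj.weight.data, block.proj.bias.data, 0)
            rel = np.abs(out.data - d).max() / max(np.abs(d).max(), 1e-12)
            assert rel < 1e-6
            assert np.allclose(state.Q, e) and np.allclose(state.K, e)

    def test_zero_value_embedding_kills_dynamic_context(self, rng):
        block = CoTBlock(2, 3, rng)
        block.value_embed.weight.data[...] = 0.0
        block.value_embed.bias.data[...] = 0.0
        _, state = block(Tensor(rng.normal(size=(1, 2, 5))), return_state=True)
        assert np.all(state.K2 == 0.0)

    def test_zero_attention_map_kills_dynamic_context(self, rng):
        block = CoTBlock(2, 3, rng)
        block.attn2.weight.data[...] = 0.0
        block.attn2.bias.data[...] = 0.0
        _, state = block(Tensor(rng.normal(size=(1, 2, 5))), return_state=True)
        assert np.all(state.A == 0.0) and np.all(state.K2 == 0.0)

    def test_preserves_time_length_and_channels(self, rng):
        block = CoTBlock(3, 5, rng)
        out = block(Tensor(rng.normal(size=(2, 3, 11))))
        assert out.shape == (2, 3, 11)

    def test_rejects_nonfinite_input(self, rng):
        block = CoTBlock(1, 3, rng)
        bad = np.full((1, 1, 4), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            block(Tensor(bad))


class TestGRU:
    def test_hand_unrolled_three_step_recurrence(self, rng):
        gru = GRU(1, 2, rng)
        x = rng.normal(size=(1, 3, 1))
        out = gru(Tensor(x)).data[0]

        h = np.zeros(2)
        wx, wh = gru.wx.data, gru.wh.data
        bx, bh = gru.bx.data, gru.bh.data
        for t in range(3):
            a = x[0, t] @ wx + bx
            b = h @ wh + bh
            r = sigmoid(a[:2] + b[:2])
            z = sigmoid(a[2:4] + b[2:4])
            n = np.tanh(a[4:] + r * b[4:])
            h = (1 - z) * n + z * h
        assert np.abs(out - h).max() < 1e-12

    def test_reversal_symmetry(self, rng):
        gru = GRU(2, 3, rng)
        x = rng.normal(size=(2, 5, 2))
        fwd = gru(Tensor(x)).data
        bwd_on_reversed = gru(Tensor(x[:, ::-1, :].copy()), reverse=True).data
        assert np.allclose(fwd, bwd_on_reversed)

    def test_length_one_directions_agree(self, rng):
        gru = GRU(2, 3, rng)
        x = rng.normal(size=(1, 1, 2))
        assert np.allclose(gru(Tensor(x)).data,
                           gru(Tensor(x), reverse=True).data)

    def test_rejects_empty_sequence(self, rng):
        with pytest.raises(ValueError):
            GRU(2, 3, rng)(Tensor(np.zeros((1, 0, 2))))

    def test_bigru_output_dimension(self, rng):
        bigru = BiGRU(4, 5, rng)
        out = bigru(Tensor(rng.normal(size=(3, 6, 4))))
        assert out.shape == (3, 10)


def small_cfg(**kw):
    base = dict(in_leads=3, n_main_classes=9, n_aux_classes=5,
                block_channels=(4, 8), block_strides=(2, 2), se_reduction=2,
                gru_hidden=4, dropout=0.2)
    base.update(kw)
    return ModelConfig(**base)


class TestMultiTaskForward:
    def test_head_sizes_match_task_label_spaces(self, rng):
        model = MultiTaskECGNet(small_cfg(), seed=0).eval()
        main, aux = model.forward(rng.normal(size=(2, 3, 32)))
        assert main.shape == (2, 9) and aux.shape == (2, 5)
        assert np.isfinite(main.data).all() and np.isfinite(aux.data).all()

    def test_ablation_toggles_reduce_to_pooled_trunk(self, rng):
        model = MultiTaskECGNet(small_cfg(use_cot=False, use_bigru=False),
                                seed=0).eval()
        assert model.cot is None and model.bigru is None
        main, aux = model.forward(rng.normal(size=(2, 3, 32)))
        assert main.shape == (2, 9) and aux.shape == (2, 5)

    def test_identical_records_get_identical_rows_in_eval(self, rng):
        model = MultiTaskECGNet(small_cfg(), seed=0).eval()
        one = rng.normal(size=(1, 3, 32))
        batch = np.repeat(one, 3, axis=0)
        main, _ = model.forward(batch)
        assert np.allclose(main.data[0], main.data[1])
        assert np.allclose(main.data[0], main.data[2])

    def test_eval_forward_is_pure_function(self, rng):
        model = MultiTaskECGNet(small_cfg(), seed=0).eval()
        x = rng.normal(size=(2, 3, 32))
        a, _ = model.forward(x)
        b, _ = model.forward(x)
        assert np.array_equal(a.data, b.data)

    def test_lead_mismatch_raises(self, rng):
        model = MultiTaskECGNet(small_cfg(), seed=0)
        with pytest.raises(ValueError, match="lead mismatch"):
            model.forward(rng.normal(size=(2, 5, 32)))

    def test_aux_only_loss_updates_trunk_but_not_main_head(self, rng):
        """Hard parameter sharing: the auxiliary gradient reaches the shared
        trunk while the main head stays untouched."""
        model = MultiTaskECGNet(small_cfg(dropout=0.0), seed=0)
        x = rng.normal(size=(4, 3, 32))
        y_aux = (rng.random((4, 5)) < 0.4).astype(float)
        main_before = model.main_head.weight.data.copy()
        trunk_param = model.blocks[0].conv1.weight
        trunk_before = trunk_param.data.copy()
        opt = Adam(model.parameters(), lr=1e-2)
        _, aux_scores = model.forward(x)
        loss = bce_with_logits(aux_scores, y_aux)
        opt.zero_grad()
        loss.backward()
        opt.step()
        assert model.main_head.weight.grad is None
        assert np.array_equal(model.main_head.weight.data, main_before)
        assert not np.array_equal(trunk_param.data, trunk_before)

    def test_per_task_branch_variant_runs(self, rng):
        model = MultiTaskECGNet(small_cfg(per_task_branch=True), seed=0).eval()
        main, aux = model.forward(rng.normal(size=(2, 3, 32)))
        assert main.shape == (2, 9) and aux.shape == (2, 5)

    def test_trunk_blocks_preserve_time_axis_up_to_stride(self, rng):
        model = MultiTaskECGNet(small_cfg(), seed=0).eval()
        feat = model.trunk(Tensor(rng.normal(size=(1, 3, 32))))
        assert feat.shape[2] == 32 // (2 * 2)


def test_checkpoint_roundtrip(tmp_path, rng):
    from ecgmtl.config import load_checkpoint, save_checkpoint
    model = MultiTaskECGNet(small_cfg(), seed=3).eval()
    x = rng.normal(size=(2, 3, 32))
    before, _ = model.forward(x)
    save_checkpoint(model, tmp_path / "ckpt.npz", seed=3)
    back = load_checkpoint(tmp_path / "ckpt.npz")
    after, _ = back.forward(x)
    assert np.allclose(before.data, after.data)
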