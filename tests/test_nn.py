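"""Autodiff core, encoder shape chain, LSTM equations, classifier head."""

import numpy as np
import pytest

from preictal import (ClassifierConfig, EncoderConfig, HybridModel,
                      LSTMParams, LSTMState, SpectrogramEncoder, classify,
                      encoder_forward, hybrid_forward, lstm_cell,
                      lstm_forward)
from preictal.model import ClassifierHead
from preictal.nn.autograd import Tensor, conv2d, dropout, no_grad
from preictal.nn.layers import SGD, BatchNorm2d


def conv_oracle(x, w, stride, padding):
    """Quadruple-loop 2-D cross-correlation."""
    B, C, H, W = x.shape
    O, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (xp.shape[2] - kh) // stride + 1
    Wo = (xp.shape[3] - kw) // stride + 1
    out = np.zeros((B, O, Ho, Wo))
    for b in range(B):
        for o in range(O):
            for i in range(Ho):
                for j in range(Wo):
                    patch = xp[b, :, i * stride:i * stride + kh,
                               j * stride:j * stride + kw]
                    out[b, o, i, j] = (patch * w[o]).sum()
    return out


class TestAutodiff:
    @pytest.mark.parametrize("stride", [1, 2])
    def test_conv2d_matches_loop_oracle(self, rng, stride):
        x = rng.normal(size=(2, 3, 7, 9))
        w = rng.normal(size=(4, 3, 3, 3))
        got = conv2d(Tensor(x), Tensor(w), stride=stride, padding=1)
        np.testing.assert_allclose(got.data,
                                   conv_oracle(x, w, stride, 1), atol=1e-12)

    def test_conv_and_batchnorm_gradients_match_finite_differences(self):
        """Central finite differences on a conv -> BN -> ReLU -> sum
        graph agree with the backward pass to 1e-4."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 2, 6, 7))
        w0 = rng.normal(size=(4, 2, 3, 3)) * 0.5

        def network(wdata, xdata, want_grads=False):
            wt = Tensor(wdata.copy(), requires_grad=want_grads)
            xt = Tensor(xdata.copy(), requires_grad=want_grads)
            h = conv2d(xt, wt, stride=2, padding=1)
            mu = h.mean(axis=(0, 2, 3), keepdims=True)
            hc = h - mu
            var = (hc * hc).mean(axis=(0, 2, 3), keepdims=True)
            out = (hc / (var + 1e-5).sqrt()).relu()
            loss = (out * out).sum()
            if want_grads:
                loss.backward()
                return float(loss.data), wt.grad, xt.grad
            return float(loss.data)

        _, gw, gx = network(w0, x, want_grads=True)
        eps = 1e-6
        for arr, grad, pick in ((w0, gw, (2, 1, 0, 2)), (x, gx, (1, 1, 3, 4))):
            plus, minus = arr.copy(), arr.copy()
            plus[pick] += eps
            minus[pick] -= eps
            if arr is w0:
                fd = (network(plus, x) - network(minus, x)) / (2 * eps)
            else:
                fd = (network(w0, plus) - network(w0, minus)) / (2 * eps)
            assert grad[pick] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_batchnorm_eval_uses_running_statistics(self, rng):
        bn = BatchNorm2d(3, momentum=1.0)
        x = rng.normal(size=(8, 3, 4, 5)).astype(np.float32)
        bn.forward(Tensor(x))  # momentum 1: running stats = batch stats
        bn.eval()
        out = bn.forward(Tensor(x)).data
        assert abs(out.mean()) < 1e-2 and abs(out.std() - 1) < 1e-2

    def test_sgd_zero_lr_is_identity(self, rng):
        p = Tensor(rng.normal(size=(3, 3)), requires_grad=True)
        before = p.data.copy()
        opt = SGD([p], lr=0.0)
        (p * p).sum().backward()
        opt.step()
        np.testing.assert_array_equal(p.data, before)

    def test_dropout_retention_follows_bernoulli_law(self):
        rng = np.random.default_rng(0)
        out = dropout(Tensor(np.ones(10000)), 0.5, rng, training=True)
        kept = (out.data != 0).mean()
        assert kept == pytest.approx(0.5, abs=0.02)
        np.testing.assert_array_equal(
            dropout(Tensor(np.ones(100)), 0.5, rng, training=False).data,
            np.ones(100))


class TestEncoder:
    def test_printed_shape_chain_and_embedding(self, rng):
        enc = SpectrogramEncoder(EncoderConfig(in_channels=18))
        maps, emb = encoder_forward(
            rng.normal(size=(18, 21, 60)).astype(np.float32), enc)
        assert [m.shape for m in maps] == [
            (64, 21, 60), (64, 21, 60), (128, 11, 30), (256, 6, 15),
            (512, 3, 8)]
        assert emb.shape == (512,)

    def test_spatial_chain_independent_of_input_channels(self, rng):
        enc = SpectrogramEncoder(EncoderConfig(in_channels=21).scaled(8))
        maps, emb = encoder_forward(
            rng.normal(size=(21, 21, 60)).astype(np.float32), enc)
        assert [m.shape[1:] for m in maps] == [
            (21, 60), (21, 60), (11, 30), (6, 15), (3, 8)]
        assert emb.shape == (enc.cfg.embedding_dim,)

    def test_config_requires_five_blocks(self):
        with pytest.raises(ValueError):
            EncoderConfig(block_channels=(64, 128, 256, 512),
                          strides=(1, 2, 2, 2))

    def test_all_zero_input_zero_embedding(self):
        enc = SpectrogramEncoder(EncoderConfig(in_channels=2).scaled(16))
        _, emb = encoder_forward(np.zeros((2, 21, 60), np.float32), enc)
        np.testing.assert_allclose(emb, 0.0, atol=1e-7)


def oracle_cell(p, x, h, C):
    """Literal transcription of the six gate equations."""
    sig = lambda v: 1 / (1 + np.exp(-v))
    hx = np.concatenate([h, x])
    f = sig(p.W_f @ hx + p.b_f)
    i = sig(p.W_i @ hx + p.b_i)
    c_tilde = np.tanh(p.W_c @ hx + p.b_c)
    C_new = f * C + i * c_tilde
    o = sig(p.W_o @ hx + p.b_o)
    return o * np.tanh(C_new), C_new


class TestLSTM:
    def test_cell_matches_equation_oracle_1000_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = LSTMParams.init(5, 4, rng)
            x = rng.normal(size=5)
            state = LSTMState(h=rng.normal(size=4), C=rng.normal(size=4))
            got = lstm_cell(p, x, state)
            h_ref, c_ref = oracle_cell(p, x, state.h, state.C)
            np.testing.assert_allclose(got.h, h_ref, atol=1e-7)
            np.testing.assert_allclose(got.C, c_ref, atol=1e-7)

    def test_zero_weights_zero_state(self):
        z = np.zeros((4, 9))
        p = LSTMParams(W_f=z, W_i=z, W_c=z, W_o=z, b_f=np.zeros(4),
                       b_i=np.zeros(4), b_c=np.zeros(4), b_o=np.zeros(4))
        got = lstm_cell(p, np.zeros(5), LSTMState.zeros(4))
        np.testing.assert_array_equal(got.h, 0.0)
        np.testing.assert_array_equal(got.C, 0.0)

    def test_saturated_gates_preserve_memory(self, rng):
        """Forget gate open (+50 bias), input gate shut (-50): the cell
        state passes through unchanged."""
        p = LSTMParams.init(6, 4, rng)
        p.b_f[:] = 50.0
        p.b_i[:] = -50.0
        C0 = rng.normal(size=4)
        got = lstm_cell(p, rng.normal(size=6),
                        LSTMState(h=rng.normal(size=4), C=C0))
        np.testing.assert_allclose(got.C, C0, atol=1e-9)

    def test_hidden_state_tanh_bounded(self, rng):
        p = LSTMParams.init(8, 8, rng)
        h = lstm_forward(p, rng.normal(size=(20, 8)) * 5)
        assert np.all(np.abs(h) <= 1.0)

    def test_forward_is_iterated_cell(self, rng):
        p = LSTMParams.init(5, 3, rng)
        xs = rng.normal(size=(5, 5))
        state = LSTMState.zeros(3)
        for x in xs:
            state = lstm_cell(p, x, state)
        np.testing.assert_allclose(lstm_forward(p, xs), state.h, atol=1e-12)
        np.testing.assert_allclose(
            lstm_forward(p, xs[:1]), lstm_cell(p, xs[0],
                                               LSTMState.zeros(3)).h)

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            lstm_forward(LSTMParams.init(5, 3, rng), [])


class TestClassifier:
    def test_zero_hidden_gives_zero_logits(self, rng):
        head = ClassifierHead(16, ClassifierConfig(), rng)
        np.testing.assert_array_equal(classify(np.zeros(16), head), 0.0)

    def test_eval_mode_deterministic(self, rng):
        head = ClassifierHead(16, ClassifierConfig(dropout_p=0.5), rng)
        h = rng.normal(size=16)
        a = classify(h, head, train_mode=False)
        b = classify(h, head, train_mode=False)
        np.testing.assert_array_equal(a, b)


class TestHybrid:
    def test_sequence_forward_equals_stage_composition(self, rng):
        """hybrid_forward(S=3) equals running the three stage surfaces
        (encoder -> LSTM iteration -> head) by hand."""
        enc = SpectrogramEncoder(EncoderConfig(in_channels=2, seed=4)
                                 .scaled(16))
        model = HybridModel(enc, lstm_hidden=8, seed=4)
        windows = rng.normal(size=(3, 2, 21, 60)).astype(np.float32)
        got = hybrid_forward(windows, model)
        embs = [encoder_forward(w, enc)[1] for w in windows]
        h = lstm_forward(model.lstm.params(), embs)
        expected = classify(h, model.head)
        np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_single_window_is_base_case(self, rng):
        enc = SpectrogramEncoder(EncoderConfig(in_channels=2, seed=1)
                                 .scaled(16))
        model = HybridModel(enc, lstm_hidden=8, seed=1)
        w = rng.normal(size=(2, 21, 60)).astype(np.float32)
        np.testing.assert_allclose(hybrid_forward(w, model),
                                   hybrid_forward(w[None], model), atol=1e-6)

    def test_eval_logits_repeatable(self, rng):
        enc = SpectrogramEncoder(EncoderConfig(in_channels=2, seed=2)
                                 .scaled(16))
        model = HybridModel(enc, lstm_hidden=8, seed=2)
        seq = np.tile(rng.normal(size=(1, 2, 21, 60)), (5, 1, 1, 1)).astype(
            np.float32)
        np.testing.assert_array_equal(hybrid_forward(seq, model),
                                      hybrid_forward(seq, model))

    def test_state_dict_round_trip(self, rng):
        enc = SpectrogramEncoder(EncoderConfig(in_channels=2, seed=3)
                                 .scaled(16))
        model = HybridModel(enc, lstm_hidden=8, seed=3)
        w = rng.normal(size=(2, 21, 60)).astype(np.float32)
        before = hybrid_forward(w, model)
        state = model.state_dict()
        enc2 = SpectrogramEncoder(EncoderConfig(in_channels=2, seed=9)
                                  .scaled(16))
        clone = HybridModel(enc2, lstm_hidden=8, seed=9)
        clone.load_state_dict({k: v.copy() for k, v in state.items()})
        np.testing.assert_allclose(hybrid_forward(w, clone), before,
                                   atol=1e-7)
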