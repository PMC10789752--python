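"""The hybrid classifier: encoder -> LSTM -> linear head.

The encoder turns each spectrogram window into an embedding; the LSTM
consumes a sequence of embeddings (length 1 by default — one 10-s
window is one classification unit); the head applies ReLU, dropout
(training only) and an affine map to two logits (inter-ictal,
pre-ictal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, dropout, no_grad
from .nn.encoder import EncoderConfig, SpectrogramEncoder
from .nn.layers import DTYPE, Linear, Module
from .nn.lstm import LSTMLayer


@dataclass
class ClassifierConfig:
    dropout_p: float = 0.5
    n_classes: int = 2

    def __post_init__(self):
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")


class ClassifierHead(Module):
    """ReLU -> dropout -> affine map to class logits."""

    def __init__(self, in_dim: int, cfg: ClassifierConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.fc = Linear(in_dim, cfg.n_classes, rng)
        self._rng = np.random.default_rng(rng.integers(2 ** 31))

    def forward(self, h: Tensor) -> Tensor:
        out = h.relu()
        out = dropout(out, self.cfg.dropout_p, self._rng, self.training)
        return self.fc.forward(out)


def classify(h: np.ndarray, head: ClassifierHead,
             train_mode: bool = False) -> np.ndarray:
    """Numpy surface over the head; eval mode is deterministic."""
    arr = np.atleast_2d(np.asarray(h, dtype=DTYPE))
    was = head.training
    head.train(train_mode)
    if train_mode:
        logits = head.forward(Tensor(arr)).data
    else:
        with no_grad():
            logits = head.forward(Tensor(arr)).data
    head.train(was)
    return logits[0] if np.asarray(h).ndim == 1 else logits


class HybridModel(Module):
    """Encoder + single-layer LSTM + classifier head."""

    def __init__(self, encoder: SpectrogramEncoder, lstm_hidden: int = 128,
                 head_cfg: ClassifierConfig = None, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.encoder = encoder
        self.lstm = LSTMLayer(encoder.cfg.embedding_dim, lstm_hidden, rng)
        self.head = ClassifierHead(lstm_hidden, head_cfg or ClassifierConfig(),
                                   rng)

    def forward(self, x, seq_len: int = 1) -> Tensor:
        """Batched forward: ``x`` is (B*seq_len, C, T, F) with the
        sequence axis fastest (row b*S + t); returns (B, n_classes)
        logits.  Gradients flow to the parameters only, so the input may
        be a plain array."""
        arr = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=DTYPE)
        if seq_len == 1:
            steps = [self.encoder.forward(Tensor(arr))]
        else:
            steps = [self.encoder.forward(Tensor(arr[t::seq_len]))
                     for t in range(seq_len)]
        h = self.lstm.forward(steps)
        return self.head.forward(h)

    def predict(self, specs: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Deterministic class predictions for a (N, C, T, F) array."""
        was = self.training
        self.eval()
        preds = []
        with no_grad():
            for i in range(0, specs.shape[0], batch_size):
                chunk = np.asarray(specs[i:i + batch_size], dtype=DTYPE)
                logits = self.forward(Tensor(chunk))
                preds.append(np.argmax(logits.data, axis=1))
        self.train(was)
        return np.concatenate(preds) if preds else np.empty(0, dtype=int)


def hybrid_forward(windows: np.ndarray, model: HybridModel) -> np.ndarray:
    """Classify one sequence of spectrogram windows (S, C, T, F): the
    per-window embeddings feed the LSTM in order and the final hidden
    state is classified.  Returns the two logits."""
    arr = np.asarray(windows, dtype=DTYPE)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.shape[0] < 1:
        raise ValueError("sequence must be nonempty")
    was = model.training
    model.eval()
    with no_grad():
        logits = model.forward(Tensor(arr), seq_len=arr.shape[0])
    model.train(was)
    return logits.data[0]
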