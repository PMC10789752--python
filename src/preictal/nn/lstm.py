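"""The LSTM used downstream of the encoder.

Single-layer LSTM with the classic gate arithmetic on the concatenated
``[h_{t-1}, x_t]`` vector:

    f_t = sigmoid(W_f . [h, x] + b_f)        (forget gate)
    i_t = sigmoid(W_i . [h, x] + b_i)        (input gate)
    c~_t = tanh(W_c . [h, x] + b_c)          (candidate cell)
    C_t = f_t * C_{t-1} + i_t * c~_t         (cell update)
    o_t = sigmoid(W_o . [h, x] + b_o)        (output gate)
    h_t = o_t * tanh(C_t)

``lstm_cell``/``lstm_forward`` are the plain-numpy reference used by the
oracle tests; :class:`LSTMLayer` is the autodiff twin sharing the same
weight layout, used during fine-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat
from .layers import DTYPE, Module


@dataclass
class LSTMParams:
    """Gate weights over the concatenated [h, x]; shapes
    (hidden, hidden + input) and (hidden,)."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self):
        h = self.b_f.shape[0]
        for name in ("W_f", "W_i", "W_c", "W_o"):
            W = getattr(self, name)
            if W.shape[0] != h:
                raise ValueError(f"{name} rows must equal hidden_dim {h}")
            if W.shape[1] <= h:
                raise ValueError(f"{name} must act on [h, x] (cols > hidden)")
        for name in ("b_i", "b_c", "b_o"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have shape ({h},)")

    @property
    def hidden_dim(self) -> int:
        return self.b_f.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_f.shape[1] - self.hidden_dim

    @classmethod
    def init(cls, input_dim: int, hidden_dim: int,
             rng: np.random.Generator) -> "LSTMParams":
        """Uniform fan-in initialisation, all biases zero."""
        bound = 1.0 / np.sqrt(hidden_dim + input_dim)
        def W():
            return rng.uniform(-bound, bound,
                               (hidden_dim, hidden_dim + input_dim))
        z = np.zeros(hidden_dim)
        return cls(W_f=W(), W_i=W(), W_c=W(), W_o=W(),
                   b_f=z.copy(), b_i=z.copy(), b_c=z.copy(), b_o=z.copy())


@dataclass
class LSTMState:
    """Hidden state h and cell state C (each length hidden_dim)."""

    h: np.ndarray
    C: np.ndarray

    @classmethod
    def zeros(cls, hidden_dim: int) -> "LSTMState":
        return cls(h=np.zeros(hidden_dim), C=np.zeros(hidden_dim))


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def lstm_cell(p: LSTMParams, x_t: np.ndarray,
              state: LSTMState) -> LSTMState:
    """One LSTM step on a single input vector."""
    hx = np.concatenate([state.h, x_t])
    f = _sigmoid(p.W_f @ hx + p.b_f)
    i = _sigmoid(p.W_i @ hx + p.b_i)
    c_tilde = np.tanh(p.W_c @ hx + p.b_c)
    C = f * state.C + i * c_tilde
    o = _sigmoid(p.W_o @ hx + p.b_o)
    return LSTMState(h=o * np.tanh(C), C=C)


def lstm_forward(p: LSTMParams, xs, init_state: LSTMState = None
                 ) -> np.ndarray:
    """Iterate the cell over a nonempty sequence; return the final h_T."""
    xs = list(xs)
    if not xs:
        raise ValueError("lstm_forward requires a nonempty sequence")
    state = init_state if init_state is not None \
        else LSTMState.zeros(p.hidden_dim)
    for x in xs:
        state = lstm_cell(p, np.asarray(x), state)
    return state.h


class LSTMLayer(Module):
    """Autodiff LSTM sharing the :class:`LSTMParams` layout.

    Processes batched sequences: input list of (B, D) tensors, returns
    the final hidden state (B, H).
    """

    def __init__(self, input_dim: int, hidden_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        p = LSTMParams.init(input_dim, hidden_dim, rng)
        for name in ("W_f", "W_i", "W_c", "W_o"):
            setattr(self, name,
                    Tensor(getattr(p, name).astype(DTYPE), requires_grad=True))
        for name in ("b_f", "b_i", "b_c", "b_o"):
            setattr(self, name,
                    Tensor(getattr(p, name).astype(DTYPE), requires_grad=True))

    def forward(self, xs) -> Tensor:
        if len(xs) == 0:
            raise ValueError("empty sequence")
        B = xs[0].data.shape[0]
        h = Tensor(np.zeros((B, self.hidden_dim), dtype=DTYPE))
        C = Tensor(np.zeros((B, self.hidden_dim), dtype=DTYPE))
        for x in xs:
            hx = concat([h, x], axis=1)
            f = (hx @ self.W_f.T + self.b_f).sigmoid()
            i = (hx @ self.W_i.T + self.b_i).sigmoid()
            c_tilde = (hx @ self.W_c.T + self.b_c).tanh()
            C = f * C + i * c_tilde
            o = (hx @ self.W_o.T + self.b_o).sigmoid()
            h = o * C.tanh()
        return h

    def params(self) -> LSTMParams:
        """Snapshot as plain-numpy :class:`LSTMParams`."""
        return LSTMParams(
            W_f=self.W_f.data.copy(), W_i=self.W_i.data.copy(),
            W_c=self.W_c.data.copy(), W_o=self.W_o.data.copy(),
            b_f=self.b_f.data.copy(), b_i=self.b_i.data.copy(),
            b_c=self.b_c.data.copy(), b_o=self.b_o.data.copy())
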