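"""Contrastive losses for pretraining the spectrogram encoder.

Two objectives over a batch of 2N L2-normalised embeddings (two
augmented views per source window), with temperature-scaled dot-product
similarities:

* the self-supervised (InfoNCE-style) loss, where the only positive for
  an anchor is its sibling view;
* the supervised contrastive (SupCon) loss, where every same-class
  embedding in the batch is a positive and the log-likelihood terms are
  averaged over the positive set P(i).

Both losses sum over all 2N anchors; the denominator runs over
A(i) = I \\ {i}.  The functions here are plain vectorised numpy and are
the package's reference implementation; training uses an equivalent
composition of autodiff primitives (see ``preictal.train``) that is
tested against these.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ContrastiveBatch:
    """2N unit-norm embeddings with labels and the view-pairing map.

    ``pair_index[i]`` is the index of anchor i's sibling view — an
    involution without fixed points.  ``tau`` is the softmax
    temperature.
    """

    z: np.ndarray
    labels: np.ndarray
    pair_index: np.ndarray
    tau: float = 0.07

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.labels = np.asarray(self.labels)
        self.pair_index = np.asarray(self.pair_index, dtype=int)
        n = self.z.shape[0]
        if n == 0:
            raise ValueError("empty batch")
        if n % 2 != 0:
            raise ValueError("batch must hold two views per source (2N rows)")
        if self.tau <= 0:
            raise ValueError("temperature tau must be positive")
        if self.labels.shape != (n,) or self.pair_index.shape != (n,):
            raise ValueError("labels and pair_index must have 2N entries")
        idx = np.arange(n)
        if np.any(self.pair_index == idx) or np.any(
                self.pair_index[self.pair_index] != idx):
            raise ValueError("pair_index must be a fixed-point-free involution")
        norms = np.linalg.norm(self.z, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("embeddings must be unit-norm (within 1e-6)")

    @property
    def n_views(self) -> int:
        return self.z.shape[0]

    @classmethod
    def from_views(cls, z_a: np.ndarray, z_b: np.ndarray, labels,
                   tau: float = 0.07) -> "ContrastiveBatch":
        """Stack two aligned view arrays (each N x D) into a batch."""
        n = z_a.shape[0]
        z = np.concatenate([z_a, z_b], axis=0)
        z = z / np.linalg.norm(z, axis=1, keepdims=True)
        labels = np.concatenate([np.asarray(labels)] * 2)
        pair = np.concatenate([np.arange(n) + n, np.arange(n)])
        return cls(z=z, labels=labels, pair_index=pair, tau=tau)


def similarity_logits(batch: ContrastiveBatch) -> np.ndarray:
    """The 2N x 2N matrix of (z_i . z_a)/tau; the diagonal (the anchor
    itself, excluded from A(i)) is set to -inf."""
    logits = (batch.z @ batch.z.T) / batch.tau
    np.fill_diagonal(logits, -np.inf)
    return logits


def _log_prob(batch: ContrastiveBatch) -> np.ndarray:
    """log softmax over each anchor's candidate set A(i)."""
    logits = similarity_logits(batch)
    m = logits.max(axis=1, keepdims=True)
    lse = m + np.log(np.exp(logits - m).sum(axis=1, keepdims=True))
    return logits - lse


def selfsup_loss(batch: ContrastiveBatch) -> float:
    """Self-supervised contrastive loss: the positive for anchor i is
    its sibling view j(i) only.  Nonnegative; sums over all 2N anchors."""
    logp = _log_prob(batch)
    idx = np.arange(batch.n_views)
    return float(-logp[idx, batch.pair_index].sum())


def supcon_loss(batch: ContrastiveBatch) -> float:
    """Supervised contrastive loss: positives are all same-class
    embeddings in the batch, log-probabilities averaged over P(i).

    Anchors without any positive are dropped with a warning; if no
    anchor has one (all-singleton classes) the loss falls back to the
    self-supervised view pairing.
    """
    pos = (batch.labels[:, None] == batch.labels[None, :])
    np.fill_diagonal(pos, False)
    counts = pos.sum(axis=1)
    if not counts.any():
        warnings.warn("degenerate batch: all classes singletons; falling "
                      "back to view-pair positives", RuntimeWarning)
        return selfsup_loss(batch)
    if (counts == 0).any():
        warnings.warn(f"{int((counts == 0).sum())} anchors have no "
                      "positives and are dropped", RuntimeWarning)
    logp = _log_prob(batch)
    keep = counts > 0
    per_anchor = np.where(pos[keep], logp[keep], 0.0).sum(axis=1) \
        / counts[keep]
    return float(-per_anchor.sum())
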