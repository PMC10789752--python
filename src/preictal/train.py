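"""Pretraining, fine-tuning, leave-one-out evaluation and reporting.

The protocol mirrors the three-phase method: per patient, each seizure
contributes one (pre-ictal, inter-ictal) segment pair treated as a
single cross-validation unit.  For every fold, the encoder is first
pretrained with the supervised contrastive loss on augmented
spectrogram views of the training units, then the hybrid
encoder+LSTM+head classifier is fine-tuned with cross-entropy on the
original spectrograms, and the held-out unit's windows are scored.
Confusion counts are summed over folds (micro-average) before the
Table-style metrics are computed.

Reference hyperparameters: SGD, batch 512, 300 pretraining epochs at
lr 0.05, 100 fine-tuning epochs at lr 0.01.  ``TrainConfig.desk_scale``
gives the reduced profile used by the tests (batch 32, 10+10 epochs,
width-divided encoder, sparse training windows).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sstats

from .augment import AugmentConfig, make_view_batch
from .model import ClassifierConfig, HybridModel
from .nn.autograd import Tensor, l2_normalize_rows, logsumexp, no_grad
from .nn.encoder import EncoderConfig, SpectrogramEncoder
from .nn.layers import DTYPE, SGD
from .recording import Recording, SeizureAnnotation
from .segmentation import (PeriodLabels, SegmentPair, build_pairs,
                           define_periods, pair_windows)
from .spectrogram import SpectrogramConfig, windows_to_tensors

logger = logging.getLogger("preictal")


class DegenerateBatchError(RuntimeError):
    """Pretraining data contains a single class."""


class InsufficientUnitsError(ValueError):
    """Fewer than two units for leave-one-out cross-validation."""


@dataclass
class PhaseConfig:
    batch_size: int
    epochs: int
    lr: float


@dataclass
class TrainConfig:
    """Optimiser and scaling knobs for both training phases."""

    pretrain: PhaseConfig = field(
        default_factory=lambda: PhaseConfig(512, 300, 0.05))
    finetune: PhaseConfig = field(
        default_factory=lambda: PhaseConfig(512, 100, 0.01))
    momentum: float = 0.9
    tau: float = 0.07
    lstm_hidden: int = 128
    width_divisor: int = 1
    train_window_stride_s: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for phase in (self.pretrain, self.finetune):
            if phase.lr < 0:
                raise ValueError("learning rate must be nonnegative")
            if phase.epochs < 0:
                raise ValueError("epochs must be nonnegative")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "TrainConfig":
        """Reduced profile for CPU-scale runs: batch 32, 10+10 epochs,
        encoder width divided by 8, one window kept per 50 s of segment."""
        return cls(pretrain=PhaseConfig(32, 10, 0.05),
                   finetune=PhaseConfig(32, 10, 0.01),
                   lstm_hidden=32, width_divisor=8,
                   train_window_stride_s=50.0, seed=seed)


# ----------------------------------------------------------------- losses

def supcon_loss_tensor(z: Tensor, labels: np.ndarray, tau: float,
                       mean_over_anchors: bool = True) -> Tensor:
    """Supervised contrastive loss as an autodiff graph.

    ``z`` holds raw (un-normalised) embeddings; rows are L2-normalised
    inside the loss.  Matches ``preictal.contrastive.supcon_loss`` (up
    to the 1/2N factor when ``mean_over_anchors``)."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    n = z.data.shape[0]
    labels = np.asarray(labels)
    zn = l2_normalize_rows(z)
    logits = (zn @ zn.T) * (1.0 / tau)
    eye = np.eye(n, dtype=bool)
    logits = logits + Tensor(
        np.where(eye, -1e9, 0.0).astype(z.data.dtype))
    pos = (labels[:, None] == labels[None, :]) & ~eye
    counts = pos.sum(axis=1)
    if not counts.any():
        raise DegenerateBatchError("no anchor has a positive sample")
    keep = counts > 0
    W = np.zeros((n, n), dtype=z.data.dtype)
    W[keep] = pos[keep] / counts[keep, None]
    lse = logsumexp(logits, axis=1)
    loss = (lse * Tensor(keep.astype(z.data.dtype))).sum() \
        - (logits * Tensor(W)).sum()
    return loss * (1.0 / n) if mean_over_anchors else loss


def cross_entropy_tensor(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch."""
    n = logits.data.shape[0]
    onehot = np.zeros_like(logits.data)
    onehot[np.arange(n), np.asarray(y, dtype=int)] = 1.0
    lse = logsumexp(logits, axis=1)
    return (lse.sum() - (logits * Tensor(onehot)).sum()) * (1.0 / n)


# ----------------------------------------------------------------- sampling

def _balanced_batches(y: np.ndarray, batch_size: int, n_batches: int,
                      rng: np.random.Generator):
    """Class-balanced batch index sampler: half of each batch per class,
    so every anchor has at least one same-class positive besides its
    sibling view."""
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise DegenerateBatchError(
            "pretraining requires both classes in the data")
    half = max(batch_size // 2, 2)
    for _ in range(n_batches):
        a = rng.choice(idx0, half, replace=len(idx0) < half)
        b = rng.choice(idx1, half, replace=len(idx1) < half)
        yield np.concatenate([a, b])


# ----------------------------------------------------------------- training

def pretrain_encoder(specs: np.ndarray, y: np.ndarray, frame_times,
                     bin_freqs, encoder: SpectrogramEncoder,
                     cfg: TrainConfig, aug: AugmentConfig):
    """Pretext task: SGD on the supervised contrastive loss over
    two-view augmented batches.  Returns the per-epoch mean loss
    history; the encoder is trained in place."""
    rng = np.random.default_rng(cfg.seed)
    aug_rng = np.random.default_rng(aug.seed)
    opt = SGD(encoder.parameters(), cfg.pretrain.lr, cfg.momentum)
    n_batches = max(1, math.ceil(len(y) / cfg.pretrain.batch_size))
    history = []
    encoder.train()
    for epoch in range(cfg.pretrain.epochs):
        losses = []
        for sel in _balanced_batches(y, cfg.pretrain.batch_size,
                                     n_batches, rng):
            views = make_view_batch(specs[sel], frame_times, bin_freqs,
                                    aug, aug_rng)
            vlabels = np.concatenate([y[sel], y[sel]])
            emb = encoder.forward(Tensor(views.astype(DTYPE)))
            loss = supcon_loss_tensor(emb, vlabels, cfg.tau)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        logger.info("pretrain epoch %d/%d supcon_loss %.4f",
                    epoch + 1, cfg.pretrain.epochs, history[-1])
    recalibrate_batchnorm(encoder, specs)
    return history


def finetune(encoder: SpectrogramEncoder, specs: np.ndarray, y: np.ndarray,
             cfg: TrainConfig) -> HybridModel:
    """Downstream task: cross-entropy fine-tuning of the hybrid model on
    the original (un-augmented) spectrograms.  ``encoder`` may carry
    pretrained weights or a fresh initialisation (ablation arm)."""
    rng = np.random.default_rng(cfg.seed + 1)
    model = HybridModel(encoder, lstm_hidden=cfg.lstm_hidden,
                        head_cfg=ClassifierConfig(),
                        seed=int(rng.integers(2 ** 31)))
    if cfg.finetune.epochs == 0:
        return model
    opt = SGD(model.parameters(), cfg.finetune.lr, cfg.momentum)
    n = len(y)
    model.train()
    for epoch in range(cfg.finetune.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.finetune.batch_size):
            sel = order[i:i + cfg.finetune.batch_size]
            logits = model.forward(specs[sel].astype(DTYPE))
            loss = cross_entropy_tensor(logits, y[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        logger.info("finetune epoch %d/%d ce_loss %.4f",
                    epoch + 1, cfg.finetune.epochs, float(np.mean(losses)))
    recalibrate_batchnorm(model, specs)
    return model


def recalibrate_batchnorm(module, specs: np.ndarray, batch_size: int = 64):
    """Replace batch-norm running statistics with exact averages over
    the training data.

    With few optimiser steps the exponential running estimates lag the
    final weights, which skews eval-mode predictions; a calibration pass
    with cumulative averaging fixes the statistics to the trained
    network.  Standard practice for small-batch batch-norm."""
    from .nn.layers import BatchNorm2d

    bns = [m for m in module.modules() if isinstance(m, BatchNorm2d)]
    saved = [(bn.momentum,) for bn in bns]
    was = module.training
    module.train()
    with no_grad():
        for i, start in enumerate(range(0, specs.shape[0], batch_size)):
            for bn in bns:
                bn.momentum = 1.0 / (i + 1)  # cumulative moving average
            module.forward(Tensor(np.asarray(
                specs[start:start + batch_size], dtype=DTYPE)))
    for bn, (m,) in zip(bns, saved):
        bn.momentum = m
    module.train(was)


# ----------------------------------------------------------------- metrics

@dataclass
class ConfusionCounts:
    """Window-level confusion counts (positive class = pre-ictal)."""

    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(TP=int(((y_true == 1) & (y_pred == 1)).sum()),
                   TN=int(((y_true == 0) & (y_pred == 0)).sum()),
                   FP=int(((y_true == 0) & (y_pred == 1)).sum()),
                   FN=int(((y_true == 1) & (y_pred == 0)).sum()))


def compute_metrics(c: ConfusionCounts):
    """Accuracy, sensitivity, specificity, FPR.  A metric whose
    denominator is zero is returned as nan (undefined), never as 0."""
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return (ratio(c.TP + c.TN, c.total),
            ratio(c.TP, c.TP + c.FN),
            ratio(c.TN, c.TN + c.FP),
            ratio(c.FP, c.FP + c.TN))


def paired_ttest(a, b, alternative: str = "two-sided"):
    """Classical paired t-test on per-patient metric lists.

    Returns ``(t, p)``; both are nan (a degenerate-test marker) when
    the differences have zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_ttest needs two equal-length lists (n >= 2)")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        warnings.warn("zero-variance differences: t-test undefined",
                      RuntimeWarning)
        return float("nan"), float("nan")
    res = sstats.ttest_rel(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------- protocol

def loocv_folds(pairs):
    """Leave-one-unit-out folds over segment pairs: each unit is the
    test set exactly once; training and test units are disjoint."""
    pairs = list(pairs)
    if len(pairs) < 2:
        raise InsufficientUnitsError(
            "leave-one-out cross-validation needs at least 2 units")
    return [([p for j, p in enumerate(pairs) if j != i], pairs[i])
            for i in range(len(pairs))]


@dataclass
class UnitData:
    """Spectrogram tensors of one cross-validation unit."""

    pair: SegmentPair
    specs: np.ndarray
    labels: np.ndarray
    segment_ids: np.ndarray


@dataclass
class PatientResult:
    patient: str
    arm: str
    preictal_minutes: float
    fold_counts: list
    pretrain_history: list = field(default_factory=list)

    @property
    def counts(self) -> ConfusionCounts:
        total = ConfusionCounts()
        for c in self.fold_counts:
            total = total + c
        return total

    @property
    def metrics(self):
        return compute_metrics(self.counts)


def prepare_units(recording: Recording, ann: SeizureAnnotation,
                  preictal_minutes: float, spec_cfg: SpectrogramConfig,
                  stride_s: float, seed: int):
    """Label periods, draw the balanced pairs, window both segments and
    compute spectrograms for every ``stride_s``-th window."""
    labels = define_periods(ann, recording.duration_s, preictal_minutes)
    pairs = build_pairs(labels, seed)
    stride = max(1, int(round(stride_s)))
    units = []
    frame_times = bin_freqs = None
    for pair in pairs:
        ws = pair_windows(recording, pair)
        sel = np.concatenate([
            np.flatnonzero(ws.segment_ids == sid)[::stride]
            for sid in np.unique(ws.segment_ids)])
        specs = windows_to_tensors([ws.windows[i] for i in sel], spec_cfg,
                                   recording.sfreq)
        if frame_times is None:
            from .spectrogram import window_to_tensor
            probe = window_to_tensor(ws.windows[0], spec_cfg, recording.sfreq)
            frame_times, bin_freqs = probe.frame_times, probe.bin_freqs
        units.append(UnitData(pair=pair, specs=specs,
                              labels=ws.labels[sel],
                              segment_ids=ws.segment_ids[sel]))
    return labels, units, frame_times, bin_freqs


def run_patient(recording: Recording, ann: SeizureAnnotation,
                preictal_minutes: float, cfg: TrainConfig,
                aug: AugmentConfig, spec_cfg: SpectrogramConfig = None,
                patient: str = "patient", pretrain: bool = True
                ) -> PatientResult:
    """Full leave-one-out protocol for one patient.

    For each fold a fresh, fold-seeded encoder is (optionally)
    pretrained on the training units' augmented views, the hybrid model
    is fine-tuned, and the held-out unit is scored window by window.
    """
    spec_cfg = spec_cfg or SpectrogramConfig()
    _labels, units, frame_times, bin_freqs = prepare_units(
        recording, ann, preictal_minutes, spec_cfg,
        cfg.train_window_stride_s, cfg.seed)
    folds = loocv_folds(units)
    ss = np.random.SeedSequence(cfg.seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in ss.spawn(len(folds))]
    arm = "pretrained" if pretrain else "scratch"
    fold_counts, histories = [], []
    in_channels = units[0].specs.shape[1]
    for k, (train_units, test_unit) in enumerate(folds):
        train_ids = np.concatenate([u.segment_ids for u in train_units])
        if np.intersect1d(train_ids, test_unit.segment_ids).size:
            raise RuntimeError("fold leakage: test segment in training set")
        X = np.concatenate([u.specs for u in train_units])
        y = np.concatenate([u.labels for u in train_units])
        fold_cfg = replace(cfg, seed=fold_seeds[k])
        enc_cfg = EncoderConfig(in_channels=in_channels,
                                seed=fold_seeds[k]).scaled(cfg.width_divisor)
        encoder = SpectrogramEncoder(enc_cfg)
        if pretrain:
            fold_aug = AugmentConfig(aug.cutout_duration_s,
                                     aug.bandstop_width_hz,
                                     seed=fold_seeds[k] + 1)
            histories.append(pretrain_encoder(
                X, y, frame_times, bin_freqs, encoder, fold_cfg, fold_aug))
        model = finetune(encoder, X, y, fold_cfg)
        preds = model.predict(test_unit.specs)
        fold_counts.append(
            ConfusionCounts.from_predictions(test_unit.labels, preds))
        logger.info("fold %d/%d (%s): %s", k + 1, len(folds), arm,
                    fold_counts[-1])
    return PatientResult(patient=patient, arm=arm,
                         preictal_minutes=preictal_minutes,
                         fold_counts=fold_counts,
                         pretrain_history=histories)


# ----------------------------------------------------------------- report

def report(results, path_prefix=None):
    """Tabulate per-patient metrics with per-arm means and, when both
    arms are present, the pretrained-minus-scratch mean deltas.

    Returns a pandas DataFrame; with ``path_prefix`` also writes
    ``<prefix>.csv`` and ``<prefix>.json``."""
    import pandas as pd

    if not results:
        raise ValueError("report needs at least one patient result")
    rows = []
    for r in results:
        acc, sens, spec, fpr = r.metrics
        rows.append({"patient": r.patient, "arm": r.arm,
                     "preictal_minutes": r.preictal_minutes,
                     "sensitivity": sens, "specificity": spec,
                     "accuracy": acc, "fpr": fpr})
    df = pd.DataFrame(rows)
    metric_cols = ["sensitivity", "specificity", "accuracy", "fpr"]
    means = (df.groupby(["arm", "preictal_minutes"], as_index=False)
             [metric_cols].mean())
    means.insert(0, "patient", "mean")
    table = pd.concat([df, means], ignore_index=True)
    arms = sorted(df["arm"].unique())
    if len(arms) == 2:
        a1, a0 = (("pretrained", "scratch")
                  if set(arms) == {"pretrained", "scratch"}
                  else (arms[1], arms[0]))
        for pm in sorted(df["preictal_minutes"].unique()):
            m1 = means[(means.arm == a1) & (means.preictal_minutes == pm)]
            m0 = means[(means.arm == a0) & (means.preictal_minutes == pm)]
            if len(m1) == 1 and len(m0) == 1:
                row = {"patient": "delta", "arm": f"{a1}-{a0}",
                       "preictal_minutes": pm}
                for m in metric_cols:
                    row[m] = float(m1[m].iloc[0] - m0[m].iloc[0])
                table.loc[len(table)] = row
    if path_prefix is not None:
        table.to_csv(f"{path_prefix}.csv", index=False)
        table.to_json(f"{path_prefix}.json", orient="records", indent=2)
    return table
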