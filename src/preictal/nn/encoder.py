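"""Residual convolutional encoder for spectrogram windows.

A ResNet-18-style network adapted to small time-frequency images
(21 frames x 60 one-hertz bins).  Five blocks: a 3x3 stem at stride 1,
then four residual stages of two basic blocks each with stage strides
(1, 2, 2, 2).  For the default width the block outputs on a (C, 21, 60)
input are

    (64, 21, 60), (64, 21, 60), (128, 11, 30), (256, 6, 15), (512, 3, 8)

and adaptive average pooling + flatten yields a 512-dimensional
embedding.  Spatial sizes follow the stride-2 convolution arithmetic
floor((n + 2*pad - 3)/2) + 1 with pad = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, no_grad
from .layers import BatchNorm2d, Conv2d, Linear, Module


@dataclass
class EncoderConfig:
    """Width/stride layout of the five-block encoder.

    ``block_channels[0]`` is the stem width; the remaining four entries
    are the residual-stage widths.  The embedding dimension equals the
    final stage width (512 at full width).  ``width_divisor`` > 1 gives
    the reduced-width profile used for small-scale experiments.
    """

    in_channels: int = 18
    block_channels: tuple = (64, 64, 128, 256, 512)
    strides: tuple = (1, 1, 2, 2, 2)
    seed: int = 0

    def __post_init__(self):
        if len(self.block_channels) != 5 or len(self.strides) != 5:
            raise ValueError("encoder has exactly five blocks")
        if self.strides[0] != 1:
            raise ValueError("stem stride must be 1")

    @property
    def embedding_dim(self) -> int:
        return self.block_channels[-1]

    def scaled(self, width_divisor: int) -> "EncoderConfig":
        return EncoderConfig(
            in_channels=self.in_channels,
            block_channels=tuple(max(1, c // width_divisor)
                                 for c in self.block_channels),
            strides=self.strides,
            seed=self.seed,
        )


class BasicBlock(Module):
    """Two 3x3 convolutions with a shortcut connection.

    When the block changes resolution or width, the shortcut is a 1x1
    stride-s projection convolution followed by batch norm.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, 1, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, 1, rng)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, stride, 0, rng)
            self.proj_bn = BatchNorm2d(out_ch)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1.forward(self.conv1.forward(x)).relu()
        out = self.bn2.forward(self.conv2.forward(out))
        shortcut = x if self.proj is None \
            else self.proj_bn.forward(self.proj.forward(x))
        return (out + shortcut).relu()


class SpectrogramEncoder(Module):
    def __init__(self, cfg: EncoderConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.block_channels
        self.stem_conv = Conv2d(cfg.in_channels, ch[0], 3, 1, 1, rng)
        self.stem_bn = BatchNorm2d(ch[0])
        self.stages = []
        in_ch = ch[0]
        for out_ch, stride in zip(ch[1:], cfg.strides[1:]):
            self.stages.append([
                BasicBlock(in_ch, out_ch, stride, rng),
                BasicBlock(out_ch, out_ch, 1, rng),
            ])
            in_ch = out_ch

    def forward_blocks(self, x: Tensor):
        """Return the five block outputs and the pooled embedding."""
        maps = []
        out = self.stem_bn.forward(self.stem_conv.forward(x)).relu()
        maps.append(out)
        for blocks in self.stages:
            for b in blocks:
                out = b.forward(out)
            maps.append(out)
        embedding = out.mean(axis=(2, 3))  # adaptive average pool + flatten
        return maps, embedding

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_blocks(x)[1]


def encoder_forward(x: np.ndarray, encoder: SpectrogramEncoder):
    """Run one spectrogram (C x T x F) or a batch (B x C x T x F) through
    the encoder without building an autodiff tape.

    Returns ``(feature_maps, embedding)`` as numpy arrays; for a single
    spectrogram the leading batch axis is stripped.
    """
    arr = np.asarray(x, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    was_training = encoder.training
    encoder.eval()
    with no_grad():
        maps, emb = encoder.forward_blocks(Tensor(arr))
    encoder.train(was_training)
    maps = [m.data for m in maps]
    emb = emb.data
    if single:
        maps = [m[0] for m in maps]
        emb = emb[0]
    return maps, emb
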