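"""Spectrogram augmentation: band-stop masking and temporal cutout.

Both masks are applied in the spectrogram domain as zeroed stripes —
a horizontal band of frequency rows, or a vertical span of time frames —
synchronised across all channels.  Each source spectrogram yields two
views (one per mask type) for contrastive pretraining; untouched entries
are bit-identical to the source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrogram import Spectrogram


@dataclass
class AugmentConfig:
    """Mask sizes: the cutout removes ``cutout_duration_s`` of the 10-s
    span (6 s by default); the band-stop removes a contiguous
    ``bandstop_width_hz`` band (default 10 Hz, tuned experimentally)."""

    cutout_duration_s: float = 6.0
    bandstop_width_hz: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.cutout_duration_s <= 10:
            raise ValueError("cutout_duration_s must be within [0, 10]")
        if not 0 <= self.bandstop_width_hz <= 60:
            raise ValueError("bandstop_width_hz must be within [0, 60]")


def temporal_cutout(spec: Spectrogram, cfg: AugmentConfig,
                    rng: np.random.Generator) -> Spectrogram:
    """Zero a contiguous ``cutout_duration_s`` time span.

    The span start is drawn uniformly on the frame grid (multiples of
    the hop) within [0, span - duration]; frames whose centre lies in
    the half-open masked interval are zeroed across all channels and
    frequencies.  With the 6-s default on a 21-frame spectrogram this
    zeroes exactly 12 frames for every admissible start.
    """
    times = spec.frame_times
    span = times[-1] - times[0]
    dur = cfg.cutout_duration_s
    if dur > span + 1e-9:
        raise ValueError(f"cutout of {dur} s exceeds the {span} s window")
    out = spec.copy()
    if dur == 0:
        return out
    if dur >= span - 1e-9:  # full mask: the boundary frame goes too
        out.values[:] = 0.0
        return out
    hop = times[1] - times[0]
    n_starts = int(round((span - dur) / hop)) + 1
    t0 = times[0] + hop * rng.integers(n_starts)
    mask = (times >= t0 - 1e-9) & (times < t0 + dur - 1e-9)
    out.values[:, mask, :] = 0.0
    return out


def band_stop(spec: Spectrogram, cfg: AugmentConfig,
              rng: np.random.Generator) -> Spectrogram:
    """Zero a contiguous frequency band [f0, f0 + width) Hz, f0 drawn
    uniformly among the admissible integer offsets."""
    freqs = spec.bin_freqs
    width = cfg.bandstop_width_hz
    if width > len(freqs):
        raise ValueError(f"band-stop of {width} Hz exceeds the "
                         f"{len(freqs)}-bin spectrum")
    out = spec.copy()
    if width == 0:
        return out
    f0 = freqs[0] + rng.integers(len(freqs) - width + 1)
    mask = (freqs >= f0 - 1e-9) & (freqs < f0 + width - 1e-9)
    out.values[:, :, mask] = 0.0
    return out


def make_views(spec: Spectrogram, cfg: AugmentConfig,
               rng: np.random.Generator):
    """The two contrastive views of one spectrogram:
    view A = band-stop mask, view B = temporal cutout."""
    return band_stop(spec, cfg, rng), temporal_cutout(spec, cfg, rng)


def make_view_batch(specs: np.ndarray, frame_times, bin_freqs,
                    cfg: AugmentConfig, rng: np.random.Generator):
    """Vectorised two-view augmentation of a (N, C, T, F) batch.

    Returns a (2N, C, T, F) array: the first N rows are band-stop views,
    the last N are cutout views, aligned so rows i and i+N come from
    source i.  Equivalent to calling :func:`make_views` per spectrogram.
    """
    n = specs.shape[0]
    views = np.empty((2 * n,) + specs.shape[1:], dtype=specs.dtype)
    for i in range(n):
        s = Spectrogram(specs[i], np.asarray(frame_times),
                        np.asarray(bin_freqs))
        a, b = make_views(s, cfg, rng)
        views[i] = a.values
        views[i + n] = b.values
    return views
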