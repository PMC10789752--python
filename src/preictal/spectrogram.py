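"""Short-time Fourier spectrograms of 10-s EEG windows.

Each window becomes a channels x time-frames x frequency-bins tensor:
a 1-s Hanning window with 50 % overlap and zero-padded boundary framing
gives 21 frames (centres at 0, 0.5, ..., 10 s) at 1-Hz frequency
resolution, and the band crop keeps the 60 bins covering 0-59 Hz.  The
tensor shapes consumed by the models are therefore (18, 21, 60) for the
18-channel bipolar montage at 256 Hz and (21, 21, 60) for the
21-channel average-reference montage at 200 Hz.

Frames are the literal windowed DFT sums (no 1/window-sum scaling); the
default magnitude transform is log(1 + |X|).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps


@dataclass
class SpectrogramConfig:
    window_function: str = "hann"
    window_length_s: float = 1.0
    overlap_fraction: float = 0.5
    fmax_hz: float = 60.0
    log_magnitude: bool = True

    def __post_init__(self):
        if not 0.0 < self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in (0, 1)")
        if self.window_length_s <= 0:
            raise ValueError("window_length_s must be positive")

    def nperseg(self, sfreq: float) -> int:
        n = self.window_length_s * sfreq
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window_length_s * sfreq must be an integer")
        return int(round(n))


@dataclass
class Spectrogram:
    """Nonnegative magnitude tensor (channels x time x frequency)."""

    values: np.ndarray
    frame_times: np.ndarray
    bin_freqs: np.ndarray

    @property
    def shape(self):
        return self.values.shape

    def copy(self) -> "Spectrogram":
        return Spectrogram(self.values.copy(), self.frame_times.copy(),
                           self.bin_freqs.copy())


def stft_window(x: np.ndarray, cfg: SpectrogramConfig, sfreq: float):
    """One-sided STFT of a single-channel window.

    Returns ``(frames, frame_times, bin_freqs)`` with ``frames`` complex
    of shape (time, freq).  Zero-padded boundary framing places frame
    centres at 0, hop, 2*hop, ... through the window end, so a 10-s
    window at the 1-s / 50 % configuration yields 21 frames.
    """
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError("stft_window expects a single channel")
    nper = cfg.nperseg(sfreq)
    nover = int(round(nper * cfg.overlap_fraction))
    freqs, times, Z = sps.stft(x, fs=sfreq, window=cfg.window_function,
                               nperseg=nper, noverlap=nover,
                               boundary="zeros", padded=True,
                               detrend=False, return_onesided=True)
    # scipy normalises by the window sum; undo it so frames equal the
    # plain windowed DFT sum.
    wsum = sps.get_window(cfg.window_function, nper).sum()
    return (Z.T * wsum), times, freqs


def to_power(frames: np.ndarray, log_magnitude: bool = True) -> np.ndarray:
    """Magnitude (optionally log-compressed) of complex STFT frames."""
    mag = np.abs(frames)
    return np.log1p(mag) if log_magnitude else mag


def crop_band(mag: np.ndarray, bin_freqs: np.ndarray,
              fmax_hz: float = 60.0):
    """Keep the frequency bins in [0, fmax_hz), i.e. 0..59 Hz -> 60 rows.

    Requires 1-Hz bin resolution (window length of exactly one second).
    """
    bin_freqs = np.asarray(bin_freqs)
    df = bin_freqs[1] - bin_freqs[0]
    if abs(df - 1.0) > 1e-9:
        raise ValueError("crop_band requires 1-Hz frequency resolution")
    if fmax_hz > bin_freqs[-1] + df / 2:
        raise ValueError(
            f"fmax_hz={fmax_hz} exceeds the spectrum's Nyquist range "
            f"({bin_freqs[-1]} Hz)")
    keep = bin_freqs <= fmax_hz - 1.0 + 1e-9  # bins 0 .. fmax-1 Hz
    mag = np.asarray(mag)
    return mag[..., keep], bin_freqs[keep]


def window_to_tensor(window: np.ndarray, cfg: SpectrogramConfig,
                     sfreq: float) -> Spectrogram:
    """Per-channel STFT -> magnitude -> band crop, stacked channel-first."""
    window = np.atleast_2d(window)
    chans = []
    for ch in window:
        frames, times, freqs = stft_window(ch, cfg, sfreq)
        mag = to_power(frames, cfg.log_magnitude)
        cropped, kept = crop_band(mag, freqs, cfg.fmax_hz)
        chans.append(cropped)
    return Spectrogram(values=np.stack(chans, axis=0),
                       frame_times=times, bin_freqs=kept)


def windows_to_tensors(windows, cfg: SpectrogramConfig, sfreq: float,
                       dtype=np.float32) -> np.ndarray:
    """Stack many windows into a (N, C, T, F) array for the models."""
    tensors = [window_to_tensor(w, cfg, sfreq).values for w in windows]
    return np.stack(tensors).astype(dtype)


def save_spectrograms(path, specs: np.ndarray, labels, cfg: SpectrogramConfig,
                      frame_times, bin_freqs, segment_ids=None):
    """Persist a spectrogram batch as a compressed archive with the
    configuration and axes stored alongside."""
    import json
    np.savez_compressed(path, values=specs, labels=np.asarray(labels),
                        segment_ids=np.asarray(
                            segment_ids if segment_ids is not None else []))
    sidecar = str(path)
    sidecar = sidecar[:-4] if sidecar.endswith(".npz") else sidecar
    with open(sidecar + ".json", "w") as fh:
        json.dump({"config": asdict(cfg),
                   "frame_times": np.asarray(frame_times).tolist(),
                   "bin_freqs": np.asarray(bin_freqs).tolist()}, fh)
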