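"""EEG recordings, seizure annotations, and EDF / CSV input-output.

Recordings are held in memory as channels x samples arrays in microvolts.
EDF files are read through MNE; writing uses a built-in EDF (16-bit)
writer so synthetic datasets round-trip through the same reader used for
clinical files.  Seizure annotations travel as a CSV with columns
``recording_id, onset_s, offset_s``.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The 18 bipolar channels shared by the CHB-MIT recordings.
CHB_MIT_18 = [
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ",
]

#: The 21 average-referenced (unipolar) channels of the SNUH montage.
SNUH_21 = [
    "Fp1-AVG", "F3-AVG", "C3-AVG", "P3-AVG",
    "Fp2-AVG", "F4-AVG", "C4-AVG", "P4-AVG",
    "F7-AVG", "T1-AVG", "T3-AVG", "T5-AVG",
    "O1-AVG", "F8-AVG", "T2-AVG", "T4-AVG",
    "T6-AVG", "O2-AVG", "Fz-AVG", "Cz-AVG", "Pz-AVG",
]


class ChannelSelectionError(KeyError):
    """A montage channel is missing from the file."""


@dataclass
class Recording:
    """Multichannel scalp EEG held as a channels x samples array (µV)."""

    signal: np.ndarray
    sfreq: float
    channel_names: list
    start_time: float = 0.0

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal))
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match signal rows")
        if len(set(_norm(c) for c in self.channel_names)) != len(
                self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.sfreq


@dataclass
class SeizureAnnotation:
    """Seizure onset/offset times in seconds from recording start."""

    onsets: list = field(default_factory=list)
    offsets: list = field(default_factory=list)

    def __post_init__(self):
        self.onsets = [float(t) for t in self.onsets]
        self.offsets = [float(t) for t in self.offsets]
        if len(self.onsets) != len(self.offsets):
            raise ValueError("onsets and offsets must pair up")
        if any(b < a for a, b in zip(self.onsets, self.offsets)):
            raise ValueError("each offset must be >= its onset")
        if any(b <= a for a, b in zip(self.onsets, self.onsets[1:])):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)

    def intervals(self):
        return list(zip(self.onsets, self.offsets))


def _norm(name: str) -> str:
    return name.strip().casefold()


def read_recording(path, montage=None) -> Recording:
    """Read an EDF file and select/order channels per the montage list.

    Channel matching is case-insensitive with surrounding whitespace
    stripped (EDF header dialects vary).  With ``montage=None`` all
    channels are kept in file order.  Raises
    :class:`ChannelSelectionError` naming the missing channels if the
    montage cannot be satisfied.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if montage is None:
        montage = list(raw.ch_names)
    available = {_norm(ch): ch for ch in raw.ch_names}
    missing = [ch for ch in montage if _norm(ch) not in available]
    if missing:
        raise ChannelSelectionError(
            f"montage channels not in {Path(path).name}: {missing}")
    picks = [available[_norm(ch)] for ch in montage]
    data = raw.get_data(picks=picks) * 1e6  # MNE returns volts
    return Recording(signal=data, sfreq=float(raw.info["sfreq"]),
                     channel_names=list(montage))


def write_edf(path, recording: Recording):
    """Write a Recording to a 16-bit EDF file (one 1-s data record per
    second; physical units µV).  The trailing partial second, if any, is
    dropped so records are complete."""
    sfreq = recording.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per record per channel
    n_rec = recording.signal.shape[1] // spr
    nch = recording.n_channels
    sig = recording.signal[:, :n_rec * spr]

    pmax = np.maximum(np.abs(sig).max(axis=1), 1.0)
    pmin = -pmax
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.clip(np.rint((sig - pmin[:, None]) / gain[:, None]) + dmin,
                      dmin, dmax).astype("<i2")

    def pad(value, width):
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate 01-JAN-2000 X X X", 80),
        pad(now.strftime("%d.%m.%y"), 8),
        pad(now.strftime("%H.%M.%S"), 8),
        pad(256 * (nch + 1), 8),
        pad("", 44),
        pad(n_rec, 8),
        pad("1", 8),
        pad(nch, 4),
    ])
    fields = [
        [pad(ch, 16) for ch in recording.channel_names],
        [pad("", 80)] * nch,
        [pad("uV", 8)] * nch,
        [pad(f"{v:.6g}", 8) for v in pmin],
        [pad(f"{v:.6g}", 8) for v in pmax],
        [pad(dmin, 8)] * nch,
        [pad(dmax, 8)] * nch,
        [pad("", 80)] * nch,
        [pad(spr, 8)] * nch,
        [pad("", 32)] * nch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        # data records: per record, all samples of ch0, then ch1, ...
        recs = digital.reshape(nch, n_rec, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(recs).tobytes())


def write_annotations(path, annotations: dict):
    """Write ``{recording_id: SeizureAnnotation}`` to the bridge CSV."""
    rows = []
    for rec_id, ann in annotations.items():
        for onset, offset in ann.intervals():
            rows.append({"recording_id": rec_id, "onset_s": onset,
                         "offset_s": offset})
    pd.DataFrame(rows, columns=["recording_id", "onset_s", "offset_s"]).to_csv(
        path, index=False)


def read_annotations(path) -> dict:
    """Read the bridge CSV back into ``{recording_id: SeizureAnnotation}``."""
    df = pd.read_csv(path)
    out = {}
    for rec_id, grp in df.groupby("recording_id", sort=False):
        grp = grp.sort_values("onset_s")
        out[rec_id] = SeizureAnnotation(onsets=grp["onset_s"].tolist(),
                                        offsets=grp["offset_s"].tolist())
    return out
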