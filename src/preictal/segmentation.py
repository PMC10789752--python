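"""Period labelling, class balancing, and sliding-window extraction.

The recording timeline is partitioned into three half-open interval
sets, all in seconds from recording start:

* **pre-ictal** — the configured 10/15/30 minutes immediately before
  each seizure onset, ending exactly at onset;
* **inter-ictal** — everything further than ``gap_hours`` (3 h) from any
  seizure interval;
* **excluded** — the remainder: ictal spans, the 3-h buffers, and any
  pre-ictal candidate time contaminated by an earlier seizure.

Class balance is restored per seizure by drawing one contiguous
inter-ictal block of exactly the pre-ictal duration (undersampling);
both segments are then oversampled into 10-s windows sliding by 1 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .recording import Recording, SeizureAnnotation

WINDOW_S = 10.0
STEP_S = 1.0


class InsufficientDataError(RuntimeError):
    """No admissible inter-ictal block for a seizure."""


class EmptyWindowError(ValueError):
    """Segment shorter than one window."""


# --------------------------------------------------------------- intervals

def _subtract(intervals, cuts):
    """Set difference of half-open interval lists (both sorted)."""
    out = []
    for a, b in intervals:
        pieces = [(a, b)]
        for ca, cb in cuts:
            nxt = []
            for pa, pb in pieces:
                if cb <= pa or ca >= pb:
                    nxt.append((pa, pb))
                    continue
                if pa < ca:
                    nxt.append((pa, ca))
                if cb < pb:
                    nxt.append((cb, pb))
            pieces = nxt
        out.extend(pieces)
    return [(a, b) for a, b in out if b > a]


def _total(intervals) -> float:
    return float(sum(b - a for a, b in intervals))


@dataclass
class PeriodLabels:
    """Pre-ictal / inter-ictal / excluded partition of one recording.

    ``preictal[i]`` is the contiguous pre-ictal segment of the i-th
    usable seizure; ``preictal_seizure_ids[i]`` is that seizure's index
    in the annotation list.  ``skipped_seizures`` lists annotation
    indices whose clean pre-ictal remainder was shorter than one window.
    """

    preictal: list = field(default_factory=list)
    interictal: list = field(default_factory=list)
    excluded: list = field(default_factory=list)
    preictal_seizure_ids: list = field(default_factory=list)
    skipped_seizures: list = field(default_factory=list)
    duration_s: float = 0.0

    def to_json(self) -> str:
        return json.dumps({
            "preictal": self.preictal,
            "interictal": self.interictal,
            "excluded": self.excluded,
            "preictal_seizure_ids": self.preictal_seizure_ids,
            "skipped_seizures": self.skipped_seizures,
            "duration_s": self.duration_s,
        })

    @classmethod
    def from_json(cls, text: str) -> "PeriodLabels":
        d = json.loads(text)
        return cls(preictal=[tuple(x) for x in d["preictal"]],
                   interictal=[tuple(x) for x in d["interictal"]],
                   excluded=[tuple(x) for x in d["excluded"]],
                   preictal_seizure_ids=d["preictal_seizure_ids"],
                   skipped_seizures=d["skipped_seizures"],
                   duration_s=d["duration_s"])


def define_periods(ann: SeizureAnnotation, duration_s: float,
                   preictal_minutes: float,
                   gap_hours: float = 3.0) -> PeriodLabels:
    """Label the timeline of one recording.

    For each onset ``o`` the pre-ictal candidate is
    ``[o - 60*preictal_minutes, o)``, clipped to the recording and with
    any overlap with earlier ictal intervals removed; only the final
    contiguous piece (the one abutting the onset) is kept.  Seizures
    whose clean remainder is shorter than one window are skipped.
    Inter-ictal time is the complement of the union of all
    ``[onset - gap, offset + gap]`` buffers.  Everything else —
    including the removed pre-ictal fragments — is excluded.
    """
    if duration_s < 0:
        raise ValueError("duration_s must be nonnegative")
    gap = gap_hours * 3600.0
    pre_len = preictal_minutes * 60.0
    ictal = [(max(0.0, a), min(duration_s, b)) for a, b in ann.intervals()]

    buffers = [(max(0.0, a - gap), min(duration_s, b + gap))
               for a, b in ann.intervals()]
    interictal = _subtract([(0.0, duration_s)], buffers)

    preictal, ids, skipped = [], [], []
    for i, (onset, _offset) in enumerate(ann.intervals()):
        cand = (max(0.0, onset - pre_len), min(onset, duration_s))
        if cand[1] <= cand[0]:
            skipped.append(i)
            continue
        prior_ictal = ictal[:i]
        pieces = _subtract([cand], prior_ictal)
        # keep the contiguous piece that ends at onset
        pieces = [p for p in pieces if abs(p[1] - cand[1]) < 1e-9]
        if not pieces or (pieces[-1][1] - pieces[-1][0]) < WINDOW_S:
            skipped.append(i)
            continue
        preictal.append(pieces[-1])
        ids.append(i)

    excluded = _subtract([(0.0, duration_s)], interictal + preictal)
    return PeriodLabels(preictal=preictal, interictal=interictal,
                        excluded=excluded, preictal_seizure_ids=ids,
                        skipped_seizures=skipped, duration_s=duration_s)


@dataclass
class SegmentPair:
    """One LOOCV unit: a pre-ictal segment and an equally long
    inter-ictal segment drawn for the same seizure."""

    preictal_segment: tuple
    interictal_segment: tuple
    seizure_id: int

    def __post_init__(self):
        d1 = self.preictal_segment[1] - self.preictal_segment[0]
        d2 = self.interictal_segment[1] - self.interictal_segment[0]
        if abs(d1 - d2) > 1e-6:
            raise ValueError("segments of a pair must have equal duration")

    @property
    def duration_s(self) -> float:
        return self.preictal_segment[1] - self.preictal_segment[0]


def undersample_pair(labels: PeriodLabels, seizure_id: int,
                     rng_seed) -> SegmentPair:
    """Draw the inter-ictal counterpart for one seizure.

    The block start is uniform over all admissible positions (those
    keeping the block inside a single inter-ictal interval), using a
    dedicated seeded generator so each fold is reproducible.
    """
    if seizure_id not in labels.preictal_seizure_ids:
        raise KeyError(f"seizure {seizure_id} has no usable pre-ictal segment")
    pre = labels.preictal[labels.preictal_seizure_ids.index(seizure_id)]
    dur = pre[1] - pre[0]
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    starts = [(a, b - dur) for a, b in labels.interictal if b - a >= dur]
    if not starts:
        raise InsufficientDataError(
            f"no inter-ictal interval of length >= {dur:.0f} s "
            f"for seizure {seizure_id}")
    slacks = np.array([hi - lo for lo, hi in starts])
    if slacks.sum() == 0:
        t0 = starts[rng.integers(len(starts))][0]
    else:
        u = rng.uniform(0.0, slacks.sum())
        cum = np.cumsum(slacks)
        k = int(np.searchsorted(cum, u, side="right"))
        t0 = starts[k][0] + (u - (cum[k] - slacks[k]))
    return SegmentPair(preictal_segment=pre,
                       interictal_segment=(t0, t0 + dur),
                       seizure_id=seizure_id)


def build_pairs(labels: PeriodLabels, rng_seed) -> list:
    """One SegmentPair per usable seizure, independently seeded draws."""
    root = np.random.default_rng(rng_seed)
    pairs = []
    for sid in labels.preictal_seizure_ids:
        pairs.append(undersample_pair(labels, sid, root.spawn(1)[0]))
    return pairs


@dataclass
class WindowSet:
    """Overlapping 10-s windows cut from contiguous segments.

    ``windows[i]`` is a channels x samples view; ``labels[i]`` is 1 for
    pre-ictal, 0 for inter-ictal; ``segment_ids[i]`` identifies the
    source segment (used by the cross-validation leakage guard).
    """

    windows: list
    labels: np.ndarray
    segment_ids: np.ndarray
    sfreq: float

    def __len__(self) -> int:
        return len(self.windows)

    @staticmethod
    def concatenate(sets):
        sets = list(sets)
        return WindowSet(
            windows=[w for s in sets for w in s.windows],
            labels=np.concatenate([s.labels for s in sets]),
            segment_ids=np.concatenate([s.segment_ids for s in sets]),
            sfreq=sets[0].sfreq)


def slide_windows(segment: np.ndarray, sfreq: float,
                  window_s: float = WINDOW_S, step_s: float = STEP_S,
                  label: int = 0, segment_id: int = 0) -> WindowSet:
    """Cut overlapping windows from one contiguous segment.

    The count is ``floor((L - window_s)/step_s) + 1`` for an L-second
    segment; consecutive windows start ``step_s`` apart (9-s overlap at
    the defaults).
    """
    segment = np.atleast_2d(segment)
    wlen = int(round(window_s * sfreq))
    step = int(round(step_s * sfreq))
    n_samp = segment.shape[1]
    if n_samp < wlen:
        raise EmptyWindowError(
            f"segment of {n_samp / sfreq:.1f} s is shorter than one "
            f"{window_s:.0f}-s window")
    n_win = (n_samp - wlen) // step + 1
    windows = [segment[:, i * step:i * step + wlen] for i in range(n_win)]
    return WindowSet(windows=windows,
                     labels=np.full(n_win, label, dtype=int),
                     segment_ids=np.full(n_win, segment_id, dtype=int),
                     sfreq=sfreq)


def segment_signal(recording: Recording, interval) -> np.ndarray:
    """Slice the recording's signal array for a [start, end) interval."""
    i0 = int(round(interval[0] * recording.sfreq))
    i1 = int(round(interval[1] * recording.sfreq))
    return recording.signal[:, i0:i1]


def pair_windows(recording: Recording, pair: SegmentPair,
                 window_s: float = WINDOW_S,
                 step_s: float = STEP_S) -> WindowSet:
    """Windows of both segments of one pair, labelled 1/0, with segment
    ids ``2*seizure_id`` (pre-ictal) and ``2*seizure_id + 1``."""
    pre = slide_windows(segment_signal(recording, pair.preictal_segment),
                        recording.sfreq, window_s, step_s,
                        label=1, segment_id=2 * pair.seizure_id)
    inter = slide_windows(segment_signal(recording, pair.interictal_segment),
                          recording.sfreq, window_s, step_s,
                          label=0, segment_id=2 * pair.seizure_id + 1)
    return WindowSet.concatenate([pre, inter])
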