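"""Period labelling, undersampling, windowing, and EDF/CSV round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from preictal import (CHB_MIT_18, ChannelSelectionError, PeriodLabels,
                      Recording, SeizureAnnotation, define_periods,
                      read_annotations, read_recording, slide_windows,
                      undersample_pair, write_annotations, write_edf)
from preictal.segmentation import (EmptyWindowError, InsufficientDataError,
                                   build_pairs, pair_windows)


def grid_labels(ann, duration_s, preictal_minutes, gap_hours=3.0):
    """Brute-force label of every 1-s grid point: 2 = pre-ictal,
    0 = inter-ictal, 1 = excluded.  Mirrors the stated rules only."""
    t = np.arange(int(duration_s))
    lab = np.ones(len(t), dtype=int)
    far = np.ones(len(t), dtype=bool)
    for onset, offset in ann.intervals():
        far &= (t < onset - gap_hours * 3600) | (t >= offset + gap_hours * 3600)
    lab[far] = 0
    for i, (onset, offset) in enumerate(ann.intervals()):
        lo = max(0.0, onset - preictal_minutes * 60)
        pre = (t >= lo) & (t < onset)
        for po, pf in ann.intervals()[:i]:
            # only the clean run abutting the onset survives
            pre &= t >= pf if pf <= onset else ~pre
        lab[pre] = 2
    return t, lab


class TestDefinePeriods:
    def test_no_seizures_all_interictal(self):
        labels = define_periods(SeizureAnnotation(), 7200, 15)
        assert labels.interictal == [(0.0, 7200.0)]
        assert labels.preictal == [] and labels.excluded == []

    def test_single_seizure_reference_layout(self):
        """One onset at 5 h in a 10-h record, 15-min pre-ictal, 3-h gap."""
        ann = SeizureAnnotation(onsets=[5 * 3600], offsets=[5 * 3600 + 60])
        labels = define_periods(ann, 10 * 3600, 15)
        assert labels.preictal == [(4 * 3600 + 45 * 60, 5 * 3600)]
        assert labels.interictal == [(0.0, 2 * 3600.0),
                                     (5 * 3600 + 60 + 3 * 3600, 10 * 3600)]

    def test_clustered_seizures_truncate_against_grid_oracle(self):
        """Two onsets 5 min apart: the second pre-ictal candidate is cut
        at the first seizure's offset; checked point-by-point on a 1-s
        grid."""
        ann = SeizureAnnotation(onsets=[3600, 3900],
                                offsets=[3660, 3960])
        labels = define_periods(ann, 6 * 3600, 10)
        assert labels.preictal[1] == (3660.0, 3900.0)
        t, expect = grid_labels(ann, 6 * 3600, 10)

        def member(point, intervals):
            return any(a <= point < b for a, b in intervals)

        for point, e in zip(t + 0.5, expect):
            assert member(point, labels.preictal) == (e == 2)
            assert member(point, labels.interictal) == (e == 0)

    def test_idempotent(self):
        ann = SeizureAnnotation(onsets=[4 * 3600], offsets=[4 * 3600 + 30])
        once = define_periods(ann, 8 * 3600, 10)
        twice = define_periods(ann, 8 * 3600, 10)
        assert once == twice

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.integers(0, 500), min_size=0, max_size=4,
                    unique=True),
           st.sampled_from([10, 15, 30]))
    def test_three_sets_partition_the_recording(self, raw_onsets, minutes):
        duration = 10 * 3600.0
        onsets = sorted(o * 60.0 for o in raw_onsets)
        ann = SeizureAnnotation(onsets=onsets,
                                offsets=[o + 30 for o in onsets])
        labels = define_periods(ann, duration, minutes)
        pieces = labels.preictal + labels.interictal + labels.excluded
        assert sum(b - a for a, b in pieces) == pytest.approx(duration)
        starts = sorted(pieces)
        for (a1, b1), (a2, b2) in zip(starts, starts[1:]):
            assert b1 <= a2 + 1e-9  # pairwise disjoint

    def test_json_round_trip(self):
        ann = SeizureAnnotation(onsets=[4 * 3600], offsets=[4 * 3600 + 60])
        labels = define_periods(ann, 9 * 3600, 30)
        assert PeriodLabels.from_json(labels.to_json()) == labels


class TestUndersamplePair:
    def _labels(self, inter_len=7200.0):
        return PeriodLabels(preictal=[(12000.0, 12900.0)],
                            interictal=[(0.0, inter_len)],
                            excluded=[], preictal_seizure_ids=[0],
                            duration_s=13000.0)

    def test_deterministic_under_fixed_seed(self):
        labels = self._labels()
        a = undersample_pair(labels, 0, 123)
        b = undersample_pair(labels, 0, 123)
        assert a == b
        assert a.duration_s == pytest.approx(900.0)

    def test_insufficient_interictal_raises(self):
        with pytest.raises(InsufficientDataError):
            undersample_pair(self._labels(inter_len=600.0), 0, 0)

    def test_start_points_uniform_over_admissible_range(self):
        """1000 seeded draws: chi-squared against the uniform law over
        [0, 6300] at alpha = 0.01."""
        labels = self._labels()
        starts = np.array([
            undersample_pair(labels, 0, seed).interictal_segment[0]
            for seed in range(1000)])
        assert starts.min() >= 0 and starts.max() <= 7200 - 900
        counts, _ = np.histogram(starts, bins=9, range=(0, 6300))
        assert sstats.chisquare(counts).pvalue > 0.01


class TestSlideWindows:
    @pytest.mark.parametrize("L,expected", [(600, 591), (10, 1), (11, 2)])
    def test_window_counts(self, L, expected):
        ws = slide_windows(np.zeros((2, L * 50)), 50)
        assert len(ws) == expected

    def test_too_short_segment_raises(self):
        with pytest.raises(EmptyWindowError):
            slide_windows(np.zeros((2, 9 * 50)), 50)

    def test_consecutive_windows_one_second_apart(self, rng):
        sig = rng.normal(size=(1, 15 * 100))
        ws = slide_windows(sig, 100)
        np.testing.assert_array_equal(ws.windows[3],
                                      sig[:, 300:300 + 1000])

    @settings(deadline=None, max_examples=40)
    @given(st.integers(10, 400))
    def test_count_formula_for_all_lengths(self, L):
        ws = slide_windows(np.zeros((1, L * 20)), 20)
        assert len(ws) == L - 10 + 1


class TestPairing:
    def test_balanced_windows_and_gap_guard(self, tiny_recording):
        """Each pair yields equal pre/inter window counts and its
        inter-ictal block sits more than 3 h from every seizure."""
        _, rec, ann = tiny_recording
        labels = define_periods(ann, rec.duration_s, 10)
        pairs = build_pairs(labels, 77)
        assert len(pairs) == len(ann)
        for pair in pairs:
            ws = pair_windows(rec, pair)
            assert (ws.labels == 1).sum() == (ws.labels == 0).sum()
            a, b = pair.interictal_segment
            for onset, offset in ann.intervals():
                assert b <= onset - 3 * 3600 or a >= offset + 3 * 3600


class TestEdfBridge:
    def test_montage_selection_and_order(self, tmp_path, rng):
        extra = ["VNS", "ECG", "T8-P8-1", "LOC-ROC"]
        names = list(CHB_MIT_18) + extra
        rec = Recording(signal=rng.normal(size=(22, 2560)) * 40,
                        sfreq=256.0, channel_names=names)
        write_edf(tmp_path / "r.edf", rec)
        got = read_recording(tmp_path / "r.edf", CHB_MIT_18)
        assert got.channel_names == CHB_MIT_18
        assert got.sfreq == 256.0
        assert got.signal.shape == (18, 2560)

    def test_case_insensitive_matching(self, tmp_path, rng):
        rec = Recording(signal=rng.normal(size=(2, 512)) * 10, sfreq=256.0,
                        channel_names=["FP1-F7", "F7-T7"])
        write_edf(tmp_path / "r.edf", rec)
        got = read_recording(tmp_path / "r.edf", ["fp1-f7 ", "f7-t7"])
        assert got.signal.shape == (2, 512)

    def test_missing_channel_named_in_error(self, tmp_path, rng):
        rec = Recording(signal=rng.normal(size=(2, 512)), sfreq=256.0,
                        channel_names=["FP1-F7", "F7-T7"])
        write_edf(tmp_path / "r.edf", rec)
        with pytest.raises(ChannelSelectionError, match="CZ-PZ"):
            read_recording(tmp_path / "r.edf", ["FP1-F7", "CZ-PZ"])

    def test_write_read_quantisation_bound(self, tmp_path, tiny_recording):
        _, rec, _ = tiny_recording
        clip = Recording(signal=rec.signal[:, :120 * 256], sfreq=rec.sfreq,
                         channel_names=rec.channel_names)
        write_edf(tmp_path / "clip.edf", clip)
        got = read_recording(tmp_path / "clip.edf", clip.channel_names)
        step = 2 * np.abs(clip.signal).max(axis=1) / 65535
        err = np.abs(got.signal - clip.signal).max(axis=1)
        assert np.all(err <= step + 1e-9)

    def test_annotation_csv_round_trip(self, tmp_path):
        ann = SeizureAnnotation(onsets=[100.0, 5000.5], offsets=[160.0,
                                                                 5060.5])
        write_annotations(tmp_path / "ann.csv", {"rec1": ann})
        got = read_annotations(tmp_path / "ann.csv")["rec1"]
        assert got == ann
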