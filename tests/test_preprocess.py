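"""Recording I/O, segmentation geometry, 20x20x6 reshaping, normalization,
and the stratified cohort split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fallrisk.errors import DataError, FormatError, SizeError
from fallrisk.preprocess import (CHANNELS, ChannelNormalizer, ImuRecording,
                                 ModelInput, SignalWindow, flatten_input,
                                 read_recording, reshape_window,
                                 segment_recording, split_cohort,
                                 write_recording)


def make_recording(n, rate=40.0, fill=None, rng=None):
    if fill is not None:
        channels = np.full((6, n), float(fill))
    else:
        rng = rng or np.random.default_rng(0)
        channels = rng.normal(size=(6, n))
    return ImuRecording("S01", "walk", rate, channels)


class TestIo:
    def test_roundtrip_identity(self, tmp_path, rng):
        rec = make_recording(400, rng=rng)
        path = tmp_path / "rec.csv"
        write_recording(rec, path)
        back = read_recording(path, subject_id="S01", activity="walk")
        assert back.rate_hz == pytest.approx(40.0, abs=1e-6)
        np.testing.assert_allclose(back.channels, rec.channels, atol=1e-9)

    def test_missing_column_is_format_error(self, tmp_path):
        rec = make_recording(50)
        path = tmp_path / "rec.csv"
        write_recording(rec, path)
        df = pd.read_csv(path).drop(columns=["gyr_z"])
        df.to_csv(path, index=False)
        with pytest.raises(FormatError, match="gyr_z"):
            read_recording(path)

    def test_nonuniform_timestamps_rejected(self, tmp_path):
        rec = make_recording(50)
        path = tmp_path / "rec.csv"
        write_recording(rec, path)
        df = pd.read_csv(path)
        df.loc[10, "t"] += 0.01
        df.to_csv(path, index=False)
        with pytest.raises(FormatError, match="non-uniform"):
            read_recording(path)


def brute_force_starts(length, n_win, stride):
    return [s for s in range(0, length, stride) if s + n_win <= length]


class TestSegmentation:
    @pytest.mark.parametrize("length,expected_starts", [
        (400, [0]),            # exact fit
        (399, []),             # under one window
        (1200, [0, 350, 700]),  # 1050 + 400 > 1200
    ])
    def test_default_geometry(self, length, expected_starts):
        rec = make_recording(length)
        if not expected_starts:
            with pytest.warns(UserWarning, match="shorter than one"):
                windows = segment_recording(rec)
        else:
            windows = segment_recording(rec)
        assert [w.start_sample for w in windows] == expected_starts
        for w in windows:
            assert w.n_samples == 400

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_counts_match_brute_force(self, data):
        length = data.draw(st.integers(10, 3000))
        window_s = data.draw(st.sampled_from([2.0, 5.0, 10.0]))
        overlap_s = data.draw(st.sampled_from([0.0, 0.5, 1.25, 4.0]))
        if overlap_s >= window_s:
            return
        rec = make_recording(length)
        n_win = int(round(window_s * 40))
        stride = int(round((window_s - overlap_s) * 40))
        expected = brute_force_starts(length, n_win, stride)
        if not expected:
            with pytest.warns(UserWarning):
                windows = segment_recording(rec, window_s, overlap_s)
        else:
            windows = segment_recording(rec, window_s, overlap_s)
        assert [w.start_sample for w in windows] == expected

    def test_window_outside_parent_rejected(self):
        rec = make_recording(100)
        with pytest.raises(SizeError):
            SignalWindow(parent=rec, start_sample=90,
                         channels=rec.channels[:, 80:100])


class TestReshape:
    def test_row_major_indexing(self):
        # channel with value t at sample t: matrix[2][5] = 20*2 + 5 = 45
        channels = np.tile(np.arange(400.0), (6, 1))
        w = SignalWindow(parent=None, start_sample=0, channels=channels)
        mi = reshape_window(w)
        assert mi.data.shape == (6, 20, 20)
        assert mi.data[0, 2, 5] == 45
        assert mi.data[3, 19, 19] == 399

    def test_constant_channel(self):
        w = SignalWindow(None, 0, np.full((6, 400), 7.0))
        assert (reshape_window(w).data == 7.0).all()

    def test_roundtrip_bijective(self, rng):
        channels = rng.normal(size=(6, 400))
        w = SignalWindow(None, 0, channels)
        np.testing.assert_array_equal(flatten_input(reshape_window(w)),
                                      channels)

    def test_wrong_length_rejected(self):
        w = SignalWindow(None, 0, np.zeros((6, 300)))
        with pytest.raises(SizeError):
            reshape_window(w)


class TestNormalizer:
    def test_identity_mode(self, rng):
        x = rng.normal(size=(6, 400))
        norm = ChannelNormalizer(mode="identity")
        np.testing.assert_array_equal(norm.transform(x), x)

    def test_training_set_standardized(self, rng):
        windows = [rng.normal(loc=3.0, scale=2.0, size=(6, 400))
                   for _ in range(10)]
        norm = ChannelNormalizer().fit(windows)
        stacked = np.concatenate([norm.transform(w) for w in windows], axis=1)
        np.testing.assert_allclose(stacked.mean(axis=1), 0.0, atol=1e-6)
        np.testing.assert_allclose(stacked.std(axis=1), 1.0, atol=1e-6)

    def test_constant_channel_guard(self, rng):
        x = rng.normal(size=(6, 400))
        x[2] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            norm = ChannelNormalizer().fit([x])
        out = norm.transform(x)
        assert np.isfinite(out).all()
        np.testing.assert_allclose(out[2], 0.0, atol=1e-12)

    def test_roundtrip_serialization(self, rng):
        norm = ChannelNormalizer().fit([rng.normal(size=(6, 400))])
        back = ChannelNormalizer.from_dict(norm.to_dict())
        x = rng.normal(size=(6, 400))
        np.testing.assert_allclose(back.transform(x), norm.transform(x))


class TestSplit:
    def manifest(self, n_per=100, subjects=("S01",), activities=("walk",)):
        rows = [{"subject_id": s, "activity": a, "window": i}
                for s in subjects for a in activities for i in range(n_per)]
        return pd.DataFrame(rows)

    def test_twenty_eighty(self):
        train, evl = split_cohort(self.manifest(100), train_fraction=0.2,
                                  seed=0)
        assert len(train) == 20
        assert len(evl) == 80

    def test_deterministic_and_partition(self):
        m = self.manifest(37, subjects=("S01", "S02"),
                          activities=("walk", "step"))
        t1, e1 = split_cohort(m, seed=5)
        t2, e2 = split_cohort(m, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        union = pd.concat([t1, e1]).sort_index()
        pd.testing.assert_frame_equal(union, m)
        assert set(t1.index).isdisjoint(e1.index)

    def test_stratified_per_subject_activity(self):
        m = self.manifest(50, subjects=("S01", "S02"), activities=("walk",))
        train, _ = split_cohort(m, train_fraction=0.2, seed=1)
        counts = train.groupby("subject_id").size()
        assert (counts == 10).all()

    def test_tiny_stratum_goes_to_eval(self):
        m = self.manifest(1)
        with pytest.warns(UserWarning, match="assigned to eval"):
            train, evl = split_cohort(m, seed=0)
        assert len(train) == 0
        assert len(evl) == 1

    def test_bad_fraction(self):
        with pytest.raises(DataError):
            split_cohort(self.manifest(10), train_fraction=1.5)
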