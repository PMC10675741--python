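"""Attention-to-timestamp projection, weight thresholding, the reference
threshold labeler (against a brute-force scan), and whole-recording
detection."""

import numpy as np
import pytest

from fallrisk.detect import (RiskEvents, TimestampWeights,
                             attention_to_timestamp_weights, detect,
                             threshold_labeler, weights_to_events)
from fallrisk.errors import DataError, SizeError
from fallrisk.model import AttentionRecord, ModelConfig, init_model
from fallrisk.preprocess import ImuRecording, SignalWindow


def make_rec(acc_y, rate=40.0):
    channels = np.zeros((6, len(acc_y)))
    channels[1] = acc_y
    return ImuRecording("S01", "walk", rate, channels)


class TestAttentionProjection:
    def test_uniform_attention_all_ones(self):
        rec = AttentionRecord(np.full((400, 400), 1 / 400), gamma=0.5)
        tw = attention_to_timestamp_weights(rec)
        np.testing.assert_allclose(tw.weights, 1.0)

    def test_one_hot_column(self):
        attn = np.zeros((400, 400))
        attn[:, 45] = 1.0
        tw = attention_to_timestamp_weights(AttentionRecord(attn, gamma=1.0))
        assert tw.weights[45] == 1.0
        assert np.delete(tw.weights, 45).max() == 0.0

    def test_gamma_zero_means_zero_weights_and_no_events(self):
        rec = AttentionRecord(np.full((400, 400), 1 / 400), gamma=0.0)
        tw = attention_to_timestamp_weights(rec)
        assert tw.weights.max() == 0.0
        assert len(weights_to_events(tw).instants) == 0

    def test_non_stochastic_rows_rejected(self):
        rec = AttentionRecord(np.full((400, 400), 0.5), gamma=1.0)
        with pytest.raises(SizeError):
            attention_to_timestamp_weights(rec)

    def test_row_mode_differs_from_column_mode(self, rng):
        logits = rng.normal(size=(400, 400))
        attn = np.exp(logits)
        attn /= attn.sum(axis=1, keepdims=True)
        rec = AttentionRecord(attn, gamma=1.0)
        col = attention_to_timestamp_weights(rec, mode="column").weights
        row = attention_to_timestamp_weights(rec, mode="row").weights
        assert not np.allclose(col, row)


class TestWeightsToEvents:
    def test_all_zero_no_events(self):
        tw = TimestampWeights(np.zeros(400))
        assert len(weights_to_events(tw).instants) == 0

    def test_single_spike_translated_to_recording_coords(self):
        w = np.zeros(400)
        w[100] = 1.0
        parent = make_rec(np.zeros(2000))
        window = SignalWindow(parent, start_sample=350,
                              channels=parent.channels[:, 350:750])
        tw = TimestampWeights(w, window_ref=window)
        events = weights_to_events(tw, threshold=0.1)
        np.testing.assert_array_equal(events.instants, [450])

    def test_event_count_monotone_in_threshold(self, rng):
        # well-separated smooth bumps: raising the threshold can only
        # silence bumps, never create detections
        for _ in range(20):
            w = np.zeros(400)
            centers = rng.choice(np.arange(20, 380, 40), size=5,
                                 replace=False)
            for c in centers:
                peak = rng.uniform(0.05, 1.0)
                w[c - 4:c + 5] = np.maximum(
                    w[c - 4:c + 5], peak * np.hanning(9))
            w /= w.max()
            counts = [len(weights_to_events(TimestampWeights(w),
                                            threshold=t).instants)
                      for t in (0.05, 0.15, 0.35, 0.5, 0.75, 0.95)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_spike_events_exact_subset_across_thresholds(self, rng):
        # isolated single-sample spikes: the flagged instants at a high
        # threshold are exactly a subset of those at a low threshold
        w = np.zeros(400)
        spikes = rng.choice(np.arange(10, 390, 20), size=8, replace=False)
        w[spikes] = rng.uniform(0.05, 1.0, size=8)
        w /= w.max()
        tw = TimestampWeights(w)
        at_01 = set(weights_to_events(tw, threshold=0.1).instants)
        at_05 = set(weights_to_events(tw, threshold=0.5).instants)
        assert at_05 <= at_01

    def test_refractory_merges_nearby(self):
        w = np.zeros(400)
        w[[50, 55, 200]] = 1.0
        tw = TimestampWeights(w)
        events = weights_to_events(tw, threshold=0.5, refractory_ms=250)
        np.testing.assert_array_equal(events.instants, [50, 200])


def brute_force_labeler(acc_y, rate=40.0, level=5.0, jump_level=15.0,
                        jump_window_ms=300.0, refractory_ms=250.0):
    """Plain per-sample scan used as the independent oracle."""
    a = [abs(v) for v in acc_y]
    n = len(a)
    candidates = set()
    for i in range(n):  # rising crossings of `level`
        if a[i] > level and (i == 0 or a[i - 1] <= level):
            candidates.add(i)
    jump_w = round(jump_window_ms * rate / 1000.0)
    for j in range(n):  # start of a rise from <= level to >= jump_level
        if a[j] >= jump_level:
            for i in range(j - 1, max(-1, j - jump_w - 1), -1):
                if a[i] <= level:
                    candidates.add(i)
                    break
    refractory = max(1, round(refractory_ms * rate / 1000.0))
    out = []
    for t in sorted(candidates):
        if not out or t - out[-1] >= refractory:
            out.append(t)
    return out


class TestThresholdLabeler:
    def test_zero_signal_no_events(self):
        assert len(threshold_labeler(make_rec(np.zeros(1000))).instants) == 0

    def test_plateau_crossing(self):
        acc = np.zeros(200)
        acc[50:54] = 8.0
        events = threshold_labeler(make_rec(acc)).instants
        np.testing.assert_array_equal(events, [50])

    def test_jump_rule_fires_at_rise_start(self):
        # 4 -> 16 m/s^2 over 8 samples (200 ms <= 300 ms) starting at 30
        acc = np.zeros(200)
        acc[30:38] = np.linspace(4.0, 16.0, 8)
        events = threshold_labeler(make_rec(acc)).instants
        assert events[0] == 30

    def test_slow_rise_only_crossing(self):
        # a 1 s ramp exceeds the jump window: only the level crossing fires
        acc = np.zeros(400)
        acc[100:140] = np.linspace(4.0, 16.0, 40)
        events = threshold_labeler(make_rec(acc)).instants
        assert 100 not in events
        assert any(e > 100 for e in events)

    def test_negative_magnitude_detected(self):
        acc = np.zeros(200)
        acc[60:64] = -20.0
        events = threshold_labeler(make_rec(acc)).instants
        assert len(events) == 1

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_brute_force_scan(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(50, 1500))
        acc = rng.normal(scale=rng.uniform(1, 8), size=n)
        k = int(rng.integers(0, 4))
        for _ in range(k):
            s = int(rng.integers(0, n - 10))
            acc[s:s + 8] += rng.uniform(10, 30)
        expected = brute_force_labeler(acc)
        got = threshold_labeler(make_rec(acc)).instants
        np.testing.assert_array_equal(got, expected)


class TestDetect:
    def test_gamma_zero_model_emits_nothing(self, rng):
        model = init_model(ModelConfig(embed_dim=8, gamma_init=0.0, seed=0))
        rec = make_rec(rng.normal(size=1200))
        events, weights = detect(rec, model)
        assert len(events.instants) == 0
        assert (weights["weight"] == 0).all()

    def test_short_recording_empty_result(self, rng):
        model = init_model(ModelConfig(embed_dim=8, seed=0))
        rec = make_rec(rng.normal(size=100))
        with pytest.warns(UserWarning):
            events, weights = detect(rec, model)
        assert len(events.instants) == 0
        assert weights.empty

    def test_instants_inside_recording_and_no_crosstalk(self, rng):
        model = init_model(ModelConfig(embed_dim=8, gamma_init=0.5, seed=1))
        rec_a = make_rec(rng.normal(size=1200))
        rec_b = make_rec(rng.normal(size=1550))
        ev_a1, _ = detect(rec_a, model)
        ev_b, _ = detect(rec_b, model)
        ev_a2, _ = detect(rec_a, model)
        np.testing.assert_array_equal(ev_a1.instants, ev_a2.instants)
        for ev, rec in ((ev_a1, rec_a), (ev_b, rec_b)):
            if len(ev.instants):
                assert ev.instants.min() >= 0
                assert ev.instants.max() < rec.length

    def test_sorted_strictly_increasing_enforced(self):
        with pytest.raises(DataError):
            RiskEvents("model", np.array([5, 5, 9]))
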