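"""From attention maps to flagged fall-risk instants, plus the reference
threshold labeler.

The trained encoder's 400 x 400 spatial attention map is projected back
onto the signal timeline: the importance of timestamp ``t`` is the mean
attention its position receives over all query positions (the column
mean), scaled by |gamma| and max-normalized to [0, 1].  Instants whose
weight crosses a threshold (0.1 by default) are flagged as fall-risk
moments.

The reference labeler is the classic accelerometer rule: an event at
every rising crossing of |acc_y| above 5 m/s^2 (about 0.5 g, the
free-fall onset level), plus the start of any rise from at most 5 to at
least 15 m/s^2 within 300 ms.  Events closer than a refractory period
are merged to the first instant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, SizeError
from .model import AttentionModel, AttentionRecord, encode_batch
from .preprocess import (CHANNELS, ChannelNormalizer, ImuRecording,
                         MATRIX_SIDE, SignalWindow, segment_recording)

ACC_Y = CHANNELS.index("acc_y")


@dataclass
class TimestampWeights:
    """Max-normalized per-timestamp importance for one window."""

    weights: np.ndarray  # (400,) in [0, 1]
    window_ref: SignalWindow | None = None
    threshold: float = 0.1


@dataclass
class RiskEvents:
    """Sorted flagged instants in recording coordinates."""

    source: str  # "model" or "threshold"
    instants: np.ndarray
    recording_ref: ImuRecording | None = None

    def __post_init__(self) -> None:
        self.instants = np.asarray(self.instants, dtype=int)
        if len(self.instants) > 1 and not (np.diff(self.instants) > 0).all():
            raise DataError("event instants must be strictly increasing")
        if self.recording_ref is not None and len(self.instants):
            if self.instants[0] < 0 or self.instants[-1] >= self.recording_ref.length:
                raise DataError("event instant outside the recording")


def attention_to_timestamp_weights(rec: AttentionRecord,
                                   window_ref: SignalWindow | None = None,
                                   mode: str = "column") -> TimestampWeights:
    """Project an attention map onto per-timestamp importance weights.

    Position ``p`` (attention column) corresponds to timestamp
    ``t = p`` through the row-major inverse of the 20 x 20 reshape
    (``p = 20 * i + j``).  ``mode='column'`` uses attention *received*
    (column mean); ``mode='row'`` uses attention *paid* (row mean).  The
    result is scaled by |gamma| and max-normalized, so a gamma of zero
    — an encoder that ignores its attention block — yields all-zero
    weights and no events downstream.
    """
    rec.validate()
    if mode == "column":
        w = rec.attention.mean(axis=0)
    elif mode == "row":
        w = rec.attention.mean(axis=1)
    else:
        raise DataError(f"unknown projection mode {mode!r}")
    w = w * abs(rec.gamma)
    peak = w.max()
    if peak > 0:
        w = w / peak
    return TimestampWeights(weights=w, window_ref=window_ref)


def _dedup(instants: np.ndarray, refractory: int) -> np.ndarray:
    """Merge instants closer than ``refractory`` samples, keeping the first."""
    out: list[int] = []
    for t in np.sort(np.unique(instants)):
        if not out or t - out[-1] >= refractory:
            out.append(int(t))
    return np.array(out, dtype=int)


def _nms(instants: np.ndarray, weights: np.ndarray,
         refractory: int) -> np.ndarray:
    """Non-maximum suppression: keep the highest-weight instant of every
    refractory neighbourhood (ties break toward the earlier instant)."""
    order = np.lexsort((instants, -weights))
    kept: list[int] = []
    for i in order:
        t = int(instants[i])
        if all(abs(t - k) >= refractory for k in kept):
            kept.append(t)
    return np.array(sorted(kept), dtype=int)


def weights_to_events(tw: TimestampWeights, threshold: float = 0.1,
                      refractory_ms: float = 250.0,
                      rate_hz: float = 40.0) -> RiskEvents:
    """Flag the peak instants of above-threshold weight excursions.

    Candidate instants are all samples with weight >= ``threshold``;
    weight-ordered non-maximum suppression with the refractory radius
    keeps the locally highest-attention sample of each excursion.  Flag
    sets are therefore nested: raising the threshold can only remove
    flags, never move or create them.  Indices are translated to
    recording coordinates via the window start.
    """
    if not 0 < threshold <= 1:
        raise DataError(f"threshold must be in (0, 1], got {threshold}")
    w = tw.weights
    candidates = np.flatnonzero(w >= threshold)
    refractory = max(1, int(round(refractory_ms * rate_hz / 1000.0)))
    instants = _nms(candidates, w[candidates], refractory)
    start = tw.window_ref.start_sample if tw.window_ref is not None else 0
    return RiskEvents(source="model", instants=instants + start)


def threshold_labeler(rec: ImuRecording, level: float = 5.0,
                      jump_level: float = 15.0, jump_window_ms: float = 300.0,
                      refractory_ms: float = 250.0,
                      axis: int = ACC_Y) -> RiskEvents:
    """Reference fall-risk labels from the vertical acceleration channel.

    An event is recorded at every rising crossing of ``|acc_y|`` above
    ``level`` (5 m/s^2 ~= 0.5 g), and at the start of any rise from
    ``<= level`` to ``>= jump_level`` within ``jump_window_ms`` (12
    samples at 40 Hz).  Events within the refractory period collapse to
    the first instant.
    """
    a = np.abs(rec.channels[axis])
    above = a > level
    rising = above & ~np.concatenate(([False], above[:-1]))
    candidates = list(np.flatnonzero(rising))

    # Jump rule: for each sample at or above jump_level, the start of its
    # rise is the latest preceding sample at or below `level`; it is an
    # event if the whole rise fits inside the jump window.
    jump_w = int(round(jump_window_ms * rec.rate_hz / 1000.0))
    if jump_w >= 1 and len(a) > 1:
        idx = np.where(a <= level, np.arange(len(a)), -1)
        last_low = np.maximum.accumulate(idx)
        highs = np.flatnonzero(a >= jump_level)
        starts = last_low[highs]
        ok = (starts >= 0) & (highs - starts <= jump_w)
        candidates.extend(np.unique(starts[ok]).tolist())

    refractory = max(1, int(round(refractory_ms * rec.rate_hz / 1000.0)))
    instants = _dedup(np.array(candidates, dtype=int), refractory)
    return RiskEvents(source="threshold", instants=instants, recording_ref=rec)


def detect(rec: ImuRecording, model: AttentionModel,
           normalizer: ChannelNormalizer | None = None,
           weight_threshold: float = 0.1, refractory_ms: float = 250.0,
           projection: str = "column",
           window_s: float = 10.0, overlap_s: float = 1.25):
    """Run the model pipeline on a recording: flagged instants + weights.

    Segments the recording, encodes each window, projects attention to
    timestamp weights, thresholds them into events, and merges events
    across overlapping windows (union with refractory deduplication).
    Returns ``(RiskEvents, weights_table)`` where the table has columns
    ``window_start, sample_index, weight`` for plotting overlays.
    """
    windows = segment_recording(rec, window_s=window_s, overlap_s=overlap_s)
    if not windows:
        return (RiskEvents(source="model", instants=np.array([], dtype=int),
                           recording_ref=rec),
                pd.DataFrame(columns=["window_start", "sample_index", "weight"]))
    arrays = []
    for w in windows:
        chan = w.channels if normalizer is None else normalizer.transform(w.channels)
        arrays.append(chan.reshape(len(CHANNELS), MATRIX_SIDE, MATRIX_SIDE))
    emb, attn = encode_batch(np.stack(arrays), model)
    gamma = float(model.params["gamma"][0])

    # pool above-threshold instants across overlapping windows, keeping
    # each instant's highest normalized weight, then suppress non-maxima
    pooled: dict[int, float] = {}
    frames = []
    for w, a in zip(windows, attn):
        record = AttentionRecord(attention=a, gamma=gamma)
        tw = attention_to_timestamp_weights(record, window_ref=w, mode=projection)
        for idx in np.flatnonzero(tw.weights >= weight_threshold):
            t = w.start_sample + int(idx)
            pooled[t] = max(pooled.get(t, 0.0), float(tw.weights[idx]))
        frames.append(pd.DataFrame({
            "window_start": w.start_sample,
            "sample_index": w.start_sample + np.arange(tw.weights.size),
            "weight": tw.weights,
        }))
    refractory = max(1, int(round(refractory_ms * rec.rate_hz / 1000.0)))
    if pooled:
        instants = np.array(sorted(pooled), dtype=int)
        merged = _nms(instants, np.array([pooled[t] for t in sorted(pooled)]),
                      refractory)
    else:
        merged = np.array([], dtype=int)
    events = RiskEvents(source="model", instants=merged, recording_ref=rec)
    return events, pd.concat(frames, ignore_index=True)
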