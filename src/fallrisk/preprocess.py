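"""Recording I/O, sliding-window segmentation, and model-input reshaping.

An ankle IMU recording is six synchronous channels (three accelerometer
axes in m/s^2, three gyroscope axes in deg/s) sampled at a common rate,
40 Hz by default.  Recordings are cut into 10 s windows that overlap by
1.25 s, and each 400-sample window is folded, channel by channel, into a
20 x 20 matrix; the six stacked matrices form the encoder input.

Index conventions are 0-based and half-open throughout: a window starting
at sample ``s`` covers ``[s, s + n_samples)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, SizeError

#: Fixed channel order used everywhere in the package.
CHANNELS: tuple[str, ...] = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

#: Window geometry at the default 40 Hz sampling rate.
WINDOW_S = 10.0
OVERLAP_S = 1.25
MATRIX_SIDE = 20
WINDOW_SAMPLES = MATRIX_SIDE * MATRIX_SIDE  # 400


@dataclass
class ImuRecording:
    """One subject/activity multichannel time series.

    ``channels`` is a ``(6, n)`` float array in the order given by
    :data:`CHANNELS`.
    """

    subject_id: str
    activity: str
    rate_hz: float
    channels: np.ndarray

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != len(CHANNELS):
            raise SizeError(
                f"channels must be (6, n); got shape {self.channels.shape}"
            )
        if self.rate_hz <= 0:
            raise DataError(f"rate_hz must be positive, got {self.rate_hz}")

    @property
    def length(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.length / self.rate_hz


@dataclass
class SignalWindow:
    """A view onto ``n_samples`` consecutive samples of a recording."""

    parent: ImuRecording | None
    start_sample: int
    channels: np.ndarray  # (6, n_samples)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.parent is not None:
            end = self.start_sample + self.n_samples
            if self.start_sample < 0 or end > self.parent.length:
                raise SizeError(
                    f"window [{self.start_sample}, {end}) outside parent "
                    f"recording of length {self.parent.length}"
                )

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]


@dataclass
class ModelInput:
    """A 20 x 20 x 6 stacked matrix built from one 10 s window.

    ``data`` is stored channels-first, ``(6, 20, 20)``, with
    ``data[c, i, j] == channel_c[20 * i + j]`` so that a row-major
    flatten of each channel plane reproduces the original 400 samples
    exactly.
    """

    data: np.ndarray
    window_ref: SignalWindow | None = None
    channel_order: tuple[str, ...] = CHANNELS


def write_recording(rec: ImuRecording, path) -> None:
    """Write a recording as CSV: ``t,acc_x,...,gyr_z`` with t in seconds."""
    t = np.arange(rec.length) / rec.rate_hz
    df = pd.DataFrame({"t": t})
    for i, name in enumerate(CHANNELS):
        df[name] = rec.channels[i]
    df.to_csv(path, index=False)


def read_recording(path, subject_id: str = "", activity: str = "") -> ImuRecording:
    """Read a recording CSV, checking the column set and uniform timestamps."""
    df = pd.read_csv(path)
    missing = [c for c in ("t", *CHANNELS) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer the rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], atol=1e-6):
        bad = int(np.argmax(np.abs(dt - dt[0]) > 1e-6)) + 1
        raise FormatError(f"{path}: non-uniform timestamps near row {bad}")
    rate = 1.0 / dt[0]
    channels = np.stack([df[c].to_numpy(dtype=float) for c in CHANNELS])
    if np.isnan(channels).any():
        raise FormatError(f"{path}: NaN values in channel data")
    return ImuRecording(subject_id=subject_id, activity=activity,
                        rate_hz=rate, channels=channels)


def segment_recording(
    rec: ImuRecording,
    window_s: float = WINDOW_S,
    overlap_s: float = OVERLAP_S,
) -> list[SignalWindow]:
    """Cut a recording into overlapping windows anchored at sample 0.

    Consecutive windows share ``overlap_s`` seconds, i.e. the stride is
    ``(window_s - overlap_s) * rate`` samples (350 at the defaults).
    Trailing samples that do not fill a whole window are discarded.  A
    recording shorter than one window yields an empty list with a warning.
    """
    if not 0 <= overlap_s < window_s:
        raise DataError(f"need 0 <= overlap_s < window_s, got {overlap_s}, {window_s}")
    n_win = int(round(window_s * rec.rate_hz))
    stride = int(round((window_s - overlap_s) * rec.rate_hz))
    if rec.length < n_win:
        warnings.warn(
            f"recording {rec.subject_id}/{rec.activity} has {rec.length} samples, "
            f"shorter than one {n_win}-sample window; no windows produced",
            stacklevel=2,
        )
        return []
    starts = range(0, rec.length - n_win + 1, stride)
    return [
        SignalWindow(parent=rec, start_sample=s, channels=rec.channels[:, s:s + n_win])
        for s in starts
    ]


def reshape_window(w: SignalWindow) -> ModelInput:
    """Fold a 400-sample window into the 20 x 20 x 6 model input.

    Each channel is clipped into 20 equally sized sequences of length 20
    which become the rows of a 20 x 20 matrix; the six matrices are
    superimposed along the leading axis.
    """
    if w.n_samples != WINDOW_SAMPLES:
        raise SizeError(f"reshape requires {WINDOW_SAMPLES} samples, got {w.n_samples}")
    data = w.channels.reshape(len(CHANNELS), MATRIX_SIDE, MATRIX_SIDE)
    return ModelInput(data=data.copy(), window_ref=w)


def flatten_input(mi: ModelInput) -> np.ndarray:
    """Inverse of :func:`reshape_window`; returns a ``(6, 400)`` array."""
    return mi.data.reshape(len(CHANNELS), WINDOW_SAMPLES)


class ChannelNormalizer:
    """Per-channel z-scoring with statistics frozen on the training split.

    The six channels mix units (m/s^2 and deg/s) whose raw scales differ
    by roughly a factor of six; z-scoring puts them on a common footing
    before augmentation and encoding.  ``mode='identity'`` disables the
    transform while keeping the interface.
    """

    def __init__(self, mode: str = "zscore") -> None:
        if mode not in ("zscore", "identity"):
            raise DataError(f"unknown normalizer mode {mode!r}")
        self.mode = mode
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, windows: Iterable[SignalWindow | np.ndarray]) -> "ChannelNormalizer":
        arrays = [w.channels if isinstance(w, SignalWindow) else np.asarray(w, float)
                  for w in windows]
        if not arrays:
            raise DataError("cannot fit normalizer on an empty window set")
        stacked = np.concatenate(arrays, axis=1)
        self.mean_ = stacked.mean(axis=1)
        sd = stacked.std(axis=1)
        zero = sd < 1e-12
        if zero.any():
            names = [CHANNELS[i] for i in np.flatnonzero(zero)]
            warnings.warn(f"zero-variance channel(s) {names}; using unit divisor",
                          stacklevel=2)
            sd = np.where(zero, 1.0, sd)
        self.sd_ = sd
        return self

    def transform(self, channels: np.ndarray) -> np.ndarray:
        channels = np.asarray(channels, dtype=float)
        if self.mode == "identity":
            return channels.copy()
        if self.mean_ is None or self.sd_ is None:
            raise DataError("normalizer not fitted")
        return (channels - self.mean_[:, None]) / self.sd_[:, None]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "mean": None if self.mean_ is None else self.mean_.tolist(),
            "sd": None if self.sd_ is None else self.sd_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelNormalizer":
        norm = cls(mode=d["mode"])
        if d.get("mean") is not None:
            norm.mean_ = np.asarray(d["mean"], dtype=float)
            norm.sd_ = np.asarray(d["sd"], dtype=float)
        return norm


def split_cohort(
    manifest: pd.DataFrame,
    train_fraction: float = 0.2,
    per: Sequence[str] = ("subject_id", "activity"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/eval split of a window manifest.

    Rows are grouped by the ``per`` columns and each stratum is split at
    ``train_fraction`` (rounded).  The default fraction of 0.2 follows the
    protocol of training the representation on 20% of the windows and
    evaluating on the remaining 80%.  Strata with fewer than two rows go
    entirely to the evaluation split, with a warning.
    """
    if not 0 < train_fraction < 1:
        raise DataError(f"train_fraction must be in (0, 1), got {train_fraction}")
    for col in per:
        if col not in manifest.columns:
            raise DataError(f"manifest lacks stratification column {col!r}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    eval_idx: list[int] = []
    for _, group in manifest.groupby(list(per), sort=True):
        idx = group.index.to_numpy()
        if len(idx) < 2:
            warnings.warn(
                f"stratum {tuple(group.iloc[0][list(per)])} has {len(idx)} "
                "window(s); assigned to eval", stacklevel=2)
            eval_idx.extend(idx)
            continue
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        train_idx.extend(idx[perm[:n_train]])
        eval_idx.extend(idx[perm[n_train:]])
    return manifest.loc[sorted(train_idx)], manifest.loc[sorted(eval_idx)]
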