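"""Tolerance-window scoring of flagged instants against reference labels.

A prediction that lands near a reference event still carries clinical
value: before the reference it is preventive, after it is a confirmation
within a confidence interval.  Each reference event therefore owns an
acceptance interval — ``[r - w, r]`` (before), ``[r, r + w]`` (after),
or ``[r - w, r + w]`` (centered) — and counts as a true positive when at
least one prediction falls inside it.  Matching is greedy
earliest-first and one-to-one, so a single prediction cannot claim
several references.  Endpoints are inclusive.

Confusion counts are kept at sample-instant granularity: true negatives
are all remaining instants of the recording, which makes the class
imbalance of rare-event detection explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .detect import RiskEvents
from .errors import DataError

MODES = ("before", "after", "centered")
DEFAULT_WINDOWS_MS = (125.0, 250.0, 500.0)


@dataclass
class EvalConfig:
    mode: str = "centered"
    window_ms: float = 500.0
    rate_hz: float = 40.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise DataError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.window_ms <= 0:
            raise DataError("window_ms must be positive")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_ms * self.rate_hz / 1000.0))


@dataclass
class ToleranceEvalResult:
    tp: int
    fp: int
    fn: int
    tn: int
    config: EvalConfig

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            warnings.warn("precision undefined (no predictions)", stacklevel=2)
            return float("nan")
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            warnings.warn("recall undefined (no reference events)", stacklevel=2)
            return float("nan")
        return self.tp / (self.tp + self.fn)

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else float("nan")


def _interval(r: int, w: int, mode: str) -> tuple[int, int]:
    if mode == "before":
        return r - w, r
    if mode == "after":
        return r, r + w
    return r - w, r + w


def match_events(pred: RiskEvents, ref: RiskEvents, cfg: EvalConfig,
                 n_samples: int) -> ToleranceEvalResult:
    """Score predicted instants against reference instants.

    References are visited in increasing order; each claims the earliest
    unused prediction inside its acceptance interval.  Unclaimed
    references are false negatives, unclaimed predictions false
    positives, and every other sample instant a true negative.
    """
    p = np.asarray(pred.instants, dtype=int)
    r = np.asarray(ref.instants, dtype=int)
    for name, arr in (("pred", p), ("ref", r)):
        if len(arr) and (arr.min() < 0 or arr.max() >= n_samples):
            raise DataError(f"{name} events outside [0, {n_samples})")
    w = cfg.window_samples
    used = np.zeros(len(p), dtype=bool)
    tp = 0
    for ri in np.sort(r):
        lo, hi = _interval(int(ri), w, cfg.mode)
        hits = np.flatnonzero(~used & (p >= lo) & (p <= hi))
        if hits.size:
            # earliest unused prediction in the interval
            chosen = hits[np.argmin(p[hits])]
            used[chosen] = True
            tp += 1
    fn = len(r) - tp
    fp = int((~used).sum())
    tn = n_samples - tp - fp - fn
    return ToleranceEvalResult(tp=tp, fp=fp, fn=fn, tn=tn, config=cfg)


def metrics(result: ToleranceEvalResult) -> tuple[float, float, float]:
    """(precision, recall, accuracy); undefined ratios come back as NaN."""
    return result.precision, result.recall, result.accuracy


def evaluate_suite(pred_by_recording: dict[str, RiskEvents],
                   ref_by_recording: dict[str, RiskEvents],
                   n_samples_by_recording: dict[str, int],
                   modes=MODES, windows_ms=DEFAULT_WINDOWS_MS,
                   rate_hz: float = 40.0) -> pd.DataFrame:
    """The full mode x window-size grid, counts summed over recordings.

    Returns one row per (mode, window_ms) cell with columns
    ``mode, window_ms, tp, fp, fn, tn, precision, recall, accuracy``.
    """
    missing = set(pred_by_recording) ^ set(ref_by_recording)
    if missing:
        raise DataError(f"recording keys mismatch: {sorted(missing)}")
    rows = []
    for mode in modes:
        for wms in windows_ms:
            tp = fp = fn = tn = 0
            for key in sorted(pred_by_recording):
                cfg = EvalConfig(mode=mode, window_ms=wms, rate_hz=rate_hz)
                res = match_events(pred_by_recording[key],
                                   ref_by_recording[key], cfg,
                                   n_samples_by_recording[key])
                tp += res.tp
                fp += res.fp
                fn += res.fn
                tn += res.tn
            agg = ToleranceEvalResult(tp, fp, fn, tn,
                                      EvalConfig(mode=mode, window_ms=wms,
                                                 rate_hz=rate_hz))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.append({
                    "mode": mode, "window_ms": wms,
                    "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                    "precision": agg.precision, "recall": agg.recall,
                    "accuracy": agg.accuracy,
                })
    return pd.DataFrame(rows)


def plot_confusion_grid(report: pd.DataFrame, out_path) -> None:
    """Render the 3 x 3 grid of confusion matrices to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    modes = list(dict.fromkeys(report["mode"]))
    widths = sorted(set(report["window_ms"]))
    fig, axes = plt.subplots(len(modes), len(widths),
                             figsize=(3.2 * len(widths), 3.0 * len(modes)),
                             squeeze=False)
    for i, mode in enumerate(modes):
        for j, wms in enumerate(widths):
            row = report[(report["mode"] == mode)
                         & (report["window_ms"] == wms)].iloc[0]
            mat = np.array([[row.tp, row.fn], [row.fp, row.tn]], dtype=float)
            ax = axes[i][j]
            ax.imshow(np.log1p(mat), cmap="Blues")
            for (a, b), v in np.ndenumerate(mat):
                ax.text(b, a, f"{int(v)}", ha="center", va="center")
            ax.set_xticks([0, 1], ["risk", "no risk"])
            ax.set_yticks([0, 1], ["risk", "no risk"])
            ax.set_title(f"{mode}, {wms:g} ms", fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
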