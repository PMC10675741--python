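"""End-to-end orchestration: cohort -> windows -> training -> detection
-> tolerance-window evaluation.

These helpers glue the modules together for the CLI, the test suite,
and the reproduction script, keeping each stage's interface unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .detect import RiskEvents, detect, threshold_labeler
from .errors import DataError
from .evaluate import EvalConfig, match_events
from .model import AttentionModel, ModelConfig, init_model
from .preprocess import (ChannelNormalizer, ImuRecording, segment_recording,
                         split_cohort)
from .synthetic import SimulationConfig, SyntheticRecording, simulate_cohort
from .train import TrainConfig, TrainWindow, predict_windows, train


@dataclass
class WindowDataset:
    """All windows of a cohort plus their manifest (one row per window)."""

    manifest: pd.DataFrame  # subject_id, activity, berg_score, start_sample
    raw: list[np.ndarray]   # (6, 400) raw channels, indexed by manifest row


def build_window_dataset(cohort: list[SyntheticRecording],
                         window_s: float = 10.0,
                         overlap_s: float = 1.25) -> WindowDataset:
    rows = []
    raw: list[np.ndarray] = []
    for sr in cohort:
        for w in segment_recording(sr.recording, window_s, overlap_s):
            rows.append({
                "subject_id": sr.profile.subject_id,
                "activity": sr.activity,
                "berg_score": sr.profile.berg_score,
                "start_sample": w.start_sample,
            })
            raw.append(w.channels.copy())
    if not rows:
        raise DataError("cohort produced no windows")
    return WindowDataset(manifest=pd.DataFrame(rows), raw=raw)


def to_train_windows(ds: WindowDataset, manifest: pd.DataFrame,
                     normalizer: ChannelNormalizer) -> list[TrainWindow]:
    return [
        TrainWindow(
            channels=normalizer.transform(ds.raw[i]),
            berg_score=float(row.berg_score),
            subject_id=row.subject_id,
            activity=row.activity,
            start_sample=int(row.start_sample),
        )
        for i, row in zip(manifest.index, manifest.itertuples())
    ]


@dataclass
class TrainedPipeline:
    model: AttentionModel
    normalizer: ChannelNormalizer
    dataset: WindowDataset
    train_manifest: pd.DataFrame
    eval_manifest: pd.DataFrame
    history: object


def train_on_cohort(cohort: list[SyntheticRecording],
                    model_config: ModelConfig | None = None,
                    train_config: TrainConfig | None = None,
                    train_fraction: float = 0.2,
                    split_seed: int = 0) -> TrainedPipeline:
    """Split the cohort windows 20/80, fit the normalizer on the training
    split, and train the encoder + head on it."""
    ds = build_window_dataset(cohort)
    train_m, eval_m = split_cohort(ds.manifest, train_fraction=train_fraction,
                                   seed=split_seed)
    normalizer = ChannelNormalizer().fit([ds.raw[i] for i in train_m.index])
    train_w = to_train_windows(ds, train_m, normalizer)
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    model, history = train(train_w, init_model(model_config), train_config)
    return TrainedPipeline(model=model, normalizer=normalizer, dataset=ds,
                           train_manifest=train_m, eval_manifest=eval_m,
                           history=history)


def subject_level_predictions(tp: TrainedPipeline,
                              manifest: pd.DataFrame | None = None
                              ) -> pd.DataFrame:
    """Mean predicted Berg per subject over the given manifest's windows."""
    manifest = tp.eval_manifest if manifest is None else manifest
    windows = to_train_windows(tp.dataset, manifest, tp.normalizer)
    preds = predict_windows(windows, tp.model)
    df = manifest.copy()
    df["predicted"] = preds
    return (df.groupby("subject_id")
              .agg(berg_score=("berg_score", "first"),
                   predicted=("predicted", "mean"))
              .reset_index())


def berg_spearman(tp: TrainedPipeline) -> float:
    """Spearman rho between true and predicted Berg on held-out subjects."""
    per_subject = subject_level_predictions(tp)
    rho, _ = spearmanr(per_subject["berg_score"], per_subject["predicted"])
    return float(rho)


def detect_cohort(cohort: list[SyntheticRecording], tp: TrainedPipeline,
                  weight_threshold: float = 0.1,
                  projection: str = "column"):
    """Model events, reference events, and lengths for every recording."""
    pred: dict[str, RiskEvents] = {}
    ref: dict[str, RiskEvents] = {}
    n_samples: dict[str, int] = {}
    for sr in cohort:
        key = f"{sr.profile.subject_id}/{sr.activity}"
        events, _ = detect(sr.recording, tp.model, tp.normalizer,
                           weight_threshold=weight_threshold,
                           projection=projection)
        pred[key] = events
        ref[key] = threshold_labeler(sr.recording)
        n_samples[key] = sr.recording.length
    return pred, ref, n_samples


def random_placement_null(pred: dict[str, RiskEvents],
                          ref: dict[str, RiskEvents],
                          n_samples: dict[str, int],
                          cfg: EvalConfig, n_draws: int = 200,
                          seed: int = 0) -> np.ndarray:
    """Recall distribution under random placement of the predictions.

    Each draw re-places, per recording, the same *number* of predicted
    instants uniformly at random (without replacement) and scores them
    against the same references, giving a chance baseline for the
    tolerance-window recall.
    """
    rng = np.random.default_rng(seed)
    recalls = np.empty(n_draws)
    for d in range(n_draws):
        tp_total = 0
        fn_total = 0
        for key in sorted(ref):
            n = n_samples[key]
            k = min(len(pred[key].instants), n)
            instants = np.sort(rng.choice(n, size=k, replace=False))
            random_events = RiskEvents(source="model", instants=instants)
            res = match_events(random_events, ref[key], cfg, n)
            tp_total += res.tp
            fn_total += res.fn
        recalls[d] = tp_total / (tp_total + fn_total) if tp_total + fn_total else 0.0
    return recalls
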