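"""Joint training: view-similarity (contrastive) loss + Berg-score MAE.

Every training step builds the five-member view set for each window in
the batch, encodes all views, and optimizes

    total = lambda * L_contrastive + (1 - lambda) * L_mae

with Adam.  The contrastive loss uses the margin form

    l(e1, e2, y) = y * d + (1 - y) * max(margin - d, 0),   d = ||e1 - e2||

over pairs of view embeddings: all C(5,2) = 10 pairs of views of the
same window are positives (y = 1); original-vs-original pairs across
windows are negatives (y = 0), subsampled to at most the positive count.
Including negatives keeps the hinge branch live and guards against
representation collapse; ``positives_only=True`` gives the strict
multi-view-alignment reading.

The regression branch feeds the concatenation of the five view
embeddings to the linear head and takes the mean absolute error against
the window's Berg score.  Targets are z-scored internally (statistics
stored on the model) so the scalar head converges at the same Adam step
scale as the rest of the network; histories and predictions are reported
in Berg points.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _nn
from .augment import AugmentConfig, make_views
from .errors import ConfigurationError, DataError, SizeError
from .model import AttentionModel, ModelConfig, N_VIEWS, init_model
from .preprocess import CHANNELS, MATRIX_SIDE, WINDOW_SAMPLES

#: Hyperparameter grid from the study's search protocol.
SEARCH_SPACE: dict[str, tuple] = {
    "batch_size": (1, 4, 8, 16, 32),
    "learning_rate": (1e-2, 1e-3, 1e-4, 1e-5),
    "epochs": (5, 10, 15, 20, 30, 40, 50),
    "kernel_size": (1, 2, 4, 6, 8),
}


@dataclass
class TrainConfig:
    batch_size: int = 4
    learning_rate: float = 1e-3
    epochs: int = 20
    margin: float = 1.0
    loss_mix: float = 0.5  # lambda: weight of the contrastive term
    seed: int = 0
    positives_only: bool = False
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.margin <= 0:
            raise ConfigurationError("margin must be positive")
        if not 0.0 <= self.loss_mix <= 1.0:
            raise ConfigurationError("loss_mix must be in [0, 1]")


@dataclass
class PairLabel:
    """Indices into the flat view list; y = 1 iff same origin window."""

    i: int
    j: int
    y: int


@dataclass
class TrainWindow:
    """One normalized training window with its Berg label."""

    channels: np.ndarray  # (6, 400), already normalized
    berg_score: float
    subject_id: str = ""
    activity: str = ""
    start_sample: int = 0


@dataclass
class TrainHistory:
    contrastive: list[float] = field(default_factory=list)
    regression: list[float] = field(default_factory=list)  # Berg points
    total: list[float] = field(default_factory=list)


def mae_loss(prediction, target) -> float:
    """Mean absolute error |x - y|, averaged over a batch."""
    return float(np.mean(np.abs(np.asarray(prediction, float)
                                - np.asarray(target, float))))


def contrastive_loss(e1, e2, y: int, margin: float = 1.0) -> float:
    """Margin contrastive loss on a pair of embedding vectors."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape:
        raise SizeError(f"embedding shapes differ: {e1.shape} vs {e2.shape}")
    d = float(np.linalg.norm(e1 - e2))
    return y * d + (1 - y) * max(margin - d, 0.0)


def build_pairs(n_windows: int, rng: np.random.Generator | None = None,
                positives_only: bool = False) -> list[PairLabel]:
    """Pair labels for a batch of ``n_windows`` five-view sets.

    View ``v`` of window ``w`` sits at flat index ``w * 5 + v`` (view 0
    is the original).  All within-window view pairs are positives;
    cross-window original-original pairs are negative candidates,
    subsampled to at most the positive count.
    """
    if n_windows < 1:
        raise DataError("need at least one window to build pairs")
    pairs = [PairLabel(w * N_VIEWS + a, w * N_VIEWS + b, 1)
             for w in range(n_windows)
             for a, b in itertools.combinations(range(N_VIEWS), 2)]
    if not positives_only and n_windows >= 2:
        candidates = [(w1 * N_VIEWS, w2 * N_VIEWS)
                      for w1, w2 in itertools.combinations(range(n_windows), 2)]
        n_neg = min(len(candidates), len(pairs))
        if rng is not None and n_neg < len(candidates):
            chosen = rng.choice(len(candidates), size=n_neg, replace=False)
            candidates = [candidates[int(c)] for c in sorted(chosen)]
        else:
            candidates = candidates[:n_neg]
        pairs.extend(PairLabel(i, j, 0) for i, j in candidates)
    return pairs


def _contrastive_batch(emb: np.ndarray, pairs: list[PairLabel], margin: float):
    """Mean contrastive loss over pairs and its gradient wrt embeddings."""
    loss = 0.0
    demb = np.zeros_like(emb)
    for p in pairs:
        diff = emb[p.i] - emb[p.j]
        d = float(np.linalg.norm(diff))
        if p.y == 1:
            loss += d
            if d > 1e-12:
                g = diff / d
                demb[p.i] += g
                demb[p.j] -= g
        else:
            if d < margin:
                loss += margin - d
                if d > 1e-12:
                    g = -diff / d
                    demb[p.i] += g
                    demb[p.j] -= g
    n = len(pairs)
    return loss / n, demb / n


def _views_tensor(windows: Sequence[TrainWindow], cfg: TrainConfig,
                  epoch: int, indices: np.ndarray) -> np.ndarray:
    """Stack the augmented views of a batch into (5B, 6, 20, 20)."""
    arrays = []
    for idx in indices:
        w = windows[int(idx)]
        seed = (cfg.seed * 1_000_003 + epoch * 10_007 + int(idx)) % (2 ** 31)
        vs = make_views(w.channels, cfg.augment, seed=seed)
        for member in vs.members():
            arrays.append(member.reshape(len(CHANNELS), MATRIX_SIDE, MATRIX_SIDE))
    return np.stack(arrays)


def train(windows: Sequence[TrainWindow], model: AttentionModel,
          cfg: TrainConfig) -> tuple[AttentionModel, TrainHistory]:
    """Optimize the encoder and head on a set of labeled windows."""
    if len(windows) == 0:
        raise DataError("training manifest is empty")
    targets = np.array([w.berg_score for w in windows], dtype=float)
    model.target_mean = float(targets.mean())
    model.target_sd = float(targets.std()) or 1.0
    targets_z = (targets - model.target_mean) / model.target_sd

    rng_order = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    rng_pairs = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    optimizer = _nn.Adam(model.params, lr=cfg.learning_rate)
    history = TrainHistory()
    lam = cfg.loss_mix

    for epoch in range(cfg.epochs):
        order = rng_order.permutation(len(windows))
        ep_con, ep_reg, ep_tot, n_batches = 0.0, 0.0, 0.0, 0
        for b0 in range(0, len(order), cfg.batch_size):
            idx = order[b0:b0 + cfg.batch_size]
            bsz = len(idx)
            x = _views_tensor(windows, cfg, epoch, idx)
            emb, _, cache = model.forward(x)

            pairs = build_pairs(bsz, rng_pairs, cfg.positives_only)
            con_loss, demb_con = _contrastive_batch(emb, pairs, cfg.margin)

            concat = emb.reshape(bsz, N_VIEWS * model.config.embed_dim)
            pred_z = model.head_forward(concat)
            t_z = targets_z[idx]
            reg_loss = mae_loss(pred_z, t_z)
            dpred = np.sign(pred_z - t_z) / bsz * (1 - lam)
            dconcat, head_grads = model.head_backward(concat, dpred)

            demb = dconcat.reshape(emb.shape)
            if lam > 0:
                demb = demb + lam * demb_con
            grads = model.backward(demb, cache)
            grads.update(head_grads)
            optimizer.step(grads)

            total = lam * con_loss + (1 - lam) * reg_loss
            if not math.isfinite(total):
                raise DataError(
                    f"non-finite loss at epoch {epoch}, batch {b0 // cfg.batch_size}: "
                    f"contrastive={con_loss}, regression={reg_loss}")
            ep_con += con_loss
            ep_reg += reg_loss
            ep_tot += total
            n_batches += 1
        history.contrastive.append(ep_con / n_batches)
        history.regression.append(ep_reg / n_batches * model.target_sd)
        history.total.append(ep_tot / n_batches)

    model.trained = True
    return model, history


def predict_windows(windows: Sequence[TrainWindow],
                    model: AttentionModel) -> np.ndarray:
    """Berg predictions for bare windows (original embedding replicated)."""
    if len(windows) == 0:
        return np.array([])
    x = np.stack([w.channels.reshape(len(CHANNELS), MATRIX_SIDE, MATRIX_SIDE)
                  for w in windows])
    emb, _, _ = model.forward(x)
    concat = np.tile(emb, (1, N_VIEWS))
    raw = model.head_forward(concat)
    return raw * model.target_sd + model.target_mean


def evaluate_mae(windows: Sequence[TrainWindow], model: AttentionModel) -> float:
    """Mean absolute error of Berg predictions, in Berg points."""
    preds = predict_windows(windows, model)
    targets = np.array([w.berg_score for w in windows], dtype=float)
    return mae_loss(preds, targets)


def iter_grid(space: dict[str, Sequence] | None = None):
    """Yield every configuration dict in the (sub)space, validated."""
    space = dict(SEARCH_SPACE if space is None else space)
    unknown = set(space) - set(SEARCH_SPACE)
    if unknown:
        raise ConfigurationError(f"unknown search-space key(s) {sorted(unknown)}")
    if not space:
        raise ConfigurationError("empty search space")
    for key, values in space.items():
        bad = [v for v in values if v not in SEARCH_SPACE[key]]
        if bad:
            raise ConfigurationError(
                f"values {bad} for {key!r} outside the search space "
                f"{SEARCH_SPACE[key]}")
    keys = sorted(space)
    for combo in itertools.product(*(space[k] for k in keys)):
        yield dict(zip(keys, combo))


def grid_search(space: dict[str, Sequence] | None,
                train_windows: Sequence[TrainWindow],
                val_windows: Sequence[TrainWindow],
                seed: int = 0,
                model_config: ModelConfig | None = None,
                base_train_config: TrainConfig | None = None):
    """Exhaustive grid search ranked by validation MAE.

    Ties break toward fewer epochs, then smaller batch.  Returns
    ``(best_train_config, best_model_config, leaderboard)`` where the
    leaderboard is one row per configuration evaluated.
    """
    base_mc = model_config or ModelConfig()
    base_tc = base_train_config or TrainConfig()
    rows = []
    best = None
    for combo in iter_grid(space):
        mc = ModelConfig(
            in_channels=base_mc.in_channels,
            kernel_size=combo.get("kernel_size", base_mc.kernel_size),
            embed_dim=base_mc.embed_dim,
            gamma_init=base_mc.gamma_init,
            seed=seed,
        )
        tc = TrainConfig(
            batch_size=combo.get("batch_size", base_tc.batch_size),
            learning_rate=combo.get("learning_rate", base_tc.learning_rate),
            epochs=combo.get("epochs", base_tc.epochs),
            margin=base_tc.margin,
            loss_mix=base_tc.loss_mix,
            seed=seed,
            positives_only=base_tc.positives_only,
            augment=base_tc.augment,
        )
        model, _ = train(train_windows, init_model(mc), tc)
        val_mae = evaluate_mae(val_windows, model)
        row = dict(combo)
        row["val_mae"] = val_mae
        rows.append(row)
        key = (val_mae, tc.epochs, tc.batch_size)
        if best is None or key < best[0]:
            best = (key, tc, mc)
    leaderboard = pd.DataFrame(rows).sort_values(
        by=[c for c in ("val_mae", "epochs", "batch_size")
            if c in rows[0]]).reset_index(drop=True)
    return best[1], best[2], leaderboard
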