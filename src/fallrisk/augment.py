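"""The four time-series augmentations behind the non-contrastive objective.

Each training window is paired with four transformed views — additive
white noise, random quantization, smooth drift, and time reversal — and
the encoder is trained to place all five views close together in
embedding space.  Augmentations operate on normalized windows (after
:class:`fallrisk.preprocess.ChannelNormalizer`), so magnitude parameters
are in z-score units.

Every stochastic transform is a deterministic function of
``(input, parameters, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ConfigurationError

VIEW_NAMES: tuple[str, ...] = ("noise", "quantize", "drift", "reverse")


@dataclass
class AugmentConfig:
    sd_scale: float = 0.05
    n_levels: int = 20
    max_drift: float = 0.5
    n_knots: int = 5
    noise_center: str = "zero"  # "zero" or "mean"

    def __post_init__(self) -> None:
        if self.sd_scale < 0:
            raise ConfigurationError("sd_scale must be >= 0")
        if self.n_levels < 2:
            raise ConfigurationError("n_levels must be >= 2")
        if self.max_drift < 0:
            raise ConfigurationError("max_drift must be >= 0")
        if self.n_knots < 2:
            raise ConfigurationError("n_knots must be >= 2")
        if self.noise_center not in ("zero", "mean"):
            raise ConfigurationError("noise_center must be 'zero' or 'mean'")


@dataclass
class ViewSet:
    """An original window plus its four augmented views, in fixed order."""

    original: np.ndarray  # (6, n)
    views: dict[str, np.ndarray]
    seed: int

    def members(self) -> list[np.ndarray]:
        """All five members: original first, then noise/quantize/drift/reverse."""
        return [self.original] + [self.views[name] for name in VIEW_NAMES]


def add_white_noise(channels: np.ndarray, sd_scale: float, seed: int,
                    center: str = "zero") -> np.ndarray:
    """Add Gaussian noise per channel, sd = ``sd_scale`` x the channel's sd.

    With ``center='mean'`` the noise is centered on each channel's own
    mean rather than zero, which shifts the view's amplitude; the
    zero-centered default keeps views unbiased.
    """
    x = np.asarray(channels, dtype=float)
    rng = np.random.default_rng(seed)
    sd = sd_scale * x.std(axis=1, keepdims=True)
    mean = x.mean(axis=1, keepdims=True) if center == "mean" else 0.0
    return x + mean + rng.normal(0.0, 1.0, size=x.shape) * sd


def random_quantize(channels: np.ndarray, n_levels: int, seed: int = 0) -> np.ndarray:
    """Snap each channel onto ``n_levels`` levels spanning its own min-max.

    Levels are equally spaced; each sample maps to its nearest level, so
    the quantization error never exceeds the level spacing.  Constant
    channels are returned unchanged.
    """
    if n_levels < 2:
        raise ConfigurationError("n_levels must be >= 2")
    x = np.asarray(channels, dtype=float)
    out = x.copy()
    lo = x.min(axis=1)
    hi = x.max(axis=1)
    for c in range(x.shape[0]):
        if hi[c] - lo[c] < 1e-15:
            continue
        step = (hi[c] - lo[c]) / (n_levels - 1)
        out[c] = lo[c] + np.round((x[c] - lo[c]) / step) * step
    return out


def drift(channels: np.ndarray, max_drift: float, n_knots: int,
          seed: int) -> np.ndarray:
    """Add a smooth random offset curve to each channel.

    The curve interpolates ``n_knots`` offsets drawn uniformly in
    ``[-max_drift, +max_drift]`` at equally spaced times, using a
    shape-preserving (PCHIP) interpolant so the added drift never
    overshoots the knot range.
    """
    x = np.asarray(channels, dtype=float)
    rng = np.random.default_rng(seed)
    n = x.shape[1]
    knots_t = np.linspace(0, n - 1, n_knots)
    t = np.arange(n)
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        offsets = rng.uniform(-max_drift, max_drift, size=n_knots)
        out[c] = x[c] + PchipInterpolator(knots_t, offsets)(t)
    return out


def reverse(channels: np.ndarray) -> np.ndarray:
    """Render every channel backwards in time."""
    return np.asarray(channels, dtype=float)[:, ::-1].copy()


def make_views(channels: np.ndarray, config: AugmentConfig | None = None,
               seed: int = 0) -> ViewSet:
    """Build the five-member view set for one window.

    Per-view sub-seeds are spawned from ``seed`` so that each transform's
    randomness is independent yet fully reproducible.
    """
    config = config or AugmentConfig()
    x = np.asarray(channels, dtype=float)
    children = np.random.SeedSequence(seed).spawn(len(VIEW_NAMES))
    sub = {name: int(c.generate_state(1)[0] % (2 ** 31))
           for name, c in zip(VIEW_NAMES, children)}
    views = {
        "noise": add_white_noise(x, config.sd_scale, sub["noise"],
                                 center=config.noise_center),
        "quantize": random_quantize(x, config.n_levels, sub["quantize"]),
        "drift": drift(x, config.max_drift, config.n_knots, sub["drift"]),
        "reverse": reverse(x),
    }
    return ViewSet(original=x.copy(), views=views, seed=seed)
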