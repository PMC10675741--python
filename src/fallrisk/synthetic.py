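"""Synthetic ankle-IMU cohort generator with Berg-score-linked instability.

Emulates the sensor configuration of a stroke-rehabilitation gait study:
six channels (accelerometer m/s^2, gyroscope deg/s) at 40 Hz, observed
ranges within +/-40 m/s^2 and +/-260 deg/s, and a set of standardized
exercises with realistic durations.  Each subject carries a Berg balance
score in the observed 33-56 range; subjects with lower scores experience
instability events at a higher rate, so downstream stages can be tested
for the balance-score / fall-risk link without any clinical data.

An instability event is a short high-acceleration burst on the vertical
(y) accelerometer axis that rises from below 5 m/s^2 to above 15 m/s^2
within at most 300 ms — the signature the threshold-based reference
labeler is designed to detect.  The burst shape is a stand-in: the source
data do not characterize real events statistically (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocess import CHANNELS, ImuRecording, write_recording

#: Exercise catalogue: (name, mean duration s, sd s).
DEFAULT_ACTIVITIES: tuple[tuple[str, float, float], ...] = (
    ("six_minute_walk", 391.0, 13.0),
    ("get_up_and_go", 50.0, 29.0),
    ("one_foot_balance", 53.0, 31.0),
    ("step", 46.0, 27.0),
    ("leaning", 71.0, 6.0),
)

BERG_MIN, BERG_MAX = 33, 56

#: Event-rate link defaults: rate = R_MAX * (56 - berg) / 23 + R_MIN.
R_MAX_DEFAULT = 6.0
R_MIN_DEFAULT = 0.2

# Baseline gait amplitudes per channel (acc m/s^2, gyro deg/s).  Chosen so
# the event-free |acc_y| stays clearly below the 5 m/s^2 labeling level.
_BASE_AMPLITUDE = np.array([2.0, 2.5, 1.8, 30.0, 40.0, 25.0])
_HARMONIC_FRACTION = 0.4
_GYRO_NOISE_FACTOR = 10.0  # gyro noise sd relative to accel noise sd

_PARETIC_ASYMMETRY = {"left": 0.7, "right": 1.3, "none": 1.0}


@dataclass
class SubjectProfile:
    subject_id: str
    berg_score: int
    gait_group: int
    paretic_side: str
    step_frequency_hz: float
    event_rate_per_min: float

    def __post_init__(self) -> None:
        if not BERG_MIN <= self.berg_score <= BERG_MAX:
            raise ConfigurationError(
                f"berg_score {self.berg_score} outside [{BERG_MIN}, {BERG_MAX}]")
        if not 1 <= self.gait_group <= 5:
            raise ConfigurationError(f"gait_group {self.gait_group} outside [1, 5]")
        if self.paretic_side not in _PARETIC_ASYMMETRY:
            raise ConfigurationError(f"unknown paretic_side {self.paretic_side!r}")


@dataclass
class SimulationConfig:
    n_subjects: int = 27
    sampling_rate_hz: float = 40.0
    activities: tuple[tuple[str, float, float], ...] = DEFAULT_ACTIVITIES
    noise_sd: float = 0.3
    accel_clip: float = 40.0
    gyro_clip: float = 260.0
    event_rate_max: float = R_MAX_DEFAULT
    event_rate_min: float = R_MIN_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be positive")
        if self.accel_clip <= 0 or self.gyro_clip <= 0:
            raise ConfigurationError("clip ranges must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        for name, mean_s, sd_s in self.activities:
            if mean_s <= 0 or sd_s < 0:
                raise ConfigurationError(f"invalid duration for activity {name!r}")


def event_rate_link(berg_score: int, r_max: float = R_MAX_DEFAULT,
                    r_min: float = R_MIN_DEFAULT) -> float:
    """Linear, strictly decreasing link from Berg score to events/minute.

    A subject at the top of the observed range (56) gets the floor rate
    ``r_min``; a subject at the bottom (33) gets ``r_max + r_min``.
    """
    return r_max * (BERG_MAX - berg_score) / (BERG_MAX - BERG_MIN) + r_min


def sample_profiles(config: SimulationConfig) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles, deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    profiles = []
    for i in range(config.n_subjects):
        berg = int(rng.integers(BERG_MIN, BERG_MAX + 1))
        # Map the 24-point Berg range onto the 5 gait-quality groups.
        group = 1 + min(4, (berg - BERG_MIN) * 5 // (BERG_MAX - BERG_MIN + 1))
        side = str(rng.choice(["left", "right", "none"], p=[0.45, 0.45, 0.10]))
        freq = float(np.clip(rng.normal(0.6, 0.05), 0.45, 0.8))
        profiles.append(SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            berg_score=berg,
            gait_group=group,
            paretic_side=side,
            step_frequency_hz=freq,
            event_rate_per_min=event_rate_link(
                berg, config.event_rate_max, config.event_rate_min),
        ))
    return profiles


def _burst_shape(rng: np.random.Generator) -> np.ndarray:
    """One instability burst: 150-250 ms raised-sine reaching 18-34 m/s^2."""
    n = int(rng.integers(6, 11))  # samples at 40 Hz
    peak = rng.uniform(18.0, 34.0)
    sign = rng.choice([-1.0, 1.0])
    ramp = np.sin(np.pi * np.arange(n) / (n - 1)) ** 2
    return sign * peak * ramp


def generate_recording(
    profile: SubjectProfile,
    activity_name: str,
    duration_s: float,
    config: SimulationConfig,
    seed: int,
) -> tuple[ImuRecording, np.ndarray]:
    """Simulate one recording and its ground-truth instability instants.

    The base gait is a sinusoid at the subject's step frequency plus one
    harmonic whose amplitude is asymmetric by paretic side.  Instability
    events are Poisson-placed bursts on acc_y (with smaller echoes on the
    other axes); Gaussian sensor noise is added and channels are clipped
    to the configured ranges.  The returned instants are the sample
    indices where each injected burst first drives |acc_y| across
    5 m/s^2 — the same convention the threshold labeler uses.
    """
    if duration_s <= 0:
        raise ConfigurationError(f"duration_s must be positive, got {duration_s}")
    rng = np.random.default_rng(seed)
    rate = config.sampling_rate_hz
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate

    f = profile.step_frequency_hz
    asym = _PARETIC_ASYMMETRY[profile.paretic_side]
    phases = rng.uniform(0, 2 * np.pi, size=len(CHANNELS))
    phases2 = rng.uniform(0, 2 * np.pi, size=len(CHANNELS))
    sig = np.empty((len(CHANNELS), n))
    for c in range(len(CHANNELS)):
        amp = _BASE_AMPLITUDE[c]
        sig[c] = amp * np.sin(2 * np.pi * f * t + phases[c])
        sig[c] += _HARMONIC_FRACTION * amp * asym * np.sin(
            4 * np.pi * f * t + phases2[c])

    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=sig.shape)
        noise[3:] *= _GYRO_NOISE_FACTOR
        sig += noise

    # Poisson-placed bursts, kept >= 1 s apart and away from the edges.
    n_events = int(rng.poisson(profile.event_rate_per_min * duration_s / 60.0))
    margin = int(rate)  # 1 s
    truth: list[int] = []
    if n_events > 0 and n > 3 * margin:
        candidates = rng.integers(margin, n - margin, size=4 * n_events)
        starts: list[int] = []
        for s in np.sort(candidates):
            if all(abs(s - p) >= rate for p in starts):
                starts.append(int(s))
            if len(starts) == n_events:
                break
        order = rng.permutation(len(starts))  # burst draws independent of position
        for k in order:
            s = starts[k]
            burst = _burst_shape(rng)
            stop = min(n, s + len(burst))
            seg = burst[:stop - s]
            sig[1, s:stop] += seg
            sig[0, s:stop] += 0.3 * seg
            sig[2, s:stop] += 0.3 * seg
            sig[4, s:stop] += 3.0 * seg
            crossing = np.flatnonzero(np.abs(sig[1, s:stop]) >= 5.0)
            if crossing.size:
                truth.append(s + int(crossing[0]))

    sig[:3] = np.clip(sig[:3], -config.accel_clip, config.accel_clip)
    sig[3:] = np.clip(sig[3:], -config.gyro_clip, config.gyro_clip)
    rec = ImuRecording(subject_id=profile.subject_id, activity=activity_name,
                       rate_hz=rate, channels=sig)
    return rec, np.array(sorted(truth), dtype=int)


@dataclass
class SyntheticRecording:
    """A simulated recording bundled with its provenance and ground truth."""

    profile: SubjectProfile
    activity: str
    recording: ImuRecording
    injected_events: np.ndarray


def simulate_cohort(config: SimulationConfig) -> list[SyntheticRecording]:
    """Simulate every (subject, activity) recording in memory.

    Durations are drawn per recording from the activity's mean/sd
    (truncated at 12 s so every recording holds at least one window).
    Deterministic given ``config.seed``: per-recording seeds are spawned
    from a root :class:`numpy.random.SeedSequence`.
    """
    profiles = sample_profiles(config)
    root = np.random.SeedSequence(config.seed)
    dur_rng = np.random.default_rng(root.spawn(1)[0])
    child_seeds = root.spawn(len(profiles) * len(config.activities))
    out: list[SyntheticRecording] = []
    k = 0
    for profile in profiles:
        for name, mean_s, sd_s in config.activities:
            duration = max(12.0, dur_rng.normal(mean_s, sd_s))
            seed = int(child_seeds[k].generate_state(1)[0] % (2 ** 31))
            k += 1
            rec, truth = generate_recording(profile, name, duration, config, seed)
            out.append(SyntheticRecording(profile, name, rec, truth))
    return out


def generate_cohort(config: SimulationConfig, out_dir) -> pd.DataFrame:
    """Write a full synthetic cohort to ``out_dir`` and return the manifest.

    One CSV per (subject, activity) plus ``metadata.csv`` holding the
    subject profile, file name, and the injected ground-truth instants
    (semicolon-separated sample indices).  Byte-identical across reruns
    with the same config and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sr in simulate_cohort(config):
        fname = f"{sr.profile.subject_id}_{sr.activity}.csv"
        write_recording(sr.recording, out_dir / fname)
        rows.append({
            "subject_id": sr.profile.subject_id,
            "activity": sr.activity,
            "berg_score": sr.profile.berg_score,
            "gait_group": sr.profile.gait_group,
            "paretic_side": sr.profile.paretic_side,
            "step_frequency_hz": sr.profile.step_frequency_hz,
            "event_rate_per_min": sr.profile.event_rate_per_min,
            "rate_hz": sr.recording.rate_hz,
            "n_samples": sr.recording.length,
            "file": fname,
            "injected_events": ";".join(str(i) for i in sr.injected_events),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "metadata.csv", index=False)
    return manifest


def load_cohort(data_dir) -> list[SyntheticRecording]:
    """Reload a cohort previously written by :func:`generate_cohort`."""
    from .preprocess import read_recording

    data_dir = Path(data_dir)
    meta_path = data_dir / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.csv in {data_dir}")
    meta = pd.read_csv(meta_path)
    out = []
    for row in meta.itertuples():
        rec = read_recording(data_dir / row.file, subject_id=row.subject_id,
                             activity=row.activity)
        profile = SubjectProfile(
            subject_id=row.subject_id,
            berg_score=int(row.berg_score),
            gait_group=int(row.gait_group),
            paretic_side=row.paretic_side,
            step_frequency_hz=float(row.step_frequency_hz),
            event_rate_per_min=float(row.event_rate_per_min),
        )
        out.append(SyntheticRecording(
            profile=profile, activity=row.activity, recording=rec,
            injected_events=parse_injected_events(row.injected_events)))
    return out


def parse_injected_events(cell) -> np.ndarray:
    """Decode the semicolon-separated event instants from a metadata cell."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return np.array([], dtype=int)
    return np.array([int(x) for x in str(cell).split(";")], dtype=int)
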