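"""Synthetic accelerometer data with the structure of the three activities.

The generator emulates the qualitative signatures of the real signals so the
whole pipeline is testable without field data:

digging
    The lateral axis approximates a periodic square wave produced by the
    alternating turnover of the posterior paws — two waves per ~90 s
    (period 45 s), with per-wave period jitter mimicking between-individual
    frequency variation, plus additive sensor noise.
walking
    Chaotic, aperiodic oscillation of the carapace; modeled as a
    mean-reverting AR(1) (Ornstein-Uhlenbeck) process with a short
    correlation time, lightly smoothed.  A pure random walk would stay
    correlated over minutes, which the real signal is not.
eating
    Near-constant signal: baseline plus small sensor noise.

All outputs are integer counts at 4 Hz, deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .preprocessing import PreprocessConfig
from .signal import (
    AccelerometerSequence,
    DatasetSplit,
    SplitCounts,
    make_split,
)

__all__ = [
    "SimConfig",
    "ClassCounts",
    "gen_digging",
    "gen_walking",
    "gen_eating",
    "gen_sequences",
    "gen_benchmark",
]


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the generator.

    wave_period_s
        Square-wave period; 45 s puts two full waves in one 90 s window.
    amplitude
        Square-wave half-height in raw counts.
    baseline
        Resting count level of the sensor.
    noise_sd
        Additive Gaussian sensor noise (counts).
    walk_scale
        Standard deviation of the walking oscillation (counts).
    period_jitter
        Uniform relative jitter of each wave's period (+/-20% by default),
        emulating frequency variation across individuals.
    """

    rate_hz: int = 4
    wave_period_s: float = 45.0
    amplitude: int = 40
    baseline: int = 100
    noise_sd: float = 3.0
    walk_scale: float = 25.0
    period_jitter: float = 0.2
    duration_s: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz < 1:
            raise ValueError("rate_hz must be >= 1")
        if self.wave_period_s <= 0:
            raise ValueError("wave_period_s must be positive")
        if self.amplitude < 1:
            raise ValueError("amplitude must be a positive integer")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.walk_scale <= 0:
            raise ValueError("walk_scale must be positive")
        if not (0 <= self.period_jitter < 1):
            raise ValueError("period_jitter must be in [0, 1)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))


def _round_int(x: np.ndarray) -> np.ndarray:
    return np.rint(x).astype(np.int64)


def gen_digging(cfg: SimConfig, id: str = "dig-0") -> AccelerometerSequence:
    """Square-wave digging signal with per-wave period jitter and noise."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    x = np.empty(n, dtype=float)
    pos = 0
    level = +1  # start in the high phase of the wave
    while pos < n:
        period = cfg.wave_period_s
        if cfg.period_jitter:
            period *= 1.0 + rng.uniform(-cfg.period_jitter, cfg.period_jitter)
        half = max(1, int(round(period * cfg.rate_hz / 2)))
        for phase_level in (level, -level):
            take = min(half, n - pos)
            if take <= 0:
                break
            x[pos : pos + take] = phase_level * cfg.amplitude
            pos += take
    if cfg.noise_sd:
        x += rng.normal(0.0, cfg.noise_sd, size=n)
    return AccelerometerSequence(
        samples_x=_round_int(cfg.baseline + x),
        rate_hz=cfg.rate_hz,
        label="digging",
        id=id,
    )


#: Correlation time of the walking oscillation, seconds.  Tortoise gait
#: cadence is on the order of 0.5-1 Hz, so the carapace oscillation
#: decorrelates within a couple of seconds — fast and irregular at the
#: 1 Hz analysis rate, unlike the 22 s half-plateaus of digging.
_WALK_CORR_TIME_S = 2.0
#: Light smoothing applied to the walking process, samples.
_WALK_SMOOTH_POINTS = 5


def gen_walking(cfg: SimConfig, id: str = "walk-0") -> AccelerometerSequence:
    """Aperiodic mean-reverting oscillation of scale ``walk_scale``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    rho = math.exp(-1.0 / (_WALK_CORR_TIME_S * cfg.rate_hz))
    eps = rng.normal(0.0, 1.0, size=n)
    # stationary unit-variance AR(1), then light boxcar smoothing
    x = lfilter([math.sqrt(1.0 - rho**2)], [1.0, -rho], eps)
    kernel = np.ones(_WALK_SMOOTH_POINTS) / _WALK_SMOOTH_POINTS
    x = np.convolve(x, kernel, mode="same")
    x *= cfg.walk_scale / max(np.std(x), 1e-12)
    if cfg.noise_sd:
        x += rng.normal(0.0, cfg.noise_sd, size=n)
    return AccelerometerSequence(
        samples_x=_round_int(cfg.baseline + x),
        rate_hz=cfg.rate_hz,
        label="walking",
        id=id,
    )


def gen_eating(cfg: SimConfig, id: str = "eat-0") -> AccelerometerSequence:
    """Near-constant signal: baseline plus sensor noise only."""
    rng = np.random.default_rng(cfg.seed)
    x = np.full(cfg.n_samples, float(cfg.baseline))
    if cfg.noise_sd:
        x += rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples)
    return AccelerometerSequence(
        samples_x=_round_int(x),
        rate_hz=cfg.rate_hz,
        label="eating",
        id=id,
    )


_GENERATORS = {
    "digging": gen_digging,
    "walking": gen_walking,
    "eating": gen_eating,
}


@dataclass(frozen=True)
class ClassCounts:
    """Number of sequences per activity class.

    Defaults mirror the composition of the field campaign: 62 digging,
    15 walking, 6 eating sequences.
    """

    digging: int = 62
    walking: int = 15
    eating: int = 6


def gen_sequences(
    cfg: SimConfig,
    composition: ClassCounts | None = None,
    seed: int | None = None,
    durations_s: dict[str, float] | None = None,
) -> list[AccelerometerSequence]:
    """Generate a labelled collection of sequences, one seed per sequence."""
    composition = composition or ClassCounts()
    master = np.random.default_rng(cfg.seed if seed is None else seed)
    seqs: list[AccelerometerSequence] = []
    for label in ("digging", "walking", "eating"):
        count = getattr(composition, label)
        duration = (durations_s or {}).get(label, cfg.duration_s)
        for i in range(count):
            sub_seed = int(master.integers(0, 2**31 - 1))
            sub = replace(cfg, seed=sub_seed, duration_s=duration)
            seqs.append(_GENERATORS[label](sub, id=f"{label[:4]}-{i:03d}"))
    return seqs


def gen_benchmark(
    cfg: SimConfig | None = None,
    composition: ClassCounts | None = None,
    seed: int = 0,
    counts: SplitCounts | None = None,
    pre_cfg: PreprocessConfig | None = None,
) -> tuple[list[AccelerometerSequence], DatasetSplit]:
    """Generate a full synthetic benchmark dataset and its protocol split.

    Sequence durations are sized so the composition yields enough 300-step
    segments per class for the requested split (default part sizes
    134 / 20 / 30 / 56).  Returns the raw 4 Hz sequences and the split.
    """
    cfg = cfg or SimConfig()
    composition = composition or ClassCounts()
    counts = counts or SplitCounts()
    pre_cfg = pre_cfg or PreprocessConfig()

    need = counts.per_class_segments()
    if composition.digging < 1 and need > 0:
        raise ValueError("no digging sequences requested but positive patterns needed")
    n_neg_seqs = composition.walking + composition.eating
    if n_neg_seqs < 1 and need > 0:
        raise ValueError("no non-digging sequences requested but negatives needed")

    def duration_for(n_seqs: int) -> float:
        per_seq = math.ceil(need / n_seqs)
        # raw duration so that after down-sampling per_seq segments fit
        return per_seq * pre_cfg.segment_len * pre_cfg.downsample_factor / cfg.rate_hz

    durations = {
        "digging": duration_for(composition.digging),
        "walking": duration_for(n_neg_seqs),
        "eating": duration_for(n_neg_seqs),
    }
    seqs = gen_sequences(cfg, composition, seed=seed, durations_s=durations)
    split = make_split(seqs, counts=counts, seed=seed, preprocess_config=pre_cfg)
    return seqs, split
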