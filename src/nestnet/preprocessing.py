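"""Signal preprocessing: moving-average filter, integer normalization,
down-sampling, and segment/window extraction.

The chain takes the raw 4 Hz integer stream to the 1 Hz integer stream the
classifier consumes: a 5-point centered moving average suppresses sensor
noise, the per-sequence mean is subtracted in integer arithmetic (keeping
the stream integer-valued for memory-constrained devices), and every 4th
sample is kept.  Segments (300 steps) and shifted windows (90 steps, shift
22) are then cut from the 1 Hz signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signal import AccelerometerSequence, Segment, Window

__all__ = [
    "PreprocessConfig",
    "moving_average",
    "normalize_integer",
    "downsample",
    "extract_segments",
    "extract_windows",
    "preprocess_sequence",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain and window geometry.

    ma_points
        Width of the centered moving-average filter (samples at the raw rate).
    downsample_factor
        Keep every k-th filtered sample; 4 maps 4 Hz to 1 Hz.
    window_len
        Input-window length in 1 Hz steps (the length of the characteristic
        two-wave digging pattern).
    segment_len
        Segment length in 1 Hz steps; the unit of final classification.
    shift
        Window shift in steps — one quarter of the window, 22.
    """

    ma_points: int = 5
    downsample_factor: int = 4
    window_len: int = 90
    segment_len: int = 300
    shift: int = 22

    def __post_init__(self) -> None:
        if self.ma_points < 1:
            raise ValueError("ma_points must be >= 1")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.shift < 1:
            raise ValueError("shift must be >= 1")
        if self.window_len > self.segment_len:
            raise ValueError("window_len must not exceed segment_len")


def moving_average(samples, points: int = 5) -> np.ndarray:
    """Centered moving-average (boxcar) filter with boundary truncation.

    Output has the same length as the input.  Each output value is the mean
    of the centered window of up to ``points`` input values; at the edges
    the window is truncated to the samples that exist.
    """
    if points < 1:
        raise ValueError("points must be >= 1")
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("samples must be a non-empty 1-D sequence")
    half = (points - 1) // 2
    # cumulative-sum formulation of the truncated centered boxcar
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (points - half), x.size)  # exclusive
    return (csum[hi] - csum[lo]) / (hi - lo)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; the device arithmetic rounds half away
    # from zero.
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def normalize_integer(samples) -> np.ndarray:
    """Subtract the (rounded) sequence mean, keeping integer samples.

    This is deliberately not a unit-variance normalization: centring in
    integer arithmetic keeps the network input an integer stream, which is
    what makes the embedded implementation cheap.  Rounds half away from
    zero.  Output mean is within +/-1 of zero.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("samples must be a non-empty 1-D sequence")
    centre = _round_half_away(np.asarray(np.mean(x)))
    return (_round_half_away(x) - centre).astype(np.int64)


def downsample(samples, factor: int) -> np.ndarray:
    """Keep indices 0, factor, 2*factor, ...; output length ceil(n/factor)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    x = np.asarray(samples)
    if x.ndim != 1:
        raise ValueError("samples must be 1-D")
    return x[::factor]


def extract_segments(seq: AccelerometerSequence, segment_len: int = 300) -> list[Segment]:
    """Cut non-overlapping consecutive segments from a 1 Hz sequence.

    A trailing remainder shorter than ``segment_len`` is discarded; a
    sequence shorter than one segment yields an empty list.
    """
    if seq.rate_hz != 1:
        raise ValueError(
            f"extract_segments expects a 1 Hz sequence, got {seq.rate_hz} Hz"
        )
    n = len(seq)
    return [
        Segment(
            samples=seq.samples_x[off : off + segment_len],
            source_id=seq.id,
            offset=off,
            label=seq.label,
        )
        for off in range(0, n - segment_len + 1, segment_len)
    ]


def extract_windows(segment, window_len: int = 90, shift: int = 22) -> list[Window]:
    """Slide a window of ``window_len`` over a segment in steps of ``shift``.

    Windows start at offsets 0, shift, 2*shift, ... while they fit; count is
    floor((L - window_len)/shift) + 1.  With the default geometry a 300-step
    segment yields 10 windows.
    """
    if shift < 1:
        raise ValueError("shift must be >= 1")
    samples = segment.samples if isinstance(segment, Segment) else np.asarray(segment)
    L = len(samples)
    if L < window_len:
        raise ValueError(f"segment length {L} is shorter than window {window_len}")
    return [
        Window(samples=samples[off : off + window_len], offset=off)
        for off in range(0, L - window_len + 1, shift)
    ]


def preprocess_sequence(
    seq: AccelerometerSequence, cfg: PreprocessConfig | None = None
) -> AccelerometerSequence:
    """Run the full chain filter -> normalize -> down-sample on a raw sequence.

    The chain applies to the x axis (and identically to the y axis when
    present, which is retained but unused downstream); the rate metadata is
    divided by the down-sampling factor.
    """
    cfg = cfg or PreprocessConfig()

    def chain(x: np.ndarray) -> np.ndarray:
        filtered = moving_average(x, cfg.ma_points)
        centred = normalize_integer(filtered)
        return downsample(centred, cfg.downsample_factor)

    return AccelerometerSequence(
        samples_x=chain(seq.samples_x),
        samples_y=chain(seq.samples_y) if seq.samples_y is not None else None,
        rate_hz=seq.rate_hz / cfg.downsample_factor,
        label=seq.label,
        id=seq.id,
    )
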