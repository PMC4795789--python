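"""Core data types for accelerometer sequences, segments, patterns and splits.

The sensing device records lateral (x-axis) acceleration of the tortoise
carapace as raw integer counts at 4 Hz.  After preprocessing the signal runs
at 1 Hz; fixed 300-step segments are the unit of final classification and
90-step windows/patterns are the unit the neural network sees.

Sequences are stored in a flat, diffable text format: one file holds any
number of sequences, each introduced by ``#id=``, ``#label=`` and
``#rate_hz=`` header lines followed by ``t,x[,y]`` rows of integer samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LABELS",
    "AccelerometerSequence",
    "Segment",
    "Pattern",
    "Window",
    "SplitCounts",
    "DatasetSplit",
    "SequenceFormatError",
    "SplitShortfallError",
    "read_sequences",
    "write_sequences",
    "characteristic_pattern_offset",
    "make_split",
]

#: Closed activity vocabulary.  "digging" is the positive class.
LABELS = ("digging", "walking", "eating")

#: Sampling rates the system uses: 4 Hz at collection, 1 Hz after down-sampling.
VALID_RATES = (4, 1)


class SequenceFormatError(ValueError):
    """Raised when a sequence file cannot be parsed."""


class SplitShortfallError(ValueError):
    """Raised when a dataset cannot satisfy the requested split sizes."""


def _as_int_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        rounded = np.asarray(arr, dtype=float)
        if not np.allclose(rounded, np.round(rounded)):
            raise ValueError(f"{name} must contain integer samples")
        arr = np.round(rounded).astype(np.int64)
    return arr.astype(np.int64)


@dataclass
class AccelerometerSequence:
    """A labelled accelerometer time series of raw integer counts.

    Parameters
    ----------
    samples_x
        Lateral-axis samples, the only axis the classifier uses.
    rate_hz
        Sampling rate; 4 at collection, 1 after down-sampling.
    label
        One of ``digging``, ``walking``, ``eating``.
    id
        Free-text identifier, unique within a dataset file.
    samples_y
        Optional second axis; ingested and carried along but never used
        by the models.
    """

    samples_x: np.ndarray
    rate_hz: float
    label: str
    id: str
    samples_y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples_x = _as_int_array(self.samples_x, "samples_x")
        if self.samples_x.size == 0:
            raise ValueError(f"sequence {self.id!r}: samples_x is empty")
        if self.samples_y is not None:
            self.samples_y = _as_int_array(self.samples_y, "samples_y")
            if self.samples_y.size != self.samples_x.size:
                raise ValueError(
                    f"sequence {self.id!r}: x and y axes differ in length "
                    f"({self.samples_x.size} vs {self.samples_y.size})"
                )
        if self.label not in LABELS:
            raise ValueError(
                f"sequence {self.id!r}: unknown label {self.label!r}; "
                f"expected one of {LABELS}"
            )
        if self.rate_hz not in VALID_RATES:
            raise ValueError(
                f"sequence {self.id!r}: rate_hz must be one of {VALID_RATES}, "
                f"got {self.rate_hz}"
            )

    def __len__(self) -> int:
        return int(self.samples_x.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate_hz

    @property
    def is_digging(self) -> bool:
        return self.label == "digging"


@dataclass
class Segment:
    """A fixed-length (default 300-step) slice of a 1 Hz sequence."""

    samples: np.ndarray
    source_id: str
    offset: int
    label: str

    def __post_init__(self) -> None:
        self.samples = _as_int_array(self.samples, "samples")
        if self.samples.size == 0:
            raise ValueError("segment has no samples")
        if self.offset < 0:
            raise ValueError("segment offset must be non-negative")
        if self.label not in LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def key(self) -> tuple[str, int]:
        """Identity of the segment within its dataset (source id, offset)."""
        return (self.source_id, self.offset)

    @property
    def is_digging(self) -> bool:
        return self.label == "digging"


@dataclass
class Window:
    """An unlabelled input window sliced from a segment."""

    samples: np.ndarray
    offset: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("window has no samples")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass
class Pattern:
    """A labelled training exemplar: one window plus a +/-1 target.

    Target +1 marks the characteristic digging pattern (two square waves in
    ~90 s); -1 marks non-digging windows.  ``source_key`` tracks the segment
    the pattern was cut from so split disjointness can be audited.
    """

    samples: np.ndarray
    target: int
    source_key: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        self.samples = _as_int_array(self.samples, "samples")
        if self.samples.size == 0:
            raise ValueError("pattern has no samples")
        if self.target not in (+1, -1):
            raise ValueError(f"pattern target must be +1 or -1, got {self.target}")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class SplitCounts:
    """Per-class sizes of the four dataset parts.

    Defaults are the benchmark protocol: 67+67 training patterns, 10+10
    validation patterns, 15+15 filter-calibration segments, 28+28 test
    segments.
    """

    train_patterns: int = 67
    val_patterns: int = 10
    filter_segments: int = 15
    test_segments: int = 28

    def per_class_segments(self) -> int:
        return (
            self.train_patterns
            + self.val_patterns
            + self.filter_segments
            + self.test_segments
        )


@dataclass
class DatasetSplit:
    """The four disjoint dataset parts used by the training protocol."""

    ann_train: list[Pattern]
    ann_validation: list[Pattern]
    filter_validation: list[Segment]
    test: list[Segment]

    def part_sizes(self) -> tuple[int, int, int, int]:
        return (
            len(self.ann_train),
            len(self.ann_validation),
            len(self.filter_validation),
            len(self.test),
        )

    def validate_disjoint(self) -> None:
        """Raise if any two parts share a source segment."""
        parts = {
            "ann_train": {p.source_key for p in self.ann_train},
            "ann_validation": {p.source_key for p in self.ann_validation},
            "filter_validation": {s.key for s in self.filter_validation},
            "test": {s.key for s in self.test},
        }
        names = list(parts)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                shared = parts[a] & parts[b]
                if shared:
                    raise ValueError(f"split parts {a} and {b} share segments {shared}")


# ---------------------------------------------------------------------------
# Sequence file format
# ---------------------------------------------------------------------------

def write_sequences(seqs: Iterable[AccelerometerSequence], path) -> None:
    """Write sequences to the flat text format readable by :func:`read_sequences`."""
    path = Path(path)
    lines: list[str] = []
    for seq in seqs:
        lines.append(f"#id={seq.id}")
        lines.append(f"#label={seq.label}")
        rate = seq.rate_hz
        lines.append(f"#rate_hz={int(rate) if rate == int(rate) else rate}")
        if seq.samples_y is None:
            for t, x in enumerate(seq.samples_x):
                lines.append(f"{t},{x}")
        else:
            for t, (x, y) in enumerate(zip(seq.samples_x, seq.samples_y)):
                lines.append(f"{t},{x},{y}")
    path.write_text("\n".join(lines) + "\n")


def read_sequences(path) -> list[AccelerometerSequence]:
    """Read sequences from the flat text format.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SequenceFormatError
        On malformed rows (the error names the offending line), unknown
        labels, or a header with no data rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    sequences: list[AccelerometerSequence] = []
    header: dict[str, str] = {}
    xs: list[int] = []
    ys: list[int] = []
    start_line = 0

    def flush(end_line: int) -> None:
        if not header:
            return
        if not xs:
            raise SequenceFormatError(
                f"{path}: sequence {header.get('id', '?')!r} starting at line "
                f"{start_line} has an empty data section"
            )
        for key in ("id", "label", "rate_hz"):
            if key not in header:
                raise SequenceFormatError(
                    f"{path}: sequence starting at line {start_line} lacks "
                    f"a #{key}= header"
                )
        try:
            rate = float(header["rate_hz"])
        except ValueError as exc:
            raise SequenceFormatError(
                f"{path}: bad #rate_hz= value {header['rate_hz']!r} near line "
                f"{start_line}"
            ) from exc
        try:
            seq = AccelerometerSequence(
                samples_x=np.array(xs, dtype=np.int64),
                samples_y=np.array(ys, dtype=np.int64) if ys else None,
                rate_hz=rate,
                label=header["label"],
                id=header["id"],
            )
        except ValueError as exc:
            raise SequenceFormatError(f"{path}: {exc}") from exc
        sequences.append(seq)

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#id="):
                flush(lineno)
                header = {"id": line[4:]}
                xs, ys = [], []
                start_line = lineno
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise SequenceFormatError(
                        f"{path}:{lineno}: malformed header line {line!r}"
                    )
                key, _, value = line[1:].partition("=")
                header[key] = value
                continue
            fields = line.split(",")
            if len(fields) not in (2, 3):
                raise SequenceFormatError(
                    f"{path}:{lineno}: expected 't,x' or 't,x,y', got {line!r}"
                )
            try:
                values = [int(f) for f in fields]
            except ValueError as exc:
                raise SequenceFormatError(
                    f"{path}:{lineno}: non-integer sample in row {line!r}"
                ) from exc
            xs.append(values[1])
            if len(values) == 3:
                ys.append(values[2])
            elif ys:
                raise SequenceFormatError(
                    f"{path}:{lineno}: row drops the y column mid-sequence"
                )
    flush(-1)
    if not sequences:
        raise SequenceFormatError(f"{path}: no sequences found")
    return sequences


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------

def characteristic_pattern_offset(samples, window_len: int) -> int:
    """Offset of a wave-onset-aligned window within a digging segment.

    The training exemplars of the positive class are *characteristic
    patterns*: two full square waves starting at a wave onset, not windows
    cut at arbitrary phase.  The onset is located as the first upward
    crossing into the high plateau (half the peak magnitude); if no such
    crossing fits a full window, the segment start is used.
    """
    x = np.asarray(samples, dtype=float)
    peak = np.max(np.abs(x))
    if peak <= 0 or x.size < window_len:
        return 0
    th = 0.5 * peak
    above = x >= th
    for i in range(1, x.size - window_len + 1):
        if above[i] and not above[i - 1]:
            return i
    return 0


def make_split(
    seqs: Sequence[AccelerometerSequence],
    counts: SplitCounts | None = None,
    seed: int = 0,
    preprocess_config=None,
    align_jitter: int = 3,
) -> DatasetSplit:
    """Partition segments of ``seqs`` into the four disjoint protocol parts.

    Sequences still at 4 Hz are run through the preprocessing chain first.
    Segments are pooled per class (digging = positive), shuffled with
    ``seed``, and dealt out as: test segments, filter-validation segments,
    validation patterns, training patterns — class-balanced throughout.
    Each pattern is one window of its source segment, so parts stay
    disjoint by source segment.  Positive patterns are onset-aligned via
    :func:`characteristic_pattern_offset` plus a small uniform jitter of
    up to ``align_jitter`` steps, emulating the imprecision of picking the
    characteristic two-wave excerpt by eye; negative patterns are sampled
    at a uniform random offset within their segment.

    Raises
    ------
    SplitShortfallError
        If either class has fewer segments than the counts require.
    """
    from .preprocessing import (  # local import: preprocessing depends on signal
        PreprocessConfig,
        extract_segments,
        preprocess_sequence,
    )

    counts = counts or SplitCounts()
    cfg = preprocess_config or PreprocessConfig()

    pos: list[Segment] = []
    neg: list[Segment] = []
    for seq in seqs:
        if seq.rate_hz != 1:
            seq = preprocess_sequence(seq, cfg)
        segments = extract_segments(seq, cfg.segment_len)
        (pos if seq.is_digging else neg).append(segments)
    pos = [s for group in pos for s in group]
    neg = [s for group in neg for s in group]

    need = counts.per_class_segments()
    for name, pool in (("positive (digging)", pos), ("negative", neg)):
        if len(pool) < need:
            raise SplitShortfallError(
                f"need {need} {name} segments but only {len(pool)} available"
            )

    rng = np.random.default_rng(seed)
    order_pos = rng.permutation(len(pos))
    order_neg = rng.permutation(len(neg))
    pos = [pos[i] for i in order_pos]
    neg = [neg[i] for i in order_neg]

    def deal(pool: list[Segment], n: int) -> list[Segment]:
        out = pool[:n]
        del pool[:n]
        return out

    test = deal(pos, counts.test_segments) + deal(neg, counts.test_segments)
    filt = deal(pos, counts.filter_segments) + deal(neg, counts.filter_segments)
    val_seg = deal(pos, counts.val_patterns) + deal(neg, counts.val_patterns)
    train_seg = deal(pos, counts.train_patterns) + deal(neg, counts.train_patterns)

    def to_patterns(segments: list[Segment]) -> list[Pattern]:
        pats = []
        for s in segments:
            if s.is_digging:
                off = characteristic_pattern_offset(s.samples, cfg.window_len)
                if align_jitter:
                    off += int(rng.integers(-align_jitter, align_jitter + 1))
                off = min(max(off, 0), len(s) - cfg.window_len)
            else:
                off = int(rng.integers(0, len(s) - cfg.window_len + 1))
            pats.append(
                Pattern(
                    samples=s.samples[off : off + cfg.window_len],
                    target=+1 if s.is_digging else -1,
                    source_key=s.key,
                )
            )
        return pats

    split = DatasetSplit(
        ann_train=to_patterns(train_seg),
        ann_validation=to_patterns(val_seg),
        filter_validation=filt,
        test=test,
    )
    split.validate_disjoint()
    return split
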