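"""Segment-level filter over the network's output stream.

A segment produces a stream of 10 window scores in [-1, +1].  Three cheap
features summarize it:

``NP``
    number of strictly positive scores,
``MP``
    sum of positive scores divided by the stream length,
``MPT``
    sum of scores strictly above an inner threshold tau, divided by the
    stream length.

tau is calibrated as the mean of the positive scores pooled over a
validation set of streams; the MP and MPT decision bounds are the midpoint
of the gap between the highest negative-segment value and the lowest
positive-segment value (falling back to an accuracy-maximizing scan when
the two groups overlap).  A segment is called digging when at least two of
the three feature votes are positive: NP >= np_bound (default 2),
MP > mp_bound, MPT > mpt_bound.  "Positive value" means strictly greater
than zero throughout, and a vote bound is exceeded strictly — boundary
cases resolve toward non-digging.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

__all__ = [
    "OutputStream",
    "FilterThresholds",
    "CalibrationError",
    "feature_np",
    "feature_mp",
    "feature_mpt",
    "calibrate_tau",
    "calibrate_bounds",
    "calibrate_thresholds",
    "classify_segment",
]

DIGGING = "digging"
NON_DIGGING = "non-digging"


class CalibrationError(ValueError):
    """Raised when threshold calibration is impossible on the given data."""


@dataclass
class OutputStream:
    """Ordered window scores over one segment, each in [-1, +1]."""

    values: np.ndarray
    segment_ref: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("stream values must be 1-D")
        if self.values.size and (
            self.values.min() < -1.0 or self.values.max() > 1.0
        ):
            raise ValueError("stream values must lie in [-1, +1]")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class FilterThresholds:
    """Calibrated decision bounds of the three-feature vote."""

    tau: float
    mp_bound: float
    mpt_bound: float
    np_bound: int = 2

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.np_bound < 1:
            raise ValueError("np_bound must be >= 1")

    def to_json(self) -> str:
        return json.dumps(
            {
                "tau": self.tau,
                "mp_bound": self.mp_bound,
                "mpt_bound": self.mpt_bound,
                "np_bound": self.np_bound,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FilterThresholds":
        d = json.loads(text)
        return cls(
            tau=d["tau"],
            mp_bound=d["mp_bound"],
            mpt_bound=d["mpt_bound"],
            np_bound=int(d.get("np_bound", 2)),
        )


def _values(stream) -> np.ndarray:
    v = stream.values if isinstance(stream, OutputStream) else np.asarray(stream, float)
    if v.size == 0:
        raise ValueError("empty output stream")
    return v


def feature_np(stream) -> int:
    """Number of strictly positive values in the stream."""
    return int(np.sum(_values(stream) > 0))


def feature_mp(stream) -> float:
    """Sum of strictly positive values divided by the stream length."""
    v = _values(stream)
    return float(np.sum(v[v > 0]) / v.size)


def feature_mpt(stream, tau: float) -> float:
    """Sum of values strictly above tau divided by the stream length."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    v = _values(stream)
    return float(np.sum(v[v > tau]) / v.size)


def calibrate_tau(validation_streams) -> float:
    """Mean of the strictly positive values pooled over validation streams."""
    pooled = [
        x for stream in validation_streams for x in _values(stream) if x > 0
    ]
    if not pooled:
        raise CalibrationError("no positive values in validation streams")
    return float(np.mean(pooled))


def calibrate_bounds(pos_features, neg_features) -> float:
    """Decision bound between positive- and negative-segment feature values.

    If the groups are separated by a gap the bound is the midpoint of the
    gap, which separates the validation data perfectly.  When they overlap
    the bound maximizing validation accuracy (feature > bound votes
    positive) is found by an exhaustive scan of cut points, taking the
    lowest bound on ties.
    """
    pos = np.asarray(list(pos_features), dtype=float)
    neg = np.asarray(list(neg_features), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise CalibrationError("both feature groups must be non-empty")
    if neg.max() < pos.min():
        return float((neg.max() + pos.min()) / 2.0)
    # overlap: scan candidate cuts (every observed value, plus one cut
    # below all of them) for maximal accuracy under the strict > rule
    allv = np.concatenate([pos, neg])
    candidates = np.concatenate([[allv.min() - 1.0], np.unique(allv)])
    best_bound, best_acc = None, -1.0
    for c in candidates:
        acc = (np.sum(pos > c) + np.sum(neg <= c)) / (pos.size + neg.size)
        if acc > best_acc:  # strict: keeps the lowest bound on ties
            best_bound, best_acc = float(c), float(acc)
    return best_bound


def calibrate_thresholds(
    pos_streams,
    neg_streams,
    np_bound: int = 2,
) -> FilterThresholds:
    """Full calibration from filter-validation streams.

    tau is the pooled positive mean over *all* validation streams; the MP
    and MPT bounds come from :func:`calibrate_bounds` on the per-segment
    feature values of the positive vs negative streams.
    """
    pos_streams = list(pos_streams)
    neg_streams = list(neg_streams)
    tau = calibrate_tau(pos_streams + neg_streams)
    mp_bound = calibrate_bounds(
        [feature_mp(s) for s in pos_streams],
        [feature_mp(s) for s in neg_streams],
    )
    mpt_bound = calibrate_bounds(
        [feature_mpt(s, tau) for s in pos_streams],
        [feature_mpt(s, tau) for s in neg_streams],
    )
    return FilterThresholds(
        tau=tau, mp_bound=mp_bound, mpt_bound=mpt_bound, np_bound=np_bound
    )


def classify_segment(stream, thresholds: FilterThresholds) -> str:
    """Two-of-three vote: digging iff at least two feature votes pass."""
    votes = (
        feature_np(stream) >= thresholds.np_bound,
        feature_mp(stream) > thresholds.mp_bound,
        feature_mpt(stream, thresholds.tau) > thresholds.mpt_bound,
    )
    return DIGGING if sum(votes) >= 2 else NON_DIGGING
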