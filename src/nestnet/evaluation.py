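"""End-to-end evaluation: pipeline runner, confusion matrices,
multi-initialization accuracy, and repeated-segment confirmation.

Test accuracy is reported as the mean and standard deviation over several
weight initializations (default 5), with the filter thresholds recalibrated
per trained instance since they live on that instance's output scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .nets import ModelConfig, TrainConfig, WeightSet, output_stream, train
from .preprocessing import PreprocessConfig, extract_segments, preprocess_sequence
from .signal import AccelerometerSequence, DatasetSplit, Segment
from .stream_filter import (
    DIGGING,
    NON_DIGGING,
    FilterThresholds,
    calibrate_thresholds,
    classify_segment,
)

__all__ = [
    "ConfusionMatrix",
    "SeedResult",
    "MultiseedReport",
    "Detection",
    "run_ars",
    "classify_segments",
    "confusion",
    "evaluate_multiseed",
    "confirm_digging",
]


@dataclass
class ConfusionMatrix:
    """2x2 segment counts with digging as the positive class."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return (self.tp + self.tn) / self.total

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=int)

    def __str__(self) -> str:
        return (
            "real\\pred   digging  non-digging\n"
            f"digging     {self.tp:7d}  {self.fn:11d}\n"
            f"non-digging {self.fp:7d}  {self.tn:11d}"
        )


def classify_segments(
    segments: Sequence[Segment],
    cfg: ModelConfig,
    weights: WeightSet,
    thresholds: FilterThresholds,
    pre_cfg: PreprocessConfig | None = None,
) -> list[str]:
    """Filtered classification of already-extracted 1 Hz segments, in order."""
    pre_cfg = pre_cfg or PreprocessConfig()
    return [
        classify_segment(output_stream(cfg, weights, seg, pre_cfg), thresholds)
        for seg in segments
    ]


def run_ars(
    seq: AccelerometerSequence,
    cfg: ModelConfig,
    weights: WeightSet,
    thresholds: FilterThresholds,
    pre_cfg: PreprocessConfig | None = None,
) -> list[str]:
    """Run the whole recognizer on a raw 4 Hz sequence.

    Preprocess, cut segments, score each window, filter each stream;
    returns one digging / non-digging label per segment, in order.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    if seq.rate_hz != 1:
        seq = preprocess_sequence(seq, pre_cfg)
    segments = extract_segments(seq, pre_cfg.segment_len)
    return classify_segments(segments, cfg, weights, thresholds, pre_cfg)


def confusion(labels_true: Sequence[str], labels_pred: Sequence[str]) -> ConfusionMatrix:
    """Standard 2x2 counts; any label other than ``digging`` is negative."""
    if len(labels_true) != len(labels_pred):
        raise ValueError("label lists differ in length")
    cm = ConfusionMatrix()
    for t, p in zip(labels_true, labels_pred):
        t_pos = t == DIGGING
        p_pos = p == DIGGING
        if t_pos and p_pos:
            cm.tp += 1
        elif t_pos:
            cm.fn += 1
        elif p_pos:
            cm.fp += 1
        else:
            cm.tn += 1
    return cm


@dataclass
class SeedResult:
    seed: int
    weights: WeightSet
    thresholds: FilterThresholds
    train_accuracy: float
    val_accuracy: float
    test_confusion: ConfusionMatrix
    n_epochs: int

    @property
    def test_accuracy(self) -> float:
        return self.test_confusion.accuracy


@dataclass
class MultiseedReport:
    model_config: ModelConfig
    results: list[SeedResult]

    @property
    def mean_test_accuracy(self) -> float:
        return float(np.mean([r.test_accuracy for r in self.results]))

    @property
    def sd_test_accuracy(self) -> float:
        return float(np.std([r.test_accuracy for r in self.results]))

    @property
    def mean_train_accuracy(self) -> float:
        return float(np.mean([r.train_accuracy for r in self.results]))

    def __str__(self) -> str:
        lines = [
            f"variant: {self.model_config.variant.value}",
            f"seeds:   {[r.seed for r in self.results]}",
            f"train accuracy (ANN patterns): {100 * self.mean_train_accuracy:.2f}%",
            "test accuracy (segments):      "
            f"{100 * self.mean_test_accuracy:.2f}% "
            f"(+/- {100 * self.sd_test_accuracy:.2f})",
        ]
        return "\n".join(lines)


def evaluate_multiseed(
    cfg: ModelConfig,
    tcfg: TrainConfig,
    split: DatasetSplit,
    n_seeds: int = 5,
    pre_cfg: PreprocessConfig | None = None,
) -> MultiseedReport:
    """Train/calibrate/test once per weight initialization and aggregate.

    For each seed (``tcfg.seed + i``): train on the ANN training patterns,
    record validation-pattern accuracy, calibrate the output filter on the
    filter-validation segments of that trained instance, then score the
    test segments.  The report carries mean and population standard
    deviation of test accuracy (sd 0 when ``n_seeds`` is 1) plus the
    per-seed confusion matrices; it is bit-for-bit reproducible given the
    seed list.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    results: list[SeedResult] = []
    for i in range(n_seeds):
        seed = tcfg.seed + i
        res = train(cfg, replace(tcfg, seed=seed), split.ann_train, split.ann_validation)
        pos_streams = [
            output_stream(cfg, res.weights, s, pre_cfg)
            for s in split.filter_validation
            if s.is_digging
        ]
        neg_streams = [
            output_stream(cfg, res.weights, s, pre_cfg)
            for s in split.filter_validation
            if not s.is_digging
        ]
        thresholds = calibrate_thresholds(pos_streams, neg_streams)
        pred = classify_segments(split.test, cfg, res.weights, thresholds, pre_cfg)
        true = [DIGGING if s.is_digging else NON_DIGGING for s in split.test]
        results.append(
            SeedResult(
                seed=seed,
                weights=res.weights,
                thresholds=thresholds,
                train_accuracy=res.train_accuracy,
                val_accuracy=res.val_accuracy,
                test_confusion=confusion(true, pred),
                n_epochs=res.n_epochs,
            )
        )
    return MultiseedReport(model_config=cfg, results=results)


# ---------------------------------------------------------------------------
# Repeated-segment confirmation
# ---------------------------------------------------------------------------

CONFIRMED = "confirmed"
REJECTED = "rejected"
PENDING = "pending"


@dataclass(frozen=True)
class Detection:
    """One digging detection and its confirmation status."""

    segment_index: int
    status: str  # confirmed / rejected / pending


def confirm_digging(
    segment_labels: Sequence[str], gap_segments: int = 2
) -> list[Detection]:
    """Confirm digging detections by re-checking after a gap.

    Nest excavation lasts up to a couple of hours, so a genuine detection
    at segment ``i`` should recur ``gap_segments`` later (10 minutes with
    the 5-minute segment default).  A detection is confirmed iff segment
    ``i + gap_segments`` is also digging; rejected if that segment is
    non-digging; pending when it lies beyond the recorded run.
    """
    if gap_segments < 1:
        raise ValueError("gap_segments must be >= 1")
    detections: list[Detection] = []
    for i, label in enumerate(segment_labels):
        if label != DIGGING:
            continue
        j = i + gap_segments
        if j >= len(segment_labels):
            status = PENDING
        elif segment_labels[j] == DIGGING:
            status = CONFIRMED
        else:
            status = REJECTED
        detections.append(Detection(i, status))
    return detections
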