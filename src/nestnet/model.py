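"""Model/Results surface tying the pipeline together.

:class:`ActivityClassifier` is built from a protocol dataset split (or raw
labelled sequences) and a variant choice; :meth:`ActivityClassifier.fit`
trains the network, calibrates the output filter on the filter-validation
segments of that trained instance, and returns an
:class:`ActivityClassifierResults` carrying the weights, thresholds,
training log and diagnostics, with ``predict``, ``evaluate``, ``summary``
and plotting hanging off it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nets
from .evaluation import (
    DIGGING,
    NON_DIGGING,
    ConfusionMatrix,
    MultiseedReport,
    classify_segments,
    confusion,
    evaluate_multiseed,
    run_ars,
)
from .nets import ModelConfig, ModelVariant, TrainConfig, WeightSet
from .preprocessing import PreprocessConfig
from .signal import AccelerometerSequence, DatasetSplit, Segment, SplitCounts, make_split
from .stream_filter import FilterThresholds, calibrate_thresholds
from .nets import output_stream

__all__ = ["ActivityClassifier", "ActivityClassifierResults"]


class ActivityClassifier:
    """Digging-activity classifier over accelerometer segments.

    Parameters
    ----------
    split
        The four-part protocol split (training patterns, validation
        patterns, filter-validation segments, test segments).
    variant
        ``"idnn"``, ``"idnn-lrf"`` or ``"idnn-lrf-ws"``; or pass a full
        :class:`~nestnet.nets.ModelConfig` as ``model_config``.
    train_config, preprocess_config
        Hyperparameters; defaults are the package's selected values.

    Examples
    --------
    >>> from nestnet.simulate import gen_benchmark
    >>> _, split = gen_benchmark(seed=1)
    >>> model = ActivityClassifier(split, variant="idnn-lrf")
    >>> res = model.fit(seed=1)
    >>> print(res.summary())           # doctest: +SKIP
    """

    def __init__(
        self,
        split: DatasetSplit,
        variant="idnn-lrf",
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        preprocess_config: PreprocessConfig | None = None,
        np_bound: int = 2,
    ) -> None:
        self.split = split
        self.model_config = model_config or ModelConfig(variant=ModelVariant.parse(variant))
        self.train_config = train_config or TrainConfig.for_variant(
            self.model_config.variant
        )
        self.preprocess_config = preprocess_config or PreprocessConfig()
        self.np_bound = np_bound

    @classmethod
    def from_sequences(
        cls,
        seqs: Sequence[AccelerometerSequence],
        variant="idnn-lrf",
        counts: SplitCounts | None = None,
        seed: int = 0,
        **kwargs,
    ) -> "ActivityClassifier":
        """Build the protocol split from labelled sequences, then the model."""
        pre = kwargs.get("preprocess_config") or PreprocessConfig()
        split = make_split(seqs, counts=counts, seed=seed, preprocess_config=pre)
        return cls(split, variant=variant, **kwargs)

    def fit(self, seed: int | None = None) -> "ActivityClassifierResults":
        """Train the network and calibrate the output filter.

        ``seed`` overrides the training seed; everything downstream of the
        seed is deterministic.
        """
        tcfg = self.train_config if seed is None else replace(self.train_config, seed=seed)
        res = nets.train(
            self.model_config, tcfg, self.split.ann_train, self.split.ann_validation
        )
        pos = [s for s in self.split.filter_validation if s.is_digging]
        neg = [s for s in self.split.filter_validation if not s.is_digging]
        thresholds = calibrate_thresholds(
            (output_stream(self.model_config, res.weights, s, self.preprocess_config) for s in pos),
            (output_stream(self.model_config, res.weights, s, self.preprocess_config) for s in neg),
            np_bound=self.np_bound,
        )
        return ActivityClassifierResults(
            model=self,
            weights=res.weights,
            thresholds=thresholds,
            loss_log=res.loss_log,
            n_epochs=res.n_epochs,
            converged=res.converged,
            train_accuracy=res.train_accuracy,
            val_accuracy=res.val_accuracy,
        )

    def fit_multiseed(self, n_seeds: int = 5) -> MultiseedReport:
        """The multi-initialization evaluation protocol (mean +/- sd)."""
        return evaluate_multiseed(
            self.model_config,
            self.train_config,
            self.split,
            n_seeds=n_seeds,
            pre_cfg=self.preprocess_config,
        )


@dataclass
class ActivityClassifierResults:
    """Fitted weights, calibrated thresholds and diagnostics."""

    model: ActivityClassifier
    weights: WeightSet
    thresholds: FilterThresholds
    loss_log: list[float]
    n_epochs: int
    converged: bool
    train_accuracy: float
    val_accuracy: float | None

    # -- prediction --------------------------------------------------------
    def predict(self, segments: Sequence[Segment]) -> list[str]:
        """Digging / non-digging label for each 1 Hz segment."""
        return classify_segments(
            segments,
            self.model.model_config,
            self.weights,
            self.thresholds,
            self.model.preprocess_config,
        )

    def predict_sequence(self, seq: AccelerometerSequence) -> list[str]:
        """Per-segment labels for a raw 4 Hz (or 1 Hz) sequence."""
        return run_ars(
            seq,
            self.model.model_config,
            self.weights,
            self.thresholds,
            self.model.preprocess_config,
        )

    def output_stream(self, segment: Segment):
        return output_stream(
            self.model.model_config, self.weights, segment, self.model.preprocess_config
        )

    def evaluate(self, segments: Sequence[Segment] | None = None) -> ConfusionMatrix:
        """Confusion matrix on the given segments (default: the test part)."""
        segments = list(segments if segments is not None else self.model.split.test)
        true = [DIGGING if s.is_digging else NON_DIGGING for s in segments]
        return confusion(true, self.predict(segments))

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.model_config
        cm = self.evaluate()
        lines = [
            "Nest-digging activity classifier",
            "=" * 48,
            f"variant:               {cfg.variant.value}",
            f"hidden units:          {cfg.n_hidden}",
            f"weights per unit:      {nets.count_weights_per_hidden_unit(cfg)}",
            f"total float weights:   {nets.count_total_weights(cfg)}",
            f"memory footprint:      {nets.memory_footprint(cfg)} bytes",
            f"epochs trained:        {self.n_epochs}"
            + (" (converged)" if self.converged else " (max epochs)"),
            f"final training loss:   {self.loss_log[-1]:.4f}",
            f"train pattern acc.:    {100 * self.train_accuracy:.2f}%",
            f"val pattern acc.:      "
            + (f"{100 * self.val_accuracy:.2f}%" if self.val_accuracy is not None else "n/a"),
            f"filter thresholds:     tau={self.thresholds.tau:.4f} "
            f"mp>{self.thresholds.mp_bound:.4f} mpt>{self.thresholds.mpt_bound:.4f} "
            f"np>={self.thresholds.np_bound}",
            f"test segment acc.:     {100 * cm.accuracy:.2f}%",
            "test confusion matrix:",
            str(cm),
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Serialize config, weights and thresholds to a JSON text file."""
        cfg = self.model.model_config
        payload = {
            "variant": cfg.variant.value,
            "window_len": cfg.window_len,
            "n_hidden": cfg.n_hidden,
            "subwindow_len": cfg.subwindow_len,
            "weights": json.loads(self.weights.to_json()),
            "thresholds": json.loads(self.thresholds.to_json()),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @staticmethod
    def load_weights(path) -> tuple[ModelConfig, WeightSet, FilterThresholds]:
        d = json.loads(Path(path).read_text())
        cfg = ModelConfig(
            variant=d["variant"],
            window_len=d["window_len"],
            n_hidden=d["n_hidden"],
            subwindow_len=d["subwindow_len"],
        )
        return (
            cfg,
            WeightSet.from_json(json.dumps(d["weights"])),
            FilterThresholds.from_json(json.dumps(d["thresholds"])),
        )

    # -- plotting ----------------------------------------------------------
    def plot_training(self, ax=None):
        """Training-loss curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.loss_log)
        ax.set_xlabel("epoch")
        ax.set_ylabel("training loss")
        ax.set_title(f"{self.model.model_config.variant.value} training")
        return ax

    def plot_stream(self, segment: Segment, ax=None):
        """Segment signal with the window scores overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        stream = self.output_stream(segment)
        ax.plot(segment.samples, color="C0", alpha=0.6, label="signal (1 Hz)")
        offsets = np.arange(len(stream)) * self.model.preprocess_config.shift + (
            self.model.preprocess_config.window_len
        )
        scale = max(1.0, np.max(np.abs(segment.samples)))
        ax.plot(offsets, stream.values * scale, "o-", color="C1", label="window score")
        ax.axhline(0, color="grey", lw=0.5)
        ax.legend()
        ax.set_xlabel("time step (s)")
        return ax
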