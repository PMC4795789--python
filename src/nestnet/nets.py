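"""Input-delay neural networks for window classification.

Three one-hidden-layer tanh architectures read a 90-step input window and
emit a score in (-1, +1), positive when the window resembles the
characteristic two-square-wave digging pattern:

``IDNN``
    Plain input-delay network: every hidden unit is fully connected to the
    whole window (window_len + 1 weights per unit including bias).
``IDNN_LRF``
    Local receptive fields: the window is divided into four contiguous
    22-sample sub-windows, one hidden unit per sub-window (23 weights per
    unit).  Each sub-window corresponds to one ascent or descent phase of
    the two square waves.
``IDNN_LRF_WS``
    Local receptive fields with weight sharing: the two ascent sub-windows
    (0 and 2) share one weight vector and the two descent sub-windows
    (1 and 3) share the other, collapsing the hidden layer to two units.
    A shared unit sums the pre-activations of its two receptive fields,
    adds its single bias, and applies tanh.

Training is full-batch gradient descent on the summed squared error with
classical momentum and L2 weight decay, the standard backpropagation recipe
for networks this small (134 patterns, <500 weights).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .preprocessing import PreprocessConfig, extract_windows
from .signal import Pattern, Segment, Window

__all__ = [
    "ModelVariant",
    "ModelConfig",
    "TrainConfig",
    "WeightSet",
    "TrainResult",
    "init_weights",
    "forward",
    "loss",
    "gradient",
    "train",
    "classify_pattern",
    "output_stream",
    "count_weights_per_hidden_unit",
    "count_total_weights",
    "memory_footprint",
    "select_model",
    "pattern_accuracy",
]


class ModelVariant(str, Enum):
    IDNN = "idnn"
    IDNN_LRF = "idnn-lrf"
    IDNN_LRF_WS = "idnn-lrf-ws"

    @classmethod
    def parse(cls, value) -> "ModelVariant":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower().replace("_", "-").replace(" ", "-")
        aliases = {
            "idnn": cls.IDNN,
            "idnn-lrf": cls.IDNN_LRF,
            "lrf": cls.IDNN_LRF,
            "idnn-lrf-ws": cls.IDNN_LRF_WS,
            "idnn-lrf+ws": cls.IDNN_LRF_WS,
            "lrf-ws": cls.IDNN_LRF_WS,
            "ws": cls.IDNN_LRF_WS,
        }
        if key not in aliases:
            raise ValueError(f"unknown model variant {value!r}")
        return aliases[key]


# Sub-window pairing for weight sharing: receptive fields 0 and 2 cover the
# ascent phases of the two square waves, 1 and 3 the descent phases.
_WS_GROUPS = ((0, 2), (1, 3))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of one network variant.

    The LRF variants use 4 contiguous sub-windows of ``subwindow_len``
    starting at offset 0; with the defaults that covers samples 0-87 of the
    90-sample window (the last 2 samples are unused, since 4 x 22 = 88).
    """

    variant: ModelVariant = ModelVariant.IDNN
    window_len: int = 90
    n_hidden: int | None = None
    subwindow_len: int = 22
    n_subwindows: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", ModelVariant.parse(self.variant))
        if self.n_hidden is None:
            default = {
                ModelVariant.IDNN: 5,
                ModelVariant.IDNN_LRF: 4,
                ModelVariant.IDNN_LRF_WS: 2,
            }[self.variant]
            object.__setattr__(self, "n_hidden", default)
        if self.variant is ModelVariant.IDNN_LRF and self.n_hidden != 4:
            raise ValueError("IDNN_LRF has exactly 4 hidden units")
        if self.variant is ModelVariant.IDNN_LRF_WS and self.n_hidden != 2:
            raise ValueError("IDNN_LRF_WS has exactly 2 hidden units")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.variant is not ModelVariant.IDNN:
            if self.n_subwindows * self.subwindow_len > self.window_len:
                raise ValueError(
                    "sub-windows do not fit in the input window: "
                    f"{self.n_subwindows} x {self.subwindow_len} > {self.window_len}"
                )

    @property
    def uses_subwindows(self) -> bool:
        return self.variant is not ModelVariant.IDNN

    @property
    def input_len_per_unit(self) -> int:
        return self.subwindow_len if self.uses_subwindows else self.window_len

    @property
    def n_distinct_hidden(self) -> int:
        """Number of distinct hidden weight vectors stored in memory."""
        if self.variant is ModelVariant.IDNN_LRF_WS:
            return 2
        return self.n_hidden


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of backpropagation training.

    The search ranges used for model selection are learning_rate in
    [0.0001, 0.1], momentum in [0, 0.1] and weight_decay in [0, 0.001];
    input->hidden weights start uniform in +/-1e-5 and hidden->output
    weights uniform in +/-0.01.  Training stops once the relative
    improvement of the training loss stays below ``stop_tol`` for
    ``stop_patience`` consecutive epochs, or at ``max_epochs``.
    """

    learning_rate: float = 0.002
    momentum: float = 0.1
    weight_decay: float = 1e-3
    init_range_input_hidden: float = 1e-5
    init_range_hidden_output: float = 0.01
    seed: int = 0
    max_epochs: int = 3000
    stop_tol: float = 1e-5
    stop_patience: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.learning_rate):
            raise ValueError("learning_rate must be positive")
        if self.momentum < 0:
            raise ValueError("momentum must be non-negative")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")

    def in_search_ranges(self) -> bool:
        return (
            1e-4 <= self.learning_rate <= 0.1
            and 0 <= self.momentum <= 0.1
            and 0 <= self.weight_decay <= 1e-3
        )

    @classmethod
    def for_variant(cls, variant, seed: int = 0) -> "TrainConfig":
        """Per-variant defaults selected by validation-accuracy grid search
        over the stated hyperparameter ranges on the synthetic benchmark."""
        variant = ModelVariant.parse(variant)
        if variant is ModelVariant.IDNN:
            return cls(learning_rate=0.002, momentum=0.1, weight_decay=3e-4, seed=seed)
        return cls(learning_rate=0.002, momentum=0.1, weight_decay=1e-3, seed=seed)


@dataclass
class WeightSet:
    """All trainable weights of one network.

    hidden
        Array of shape (n_distinct, input_len_per_unit): one row per
        *distinct* hidden weight vector (2 rows for the weight-shared
        variant, n_hidden otherwise).
    hidden_bias
        One bias per distinct hidden vector.
    output
        One weight per hidden *unit* feeding the output unit.
    output_bias
        Scalar bias of the output unit.
    """

    hidden: np.ndarray
    hidden_bias: np.ndarray
    output: np.ndarray
    output_bias: float

    def copy(self) -> "WeightSet":
        return WeightSet(
            self.hidden.copy(),
            self.hidden_bias.copy(),
            self.output.copy(),
            float(self.output_bias),
        )

    @property
    def n_parameters(self) -> int:
        return self.hidden.size + self.hidden_bias.size + self.output.size + 1

    def to_flat(self) -> np.ndarray:
        return np.concatenate(
            [
                self.hidden.ravel(),
                self.hidden_bias,
                self.output,
                [self.output_bias],
            ]
        )

    def from_flat(self, flat: np.ndarray) -> "WeightSet":
        flat = np.asarray(flat, dtype=float)
        if flat.size != self.n_parameters:
            raise ValueError("flat vector has wrong length")
        h = self.hidden.size
        hb = self.hidden_bias.size
        o = self.output.size
        return WeightSet(
            hidden=flat[:h].reshape(self.hidden.shape).copy(),
            hidden_bias=flat[h : h + hb].copy(),
            output=flat[h + hb : h + hb + o].copy(),
            output_bias=float(flat[-1]),
        )

    def squared_norm(self) -> float:
        """Sum of squares over every parameter, biases included."""
        return float(
            np.sum(self.hidden**2)
            + np.sum(self.hidden_bias**2)
            + np.sum(self.output**2)
            + self.output_bias**2
        )

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "hidden": self.hidden.tolist(),
                "hidden_bias": self.hidden_bias.tolist(),
                "output": self.output.tolist(),
                "output_bias": self.output_bias,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "WeightSet":
        d = json.loads(text)
        return cls(
            hidden=np.asarray(d["hidden"], dtype=float),
            hidden_bias=np.asarray(d["hidden_bias"], dtype=float),
            output=np.asarray(d["output"], dtype=float),
            output_bias=float(d["output_bias"]),
        )


def init_weights(cfg: ModelConfig, tcfg: TrainConfig) -> WeightSet:
    """Draw initial weights: input->hidden uniform +/-1e-5, hidden->output
    uniform +/-0.01, deterministic given ``tcfg.seed``."""
    rng = np.random.default_rng(tcfg.seed)
    a = tcfg.init_range_input_hidden
    b = tcfg.init_range_hidden_output
    n_dist = cfg.n_distinct_hidden
    return WeightSet(
        hidden=rng.uniform(-a, a, size=(n_dist, cfg.input_len_per_unit)),
        hidden_bias=rng.uniform(-a, a, size=n_dist),
        output=rng.uniform(-b, b, size=cfg.n_hidden),
        output_bias=float(rng.uniform(-b, b)),
    )


# ---------------------------------------------------------------------------
# Forward / backward pass
# ---------------------------------------------------------------------------

def _as_batch(cfg: ModelConfig, windows) -> np.ndarray:
    """Coerce a window, Pattern, array, or collection thereof to (N, window_len)."""
    if isinstance(windows, (Pattern, Window)):
        X = np.asarray(windows.samples, dtype=float)[None, :]
    elif isinstance(windows, np.ndarray):
        X = np.asarray(windows, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
    else:
        X = np.asarray(
            [
                np.asarray(w.samples if isinstance(w, (Pattern, Window)) else w, dtype=float)
                for w in windows
            ]
        )
    if X.ndim != 2 or X.shape[1] != cfg.window_len:
        raise ValueError(
            f"expected windows of length {cfg.window_len}, got shape {X.shape}"
        )
    return X


def _subwindow(X: np.ndarray, cfg: ModelConfig, k: int) -> np.ndarray:
    L = cfg.subwindow_len
    return X[:, k * L : (k + 1) * L]


def _hidden_preact(cfg: ModelConfig, w: WeightSet, X: np.ndarray) -> np.ndarray:
    """Pre-activations of the hidden units, shape (N, n_hidden)."""
    if cfg.variant is ModelVariant.IDNN:
        return X @ w.hidden.T + w.hidden_bias
    if cfg.variant is ModelVariant.IDNN_LRF:
        cols = [
            _subwindow(X, cfg, k) @ w.hidden[k] + w.hidden_bias[k]
            for k in range(cfg.n_subwindows)
        ]
        return np.stack(cols, axis=1)
    # Weight sharing: each unit sums the pre-activations of its two
    # receptive fields through one shared vector, adding its bias once.
    cols = [
        (_subwindow(X, cfg, g0) + _subwindow(X, cfg, g1)) @ w.hidden[u]
        + w.hidden_bias[u]
        for u, (g0, g1) in enumerate(_WS_GROUPS)
    ]
    return np.stack(cols, axis=1)


def forward(cfg: ModelConfig, w: WeightSet, windows) -> np.ndarray | float:
    """Network output in (-1, +1) for one window or a batch.

    Returns a scalar for a single window, an array of shape (N,) for a batch.
    """
    single = isinstance(windows, (Pattern, Window)) or (
        isinstance(windows, np.ndarray) and windows.ndim == 1
    )
    X = _as_batch(cfg, windows)
    A = np.tanh(_hidden_preact(cfg, w, X))
    out = np.tanh(A @ w.output + w.output_bias)
    return float(out[0]) if single else out


def loss(
    cfg: ModelConfig,
    w: WeightSet,
    patterns,
    targets=None,
    weight_decay: float = 0.0,
) -> float:
    """Summed squared error plus L2 penalty.

    ``sum_i (forward(x_i) - t_i)^2 + weight_decay * ||w||^2`` with the
    squared norm taken over every parameter including biases.
    """
    X, t = _patterns_to_xy(cfg, patterns, targets)
    out = forward(cfg, w, X)
    return float(np.sum((out - t) ** 2) + weight_decay * w.squared_norm())


def gradient(
    cfg: ModelConfig,
    w: WeightSet,
    patterns,
    targets=None,
    weight_decay: float = 0.0,
) -> WeightSet:
    """Exact gradient of :func:`loss` via backpropagation.

    For the weight-shared variant the gradient of a shared vector is the
    sum of the gradients contributed by both of its receptive fields.
    Returned as a WeightSet-shaped container of partial derivatives.
    """
    X, t = _patterns_to_xy(cfg, patterns, targets)
    A = np.tanh(_hidden_preact(cfg, w, X))
    out = np.tanh(A @ w.output + w.output_bias)

    dz = 2.0 * (out - t) * (1.0 - out**2)      # dL/d(output pre-activation)
    g_output = A.T @ dz
    g_output_bias = float(np.sum(dz))
    dpre = np.outer(dz, w.output) * (1.0 - A**2)  # (N, n_hidden)

    if cfg.variant is ModelVariant.IDNN:
        g_hidden = dpre.T @ X
        g_hidden_bias = dpre.sum(axis=0)
    elif cfg.variant is ModelVariant.IDNN_LRF:
        g_hidden = np.stack(
            [dpre[:, k] @ _subwindow(X, cfg, k) for k in range(cfg.n_subwindows)]
        )
        g_hidden_bias = dpre.sum(axis=0)
    else:
        g_hidden = np.stack(
            [
                dpre[:, u] @ (_subwindow(X, cfg, g0) + _subwindow(X, cfg, g1))
                for u, (g0, g1) in enumerate(_WS_GROUPS)
            ]
        )
        g_hidden_bias = dpre.sum(axis=0)

    if weight_decay:
        g_hidden = g_hidden + 2.0 * weight_decay * w.hidden
        g_hidden_bias = g_hidden_bias + 2.0 * weight_decay * w.hidden_bias
        g_output = g_output + 2.0 * weight_decay * w.output
        g_output_bias += 2.0 * weight_decay * w.output_bias

    return WeightSet(g_hidden, g_hidden_bias, g_output, g_output_bias)


def _patterns_to_xy(cfg: ModelConfig, patterns, targets=None):
    if targets is None:
        pats = list(patterns)
        if not pats or not isinstance(pats[0], Pattern):
            raise ValueError("targets required unless patterns are Pattern objects")
        X = _as_batch(cfg, pats)
        t = np.asarray([p.target for p in pats], dtype=float)
    else:
        X = _as_batch(cfg, patterns)
        t = np.asarray(targets, dtype=float)
    if X.shape[0] != t.size:
        raise ValueError("patterns and targets differ in length")
    if t.size and not np.all(np.isin(t, (-1.0, 1.0))):
        raise ValueError("targets must be +1 or -1")
    return X, t


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    """Trained weights plus the per-epoch training log."""

    weights: WeightSet
    loss_log: list[float]
    n_epochs: int
    converged: bool
    train_accuracy: float
    val_accuracy: float | None = None


def train(
    cfg: ModelConfig,
    tcfg: TrainConfig,
    train_patterns: Sequence[Pattern],
    val_patterns: Sequence[Pattern] | None = None,
) -> TrainResult:
    """Full-batch gradient descent with momentum and weight decay.

    The heavy-ball update ``v <- momentum*v - lr*grad; w <- w + v`` is
    iterated on the summed squared error until the relative loss improvement
    stays below ``stop_tol`` for ``stop_patience`` consecutive epochs or
    ``max_epochs`` is reached.
    """
    train_patterns = list(train_patterns)
    if not train_patterns:
        raise ValueError("empty training set")
    X, t = _patterns_to_xy(cfg, train_patterns)

    w = init_weights(cfg, tcfg)
    vel = WeightSet(
        np.zeros_like(w.hidden), np.zeros_like(w.hidden_bias),
        np.zeros_like(w.output), 0.0,
    )

    log: list[float] = []
    prev = loss(cfg, w, X, t, tcfg.weight_decay)
    log.append(prev)
    quiet = 0
    converged = False
    for _epoch in range(tcfg.max_epochs):
        g = gradient(cfg, w, X, t, tcfg.weight_decay)
        vel.hidden = tcfg.momentum * vel.hidden - tcfg.learning_rate * g.hidden
        vel.hidden_bias = (
            tcfg.momentum * vel.hidden_bias - tcfg.learning_rate * g.hidden_bias
        )
        vel.output = tcfg.momentum * vel.output - tcfg.learning_rate * g.output
        vel.output_bias = (
            tcfg.momentum * vel.output_bias - tcfg.learning_rate * g.output_bias
        )
        w.hidden = w.hidden + vel.hidden
        w.hidden_bias = w.hidden_bias + vel.hidden_bias
        w.output = w.output + vel.output
        w.output_bias = w.output_bias + vel.output_bias

        cur = loss(cfg, w, X, t, tcfg.weight_decay)
        log.append(cur)
        rel = abs(prev - cur) / max(prev, 1e-300)
        prev = cur
        if rel < tcfg.stop_tol:
            quiet += 1
            if quiet >= tcfg.stop_patience:
                converged = True
                break
        else:
            quiet = 0

    train_acc = pattern_accuracy(cfg, w, train_patterns)
    val_acc = (
        pattern_accuracy(cfg, w, val_patterns) if val_patterns else None
    )
    return TrainResult(
        weights=w,
        loss_log=log,
        n_epochs=len(log) - 1,
        converged=converged,
        train_accuracy=train_acc,
        val_accuracy=val_acc,
    )


def classify_pattern(cfg: ModelConfig, w: WeightSet, pattern) -> int:
    """Sign of the network output; an exact 0 maps to -1 (non-digging)."""
    return +1 if forward(cfg, w, pattern) > 0 else -1


def pattern_accuracy(cfg: ModelConfig, w: WeightSet, patterns: Sequence[Pattern]) -> float:
    pats = list(patterns)
    out = forward(cfg, w, pats)
    pred = np.where(out > 0, 1, -1)
    t = np.asarray([p.target for p in pats])
    return float(np.mean(pred == t))


def output_stream(
    cfg: ModelConfig,
    w: WeightSet,
    segment,
    pre_cfg: PreprocessConfig | None = None,
):
    """Score every shifted window of a segment, in order.

    Returns an :class:`~nestnet.stream_filter.OutputStream`; with the
    default geometry (300-step segment, 90-step window, shift 22) the
    stream holds 10 values.
    """
    from .stream_filter import OutputStream  # circular-import guard

    pre_cfg = pre_cfg or PreprocessConfig()
    windows = extract_windows(segment, pre_cfg.window_len, pre_cfg.shift)
    values = forward(cfg, w, windows)
    ref = segment.key if isinstance(segment, Segment) else None
    return OutputStream(values=np.asarray(values, dtype=float), segment_ref=ref)


# ---------------------------------------------------------------------------
# Memory accounting
# ---------------------------------------------------------------------------

def count_weights_per_hidden_unit(cfg: ModelConfig) -> int:
    """Weights stored per hidden unit, bias included: 91 for the plain
    IDNN, 23 for both sub-window variants."""
    return cfg.input_len_per_unit + 1


def count_total_weights(cfg: ModelConfig) -> int:
    """Distinct float parameters: distinct hidden vectors (with biases)
    plus the output unit's weights and bias."""
    return (
        cfg.n_distinct_hidden * count_weights_per_hidden_unit(cfg)
        + cfg.n_hidden
        + 1
    )


def memory_footprint(cfg: ModelConfig, bytes_per_weight: int = 4) -> int:
    """Bytes needed to store the weight vectors of hidden and output units.

    With 4-byte floats: plain IDNN (5 hidden) 1844 B, LRF 388 B, LRF+WS
    196 B.  The integer input buffer is accounted separately on-device and
    is excluded here.
    """
    if bytes_per_weight < 1:
        raise ValueError("bytes_per_weight must be >= 1")
    return count_total_weights(cfg) * bytes_per_weight


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionEntry:
    index: int
    model_config: ModelConfig
    train_config: TrainConfig
    val_accuracies: list[float]

    @property
    def mean_val_accuracy(self) -> float:
        return float(np.mean(self.val_accuracies))


def select_model(
    grid: Sequence[tuple[ModelConfig, TrainConfig]],
    train_patterns: Sequence[Pattern],
    val_patterns: Sequence[Pattern],
    n_seeds: int = 5,
) -> tuple[ModelConfig, TrainConfig, list[SelectionEntry]]:
    """Grid search ranked by mean validation-pattern accuracy over seeds.

    Each candidate is trained ``n_seeds`` times (seeds ``tcfg.seed + i``);
    the winner maximizes mean validation accuracy, with ties broken by
    smaller memory footprint, then lower grid index.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty model-selection grid")
    report: list[SelectionEntry] = []
    for idx, (cfg, tcfg) in enumerate(grid):
        accs = []
        for s in range(n_seeds):
            res = train(
                cfg, replace(tcfg, seed=tcfg.seed + s), train_patterns, val_patterns
            )
            accs.append(res.val_accuracy)
        report.append(SelectionEntry(idx, cfg, tcfg, accs))
    best = min(
        report,
        key=lambda e: (-e.mean_val_accuracy, memory_footprint(e.model_config), e.index),
    )
    return best.model_config, best.train_config, report
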