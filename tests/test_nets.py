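"""Network forward/backward passes, training, and memory accounting."""

import math

import numpy as np
import pytest

from nestnet.nets import (
    ModelConfig,
    ModelVariant,
    TrainConfig,
    WeightSet,
    classify_pattern,
    count_total_weights,
    count_weights_per_hidden_unit,
    forward,
    gradient,
    init_weights,
    loss,
    memory_footprint,
    output_stream,
    select_model,
    train,
)
from nestnet.signal import Pattern, Segment

VARIANTS = ["idnn", "idnn-lrf", "idnn-lrf-ws"]


def toy_config(variant):
    """Tiny nets: window 8, sub-windows of 2."""
    n_hidden = {"idnn": 3, "idnn-lrf": 4, "idnn-lrf-ws": 2}[variant]
    return ModelConfig(variant=variant, window_len=8, n_hidden=n_hidden, subwindow_len=2)


def random_weights(cfg, rng, scale=0.3):
    w = init_weights(cfg, TrainConfig(seed=0))
    w.hidden = rng.normal(0, scale, w.hidden.shape)
    w.hidden_bias = rng.normal(0, scale, w.hidden_bias.shape)
    w.output = rng.normal(0, scale, w.output.shape)
    w.output_bias = float(rng.normal(0, scale))
    return w


class TestConfig:
    def test_variant_parsing_and_fixed_hidden(self):
        assert ModelConfig(variant="IDNN LRF").n_hidden == 4
        assert ModelConfig(variant="idnn_lrf_ws").n_hidden == 2
        assert ModelConfig(variant="idnn").n_hidden == 5
        with pytest.raises(ValueError):
            ModelConfig(variant="idnn-lrf", n_hidden=5)
        with pytest.raises(ValueError):
            ModelConfig(variant="idnn-lrf-ws", n_hidden=4)

    def test_subwindows_must_fit(self):
        with pytest.raises(ValueError, match="fit"):
            ModelConfig(variant="idnn-lrf", window_len=80, subwindow_len=22)


class TestInitWeights:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_ranges_and_determinism(self, variant):
        cfg = ModelConfig(variant=variant)
        tcfg = TrainConfig(seed=42)
        w1 = init_weights(cfg, tcfg)
        w2 = init_weights(cfg, tcfg)
        assert np.abs(w1.hidden).max() <= 1e-5
        assert np.abs(w1.hidden_bias).max() <= 1e-5
        assert np.abs(w1.output).max() <= 0.01
        assert np.array_equal(w1.hidden, w2.hidden)
        assert np.array_equal(w1.output, w2.output)

    def test_ws_allocates_two_distinct_vectors(self):
        w = init_weights(ModelConfig(variant="idnn-lrf-ws"), TrainConfig(seed=0))
        assert w.hidden.shape == (2, 22)
        assert w.output.shape == (2,)


class TestForward:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_zero_weights_give_zero(self, variant):
        cfg = ModelConfig(variant=variant)
        w = init_weights(cfg, TrainConfig(seed=0))
        w.hidden[:] = 0; w.hidden_bias[:] = 0; w.output[:] = 0; w.output_bias = 0.0
        assert forward(cfg, w, np.ones(90)) == 0.0

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_output_strictly_inside_unit_interval(self, variant, rng):
        # moderate weights: tanh is analytically inside (-1, 1) and stays
        # away from the representable +/-1.0 at these magnitudes
        cfg = ModelConfig(variant=variant)
        w = random_weights(cfg, rng, scale=0.2)
        X = rng.normal(0, 1, (20, 90))
        out = forward(cfg, w, X)
        assert np.all(out > -1) and np.all(out < 1)

    def test_ws_subwindow_swap_invariance(self, rng):
        cfg = ModelConfig(variant="idnn-lrf-ws")
        w = random_weights(cfg, rng)
        x = rng.normal(0, 10, 90)
        swapped = x.copy()
        swapped[0:22], swapped[44:66] = x[44:66].copy(), x[0:22].copy()
        swapped[22:44], swapped[66:88] = x[66:88].copy(), x[22:44].copy()
        assert forward(cfg, w, x) == forward(cfg, w, swapped)

    def test_hand_computed_toy_net(self):
        # window 4, sub-windows of 1: LRF unit k sees sample k alone
        cfg = ModelConfig(variant="idnn-lrf", window_len=4, n_hidden=4, subwindow_len=1)
        w = WeightSet(
            hidden=np.array([[1.0], [2.0], [-1.0], [0.5]]),
            hidden_bias=np.array([0.0, 0.1, -0.1, 0.0]),
            output=np.array([1.0, -1.0, 0.5, 2.0]),
            output_bias=0.25,
        )
        x = np.array([0.5, -0.5, 1.0, 2.0])
        a = np.tanh([0.5, -0.9, -1.1, 1.0])
        expected = math.tanh(a[0] - a[1] + 0.5 * a[2] + 2 * a[3] + 0.25)
        assert forward(cfg, w, x) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_errors(self, rng):
        cfg = ModelConfig(variant="idnn")
        w = init_weights(cfg, TrainConfig(seed=0))
        with pytest.raises(ValueError, match="length"):
            forward(cfg, w, np.ones(80))


class TestLossAndGradient:
    def test_degenerate_zero_loss(self):
        cfg = toy_config("idnn")
        w = init_weights(cfg, TrainConfig(seed=0))
        w.hidden[:] = 0; w.hidden_bias[:] = 0; w.output[:] = 0; w.output_bias = 0.0
        # zero network, any inputs: output 0, squared errors (0 -+ 1)^2
        X = np.ones((4, 8))
        t = np.array([1.0, -1.0, 1.0, -1.0])
        assert loss(cfg, w, X, t, 0.0) == pytest.approx(4.0)

    def test_decay_penalty_strictly_positive(self, rng):
        cfg = toy_config("idnn-lrf")
        w = random_weights(cfg, rng)
        X = rng.normal(0, 1, (5, 8))
        t = np.array([1.0, -1, 1, -1, 1])
        assert loss(cfg, w, X, t, 1e-3) > loss(cfg, w, X, t, 0.0)

    def test_hand_computed_loss(self):
        cfg = ModelConfig(variant="idnn", window_len=2, n_hidden=1)
        w = WeightSet(
            hidden=np.array([[0.5, -0.5]]), hidden_bias=np.array([0.1]),
            output=np.array([2.0]), output_bias=-0.2,
        )
        x = np.array([[1.0, 2.0]])
        out = math.tanh(2 * math.tanh(0.5 - 1.0 + 0.1) - 0.2)
        expected = (out - 1.0) ** 2 + 0.01 * (0.25 + 0.25 + 0.01 + 4.0 + 0.04)
        assert loss(cfg, w, x, [1.0], 0.01) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_gradient_matches_central_differences(self, variant, rng):
        cfg = toy_config(variant)
        w = random_weights(cfg, rng)
        X = rng.normal(0, 1, (6, 8))
        t = np.where(np.arange(6) % 2 == 0, 1.0, -1.0)
        wd = 5e-4
        g = gradient(cfg, w, X, t, wd).to_flat()
        flat = w.to_flat()
        eps = 1e-6
        fd = np.empty_like(flat)
        for i in range(flat.size):
            up, dn = flat.copy(), flat.copy()
            up[i] += eps
            dn[i] -= eps
            fd[i] = (
                loss(cfg, w.from_flat(up), X, t, wd)
                - loss(cfg, w.from_flat(dn), X, t, wd)
            ) / (2 * eps)
        rel = np.abs(g - fd) / np.maximum(np.abs(fd), 1e-8)
        assert rel.max() <= 1e-6


class TestTraining:
    def separable_patterns(self, cfg):
        pos = [Pattern(np.full(cfg.window_len, 30), +1) for _ in range(6)]
        neg = [Pattern(np.full(cfg.window_len, -30), -1) for _ in range(6)]
        return pos + neg

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_learns_separable_toy_task(self, variant):
        cfg = ModelConfig(
            variant=variant,
            window_len=90,
            n_hidden={"idnn": 2, "idnn-lrf": 4, "idnn-lrf-ws": 2}[variant],
        )
        tcfg = TrainConfig(seed=3, learning_rate=0.01, max_epochs=2000)
        res = train(cfg, tcfg, self.separable_patterns(cfg))
        assert res.train_accuracy == 1.0

    def test_first_epoch_non_increasing_at_tiny_rate(self, split):
        cfg = ModelConfig(variant="idnn-lrf")
        tcfg = TrainConfig(seed=1, learning_rate=1e-4, momentum=0.0, max_epochs=1)
        res = train(cfg, tcfg, split.ann_train)
        assert res.loss_log[1] <= res.loss_log[0]

    def test_weight_decay_shrinks_norm(self):
        # on a cleanly separable task the decay penalty shapes the optimum
        # and the converged norm is strictly smaller than without it
        cfg = ModelConfig(variant="idnn-lrf-ws")
        patterns = self.separable_patterns(cfg)
        base = dict(seed=2, learning_rate=0.002, max_epochs=3000)
        free = train(cfg, TrainConfig(weight_decay=0.0, **base), patterns)
        decayed = train(cfg, TrainConfig(weight_decay=1e-3, **base), patterns)
        assert decayed.weights.squared_norm() < free.weights.squared_norm()

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            train(ModelConfig(variant="idnn"), TrainConfig(), [])

    def test_classify_pattern_sign_rule(self, rng):
        cfg = toy_config("idnn")
        w = random_weights(cfg, rng)
        x = rng.normal(0, 1, 8)
        expected = +1 if forward(cfg, w, x) > 0 else -1
        assert classify_pattern(cfg, w, x) == expected
        w.hidden[:] = 0; w.hidden_bias[:] = 0; w.output[:] = 0; w.output_bias = 0.0
        assert classify_pattern(cfg, w, x) == -1  # exact zero -> non-digging


class TestOutputStream:
    def test_default_geometry_length_ten(self, lrf_result, split):
        stream = lrf_result.output_stream(split.test[0])
        assert len(stream) == 10

    def test_zero_weights_zero_stream(self):
        cfg = ModelConfig(variant="idnn")
        w = init_weights(cfg, TrainConfig(seed=0))
        w.hidden[:] = 0; w.hidden_bias[:] = 0; w.output[:] = 0; w.output_bias = 0.0
        seg = Segment(np.zeros(300, dtype=int), "z", 0, "eating")
        assert not output_stream(cfg, w, seg).values.any()

    def test_trained_model_fires_on_digging_segments(self, lrf_result, split):
        votes = []
        for seg in split.test:
            if seg.is_digging:
                votes.append(np.sum(lrf_result.output_stream(seg).values > 0))
        assert np.mean(votes) >= 2  # most digging segments show several hits


class TestMemoryAccounting:
    @pytest.mark.parametrize(
        "variant, per_unit, total_bytes",
        [("idnn", 91, 1844), ("idnn-lrf", 23, 388), ("idnn-lrf-ws", 23, 196)],
    )
    def test_published_counts(self, variant, per_unit, total_bytes):
        cfg = ModelConfig(variant=variant)
        assert count_weights_per_hidden_unit(cfg) == per_unit
        assert memory_footprint(cfg) == total_bytes

    @pytest.mark.parametrize("n_hidden", range(1, 11))
    def test_idnn_closed_form(self, n_hidden):
        cfg = ModelConfig(variant="idnn", n_hidden=n_hidden)
        assert memory_footprint(cfg) == 4 * (n_hidden * 91 + n_hidden + 1)

    def test_total_weights_match_weightset(self):
        for variant in VARIANTS:
            cfg = ModelConfig(variant=variant)
            w = init_weights(cfg, TrainConfig(seed=0))
            assert count_total_weights(cfg) == w.n_parameters


class TestModelSelection:
    def test_single_candidate_returned(self, split):
        cfg = ModelConfig(variant="idnn-lrf-ws")
        tcfg = TrainConfig(seed=0, max_epochs=50)
        best_cfg, best_tcfg, report = select_model(
            [(cfg, tcfg)], split.ann_train[:20], split.ann_validation, n_seeds=1
        )
        assert best_cfg is cfg and best_tcfg is tcfg and len(report) == 1

    def test_better_learner_wins(self, split):
        good = (ModelConfig(variant="idnn-lrf"), TrainConfig(seed=0, max_epochs=400))
        # a learning rate of ~0 cannot move the tiny initial weights
        stuck = (
            ModelConfig(variant="idnn-lrf"),
            TrainConfig(seed=0, learning_rate=1e-12, max_epochs=5),
        )
        best_cfg, best_tcfg, report = select_model(
            [stuck, good], split.ann_train, split.ann_validation, n_seeds=2
        )
        assert best_tcfg is good[1]
        assert report[1].mean_val_accuracy > report[0].mean_val_accuracy

    def test_empty_grid_errors(self, split):
        with pytest.raises(ValueError):
            select_model([], split.ann_train, split.ann_validation)
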