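"""Architecture pinning, parameter accounting, training and evaluation."""

import numpy as np
import pytest

from preictal.annotations import ConfigurationError
from preictal.cnn import (
    CNNModel, EvalMetrics, TrainingConfig, build_architecture,
    count_parameters, evaluate, spatial_trace, train_model,
)


class TestArchitecture:
    def test_input_planes_follow_rate(self):
        assert build_architecture(76, 256).input_F == 81
        assert build_architecture(4, 128).input_F == 65
        assert build_architecture(1, 256).n_channels == 1  # degenerate but valid

    def test_block_layout_is_pinned(self):
        spec = build_architecture(8, 256)
        kernels = [b.kernel for b in spec.conv_blocks]
        strides = [b.stride for b in spec.conv_blocks]
        assert kernels == [(5, 5), (3, 3), (3, 3)] and strides == [2, 1, 1]
        assert all(b.out_maps == 64 and b.pool == (2, 2) for b in spec.conv_blocks)

    def test_spatial_trace_81_bins(self):
        spec = build_architecture(8, 256)
        assert spatial_trace(spec) == [(28, 39), (14, 19), (12, 17), (6, 8), (4, 6), (2, 3)]

    def test_spatial_trace_65_bins(self):
        spec = build_architecture(8, 128)
        assert spatial_trace(spec) == [(28, 31), (14, 15), (12, 13), (6, 6), (4, 4), (2, 2)]

    def test_flatten_size_consistency(self):
        spec = build_architecture(5, 256)
        ft, ff = spatial_trace(spec)[-1]
        model = CNNModel(spec, seed=0)
        x = np.zeros((1, 5, 59, 81), dtype=np.float32)
        assert model.forward(x).shape == (1, 1)
        assert 64 * ft * ff == model.layers[-4].w.value.shape[1]

    def test_zero_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            build_architecture(0, 256)


class TestParameterCount:
    @pytest.mark.parametrize("n", [1, 4, 8, 16, 40, 76])
    @pytest.mark.parametrize("fs", [128, 256])
    def test_closed_form_equals_enumerated_model_weights(self, n, fs):
        spec = build_architecture(n, fs)
        assert count_parameters(spec) == CNNModel(spec, seed=0).num_parameters()

    def test_absolute_counts(self):
        assert count_parameters(build_architecture(76, 256)) == 294_721
        assert count_parameters(build_architecture(4, 256)) == 179_521

    def test_printed_electrode_ratios(self):
        p_all = count_parameters(build_architecture(76, 256))
        ratios = [round(100 * count_parameters(build_architecture(n, 256)) / p_all, 1)
                  for n in (4, 8, 16)]
        assert ratios == [60.9, 63.1, 67.4]

    def test_printed_rate_ratio(self):
        p128 = count_parameters(build_architecture(40, 128))
        p256 = count_parameters(build_architecture(40, 256))
        assert round(100 * p128 / p256, 1) == 86.2


def separable_toy(n_per_class=12, n_ch=1, fs=128, gap=2.0, noise=0.05, seed=0):
    """Two classes with disjoint constant spectra (plus tiny noise)."""
    rng = np.random.default_rng(seed)
    F = 65 if fs == 128 else 81
    X0 = -gap / 2 + noise * rng.standard_normal((n_per_class, n_ch, 59, F))
    X1 = +gap / 2 + noise * rng.standard_normal((n_per_class, n_ch, 59, F))
    X = np.concatenate([X0, X1]).astype(np.float32)
    y = np.r_[np.zeros(n_per_class), np.ones(n_per_class)]
    return X, y


class TestTraining:
    def test_overfits_perfectly_separable_toy_data(self):
        X, y = separable_toy()
        cfg = TrainingConfig(max_epochs=15, patience=15, batch_size=8, seed=0)
        model, history = train_model(build_architecture(1, 128), (X, y), (X, y), cfg)
        m = evaluate(model, (X, y))
        assert m.accuracy == 1.0
        assert history["val_loss"][-1] < history["val_loss"][0]

    def test_patience_zero_stops_at_first_non_improvement(self):
        X, y = separable_toy(n_per_class=6)
        cfg = TrainingConfig(max_epochs=50, patience=0, batch_size=4, seed=1)
        _, history = train_model(build_architecture(1, 128), (X, y), (X, y), cfg)
        losses = history["val_loss"]
        # every epoch but the last improved the running best; the last did not
        best = np.inf
        for v in losses[:-1]:
            assert v < best - 1e-6  # meaningful improvement every earlier epoch
            best = v
        assert losses[-1] >= best - 1e-6

    def test_same_seed_same_history(self):
        X, y = separable_toy(n_per_class=6)
        cfg = TrainingConfig(max_epochs=3, patience=3, batch_size=4, seed=7)
        _, h1 = train_model(build_architecture(1, 128), (X, y), (X, y), cfg)
        _, h2 = train_model(build_architecture(1, 128), (X, y), (X, y), cfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_best_weights_restored(self):
        X, y = separable_toy(n_per_class=8)
        cfg = TrainingConfig(max_epochs=10, patience=2, batch_size=8, seed=2)
        model, history = train_model(build_architecture(1, 128), (X, y), (X, y), cfg)
        from preictal.cnn import _epoch_loss
        final = _epoch_loss(model, X.astype(np.float32), y, 8)
        assert final == pytest.approx(history["best_val_loss"], rel=1e-5)

    def test_empty_split_rejected(self):
        X, y = separable_toy(n_per_class=4)
        with pytest.raises(ValueError):
            train_model(build_architecture(1, 128), (X[:0], y[:0]), (X, y),
                        TrainingConfig())


class TestEvaluate:
    class Stub:
        """Model stub with fixed probabilities."""

        def __init__(self, probs):
            self.probs = np.asarray(probs, dtype=float)

        def predict_proba(self, X):
            return self.probs

    def test_perfect_prediction(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        m = evaluate(self.Stub(np.r_[np.ones(50) * 0.9, np.ones(50) * 0.1]),
                     (np.zeros((100, 1, 1, 1)), y))
        assert (m.accuracy, m.f1, m.precision, m.recall) == (1.0, 1.0, 1.0, 1.0)

    def test_contingency_arithmetic(self):
        # TP=40, FN=10, TN=45, FP=5
        y = np.r_[np.ones(50), np.zeros(50)]
        p = np.r_[np.ones(40), np.zeros(10), np.zeros(45), np.ones(5)]
        m = evaluate(self.Stub(p), (np.zeros((100, 1, 1, 1)), y))
        assert m.precision == pytest.approx(8 / 9)
        assert m.recall == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(0.85)
        assert m.f1 == pytest.approx(2 * (8 / 9 * 0.8) / (8 / 9 + 0.8))

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
        y = rng.integers(0, 2, 200)
        probs = rng.random(200)
        m = evaluate(self.Stub(probs), (np.zeros((200, 1, 1, 1)), y))
        pred = (probs >= 0.5).astype(int)
        assert m.accuracy == pytest.approx(accuracy_score(y, pred))
        assert m.f1 == pytest.approx(f1_score(y, pred))
        assert m.precision == pytest.approx(precision_score(y, pred))
        assert m.recall == pytest.approx(recall_score(y, pred))

    def test_all_negative_predictions_on_balanced_set(self):
        y = np.r_[np.ones(25), np.zeros(25)]
        m = evaluate(self.Stub(np.zeros(50)), (np.zeros((50, 1, 1, 1)), y))
        assert m.accuracy == 0.5 and m.recall == 0.0
        assert m.precision is None and m.f1 is None  # no positive predictions

    def test_f1_between_precision_and_recall(self, rng):
        y = rng.integers(0, 2, 100)
        m = evaluate(self.Stub(rng.random(100)), (np.zeros((100, 1, 1, 1)), y))
        if None not in (m.f1, m.precision, m.recall):
            assert min(m.precision, m.recall) - 1e-12 <= m.f1 <= max(m.precision, m.recall) + 1e-12

    def test_percent_view(self):
        m = EvalMetrics(accuracy=0.995, f1=None, precision=1.0, recall=0.99)
        pct = m.as_percent()
        assert pct["accuracy"] == pytest.approx(99.5) and pct["f1"] is None
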