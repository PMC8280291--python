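import numpy as np
import pytest

import cmapcv as c
from cmapcv.cv import N_BINS
from cmapcv.inverse import round_half_away_from_zero


def tiny_split(template, n_per_group=2, seed=0):
    cfg = c.SimConfig(n_per_group=n_per_group)
    corpus = c.build_corpus(template, cfg, seed=seed)
    return c.split_corpus(corpus, cfg, seed=seed)


class TestModelSpec:
    def test_best_architecture_builds_with_correct_shapes(self):
        spec = c.ModelSpec("lstm", True, 2, hidden_units=8)
        model = c.build_model(spec, seed=0)
        assert model.n_parameters > 0
        out = model.predict(np.zeros((3, 251)))
        assert out.shape == (3, N_BINS)

    def test_degenerate_width_still_builds(self):
        model = c.build_model(c.ModelSpec("gru", False, 1, hidden_units=1), seed=0)
        assert model.predict(np.zeros((1, 251))).shape == (1, N_BINS)

    def test_bidirectional_has_more_parameters(self):
        uni = c.build_model(c.ModelSpec("lstm", False, 2, hidden_units=8), seed=0)
        bi = c.build_model(c.ModelSpec("lstm", True, 2, hidden_units=8), seed=0)
        assert bi.n_parameters > uni.n_parameters

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(cell="simple_rnn", n_layers=2, bidirectional=False),
            dict(cell="simple_rnn", n_layers=1, bidirectional=True),
            dict(cell="elman"),
            dict(n_layers=4),
            dict(hidden_units=0),
        ],
    )
    def test_unsupported_combinations_rejected(self, kwargs):
        base = dict(cell="lstm", bidirectional=False, n_layers=1, hidden_units=4)
        with pytest.raises(ValueError):
            c.ModelSpec(**{**base, **kwargs})

    def test_grid_has_13_networks(self):
        specs = c.grid_specs(hidden_units=4)
        assert len(specs) == 13
        assert sum(s.cell == "simple_rnn" for s in specs) == 1
        assert sum(s.bidirectional for s in specs) == 6


class TestTraining:
    def test_loss_decreases_on_tiny_corpus(self, template):
        split = tiny_split(template)
        model = c.build_model(c.ModelSpec("gru", False, 1, hidden_units=6), seed=0)
        cfg = c.TrainConfig(max_epochs=5, batch_size=8, seed=0,
                            early_stop_patience=5)
        res = c.train(model, split, cfg)
        assert res.final_training_loss < res.train_loss[0]
        assert len(res.train_loss) == res.stopped_epoch <= 5
        assert np.all(np.isfinite(res.train_loss))

    def test_patience_zero_stops_at_first_rise(self, template):
        split = tiny_split(template)
        model = c.build_model(c.ModelSpec("lstm", False, 1, hidden_units=4), seed=0)
        # absurd learning rate forces the loss to rise immediately
        cfg = c.TrainConfig(max_epochs=50, batch_size=8, learning_rate=5.0,
                            early_stop_patience=0, seed=0)
        res = c.train(model, split, cfg)
        assert res.stopped_epoch < 50
        assert res.train_loss[res.stopped_epoch - 1] >= res.train_loss[res.stopped_epoch - 2]

    def test_never_exceeds_max_epochs(self, template):
        split = tiny_split(template)
        model = c.build_model(c.ModelSpec("gru", False, 1, hidden_units=4), seed=0)
        res = c.train(model, split, c.TrainConfig(max_epochs=3, batch_size=16, seed=0))
        assert res.stopped_epoch <= 3

    def test_identical_seeds_give_identical_curves(self, template):
        split = tiny_split(template)
        cfg = c.TrainConfig(max_epochs=3, batch_size=8, seed=7)
        r1 = c.train(c.build_model(c.ModelSpec("lstm", True, 1, hidden_units=4), seed=7), split, cfg)
        r2 = c.train(c.build_model(c.ModelSpec("lstm", True, 1, hidden_units=4), seed=7), split, cfg)
        assert r1.train_loss == r2.train_loss
        assert r1.val_loss == r2.val_loss

    def test_empty_training_partition_rejected(self):
        split = c.DatasetSplit(train=(), test=(), seed=0)
        model = c.build_model(c.ModelSpec("lstm", False, 1, hidden_units=4), seed=0)
        with pytest.raises(ValueError):
            c.train(model, split, c.TrainConfig(max_epochs=1))

    def test_history_csv_round_trip(self, template, tmp_path):
        split = tiny_split(template)
        model = c.build_model(c.ModelSpec("gru", False, 1, hidden_units=4), seed=0)
        res = c.train(model, split, c.TrainConfig(max_epochs=2, batch_size=16, seed=0))
        p = tmp_path / "hist.csv"
        res.to_csv(p)
        import pandas as pd

        df = pd.read_csv(p)
        assert list(df.columns) == ["epoch", "train_loss", "train_acc", "val_loss", "val_acc"]
        assert len(df) == res.stopped_epoch


class TestMetrics:
    def test_perfect_predictions_score_one(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 40, size=(50, N_BINS)).astype(float)
        assert c.dominant_bin_accuracy(labels, labels) == 1.0

    def test_negated_labels_score_zero_for_distinct_maxima(self):
        labels = np.zeros((10, N_BINS))
        labels[np.arange(10), np.arange(5, 15)] = 7.0
        assert c.dominant_bin_accuracy(-labels, labels) == 0.0

    def test_chance_level_is_one_over_28(self):
        rng = np.random.default_rng(42)
        n = 10_000
        labels = np.zeros((n, N_BINS))
        labels[np.arange(n), rng.integers(0, N_BINS, n)] = 1.0
        preds = rng.standard_normal((n, N_BINS))
        acc = c.dominant_bin_accuracy(preds, labels)
        assert abs(acc - 1 / N_BINS) < 0.01

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            c.dominant_bin_accuracy(np.zeros((2, 27)), np.zeros((2, 28)))

    def test_rounding_half_away_from_zero(self):
        x = np.array([0.4, 0.5, 1.6, -0.5, -1.4, 2.5])
        assert np.array_equal(round_half_away_from_zero(x), [0, 1, 2, -1, -1, 3])


class TestPredictHistogram:
    class _Stub:
        """Duck-typed trained model emitting a fixed raw output."""

        def __init__(self, raw):
            self.raw = np.asarray(raw, dtype=float)
            self.trained = True

        def predict(self, waveform, batch_size=256):
            return self.raw[None, :]

    def test_rounding_contract(self):
        raw = np.zeros(N_BINS)
        raw[0], raw[1], raw[2] = 0.4, 1.6, 2.5
        hist = c.predict_histogram(self._Stub(raw), np.zeros(251))
        assert hist.counts[0] == 0 and hist.counts[1] == 2 and hist.counts[2] == 3

    def test_negative_outputs_clip_to_zero(self):
        hist = c.predict_histogram(self._Stub(np.full(N_BINS, -0.7)), np.zeros(251))
        assert hist.total == 0

    def test_untrained_model_rejected(self):
        model = c.build_model(c.ModelSpec("lstm", False, 1, hidden_units=4), seed=0)
        with pytest.raises(ValueError):
            c.predict_histogram(model, np.zeros(251))


class TestCheckpointing:
    def test_save_load_round_trip(self, template, tmp_path):
        split = tiny_split(template)
        model = c.build_model(c.ModelSpec("lstm", True, 1, hidden_units=4), seed=0)
        c.train(model, split, c.TrainConfig(max_epochs=2, batch_size=16, seed=0))
        c.save_model(model, tmp_path / "m")
        loaded = c.load_model(tmp_path / "m")
        x = np.stack([s.waveform for s in split.test[:4]])
        assert np.allclose(model.predict(x), loaded.predict(x))
        assert loaded.trained
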