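"""Splitting, metrics, training contract and sweeps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ptfm
from ptfm import train_eval as te
from ptfm.errors import ConfigurationError, DataError
from ptfm.models import CNNConfig
from ptfm.simulator import LabeledDataset


def fake_dataset(n_per_class, classes=tuple(range(10)), seed=0):
    """Label-only dataset (segments unused) for split arithmetic tests."""
    labels = np.repeat(np.asarray(classes, dtype=float), n_per_class)
    return LabeledDataset(segments=[None] * len(labels), labels=labels,
                          classes=list(classes), seed=seed)


class TestSplit:
    def test_study_scale_geometry(self):
        """25,000 samples at 60/20/20 -> 15,000/5,000/5,000 with 500 per
        class in the test split."""
        ds = te.split_dataset(fake_dataset(2500), te.SplitSpec(seed=0))
        counts = pd.Series(ds.split).value_counts()
        assert counts["train"] == 15000
        assert counts["val"] == 5000
        assert counts["test"] == 5000
        for c in range(10):
            in_test = ((ds.labels == c) & (ds.split == "test")).sum()
            assert in_test == 500

    def test_seeded_reproducibility(self):
        a = te.split_dataset(fake_dataset(50), te.SplitSpec(seed=3))
        b = te.split_dataset(fake_dataset(50), te.SplitSpec(seed=3))
        assert np.array_equal(a.split, b.split)
        c = te.split_dataset(fake_dataset(50), te.SplitSpec(seed=4))
        assert not np.array_equal(a.split, c.split)

    def test_remainder_goes_to_train(self):
        ds = te.split_dataset(fake_dataset(7, classes=(0.0,)),
                              te.SplitSpec(seed=0))
        counts = pd.Series(ds.split).value_counts()
        assert counts["train"] == 7 - round(0.2 * 7) - round(0.2 * 7)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            te.SplitSpec(fractions=(0.5, 0.2, 0.2))
        with pytest.raises(ConfigurationError):
            te.SplitSpec(fractions=(0.8, -0.1, 0.3))


class TestConfusionMatrix:
    def test_perfect_predictor_is_diagonal(self):
        y = np.repeat(np.arange(10), 500)
        cm = te.ConfusionMatrix.from_predictions(y, y, list(range(10)))
        assert np.array_equal(cm.counts, np.eye(10, dtype=int) * 500)
        assert all(cm.counts.sum(axis=1) == 500)

    def test_constant_predictor_single_column(self):
        y = np.repeat(np.arange(10), 50)
        cm = te.ConfusionMatrix.from_predictions(y, np.full_like(y, 3),
                                                 list(range(10)))
        assert cm.counts[:, 3].sum() == cm.total
        assert np.delete(cm.counts, 3, axis=1).sum() == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            te.ConfusionMatrix(np.array([[1, -1], [0, 1]]), [0, 1])


class TestMetrics:
    def test_reference_worked_example_969(self):
        """Balanced 10x10 matrix with diagonal 4845 of 5000: accuracy 96.9%,
        macro-recall equals accuracy, 155 misclassifications."""
        cm = balanced_confusion(diag_total=4845)
        m = te.metrics(cm)
        assert m["accuracy"] == pytest.approx(0.969)
        assert m["macro_recall"] == pytest.approx(m["accuracy"], abs=1e-12)
        assert m["misclassified"] == 155

    def test_reference_worked_example_995(self):
        cm = balanced_confusion(diag_total=4975)
        m = te.metrics(cm)
        assert m["accuracy"] == pytest.approx(0.995)
        assert m["misclassified"] == 25

    def test_identity_matrix_all_ones(self):
        cm = te.ConfusionMatrix(np.eye(10, dtype=int) * 77, list(range(10)))
        m = te.metrics(cm)
        assert m["accuracy"] == m["macro_recall"] == m["macro_f1"] == 1.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_balanced_rows_make_macro_recall_equal_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 12))
        rows = []
        row_total = int(rng.integers(10, 500))
        for _ in range(k):
            p = rng.dirichlet(np.ones(k))
            row = rng.multinomial(row_total, p)
            rows.append(row)
        cm = te.ConfusionMatrix(np.array(rows), list(range(k)))
        m = te.metrics(cm)
        assert m["macro_recall"] == pytest.approx(m["accuracy"], abs=1e-12)

    def test_empty_row_excluded_with_warning(self):
        counts = np.eye(3, dtype=int) * 10
        counts[2, :] = 0
        cm = te.ConfusionMatrix(counts, [0, 1, 2])
        with pytest.warns(UserWarning, match="excluded"):
            m = te.metrics(cm)
        assert m["excluded_classes"] == [2]
        assert m["macro_recall"] == pytest.approx(1.0)

    def test_against_sklearn_on_random_predictions(self):
        from sklearn.metrics import accuracy_score, f1_score, recall_score
        rng = np.random.default_rng(7)
        y_true = rng.integers(0, 10, 2000)
        y_pred = np.where(rng.random(2000) < 0.7, y_true,
                          rng.integers(0, 10, 2000))
        cm = te.ConfusionMatrix.from_predictions(y_true, y_pred,
                                                 list(range(10)))
        m = te.metrics(cm)
        assert m["accuracy"] == pytest.approx(accuracy_score(y_true, y_pred))
        assert m["macro_recall"] == pytest.approx(
            recall_score(y_true, y_pred, average="macro"))
        assert m["macro_f1"] == pytest.approx(
            f1_score(y_true, y_pred, average="macro"))


def balanced_confusion(diag_total, k=10, per_class=500):
    """Balanced matrix with a prescribed diagonal sum; errors spread onto
    off-diagonal cells round-robin."""
    errors = k * per_class - diag_total
    base, extra = divmod(errors, k)
    counts = np.zeros((k, k), dtype=int)
    for i in range(k):
        e = base + (1 if i < extra else 0)
        counts[i, i] = per_class - e
        counts[i, (i + 1) % k] = e
    return te.ConfusionMatrix(counts, list(range(k)))


class TestTraining:
    def test_zero_epochs_returns_initial_model_at_chance(self, tiny_benchmark):
        """An untrained model scores at the 10-class chance level on a
        balanced test set (99% binomial band around 0.1)."""
        cfg = te.TrainConfig(max_epochs=0, seed=0)
        r = te.run_experiment(tiny_benchmark, "cnn",
                              CNNConfig(n_blocks=2, base_channels=4,
                                        pool_size=4), cfg)
        assert len(r["history"]) == 0
        n = r["confusion"].total
        band = 2.576 * np.sqrt(0.1 * 0.9 / n)
        assert abs(r["metrics"]["accuracy"] - 0.1) <= band + 1e-9

    def test_two_tone_toy_converges(self, two_tone_toy):
        """A small CNN separates pure 2 kHz from 6 kHz tones within 20
        epochs (validation accuracy >= 0.99)."""
        cfg = te.TrainConfig(max_epochs=20, early_stop_patience=20,
                             learning_rate=3e-3, seed=0)
        model_cfg = CNNConfig(n_blocks=2, base_channels=4, pool_size=4,
                              n_classes=2)
        r = te.run_experiment(two_tone_toy, "cnn", model_cfg, cfg)
        assert r["history"]["val_acc"].max() >= 0.99

    def test_history_reproducible_with_fixed_seed(self, tiny_benchmark):
        cfg = te.TrainConfig(max_epochs=2, seed=5)
        model_cfg = CNNConfig(n_blocks=1, base_channels=4, pool_size=4)
        a = te.run_experiment(tiny_benchmark, "cnn", model_cfg, cfg)
        b = te.run_experiment(tiny_benchmark, "cnn", model_cfg, cfg)
        pd.testing.assert_frame_equal(a["history"], b["history"])

    def test_conservation_of_test_counts(self, tiny_benchmark):
        cfg = te.TrainConfig(max_epochs=1, seed=0)
        r = te.run_experiment(tiny_benchmark, "lstm",
                              ptfm.LSTMConfig(n_units=8), cfg)
        assert r["confusion"].total == (tiny_benchmark.split == "test").sum()


class TestSweep:
    def test_row_per_value_and_failure_column(self, tiny_benchmark):
        cfg = te.TrainConfig(max_epochs=1, seed=0)
        table = te.sweep("cnn", [1, 2], tiny_benchmark, cfg,
                         config_overrides={"base_channels": 4, "pool_size": 4})
        assert list(table["value"]) == [1, 2]
        assert set(table.columns) >= {"value", "mean_accuracy", "sd",
                                      "n_failed"}
        assert (table["n_failed"] == 0).all()

    def test_empty_grid_rejected(self, tiny_benchmark):
        with pytest.raises(ConfigurationError):
            te.sweep("cnn", [], tiny_benchmark, te.TrainConfig(max_epochs=1))
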