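"""KO/non-KO gate: encoding, architectures, training protocol, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from koassign.classifier import (
    ClassifierConfig,
    ClassifierCounts,
    build_model,
    classifier_metrics,
    counts_from_predictions,
    encode_sequence,
    load_model,
    predict_ko,
    predict_scores,
    save_model,
    train,
)
from koassign.classifier import _eval_loss


class TestEncodeSequence:
    def test_alphabetical_mapping_and_padding(self):
        assert encode_sequence("ACD", 6).tolist() == [1, 2, 3, 0, 0, 0]
        assert encode_sequence("Y", 4).tolist() == [20, 0, 0, 0]

    def test_empty_sequence_is_all_zero(self):
        assert encode_sequence("", 5).tolist() == [0] * 5

    def test_overlength_and_invalid_letter_error(self):
        with pytest.raises(ValueError):
            encode_sequence("MKVL", 3)
        with pytest.raises(ValueError):
            encode_sequence("MXV", 10)


class TestBuildModel:
    def test_mlp_outputs_scalar_probability_per_example(self):
        model = build_model(ClassifierConfig(seed=0), input_dim=16)
        probs = predict_scores(model, np.zeros((3, 16)))
        assert probs.shape == (3,)
        assert np.all((probs > 0) & (probs < 1))

    @pytest.mark.parametrize("arch", ["lstm", "attention"])
    def test_baselines_output_probability_on_padded_input(self, arch):
        cfg = ClassifierConfig(architecture=arch, max_len=40, seed=0)
        model = build_model(cfg)
        tokens = np.zeros((2, 40), dtype=np.int64)
        probs = predict_scores(model, tokens)
        assert probs.shape == (2,)
        assert np.all(np.isfinite(probs)) and np.all((probs > 0) & (probs < 1))

    @pytest.mark.parametrize("arch", ["mlp", "lstm", "attention"])
    def test_identical_seed_identical_parameters(self, arch):
        cfg = ClassifierConfig(architecture=arch, max_len=30, seed=9)
        m1 = build_model(cfg, input_dim=8)
        m2 = build_model(cfg, input_dim=8)
        for name in m1.params:
            assert np.array_equal(m1.params[name].data, m2.params[name].data)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(architecture="transformer")


class TestTrain:
    def test_separable_clusters_reach_high_f1(self, two_gaussian_fixture):
        X, y = two_gaussian_fixture
        cfg = ClassifierConfig(seed=3, max_epochs=60)
        model = build_model(cfg, input_dim=X.shape[1])
        # honest held-out evaluation: train on 80%, score the rest
        cut = int(0.8 * len(y))
        model, history = train(model, X[:cut], y[:cut], cfg)
        counts = counts_from_predictions(
            y[cut:] > 0, predict_scores(model, X[cut:]) > 0.5
        )
        assert classifier_metrics(counts).f1_star >= 0.99
        assert history.val_loss[history.best_epoch] == min(history.val_loss)

    def test_same_seed_identical_history(self, two_gaussian_fixture):
        X, y = two_gaussian_fixture
        cfg = ClassifierConfig(seed=1, max_epochs=10, patience=3)
        _, h1 = train(build_model(cfg, input_dim=X.shape[1]), X, y, cfg)
        _, h2 = train(build_model(cfg, input_dim=X.shape[1]), X, y, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_divergent_training_returns_best_snapshot(self, two_gaussian_fixture):
        """A blown-up learning rate worsens validation loss immediately;
        patience 1 must stop at epoch 2 and return the epoch-1 snapshot."""
        X, y = two_gaussian_fixture
        cfg = ClassifierConfig(seed=2, learning_rate=50.0, patience=1,
                               max_epochs=20)
        model = build_model(cfg, input_dim=X.shape[1])
        model, history = train(model, X, y, cfg)
        assert history.n_epochs == 2
        assert history.best_epoch == 0
        # returned parameters really are the best-on-validation snapshot
        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(len(y))
        n_val = max(1, int(round(cfg.validation_fraction * len(y))))
        val_idx = order[:n_val]
        restored_loss = _eval_loss(model, X[val_idx], y[val_idx])
        assert restored_loss == pytest.approx(min(history.val_loss))

    def test_single_class_input_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError, match="degenerate labels"):
            train(build_model(ClassifierConfig(), input_dim=4), X,
                  np.ones(10), ClassifierConfig())

    @pytest.mark.parametrize("arch", ["lstm", "attention"])
    def test_baselines_learn_token_composition(self, arch):
        """Loss decreases on a composition-separable toy token problem."""
        rng = np.random.default_rng(0)
        letters = "ACDEFGHIK"
        seqs = []
        for i in range(40):
            dominant = "A" if i % 2 else "Y"
            seqs.append("".join(
                dominant if rng.random() < 0.6
                else letters[rng.integers(len(letters))]
                for _ in range(40)
            ))
        X = np.stack([encode_sequence(s, 40) for s in seqs])
        y = np.array([i % 2 for i in range(40)], dtype=float)
        cfg = ClassifierConfig(architecture=arch, max_len=40, max_epochs=5,
                               patience=5, batch_size=8, seed=0)
        _, history = train(build_model(cfg), X, y, cfg)
        assert history.train_loss[-1] < history.train_loss[0]


class TestPredict:
    def test_threshold_is_strict(self, two_gaussian_fixture):
        X, y = two_gaussian_fixture
        cfg = ClassifierConfig(seed=0, max_epochs=5, patience=5)
        model, _ = train(build_model(cfg, input_dim=X.shape[1]), X, y, cfg)
        score, _ = predict_ko(model, X[0])
        # is_ko uses score > threshold: at threshold == score it must be False
        _, is_ko = predict_ko(model, X[0], threshold=score)
        assert not is_ko
        _, is_ko = predict_ko(model, X[0], threshold=0.0)
        assert is_ko  # any positive score beats a zero threshold

    def test_dimension_mismatch_errors(self):
        model = build_model(ClassifierConfig(seed=0), input_dim=8)
        with pytest.raises(ValueError):
            predict_ko(model, np.zeros(5))


class TestSaveLoad:
    def test_round_trip_preserves_predictions(self, tmp_path,
                                              two_gaussian_fixture):
        X, y = two_gaussian_fixture
        cfg = ClassifierConfig(seed=4, max_epochs=3, patience=3)
        model, _ = train(build_model(cfg, input_dim=X.shape[1]), X, y, cfg)
        path = tmp_path / "model.npz"
        save_model(model, path)
        reloaded = load_model(path)
        assert np.allclose(predict_scores(model, X), predict_scores(reloaded, X))


class TestClassifierMetrics:
    def test_symmetric_case(self):
        metrics = classifier_metrics(ClassifierCounts(TP=2, FP=1, FN=1, TN=0))
        assert metrics.precision_star == pytest.approx(2 / 3)
        assert metrics.recall_star == pytest.approx(2 / 3)
        assert metrics.f1_star == pytest.approx(2 / 3)

    def test_zero_match_limit_convention(self):
        metrics = classifier_metrics(ClassifierCounts(TP=0, FP=5, FN=5, TN=0))
        assert (metrics.precision_star, metrics.recall_star,
                metrics.f1_star) == (0.0, 0.0, 0.0)

    def test_undefined_denominator_gives_nan(self):
        metrics = classifier_metrics(ClassifierCounts(TP=0, FP=0, FN=5, TN=0))
        assert np.isnan(metrics.precision_star) and np.isnan(metrics.f1_star)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ClassifierCounts(TP=-1, FP=0, FN=0, TN=0)

    def test_counts_match_brute_force_confusion(self):
        rng = np.random.default_rng(5)
        y_true = rng.random(200) > 0.5
        y_pred = rng.random(200) > 0.5
        counts = counts_from_predictions(y_true, y_pred)
        expected = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
        for t, p in zip(y_true, y_pred):  # independent per-pair recount
            key = ("T" if t == p else "F") + ("P" if p else "N")
            expected[key] += 1
        assert (counts.TP, counts.FP, counts.FN, counts.TN) == (
            expected["TP"], expected["FP"], expected["FN"], expected["TN"]
        )

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_f1_between_precision_and_recall(self, tp, fp, fn):
        metrics = classifier_metrics(ClassifierCounts(tp, fp, fn, 0))
        values = (metrics.precision_star, metrics.recall_star)
        if not any(np.isnan(v) for v in values + (metrics.f1_star,)):
            assert min(values) - 1e-12 <= metrics.f1_star <= max(values) + 1e-12

    def test_threshold_sweep_monotonicity(self, two_gaussian_fixture):
        X, y = two_gaussian_fixture
        cfg = ClassifierConfig(seed=6, max_epochs=5, patience=5)
        model, _ = train(build_model(cfg, input_dim=X.shape[1]), X, y, cfg)
        scores = predict_scores(model, X)
        positives, recalls = [], []
        for threshold in np.linspace(0.05, 0.95, 10):
            pred = scores > threshold
            positives.append(int(pred.sum()))
            counts = counts_from_predictions(y > 0, pred)
            recalls.append(classifier_metrics(counts).recall_star)
        assert all(a >= b for a, b in zip(positives, positives[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(recalls, recalls[1:]))
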