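"""Model configuration, training protocol, epoch selection, persistence."""

import numpy as np
import pytest

from flavorlex.exceptions import UntrainedModelError, ValidationError
from flavorlex.model import (DescriptorClassifier, DescriptorResults,
                             ModelConfig, TrainingHistory, classify,
                             detect_divergence_epoch, learning_curve)

SMALL = dict(lstm_units=16, branch_dense_units=8, head_layout=(6, 4),
             embedding_dim=16, context_length=6)


@pytest.fixture(scope="module")
def fitted(small_examples):
    cfg = ModelConfig(epochs=3, seed=21, **SMALL)
    return DescriptorClassifier(small_examples, cfg).fit(), small_examples


class TestConfig:
    def test_defaults_are_reference_protocol(self):
        cfg = ModelConfig()
        assert (cfg.lstm_units, cfg.branch_dense_units) == (256, 128)
        assert cfg.head_layout == (64, 32)
        assert (cfg.learning_rate, cfg.batch_size, cfg.epochs) == (1e-4, 32, 3)
        assert cfg.validation_fraction == 0.2

    @pytest.mark.parametrize("kwargs", [
        dict(head_layout=(32, 64)),       # not decreasing
        dict(head_layout=(32, 0)),        # non-positive layer
        dict(validation_fraction=0.0),
        dict(validation_fraction=1.0),
        dict(lstm_units=0),
        dict(learning_rate=0.0),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ModelConfig(**kwargs)

    def test_round_trip_dict(self):
        cfg = ModelConfig(epochs=5, head_layout=(10, 4))
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestTraining:
    def test_history_lengths_match_epochs(self, fitted):
        results, _ = fitted
        h = results.history
        assert len(h.train_loss) == len(h.val_loss) == 3
        assert len(h.train_accuracy) == len(h.val_accuracy) == 3

    def test_validation_split_is_20_percent(self, fitted):
        results, examples = fitted
        assert results.n_val == round(0.2 * len(examples))
        assert results.n_train + results.n_val == len(examples)

    def test_loss_decreases_on_separable_data(self, fitted):
        results, _ = fitted
        assert results.history.train_loss[-1] < results.history.train_loss[0]

    def test_two_runs_identical_histories(self, small_examples):
        cfg = ModelConfig(epochs=2, seed=33, **SMALL)
        h1 = DescriptorClassifier(small_examples, cfg).fit().history
        h2 = DescriptorClassifier(small_examples, cfg).fit().history
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        assert h1.val_accuracy == h2.val_accuracy

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            DescriptorClassifier([], ModelConfig(**SMALL)).fit()

    def test_summary_mentions_fit_dimensions(self, fitted):
        results, _ = fitted
        text = results.summary()
        assert "epoch" in text and "val_loss" in text
        assert str(results.n_val) in text


class TestPrediction:
    def test_probabilities_in_unit_interval(self, fitted):
        results, examples = fitted
        probs = results.predict_proba(examples[:64])
        assert np.all((probs >= 0) & (probs <= 1))

    def test_threshold_filtering(self):
        probs = np.array([0.71, 0.80, 0.10])
        np.testing.assert_array_equal(classify(probs, 0.75), [0, 1, 0])
        np.testing.assert_array_equal(classify(probs, 0.5), [1, 1, 0])

    def test_threshold_bounds(self):
        with pytest.raises(ValidationError):
            classify(np.array([0.5]), 1.0)

    def test_checkpoint_round_trip(self, fitted, tmp_path):
        results, examples = fitted
        path = tmp_path / "model.npz"
        results.save(path)
        loaded = DescriptorResults.load(path)
        np.testing.assert_allclose(loaded.predict_proba(examples[:32]),
                                   results.predict_proba(examples[:32]),
                                   atol=1e-6)
        assert loaded.config == results.config


class TestLearningCurve:
    def test_default_is_twenty_sessions(self, small_examples):
        cfg = ModelConfig(epochs=1, seed=2, **SMALL)
        sessions = learning_curve(small_examples[:400], cfg)
        assert len(sessions) == 20
        assert [s["fraction"] for s in sessions] == \
            [round(0.05 * k, 2) for k in range(1, 21)]

    def test_subsets_nested_and_full_fraction_uses_all(self, small_examples):
        cfg = ModelConfig(epochs=1, seed=2, **SMALL)
        sessions = learning_curve(small_examples[:200], cfg,
                                  fractions=[0.1, 0.5, 1.0])
        sizes = [s["n_examples"] for s in sessions]
        assert sizes == sorted(sizes)
        assert sizes[-1] == 200

    def test_invalid_fraction_rejected(self, small_examples):
        cfg = ModelConfig(epochs=1, **SMALL)
        for bad in ([0.0], [1.2]):
            with pytest.raises(ValidationError):
                learning_curve(small_examples[:50], cfg, fractions=bad)


class TestDivergenceEpoch:
    def test_argmin_before_first_rise(self):
        h = TrainingHistory(train_loss=[0.6, 0.5, 0.4],
                            train_accuracy=[0.7, 0.8, 0.9],
                            val_loss=[0.50, 0.40, 0.45],
                            val_accuracy=[0.7, 0.8, 0.8])
        assert detect_divergence_epoch(h) == 2

    def test_monotone_improvement_returns_final_epoch(self):
        h = TrainingHistory(train_loss=[0.5, 0.4, 0.3, 0.2, 0.1],
                            train_accuracy=[0.6] * 5,
                            val_loss=[0.5, 0.4, 0.3, 0.25, 0.2],
                            val_accuracy=[0.6] * 5)
        assert detect_divergence_epoch(h) == 5

    def test_short_history_rejected(self):
        h = TrainingHistory(train_loss=[0.5], train_accuracy=[0.5],
                            val_loss=[0.5], val_accuracy=[0.5])
        with pytest.raises(ValidationError):
            detect_divergence_epoch(h)

    def test_overtrained_tiny_run_recommends_early_stop(self):
        """Overtraining a small unseparated dataset triggers divergence.

        With separation 0 the labels are not predictable from the held-out
        vectors, so a long aggressive run memorizes the training noise and
        validation loss turns upward before the final epoch.
        """
        from dataclasses import replace
        from flavorlex.corpus import segment_and_tag
        from flavorlex.sequences import assemble_examples, instances_from_gold
        from flavorlex.synthetic import (SynthConfig, build_vocabulary,
                                         generate_corpus,
                                         generate_embedding_space, make_tagger)
        cfg = SynthConfig(n_descriptor_types=150, n_nondescriptor_types=150,
                          n_reviews=30, separation=0.0, embedding_dim=16,
                          seed=19)
        vocab = build_vocabulary(cfg)
        store, _ = generate_embedding_space(cfg, vocab)
        reviews, gold = generate_corpus(replace(cfg, seed=20), vocab)
        tokens = {r.review_id: segment_and_tag(r, make_tagger(vocab))
                  for r in reviews}
        examples = assemble_examples(instances_from_gold(tokens, gold),
                                     tokens, store, n=3)
        mc = ModelConfig(epochs=12, seed=4, learning_rate=1e-2, **SMALL)
        results = DescriptorClassifier(examples, mc).fit()
        assert detect_divergence_epoch(results.history) < 12
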