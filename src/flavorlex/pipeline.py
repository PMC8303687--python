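"""End-to-end experiment orchestration and per-review lexicon extraction.

``run_experiment`` chains the pipeline stages — tag, label, assemble, split,
train, evaluate — on one corpus and returns an :class:`ExperimentReport`
holding the training history, the classifier's held-out metrics, and the
POS-baseline metrics computed on the identical test partition.
``extract_lexicon`` applies a trained model to one review and returns its
descriptor vocabulary with probabilities.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotation import ConsensusRecord, project_labels_to_tokens
from .corpus import PosTagger, Review, segment_and_tag
from .embeddings import EmbeddingStore
from .evaluation import Metrics, compute_metrics, pos_baseline_predict
from .exceptions import StageError, UntrainedModelError, ValidationError
from .model import (DescriptorClassifier, DescriptorResults, ModelConfig,
                    TrainingHistory, detect_divergence_epoch)
from .sequences import (assemble_examples, class_ratio, index_instances,
                        instances_from_gold, split_examples,
                        type_overlap_fraction)

__all__ = ["ExperimentReport", "run_experiment", "extract_lexicon"]


@dataclass
class ExperimentReport:
    """Everything one experiment produced, ready to serialize.

    Both metric blocks — the LSTM classifier and the POS baseline — are
    computed on the identical held-out test partition.
    """

    config: dict
    dataset: dict
    history: TrainingHistory
    lstm_metrics: Metrics
    pos_metrics: Metrics
    recommended_epoch: int
    results: DescriptorResults | None = None
    artifact_paths: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "dataset": self.dataset,
            "history": {
                "train_loss": self.history.train_loss,
                "train_accuracy": self.history.train_accuracy,
                "val_loss": self.history.val_loss,
                "val_accuracy": self.history.val_accuracy,
            },
            "lstm_metrics": self.lstm_metrics.to_dict(),
            "pos_baseline_metrics": self.pos_metrics.to_dict(),
            "recommended_epoch": self.recommended_epoch,
            "artifact_paths": self.artifact_paths,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2),
                              encoding="utf-8")

    def summary(self) -> str:
        m, p = self.lstm_metrics, self.pos_metrics
        lines = [
            "Experiment report",
            "=" * 60,
            f"instances: {self.dataset['n_instances']}  "
            f"(train {self.dataset['n_train']}, test {self.dataset['n_test']})",
            f"class ratio (descriptor): {self.dataset['class_ratio'][0]:.3f}",
            f"OOV rate: {self.dataset['oov_rate']:.4f}   "
            f"train/test type overlap: {self.dataset['type_overlap']:.3f}",
            "-" * 60,
            f"{'':<14}{'accuracy':>9} {'precision':>10} {'recall':>8} {'f1':>8}",
            f"{'LSTM':<14}{m.accuracy:>9.5f} {m.precision:>10.5f} "
            f"{m.recall:>8.5f} {m.f1:>8.5f}",
            f"{'POS baseline':<14}{p.accuracy:>9.5f} {p.precision:>10.5f} "
            f"{p.recall:>8.5f} {p.f1:>8.5f}",
            "-" * 60,
            f"recommended epochs (val-loss divergence): {self.recommended_epoch}",
        ]
        return "\n".join(lines)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False
    return _Ctx()


def run_experiment(
    reviews: list[Review],
    labels: Mapping,
    store: EmbeddingStore,
    tagger: PosTagger | None = None,
    model_config: ModelConfig | None = None,
    n: int = 3,
    test_fraction: float = 0.2,
    split_seed: int = 0,
    split_level: str = "instance",
    threshold: float = 0.5,
) -> ExperimentReport:
    """Run the full pipeline on one corpus and evaluate against the baseline.

    Parameters
    ----------
    labels
        Either lemma-level consensus records (``lemma -> ConsensusRecord``),
        which are projected onto token types and then located in the corpus,
        or positional gold labels (``(review_id, sentence, position) -> 0/1``)
        as produced by the synthetic generator.
    store
        Embedding store used for the context windows and target words.
    model_config
        Hyperparameters; shape fields (embedding dimension, context length)
        are overridden to match the data.
    """
    model_config = model_config or ModelConfig()

    with _stage("tag"):
        tokens_by_review = {r.review_id: segment_and_tag(r, tagger)
                            for r in reviews}

    with _stage("label"):
        if labels and isinstance(next(iter(labels)), tuple):
            instances = instances_from_gold(tokens_by_review, labels)
        else:
            all_tokens = [t for toks in tokens_by_review.values() for t in toks]
            records: Mapping[str, ConsensusRecord] = labels
            token_types = project_labels_to_tokens(records, all_tokens)
            instances = index_instances(tokens_by_review, token_types)
        if len({i.label for i in instances}) < 2:
            raise ValidationError("labels must cover both classes")

    with _stage("assemble"):
        store.reset_counters()
        examples = assemble_examples(instances, tokens_by_review, store, n=n)
        oov_rate = store.oov_rate

    with _stage("split"):
        train, test = split_examples(examples, test_fraction, split_seed,
                                     level=split_level)
        overlap = type_overlap_fraction(train, test)

    with _stage("train"):
        config = dataclasses.replace(
            model_config, embedding_dim=store.dimension, context_length=2 * n)
        classifier = DescriptorClassifier(train, config)
        results = classifier.fit()

    with _stage("evaluate"):
        y_true = np.array([e.label for e in test])
        y_pred = results.classify(test, threshold=threshold)
        lstm_metrics = compute_metrics(y_true, y_pred)
        pos_pred = pos_baseline_predict([e.provenance for e in test])
        pos_metrics = compute_metrics(y_true, pos_pred)
        recommended = detect_divergence_epoch(results.history) \
            if len(results.history) >= 2 else len(results.history)

    dataset = {
        "n_instances": len(examples),
        "n_train": len(train),
        "n_test": len(test),
        "class_ratio": list(class_ratio(examples)),
        "class_ratio_test": list(class_ratio(test)),
        "oov_rate": oov_rate,
        "type_overlap": overlap,
        "threshold": threshold,
        "context_n": n,
        "split_level": split_level,
        "split_seed": split_seed,
        "test_fraction": test_fraction,
    }
    return ExperimentReport(
        config=config.to_dict(),
        dataset=dataset,
        history=results.history,
        lstm_metrics=lstm_metrics,
        pos_metrics=pos_metrics,
        recommended_epoch=recommended,
        results=results,
    )


def extract_lexicon(
    results: DescriptorResults,
    store: EmbeddingStore,
    review: Review,
    tagger: PosTagger | None = None,
    threshold: float = 0.5,
    n: int = 3,
) -> list[tuple[str, float]]:
    """Score every word of one review and return its descriptor lexicon.

    Every non-punctuation token is scored through its context window with
    the same preprocessing used in training (punctuation removed, stop
    words retained). Token types reaching ``threshold`` are returned
    case-folded and deduplicated — keeping each type's maximum probability —
    sorted by probability descending (ties alphabetical). At threshold 0.0
    every token type of the review is returned.
    """
    if not results.model.is_fitted:
        raise UntrainedModelError(
            "refusing to extract a lexicon with an untrained model")
    if not 0 <= threshold < 1:
        raise ValidationError(f"threshold must be in [0,1), got {threshold}")
    tokens = segment_and_tag(review, tagger)
    tokens_by_review = {review.review_id: tokens}
    gold = {(review.review_id, t.sentence_index, t.filtered_position): 0
            for t in tokens if not t.is_punct}
    if not gold:
        return []
    instances = instances_from_gold(tokens_by_review, gold)
    examples = assemble_examples(instances, tokens_by_review, store, n=n)
    probs = results.predict_proba(examples)
    best: dict[str, float] = {}
    for example, prob in zip(examples, probs):
        token_type = example.provenance.token_type
        if prob > best.get(token_type, -1.0):
            best[token_type] = float(prob)
    lexicon = [(t, p) for t, p in best.items() if p >= threshold]
    lexicon.sort(key=lambda item: (-item[1], item[0]))
    return lexicon
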