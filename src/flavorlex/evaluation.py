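"""Classification metrics, the POS baseline, and 2-D embedding projection.

The positive class is always *descriptor*. Precision is TP/(TP+FP), recall
is TP/(TP+FN), F1 their harmonic mean; a zero denominator yields 0 with the
metric flagged as degenerate so batch evaluation never raises.

The baseline comparator labels every noun and adjective a descriptor and
everything else a non-descriptor — the rule-based state of the art this
classifier is measured against. Its recall is near-perfect by construction
(almost all true descriptors are nouns or adjectives) while its precision is
limited by all the non-descriptive nouns and adjectives in running text.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ValidationError

__all__ = ["Metrics", "compute_metrics", "pos_baseline_predict", "project_2d",
           "plot_projection"]

_BASELINE_POSITIVE_POS = ("NOUN", "ADJ")


@dataclass(frozen=True)
class Metrics:
    """Binary-classification metrics with their confusion counts."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    degenerate: tuple[str, ...] = field(default=())

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "n": self.n, "positive_class": "descriptor",
            "degenerate": list(self.degenerate),
        }


def compute_metrics(y_true: Sequence[int], y_pred: Sequence[int]) -> Metrics:
    """Accuracy, precision, recall, F1 and the confusion matrix.

    Zero-denominator ratios are reported as 0 and named in ``degenerate``.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValidationError(
            f"label lengths differ: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValidationError("cannot compute metrics on empty label lists")
    bad = set(np.unique(y_true)) | set(np.unique(y_pred))
    if not bad <= {0, 1}:
        raise ValidationError(f"labels must be binary 0/1, got {sorted(bad)}")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    degenerate: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / y_true.size
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        degenerate.append("f1")
        f1 = 0.0
    return Metrics(accuracy, precision, recall, f1, tp, fp, fn, tn,
                   tuple(degenerate))


def pos_baseline_predict(instances: Iterable) -> np.ndarray:
    """Baseline labels: 1 iff the instance's POS tag is NOUN or ADJ.

    Accepts anything with a ``pos`` attribute (TokenInstance, TaggedToken)
    or raw POS tag strings.
    """
    labels: list[int] = []
    for item in instances:
        pos = item if isinstance(item, str) else getattr(item, "pos", None)
        if not pos:
            raise ValidationError(f"instance {item!r} carries no POS tag")
        labels.append(1 if pos in _BASELINE_POSITIVE_POS else 0)
    return np.array(labels, dtype=np.int64)


def project_2d(vectors: np.ndarray | Sequence, seed: int,
               perplexity: float = 30.0) -> np.ndarray:
    """t-SNE projection of word vectors to 2-D, reproducible for a seed.

    Perplexity is capped at (N - 1) / 3 so small vector sets remain valid.
    """
    from sklearn.manifold import TSNE

    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or len(vectors) < 2:
        raise ValidationError("project_2d needs at least 2 vectors of equal length")
    perplexity = min(perplexity, (len(vectors) - 1) / 3)
    if perplexity <= 0:
        raise ValidationError(f"too few vectors ({len(vectors)}) for t-SNE")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(vectors)


def plot_projection(coords: np.ndarray, labels: Sequence[int],
                    path: str | Path, tokens: Sequence[str] | None = None,
                    title: str = "") -> None:
    """Scatter of 2-D points by class, with a sidecar CSV of coordinates.

    Descriptors are drawn as x markers, non-descriptors as dots, matching
    the usual presentation of labeled embedding maps.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords)
    labels = np.asarray(labels)
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 6))
    neg, pos = labels == 0, labels == 1
    ax.scatter(coords[neg, 0], coords[neg, 1], s=8, marker=".",
               label="non-descriptor", alpha=0.6)
    ax.scatter(coords[pos, 0], coords[pos, 1], s=14, marker="x",
               label="descriptor", alpha=0.8)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    with path.with_suffix(".csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["token", "x", "y", "label"])
        for i in range(len(coords)):
            token = tokens[i] if tokens is not None else ""
            writer.writerow([token, f"{coords[i, 0]:.6f}", f"{coords[i, 1]:.6f}",
                             int(labels[i])])
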