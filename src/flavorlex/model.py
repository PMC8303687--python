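"""Descriptor classifier: configuration, training, and results objects.

The public surface follows the model/results convention of statistical
modelling packages: :class:`DescriptorClassifier` is constructed from
training examples and a :class:`ModelConfig`; its :meth:`fit` runs the
training protocol (Adam, lr 1e-4, batch 32, cross entropy over one-hot
two-class targets, 20% of the training data held out for validation, 3
epochs) and returns a :class:`DescriptorResults` carrying the trained
parameters, the per-epoch :class:`TrainingHistory`, prediction methods and a
``summary()`` table. ``build_model`` / ``train_model`` / ``predict_proba``
are thin functional wrappers over the same objects.

Epoch selection mirrors the divergence heuristic used to pick three epochs:
train for longer than needed once, then read off the epoch where validation
loss starts rising while training loss still falls
(:func:`detect_divergence_epoch`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import UntrainedModelError, ValidationError
from .nn import Adam, DualBranchNet, one_hot
from .sequences import SequenceExample, examples_to_arrays

__all__ = [
    "ModelConfig",
    "TrainingHistory",
    "DescriptorClassifier",
    "DescriptorResults",
    "build_model",
    "train_model",
    "predict_proba",
    "classify",
    "learning_curve",
    "detect_divergence_epoch",
]

_EVAL_BATCH = 512


@dataclass
class ModelConfig:
    """Hyperparameters of the dual-branch LSTM and its training protocol.

    Defaults are the reference protocol: 256 LSTM units per branch, a
    128-unit dense layer per branch, a 64 -> 32 head, Adam at 1e-4, batch
    32, 3 epochs, 20% validation holdout, context length 2n with n = 3.
    """

    lstm_units: int = 256
    branch_dense_units: int = 128
    head_layout: tuple[int, ...] = (64, 32)
    context_length: int = 6          # 2n
    embedding_dim: int = 300
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 3
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.head_layout = tuple(self.head_layout)
        for name in ("lstm_units", "branch_dense_units", "context_length",
                     "embedding_dim", "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        if any(w < 1 for w in self.head_layout):
            raise ValidationError(f"head layer sizes must be positive: {self.head_layout}")
        if any(a <= b for a, b in zip(self.head_layout, self.head_layout[1:])):
            raise ValidationError(
                f"head_layout must be strictly decreasing: {self.head_layout}")
        if not 0 < self.validation_fraction < 1:
            raise ValidationError(
                f"validation_fraction must be in (0,1), got {self.validation_fraction}")
        if self.learning_rate <= 0:
            raise ValidationError(f"learning_rate must be positive, got {self.learning_rate}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["head_layout"] = list(self.head_layout)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "head_layout" in d:
            d["head_layout"] = tuple(d["head_layout"])
        return cls(**d)


@dataclass
class TrainingHistory:
    """Per-epoch training and validation loss/accuracy traces."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("epoch,train_loss,train_acc,val_loss,val_acc\n")
            for i in range(len(self)):
                fh.write(f"{i + 1},{self.train_loss[i]:.6f},{self.train_accuracy[i]:.6f},"
                         f"{self.val_loss[i]:.6f},{self.val_accuracy[i]:.6f}\n")


class DescriptorClassifier:
    """Dual-branch LSTM token classifier bound to a training set.

    Parameters
    ----------
    train_examples
        :class:`~flavorlex.sequences.SequenceExample` list used by
        :meth:`fit`; may be ``None`` for a bare network (predict-only use
        after loading a checkpoint).
    config
        Hyperparameters; ``config.embedding_dim`` and
        ``config.context_length`` must match the examples' shapes.
    """

    def __init__(self, train_examples: list[SequenceExample] | None = None,
                 config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        if train_examples is not None and len(train_examples) > 0:
            d = train_examples[0].word_vector.shape[-1]
            t = train_examples[0].context_vectors.shape[0]
            if (d, t) != (self.config.embedding_dim, self.config.context_length):
                raise ValidationError(
                    f"examples have (context, dim)=({t}, {d}) but config says "
                    f"({self.config.context_length}, {self.config.embedding_dim})")
        self.train_examples = train_examples
        self.net = DualBranchNet(
            embedding_dim=self.config.embedding_dim,
            context_length=self.config.context_length,
            lstm_units=self.config.lstm_units,
            branch_dense_units=self.config.branch_dense_units,
            head_layout=self.config.head_layout,
            seed=self.config.seed,
        )
        self.is_fitted = False

    @classmethod
    def from_examples(cls, examples: list[SequenceExample],
                      **config_kwargs) -> "DescriptorClassifier":
        """Construct with the config's shape fields inferred from the data."""
        d = examples[0].word_vector.shape[-1]
        t = examples[0].context_vectors.shape[0]
        config_kwargs.setdefault("embedding_dim", d)
        config_kwargs.setdefault("context_length", t)
        return cls(examples, ModelConfig(**config_kwargs))

    # -- training ----------------------------------------------------------

    def fit(self, epochs: int | None = None) -> "DescriptorResults":
        """Run the training protocol and return a results object.

        Holds out ``validation_fraction`` of the training examples (seeded),
        trains ``epochs`` passes of shuffled batch-32 Adam updates, and
        records per-epoch losses and accuracies. Fully reproducible for a
        fixed config seed.
        """
        if not self.train_examples:
            raise ValidationError("cannot fit: no training examples supplied")
        cfg = self.config
        n_epochs = cfg.epochs if epochs is None else epochs
        x_ctx, x_word, y = examples_to_arrays(self.train_examples)
        rng = np.random.default_rng(cfg.seed)

        n = len(y)
        n_val = round(cfg.validation_fraction * n)
        perm = rng.permutation(n)
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
        if len(fit_idx) == 0:
            raise ValidationError("validation holdout leaves no training data")
        xc_fit, xw_fit, y_fit = x_ctx[fit_idx], x_word[fit_idx], y[fit_idx]
        xc_val, xw_val, y_val = x_ctx[val_idx], x_word[val_idx], y[val_idx]

        opt = Adam(self.net.params, learning_rate=cfg.learning_rate)
        history = TrainingHistory()
        for _ in range(n_epochs):
            order = rng.permutation(len(y_fit))
            losses, accs = [], []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                yb = one_hot(y_fit[idx])
                loss, probs, grads = self.net.loss_and_grads(
                    xc_fit[idx], xw_fit[idx], yb)
                opt.step(self.net.params, grads)
                losses.append(loss)
                accs.append(float((probs.argmax(axis=1) == y_fit[idx]).mean()))
            history.train_loss.append(float(np.mean(losses)))
            history.train_accuracy.append(float(np.mean(accs)))
            if n_val:
                val_loss, val_acc = self._evaluate(xc_val, xw_val, y_val)
            else:  # pragma: no cover - validation_fraction is bounded away from 0
                val_loss, val_acc = float("nan"), float("nan")
            history.val_loss.append(val_loss)
            history.val_accuracy.append(val_acc)
        self.is_fitted = True
        return DescriptorResults(self, history, n_train=len(fit_idx), n_val=n_val)

    def _evaluate(self, xc: np.ndarray, xw: np.ndarray,
                  y: np.ndarray) -> tuple[float, float]:
        losses, correct = [], 0
        eps = 1e-12
        for start in range(0, len(y), _EVAL_BATCH):
            sl = slice(start, start + _EVAL_BATCH)
            probs, _ = self.net.forward(xc[sl], xw[sl])
            yb = one_hot(y[sl])
            losses.append(float(-(yb * np.log(probs + eps)).sum()))
            correct += int((probs.argmax(axis=1) == y[sl]).sum())
        return float(np.sum(losses) / len(y)), correct / len(y)

    # -- prediction --------------------------------------------------------

    def predict_proba(self, examples: list[SequenceExample]) -> np.ndarray:
        """Descriptor-class softmax probability for each example."""
        x_ctx, x_word, _ = examples_to_arrays(examples)
        if x_ctx.shape[2] != self.config.embedding_dim or \
                x_ctx.shape[1] != self.config.context_length:
            raise ValidationError(
                f"example shape {x_ctx.shape[1:]} does not match model config "
                f"({self.config.context_length}, {self.config.embedding_dim})")
        out = np.empty(len(examples), dtype=np.float64)
        for start in range(0, len(examples), _EVAL_BATCH):
            sl = slice(start, min(start + _EVAL_BATCH, len(examples)))
            probs, _ = self.net.forward(x_ctx[sl], x_word[sl])
            out[sl] = probs[:, 1]
        return out


@dataclass
class DescriptorResults:
    """Fitted-model results: parameters, history, predictions, summary."""

    model: DescriptorClassifier
    history: TrainingHistory
    n_train: int
    n_val: int

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    def predict_proba(self, examples: list[SequenceExample]) -> np.ndarray:
        return self.model.predict_proba(examples)

    def classify(self, examples: list[SequenceExample],
                 threshold: float = 0.5) -> np.ndarray:
        return classify(self.predict_proba(examples), threshold)

    def recommended_epochs(self) -> int:
        return detect_divergence_epoch(self.history)

    def summary(self) -> str:
        """Human-readable fit summary in the style of a results table."""
        cfg = self.config
        h = self.history
        lines = [
            "Descriptor classifier — dual-branch LSTM",
            "=" * 56,
            f"{'Parameters:':<28}{self.model.net.n_params:>12,}",
            f"{'LSTM units / branch dense:':<28}{cfg.lstm_units:>6} / {cfg.branch_dense_units}",
            f"{'Head layout:':<28}{' -> '.join(map(str, cfg.head_layout)) + ' -> 2':>20}",
            f"{'Context length (2n) / d:':<28}{cfg.context_length:>6} / {cfg.embedding_dim}",
            f"{'Optimizer:':<28}{'Adam lr=%g batch=%d' % (cfg.learning_rate, cfg.batch_size):>24}",
            f"{'Train / validation n:':<28}{self.n_train:>8} / {self.n_val}",
            "-" * 56,
            f"{'epoch':>5} {'train_loss':>11} {'train_acc':>10} {'val_loss':>11} {'val_acc':>9}",
        ]
        for i in range(len(h)):
            lines.append(f"{i + 1:>5} {h.train_loss[i]:>11.5f} {h.train_accuracy[i]:>10.5f} "
                         f"{h.val_loss[i]:>11.5f} {h.val_accuracy[i]:>9.5f}")
        lines.append("-" * 56)
        lines.append(f"Recommended epochs (val-loss divergence): {self.recommended_epochs()}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: parameters plus the embedded config."""
        path = Path(path)
        arrays = {k.replace("/", "__"): v for k, v in self.model.net.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DescriptorResults":
        with np.load(Path(path)) as data:
            cfg = ModelConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
            model = DescriptorClassifier(None, cfg)
            for k in model.net.params:
                model.net.params[k] = data[k.replace("/", "__")].copy()
            model.net._sync_lstm_views()
        model.is_fitted = True
        return cls(model, TrainingHistory(), n_train=0, n_val=0)


# -- functional wrappers (operation-style surface) -------------------------

def build_model(config: ModelConfig) -> DescriptorClassifier:
    """Initialize an untrained classifier from a config (seeded weights)."""
    return DescriptorClassifier(None, config)


def train_model(model: DescriptorClassifier, train: list[SequenceExample],
                config: ModelConfig | None = None) -> TrainingHistory:
    """Train ``model`` on ``train`` and return the epoch history."""
    if config is not None:
        model.config = config
    model.train_examples = train
    return model.fit().history


def predict_proba(model: DescriptorClassifier | DescriptorResults,
                  examples: list[SequenceExample]) -> np.ndarray:
    return model.predict_proba(examples)


def classify(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary labels: 1 iff descriptor probability >= threshold."""
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must be in (0,1), got {threshold}")
    return (np.asarray(probabilities) >= threshold).astype(np.int64)


def learning_curve(examples: list[SequenceExample],
                   config: ModelConfig,
                   fractions: Sequence[float] | None = None,
                   test_examples: list[SequenceExample] | None = None) -> list[dict]:
    """Train once per data fraction (default 5%, 10%, ..., 100%).

    Subsets are nested (the 5% subset is contained in the 10% subset, and so
    on) so curves are comparable across fractions; subsampling is seeded
    from the config. Returns one record per session with the fraction, the
    subset size, the :class:`TrainingHistory`, and — when ``test_examples``
    is given — held-out :class:`~flavorlex.evaluation.Metrics`.
    """
    from .evaluation import compute_metrics  # local import avoids a cycle

    if fractions is None:
        fractions = [round(0.05 * k, 2) for k in range(1, 21)]
    if any(not 0 < f <= 1 for f in fractions):
        raise ValidationError(f"fractions must lie in (0, 1]: {list(fractions)}")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(examples))
    sessions: list[dict] = []
    for frac in fractions:
        n_sub = max(2, round(frac * len(examples)))
        subset = [examples[i] for i in order[:n_sub]]
        model = DescriptorClassifier(subset, config)
        results = model.fit()
        record = {"fraction": frac, "n_examples": n_sub,
                  "history": results.history, "metrics": None}
        if test_examples:
            y_true = np.array([e.label for e in test_examples])
            y_pred = results.classify(test_examples)
            record["metrics"] = compute_metrics(y_true, y_pred)
        sessions.append(record)
    return sessions


def detect_divergence_epoch(history: TrainingHistory) -> int:
    """Pick the stopping epoch from train/validation loss divergence.

    Returns the 1-based epoch with minimum validation loss among epochs
    where validation loss rises at the next epoch while training loss does
    not; if validation loss never rises (no overfitting visible), returns
    the final epoch.
    """
    L = len(history)
    if L < 2:
        raise ValidationError("need at least 2 epochs to detect divergence")
    tl, vl = history.train_loss, history.val_loss
    candidates = [i for i in range(L - 1)
                  if vl[i + 1] > vl[i] and tl[i + 1] <= tl[i]]
    if not candidates:
        return L
    best = min(candidates, key=lambda i: vl[i])
    return best + 1
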