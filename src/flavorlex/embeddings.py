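"""Word-vector storage with the zero-vector PAD convention.

Vectors are read from GloVe-style plain text (one ``token v1 ... vd`` record
per line, no header; gzip transparently supported). The PAD filler used when
a context window runs past a sentence boundary is the all-zero vector, and by
default out-of-vocabulary tokens also map to zero — the "no information"
convention — with per-store counters so a run can report its OOV rate.
"""

from __future__ import annotations

import gzip
import logging
from collections.abc import Iterable
from pathlib import Path

import numpy as np

from .exceptions import FormatError, OOVLookupError

__all__ = ["PAD", "EmbeddingStore", "load_embedding_table", "write_embedding_table"]

logger = logging.getLogger(__name__)

#: Sentinel passed to :meth:`EmbeddingStore.vector_for` for PAD positions.
PAD = "<PAD>"


class EmbeddingStore:
    """Token -> d-dimensional vector map with PAD and OOV accounting.

    Parameters
    ----------
    table
        Mapping of token to 1-D float vector; all vectors must share length.
    oov_policy
        ``"zero"`` (default) maps unknown tokens to the zero vector and
        counts them; ``"error"`` raises :class:`OOVLookupError`.
    lowercase
        Case-fold tokens before lookup (GloVe vocabularies are largely
        lowercase). Keys are folded at construction when enabled.
    """

    def __init__(self, table: dict[str, np.ndarray], oov_policy: str = "zero",
                 lowercase: bool = True):
        if oov_policy not in ("zero", "error"):
            raise ValueError(f"unknown oov_policy {oov_policy!r}")
        if not table:
            raise ValueError("embedding table is empty")
        self.lowercase = lowercase
        self.table: dict[str, np.ndarray] = {}
        for token, vec in table.items():
            key = token.lower() if lowercase else token
            if key in self.table:
                logger.warning("duplicate embedding token %r; keeping first", token)
                continue
            self.table[key] = np.asarray(vec, dtype=np.float32)
        dims = {v.shape for v in self.table.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValueError(f"inconsistent vector shapes: {sorted(dims)}")
        self.dimension: int = next(iter(dims))[0]
        self.pad_vector = np.zeros(self.dimension, dtype=np.float32)
        self.oov_policy = oov_policy
        self.reset_counters()

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, token: str) -> bool:
        return (token.lower() if self.lowercase else token) in self.table

    def reset_counters(self) -> None:
        self.n_hits = 0
        self.n_oov = 0
        self.n_pad = 0

    @property
    def n_lookups(self) -> int:
        return self.n_hits + self.n_oov + self.n_pad

    @property
    def oov_rate(self) -> float:
        total = self.n_hits + self.n_oov
        return self.n_oov / total if total else 0.0

    def vector_for(self, token: str) -> np.ndarray:
        """Return the vector for ``token``; PAD and (by policy) OOV are zero."""
        if token == PAD:
            self.n_pad += 1
            return self.pad_vector
        key = token.lower() if self.lowercase else token
        vec = self.table.get(key)
        if vec is not None:
            self.n_hits += 1
            return vec
        if self.oov_policy == "error":
            raise OOVLookupError(f"token {token!r} is out of vocabulary")
        self.n_oov += 1
        return self.pad_vector

    def matrix_for(self, tokens: Iterable[str]) -> np.ndarray:
        """Stack lookups for a token sequence into an ``(T, d)`` array."""
        return np.stack([self.vector_for(t) for t in tokens])


def load_embedding_table(path: str | Path, oov_policy: str = "zero",
                         lowercase: bool = True) -> EmbeddingStore:
    """Parse a GloVe-format text file (optionally gzipped) into a store.

    The dimension is inferred from the first line; any line whose float
    count differs raises :class:`FormatError` naming the line number.
    Duplicate tokens keep the first occurrence (with a logged warning).
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    table: dict[str, np.ndarray] = {}
    dim: int | None = None
    with opener(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            token, floats = parts[0], parts[1:]
            if dim is None:
                dim = len(floats)
                if dim == 0:
                    raise FormatError(f"{path}: line 1 has no vector components")
            if len(floats) != dim:
                raise FormatError(
                    f"{path}: line {lineno} has {len(floats)} floats, expected {dim}")
            try:
                vec = np.array(floats, dtype=np.float32)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            key = token.lower() if lowercase else token
            if key in table:
                logger.warning("%s: duplicate token %r at line %d; keeping first",
                               path, token, lineno)
                continue
            table[key] = vec
    if not table:
        raise FormatError(f"{path}: no embedding records found")
    return EmbeddingStore(table, oov_policy=oov_policy, lowercase=lowercase)


def write_embedding_table(store: EmbeddingStore, path: str | Path,
                          fmt: str = "%.6g") -> None:
    """Write a store back to GloVe plain-text format (gzip if ``.gz``)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", encoding="utf-8") as fh:
        for token, vec in store.table.items():
            fh.write(token + " " + " ".join(fmt % x for x in vec) + "\n")
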