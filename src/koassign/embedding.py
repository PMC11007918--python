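"""Sequence-embedder contract and the deterministic mock embedder.

The pipeline treats the embedder as pluggable: any callable that maps an
amino-acid sequence to a fixed-dimension vector can gate the classifier and
drive nearest-neighbour annotation transfer. Two implementations are
provided:

* ``mock`` — a seeded k-mer hashing embedder. Each overlapping k-mer is
  hashed to a fixed unit direction in R^dim; a residue's vector is the sum
  of the directions of the k-mers covering it, and the sequence vector pools
  those per-residue vectors (mean by default). Identical subsequences
  therefore contribute identical directions, giving related sequences nearby
  embeddings — the statistical premise the pipeline relies on — while being
  bit-reproducible with no model weights.
* ``plm`` — an adapter for a pre-trained protein language model (loaded
  lazily; see :mod:`koassign.plm`), pooling its final hidden states the same
  way.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .records import EmbeddingVector, SequenceRecord, _STANDARD_AA_SET

logger = logging.getLogger(__name__)

__all__ = ["EmbedderSpec", "MockEmbedder", "embed", "embed_batch", "get_embedder"]

_POOLINGS = ("mean", "max", "first")


@dataclass(frozen=True)
class EmbedderSpec:
    """Configuration selecting and parameterizing an embedder."""

    name: str = "mock"
    dim: int = 64
    pooling: str = "mean"
    kmer_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ("mock", "plm"):
            raise ValueError(f"unknown embedder {self.name!r}")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.pooling not in _POOLINGS:
            raise ValueError(f"pooling must be one of {_POOLINGS}")
        if self.kmer_size < 1:
            raise ValueError("kmer_size must be >= 1")


def _pool(residue_matrix: np.ndarray, pooling: str) -> np.ndarray:
    if pooling == "mean":
        return residue_matrix.mean(axis=0)
    if pooling == "max":
        return residue_matrix.max(axis=0)
    return residue_matrix[0]


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("cannot embed an empty sequence")
    bad = set(sequence) - _STANDARD_AA_SET
    if bad:
        raise ValueError(f"invalid amino-acid letter(s) {sorted(bad)} in sequence")


class MockEmbedder:
    """Deterministic k-mer-hash embedder (see module docstring)."""

    def __init__(self, spec: EmbedderSpec) -> None:
        self.spec = spec
        self._directions: dict[str, np.ndarray] = {}

    def _direction(self, kmer: str) -> np.ndarray:
        """Stable unit direction for a k-mer, independent of platform."""
        cached = self._directions.get(kmer)
        if cached is not None:
            return cached
        digest = hashlib.blake2b(
            f"{self.spec.seed}|{kmer}".encode(), digest_size=8
        ).digest()
        stream = np.random.default_rng(int.from_bytes(digest, "big"))
        vec = stream.standard_normal(self.spec.dim)
        vec /= np.linalg.norm(vec)
        self._directions[kmer] = vec
        return vec

    def residue_matrix(self, sequence: str) -> np.ndarray:
        """Per-residue (L, dim) matrix before pooling.

        Residue i receives the sum of the directions of every k-mer window
        covering position i. Sequences shorter than the k-mer size are
        treated as a single window.
        """
        _validate_sequence(sequence)
        k = min(self.spec.kmer_size, len(sequence))
        matrix = np.zeros((len(sequence), self.spec.dim))
        for start in range(len(sequence) - k + 1):
            direction = self._direction(sequence[start : start + k])
            matrix[start : start + k] += direction
        return matrix

    def __call__(self, sequence: str) -> np.ndarray:
        return _pool(self.residue_matrix(sequence), self.spec.pooling)


def get_embedder(spec: EmbedderSpec):
    """Instantiate the embedder selected by *spec*."""
    if spec.name == "mock":
        return MockEmbedder(spec)
    from .plm import ProtT5Embedder  # deferred: heavy optional dependency

    return ProtT5Embedder(spec)


def embed(sequence: str, spec: EmbedderSpec) -> EmbeddingVector:
    """Embed a single sequence (deterministic for a fixed spec)."""
    return EmbeddingVector("query", get_embedder(spec)(sequence))


def embed_batch(
    records: list[SequenceRecord], spec: EmbedderSpec
) -> list[EmbeddingVector]:
    """Embed records in order, sharing one embedder (and its k-mer cache)."""
    embedder = get_embedder(spec)
    out: list[EmbeddingVector] = []
    for i, rec in enumerate(records, start=1):
        try:
            out.append(EmbeddingVector(rec.id, embedder(rec.sequence)))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
        if i % 1000 == 0:
            logger.info("embedded %d/%d records", i, len(records))
    return out
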