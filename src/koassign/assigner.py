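"""Nearest-neighbour K-number transfer in embedding space.

Each query embedding is compared against every annotated reference embedding
by Euclidean distance; the annotation of the closest reference is
transferred. When several references tie for the minimum distance, all are
reported and the query receives the union of their K numbers. An optional
distance threshold turns the assigner into a gate of its own: queries whose
nearest reference is farther than the threshold are left unassigned
(treated as non-KO).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .records import EmbeddingVector

__all__ = [
    "ReferenceIndex",
    "Assignment",
    "euclidean_distance",
    "build_index",
    "assign",
    "assign_with_threshold",
    "assign_batch",
]


def _as_vector(x) -> np.ndarray:
    if isinstance(x, EmbeddingVector):
        return x.values
    return np.asarray(x, dtype=np.float64)


def euclidean_distance(x, y) -> float:
    """Euclidean distance between two equal-dimension embeddings."""
    xv, yv = _as_vector(x), _as_vector(y)
    if xv.shape != yv.shape:
        raise ValueError(f"dimension mismatch: {xv.shape} vs {yv.shape}")
    return float(np.linalg.norm(xv - yv))


@dataclass(frozen=True)
class ReferenceIndex:
    """Validated, id-aligned reference embeddings with their K numbers."""

    ids: tuple[str, ...]
    embeddings: np.ndarray
    annotations: dict[str, frozenset[str]]

    @property
    def dim(self) -> int:
        return int(self.embeddings.shape[1])

    def __len__(self) -> int:
        return len(self.ids)


def build_index(
    ids: Iterable[str],
    embeddings: np.ndarray | list[EmbeddingVector],
    annotations: Mapping[str, Iterable[str]],
) -> ReferenceIndex:
    """Assemble a reference index; every reference must carry >= 1 K number."""
    ids = tuple(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate reference ids")
    if isinstance(embeddings, np.ndarray):
        matrix = np.asarray(embeddings, dtype=np.float64)
    else:
        matrix = np.stack([_as_vector(e) for e in embeddings])
    if matrix.ndim != 2 or matrix.shape[0] != len(ids):
        raise ValueError("embedding matrix rows must align with ids")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("reference embeddings contain non-finite values")
    validated: dict[str, frozenset[str]] = {}
    for ref_id in ids:
        kos = frozenset(annotations.get(ref_id, ()))
        if not kos:
            raise ValueError(f"reference {ref_id!r} has no K number")
        validated[ref_id] = kos
    return ReferenceIndex(ids, matrix, validated)


@dataclass(frozen=True)
class Assignment:
    """Result of transferring annotation(s) from the nearest reference(s)."""

    query_id: str
    best_refs: tuple[tuple[str, float], ...]
    k_numbers: frozenset[str] = field(default_factory=frozenset)
    distance: float = 0.0

    def __post_init__(self) -> None:
        if not self.best_refs:
            raise ValueError("an Assignment needs at least one best reference")
        if not self.k_numbers:
            raise ValueError("an Assignment needs at least one K number")


def _assign_from_distances(
    query_id: str, distances: np.ndarray, index: ReferenceIndex, tie_tol: float
) -> Assignment:
    best = float(distances.min())
    tied = np.flatnonzero(distances <= best + tie_tol)
    best_refs = tuple((index.ids[i], float(distances[i])) for i in tied)
    k_numbers = frozenset().union(*(index.annotations[index.ids[i]] for i in tied))
    return Assignment(query_id, best_refs, k_numbers, best)


def assign(
    query: EmbeddingVector, index: ReferenceIndex, tie_tol: float = 0.0
) -> Assignment:
    """Exhaustive nearest-neighbour search over the reference index.

    ``best_refs`` holds every reference within ``tie_tol`` of the minimum
    distance (default: exact ties only); ``k_numbers`` is the union of their
    annotations.
    """
    if len(index) == 0:
        raise ValueError("reference index is empty")
    if query.dim != index.dim:
        raise ValueError(f"dimension mismatch: query {query.dim}, index {index.dim}")
    distances = np.linalg.norm(index.embeddings - query.values, axis=1)
    return _assign_from_distances(query.id, distances, index, tie_tol)


def assign_with_threshold(
    query: EmbeddingVector,
    index: ReferenceIndex,
    distance_threshold: float,
    tie_tol: float = 0.0,
) -> Assignment | None:
    """As :func:`assign`, but return ``None`` (no assignment; treat the query
    as non-KO) when even the nearest reference is beyond the threshold."""
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be positive")
    result = assign(query, index, tie_tol)
    return result if result.distance <= distance_threshold else None


def assign_batch(
    queries: list[EmbeddingVector],
    index: ReferenceIndex,
    tie_tol: float = 0.0,
    distance_threshold: float | None = None,
) -> list[Assignment | None]:
    """Order-preserving vectorized assignment of many queries.

    Equals per-query :func:`assign` / :func:`assign_with_threshold` exactly
    (the distance matrix is computed in one shot, then reduced per row).
    """
    if not queries:
        return []
    if len(index) == 0:
        raise ValueError("reference index is empty")
    matrix = np.stack([q.values for q in queries])
    if matrix.shape[1] != index.dim:
        raise ValueError(
            f"dimension mismatch: queries {matrix.shape[1]}, index {index.dim}"
        )
    # Same reduction as the single-query path, row by row, so batch results
    # are bit-identical to per-query assign().
    results: list[Assignment | None] = []
    for query, row_query in zip(queries, matrix):
        row = np.linalg.norm(index.embeddings - row_query, axis=1)
        result = _assign_from_distances(query.id, row, index, tie_tol)
        if distance_threshold is not None and result.distance > distance_threshold:
            results.append(None)
        else:
            results.append(result)
    return results
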