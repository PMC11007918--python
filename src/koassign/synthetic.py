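"""Synthetic fixtures with the statistical structure the pipeline assumes.

Three generators, all bit-reproducible given a seed:

* protein families — each family descends from a random ancestor by 5%
  per-site point substitution and shares one K number, alongside i.i.d.
  random non-KO sequences; optional injection of undefined letters and
  exact duplicates exercises the dataset filters;
* embedding clusters — one well-separated isotropic Gaussian cluster per
  family (functionally similar proteins lie close in embedding space),
  plus far-away non-KO queries;
* toy structures — a 3.8 Å-bond random-walk CA trace and a rigidly moved,
  optionally jittered copy with identity correspondence, for the TM-score
  calculator.

These emulate cluster structure and filter-relevant defects only; they make
no claim of compositional or phylogenetic realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .records import CATrace, EmbeddingVector, SequenceRecord, STANDARD_AA

__all__ = [
    "FixtureConfig",
    "make_sequences",
    "make_embedding_clusters",
    "make_toy_structures",
]

_UNDEFINED_LETTERS = "XBZUOJ"
_MUTATION_RATE = 0.05


@dataclass(frozen=True)
class FixtureConfig:
    n_ko_families: int = 20
    members_per_family: int = 20
    n_nonko: int = 200
    seq_len_range: tuple[int, int] = (100, 600)
    embed_dim: int = 64
    cluster_sigma: float = 0.5
    centroid_separation: float = 10.0
    undefined_aa_rate: float = 0.0
    duplicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ko_families < 1 or self.members_per_family < 1:
            raise ValueError("need at least one family with one member")
        if self.seq_len_range[0] < 1 or self.seq_len_range[0] > self.seq_len_range[1]:
            raise ValueError("invalid sequence length range")
        for rate in (self.undefined_aa_rate, self.duplicate_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def family_k_number(self, family: int) -> str:
        return f"K{family + 1:05d}"


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_AA), size=length))


def _mutate(rng: np.random.Generator, sequence: str) -> str:
    letters = list(sequence)
    for i, letter in enumerate(letters):
        if rng.random() < _MUTATION_RATE:
            choices = STANDARD_AA.replace(letter, "")
            letters[i] = choices[rng.integers(len(choices))]
    return "".join(letters)


def make_sequences(
    cfg: FixtureConfig,
) -> tuple[list[SequenceRecord], dict[str, frozenset[str]]]:
    """Generate family + non-KO sequence records and their truth table."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.seq_len_range
    records: list[SequenceRecord] = []
    for family in range(cfg.n_ko_families):
        k_number = cfg.family_k_number(family)
        ancestor = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        for member in range(cfg.members_per_family):
            records.append(
                SequenceRecord(
                    f"fam{family:03d}_m{member:03d}",
                    _mutate(rng, ancestor),
                    frozenset({k_number}),
                )
            )
    for i in range(cfg.n_nonko):
        records.append(
            SequenceRecord(
                f"nonko_{i:04d}", _random_sequence(rng, int(rng.integers(lo, hi + 1)))
            )
        )

    if cfg.undefined_aa_rate > 0:
        flags = rng.random(len(records)) < cfg.undefined_aa_rate
        for i in np.flatnonzero(flags):
            rec = records[i]
            pos = int(rng.integers(len(rec.sequence)))
            letter = _UNDEFINED_LETTERS[rng.integers(len(_UNDEFINED_LETTERS))]
            seq = rec.sequence[:pos] + letter + rec.sequence[pos + 1 :]
            records[i] = SequenceRecord(rec.id, seq, rec.annotations)

    if cfg.duplicate_rate > 0:
        n_dup = int(round(cfg.duplicate_rate * len(records)))
        sources = rng.choice(len(records), size=n_dup, replace=False)
        for serial, src in enumerate(sources):
            # Exact sequence copies with no annotation: the dedup rule must
            # let the annotated original win.
            records.append(
                SequenceRecord(f"dup_{serial:04d}", records[src].sequence)
            )

    truth = {rec.id: rec.annotations for rec in records}
    return records, truth


def make_embedding_clusters(
    cfg: FixtureConfig,
) -> tuple[
    list[EmbeddingVector],
    dict[str, frozenset[str]],
    list[EmbeddingVector],
    dict[str, frozenset[str]],
]:
    """Clustered reference/query embeddings with their K-number truth.

    Returns ``(references, reference annotations, queries, query truth)``.
    Each family contributes one reference centroid cluster and an equal
    number of queries; non-KO queries are placed at least three separations
    away from every centroid and carry empty truth.
    """
    rng = np.random.default_rng(cfg.seed)
    for _ in range(100):
        centroids = rng.standard_normal((cfg.n_ko_families, cfg.embed_dim))
        centroids *= cfg.centroid_separation
        if cfg.n_ko_families == 1 or pdist(centroids).min() >= cfg.centroid_separation:
            break
    else:
        raise RuntimeError("could not place centroids at the requested separation")

    references: list[EmbeddingVector] = []
    ref_annotations: dict[str, frozenset[str]] = {}
    queries: list[EmbeddingVector] = []
    query_truth: dict[str, frozenset[str]] = {}
    for family in range(cfg.n_ko_families):
        k_number = frozenset({cfg.family_k_number(family)})
        for member in range(cfg.members_per_family):
            ref_id = f"ref_f{family:03d}_{member:03d}"
            noise = rng.standard_normal(cfg.embed_dim) * cfg.cluster_sigma
            references.append(EmbeddingVector(ref_id, centroids[family] + noise))
            ref_annotations[ref_id] = k_number
            query_id = f"query_f{family:03d}_{member:03d}"
            noise = rng.standard_normal(cfg.embed_dim) * cfg.cluster_sigma
            queries.append(EmbeddingVector(query_id, centroids[family] + noise))
            query_truth[query_id] = k_number

    # Non-KO queries: on a shell far outside every centroid, so the nearest
    # reference is at least ~3.5 separations away.
    max_norm = float(np.linalg.norm(centroids, axis=1).max())
    radius = max_norm + 3.5 * cfg.centroid_separation
    for i in range(cfg.n_nonko):
        direction = rng.standard_normal(cfg.embed_dim)
        direction /= np.linalg.norm(direction)
        query_id = f"query_nonko_{i:04d}"
        queries.append(EmbeddingVector(query_id, direction * radius))
        query_truth[query_id] = frozenset()
    return references, ref_annotations, queries, query_truth


def make_toy_structures(
    cfg: FixtureConfig,
    n_residues: int = 80,
    jitter_sigma: float = 0.0,
) -> tuple[CATrace, CATrace, tuple[tuple[int, int], ...]]:
    """A random-walk CA trace, a rigidly moved jittered copy, and the
    identity correspondence."""
    rng = np.random.default_rng(cfg.seed)
    steps = rng.standard_normal((n_residues - 1, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    target = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])

    rotation = Rotation.from_rotvec(rng.standard_normal(3)).as_matrix()
    translation = rng.standard_normal(3) * 10.0
    template = target @ rotation.T + translation
    if jitter_sigma > 0:
        template = template + rng.standard_normal(template.shape) * jitter_sigma

    correspondence = tuple((i, i) for i in range(n_residues))
    return (
        CATrace("target", target),
        CATrace("template", template),
        correspondence,
    )
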