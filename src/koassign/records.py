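"""Core domain types shared across the pipeline.

A :class:`SequenceRecord` carries a protein sequence and the set of KEGG
Orthology identifiers ("K numbers", e.g. ``K02030``) attached to it; an empty
annotation set marks the sequence as non-KO. :class:`EmbeddingVector` is the
fixed-dimension numeric representation compared by Euclidean distance during
annotation transfer, and :class:`CATrace` holds the alpha-carbon coordinates
used by the TM-score calculator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

K_NUMBER_RE = re.compile(r"^K\d{5}$")

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_AA_SET = frozenset(STANDARD_AA)


def is_k_number(token: str) -> bool:
    """True if *token* is a well-formed K number (``K`` + 5 digits)."""
    return bool(K_NUMBER_RE.match(token))


@dataclass(frozen=True)
class SequenceRecord:
    """An identified amino-acid sequence with optional K-number annotations.

    Ids are opaque strings; KEGG-style ``org:gene`` ids are never parsed.
    Sequences may contain non-standard letters until the dataset filters
    remove them.
    """

    id: str
    sequence: str
    annotations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} must be non-empty")
        object.__setattr__(self, "annotations", frozenset(self.annotations))
        for ann in self.annotations:
            if not is_k_number(ann):
                raise ValueError(
                    f"annotation {ann!r} on {self.id!r} is not a K number"
                )

    @property
    def is_ko(self) -> bool:
        """True if the record carries at least one K number."""
        return bool(self.annotations)

    def has_undefined_aa(self) -> bool:
        """True if the sequence contains a letter outside the standard 20."""
        return not _STANDARD_AA_SET.issuperset(self.sequence)


@dataclass(frozen=True)
class EmbeddingVector:
    """A fixed-dimension embedding of one protein sequence."""

    id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError(f"embedding for {self.id!r} must be a 1-D vector")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"embedding for {self.id!r} has non-finite values")
        object.__setattr__(self, "values", arr)

    @property
    def dim(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class CATrace:
    """Ordered alpha-carbon coordinates (Å), one triple per residue."""

    id: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
            raise ValueError(f"CA trace {self.id!r} must be a non-empty (N, 3) array")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"CA trace {self.id!r} has non-finite coordinates")
        object.__setattr__(self, "coords", arr)

    def __len__(self) -> int:
        return int(self.coords.shape[0])
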