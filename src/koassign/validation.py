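"""Structural and sequence validation of annotation transfers.

TM-score over a fixed residue correspondence: the template CA trace is
rigidly superposed onto the target by least squares (Kabsch), per-pair
distances d_i are scored as sum(1 / (1 + (d_i/d0)^2)) / L_target with the
length-dependent scale d0(L) = 1.24 * cbrt(L - 15) - 1.8 Å, and the
superposition is refined by discarding far outlier pairs (d_i > 2 d0) and
re-superposing, up to five rounds. Because the correspondence is fixed and
the superposition is least-squares rather than a full alignment search, the
returned value is a lower bound on the score a full structural aligner
would report. Scores >= 0.5 indicate shared structural domains, >= 0.8
highly similar structures.

Sequence-level validation uses Smith-Waterman local alignment with affine
gaps (Gotoh) and reports percent identity over alignment columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.spatial.transform import Rotation

from .records import CATrace, _STANDARD_AA_SET

__all__ = [
    "TMScoreInput",
    "AlignmentResult",
    "kabsch_superpose",
    "d0_scale",
    "tm_score",
    "smith_waterman",
    "identity_distribution",
]

D0_FLOOR = 0.5  # Å; keeps the scale positive for short targets
_REFINE_CUTOFF_FACTOR = 2.0
_MAX_REFINE_ROUNDS = 5


@dataclass(frozen=True)
class TMScoreInput:
    """A target/template CA-trace pair plus their residue correspondence.

    ``correspondence`` lists (target_index, template_index) pairs, 0-based,
    strictly increasing in target order.
    """

    target: CATrace
    template: CATrace
    correspondence: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple((int(a), int(b)) for a, b in self.correspondence)
        if not pairs:
            raise ValueError("correspondence must be non-empty")
        if len(pairs) > min(len(self.target), len(self.template)):
            raise ValueError("correspondence longer than the shorter trace")
        t_idx = [a for a, _ in pairs]
        if any(b - a <= 0 for a, b in zip(t_idx, t_idx[1:])):
            raise ValueError("target indices must be strictly increasing")
        for a, b in pairs:
            if not (0 <= a < len(self.target) and 0 <= b < len(self.template)):
                raise ValueError(f"correspondence pair ({a}, {b}) out of range")
        object.__setattr__(self, "correspondence", pairs)

    @property
    def l_target(self) -> int:
        return len(self.target)

    @property
    def l_common(self) -> int:
        return len(self.correspondence)


def kabsch_superpose(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of *moving* onto *fixed*.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) such that ``rotation @ p + translation ~= q``. Degenerate
    (e.g. collinear) point sets produce a warning and a best-effort
    transform.
    """
    P = np.asarray(moving, dtype=np.float64)
    Q = np.asarray(fixed, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (N, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(Q))):
        raise ValueError("coordinates must be finite")
    centroid_p = P.mean(axis=0)
    centroid_q = Q.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        rotation, _ = Rotation.align_vectors(Q - centroid_q, P - centroid_p)
    matrix = rotation.as_matrix()
    translation = centroid_q - matrix @ centroid_p
    # Residual recomputed from the transform itself (the rssd reported by
    # the solver carries sqrt-cancellation noise near zero).
    residual = P @ matrix.T + translation - Q
    rmsd = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return matrix, translation, rmsd


def d0_scale(l_target: int) -> float:
    """Length-dependent distance scale d0(L) = 1.24 cbrt(L - 15) - 1.8 Å.

    Floored at 0.5 Å (the printed formula is non-positive for short
    targets).
    """
    if l_target < 1:
        raise ValueError("target length must be positive")
    if l_target <= 15:
        return D0_FLOOR
    return max(D0_FLOOR, 1.24 * np.cbrt(l_target - 15.0) - 1.8)


def _score_from_distances(d: np.ndarray, l_target: int, d0: float) -> float:
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_target)


def tm_score(inputs: TMScoreInput) -> float:
    """TM-score of the template against the target over the correspondence.

    With fewer than 3 corresponding pairs no superposition is possible and
    the coordinates are scored as given.
    """
    pairs = np.asarray(inputs.correspondence, dtype=np.int64)
    target_xyz = inputs.target.coords[pairs[:, 0]]
    template_xyz = inputs.template.coords[pairs[:, 1]]
    d0 = d0_scale(inputs.l_target)

    if inputs.l_common < 3:
        d = np.linalg.norm(template_xyz - target_xyz, axis=1)
        return _score_from_distances(d, inputs.l_target, d0)

    active = np.ones(inputs.l_common, dtype=bool)
    best = 0.0
    for _ in range(_MAX_REFINE_ROUNDS):
        R, t, _ = kabsch_superpose(template_xyz[active], target_xyz[active])
        moved = template_xyz @ R.T + t
        d = np.linalg.norm(moved - target_xyz, axis=1)
        best = max(best, _score_from_distances(d, inputs.l_target, d0))
        refined = d <= _REFINE_CUTOFF_FACTOR * d0
        if refined.sum() < 3 or np.array_equal(refined, active):
            break
        active = refined
    return best


@dataclass(frozen=True)
class AlignmentResult:
    """A local alignment with its score and percent identity."""

    aligned_query: str
    aligned_ref: str
    score: float
    identity_percent: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("gapped strings must have equal length")


_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


_IDENTITY_DENOMS = ("alignment", "aligned_columns", "min_length")


def smith_waterman(
    query: str,
    ref: str,
    substitution=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    identity_denominator: str = "alignment",
) -> AlignmentResult:
    """Optimal local alignment (Gotoh affine-gap dynamic programming).

    The first residue of a gap costs ``gap_open`` and each further residue
    ``gap_extend``. Traceback ties prefer diagonal, then up (gap in the
    reference), then left. Identity is 100 x identical columns / denominator,
    where the denominator is by default the full alignment length (gap
    columns included); ``aligned_columns`` and ``min_length`` are
    alternatives. With no positive-scoring path the alignment is empty and
    identity is reported as 0.
    """
    if identity_denominator not in _IDENTITY_DENOMS:
        raise ValueError(f"identity_denominator must be one of {_IDENTITY_DENOMS}")
    for name, seq in (("query", query), ("ref", ref)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq) - _STANDARD_AA_SET
        if bad:
            raise ValueError(f"invalid letter(s) {sorted(bad)} in {name}")
    sub = substitution if substitution is not None else _blosum62()

    m, n = len(query), len(ref)
    # Per-letter substitution rows against the reference, looked up once.
    sub_rows = {
        letter: np.array([float(sub[letter, b]) for b in ref])
        for letter in set(query)
    }
    NEG = -np.inf
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)  # gap in query (left moves)
    F = np.full((m + 1, n + 1), NEG)  # gap in ref (up moves)
    for i in range(1, m + 1):
        row_scores = sub_rows[query[i - 1]]
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            diag = H[i - 1, j - 1] + row_scores[j - 1]
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])

    score = float(H.max())
    if score <= 0.0:
        return AlignmentResult("", "", 0.0, 0.0)
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)  # first max, row-major

    aligned_q: list[str] = []
    aligned_r: list[str] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0.0:
                break
            diag = H[i - 1, j - 1] + sub_rows[query[i - 1]][j - 1]
            if H[i, j] == diag:
                aligned_q.append(query[i - 1])
                aligned_r.append(ref[j - 1])
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # up: consume query residue against a gap
            aligned_q.append(query[i - 1])
            aligned_r.append("-")
            from_h = H[i - 1, j] - gap_open
            state = "H" if F[i, j] == from_h else "F"
            i -= 1
        else:  # left: consume ref residue against a gap
            aligned_q.append("-")
            aligned_r.append(ref[j - 1])
            from_h = H[i, j - 1] - gap_open
            state = "H" if E[i, j] == from_h else "E"
            j -= 1

    aligned_query = "".join(reversed(aligned_q))
    aligned_ref = "".join(reversed(aligned_r))
    columns = len(aligned_query)
    identical = sum(a == b and a != "-" for a, b in zip(aligned_query, aligned_ref))
    if identity_denominator == "alignment":
        denom = columns
    elif identity_denominator == "aligned_columns":
        denom = sum(
            a != "-" and b != "-" for a, b in zip(aligned_query, aligned_ref)
        )
    else:
        denom = min(m, n)
    identity = 100.0 * identical / denom if denom else 0.0
    return AlignmentResult(aligned_query, aligned_ref, score, identity)


def identity_distribution(
    identities: Mapping[str, float],
    outcomes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Bin percent identities into 10-point bins per outcome category.

    Bins are half-open [lo, hi) except the final [90, 100]. When *outcomes*
    is given it must cover every id in *identities* (missing ids are an
    error); otherwise everything lands in category ``all``.
    """
    if outcomes is not None:
        missing = sorted(set(identities) - set(outcomes))
        if missing:
            raise ValueError(f"ids without an outcome label: {missing}")
    rows = []
    edges = [(lo, lo + 10) for lo in range(0, 100, 10)]
    by_category: dict[str, list[float]] = {}
    for seq_id, value in identities.items():
        if not 0.0 <= value <= 100.0:
            raise ValueError(f"identity for {seq_id!r} outside [0, 100]")
        category = outcomes[seq_id] if outcomes is not None else "all"
        by_category.setdefault(category, []).append(value)
    for category in sorted(by_category):
        values = np.asarray(by_category[category])
        for lo, hi in edges:
            if hi >= 100:
                count = int(np.sum((values >= lo) & (values <= 100.0)))
            else:
                count = int(np.sum((values >= lo) & (values < hi)))
            rows.append((category, lo, hi, count))
    return pd.DataFrame(rows, columns=["category", "bin_lo", "bin_hi", "count"])
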