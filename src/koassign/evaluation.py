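"""Four-way outcome categorization and pipeline metrics.

Every evaluated sequence falls into one of five categories by comparing its
database truth (a possibly empty set of K numbers) with the pipeline's
prediction:

* match  — truth annotated, prediction made, and they agree;
* unmatch — truth annotated, prediction made, but they disagree;
* missed — truth annotated, no prediction;
* added  — truth unannotated, but a prediction was made;
* true-negative — truth unannotated and no prediction (excluded from the
  metric denominators).

Pipeline precision, recall and F1 derive from the first four counts:
precision = match / (match + unmatch + added),
recall = match / (match + unmatch + missed),
F1 = harmonic mean of the two. Truth may be set-valued (from the dataset
module's union rule on duplicate sequences); a prediction matches when the
two sets intersect, which reduces to exact equality for singletons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Outcome",
    "EvalCounts",
    "PipelineMetrics",
    "EvaluationResult",
    "categorize",
    "tally",
    "pipeline_metrics",
    "evaluate_run",
]


class Outcome(str, Enum):
    MATCH = "match"
    UNMATCH = "unmatch"
    MISSED = "missed"
    ADDED = "added"
    TRUE_NEGATIVE = "true-negative"


@dataclass(frozen=True)
class EvalCounts:
    match: int
    unmatch: int
    missed: int
    added: int

    def __post_init__(self) -> None:
        if min(self.match, self.unmatch, self.missed, self.added) < 0:
            raise ValueError("outcome counts must be non-negative")

    @property
    def n_truth_annotated(self) -> int:
        return self.match + self.unmatch + self.missed


@dataclass(frozen=True)
class PipelineMetrics:
    precision: float
    recall: float
    f1: float

    def rounded(self, ndigits: int = 3) -> "PipelineMetrics":
        """Display rounding (the tables print 3 decimals)."""
        return PipelineMetrics(
            round(self.precision, ndigits),
            round(self.recall, ndigits),
            round(self.f1, ndigits),
        )


def categorize(
    truth: Iterable[str], prediction: Iterable[str] | None
) -> Outcome:
    """Classify one sequence's prediction against its database truth.

    ``prediction`` is ``None`` (or empty) when the pipeline made no
    assignment for the sequence.
    """
    truth_set = frozenset(truth)
    pred_set = frozenset(prediction) if prediction is not None else frozenset()
    if truth_set:
        if not pred_set:
            return Outcome.MISSED
        return Outcome.MATCH if truth_set & pred_set else Outcome.UNMATCH
    return Outcome.ADDED if pred_set else Outcome.TRUE_NEGATIVE


def tally(outcomes: Iterable[Outcome]) -> tuple[EvalCounts, int]:
    """Count outcomes; true-negatives are returned separately."""
    counter = Counter(outcomes)
    counts = EvalCounts(
        match=counter[Outcome.MATCH],
        unmatch=counter[Outcome.UNMATCH],
        missed=counter[Outcome.MISSED],
        added=counter[Outcome.ADDED],
    )
    return counts, counter[Outcome.TRUE_NEGATIVE]


def pipeline_metrics(counts: EvalCounts) -> PipelineMetrics:
    """Precision/recall/F1 from the four outcome counts.

    A zero denominator makes the affected metric (and F1) NaN; match = 0
    with positive denominators gives zeros (limit convention).
    """
    prec_denom = counts.match + counts.unmatch + counts.added
    rec_denom = counts.match + counts.unmatch + counts.missed
    precision = counts.match / prec_denom if prec_denom else np.nan
    recall = counts.match / rec_denom if rec_denom else np.nan
    if np.isnan(precision) or np.isnan(recall):
        f1 = np.nan
    elif counts.match == 0:
        f1 = 0.0
    else:
        f1 = 2.0 / (1.0 / recall + 1.0 / precision)
    return PipelineMetrics(float(precision), float(recall), float(f1))


@dataclass(frozen=True)
class EvaluationResult:
    counts: EvalCounts
    metrics: PipelineMetrics
    outcomes: pd.DataFrame  # columns: id, outcome
    true_negatives: int


def evaluate_run(
    truth_table: Mapping[str, Iterable[str]],
    prediction_table: Mapping[str, Iterable[str] | None],
) -> EvaluationResult:
    """Categorize every truth id, tally, and compute pipeline metrics.

    Ids present in the predictions but absent from the truth are an error
    (the truth table defines the evaluation universe); truth ids missing
    from the predictions count as no-prediction.
    """
    unknown = sorted(set(prediction_table) - set(truth_table))
    if unknown:
        raise ValueError(f"prediction ids absent from truth: {unknown}")
    rows = []
    for seq_id in truth_table:
        outcome = categorize(truth_table[seq_id], prediction_table.get(seq_id))
        rows.append((seq_id, outcome.value))
    outcome_values = [Outcome(o) for _, o in rows]
    counts, true_negatives = tally(outcome_values)
    metrics = pipeline_metrics(counts)
    table = pd.DataFrame(rows, columns=["id", "outcome"])
    return EvaluationResult(counts, metrics, table, true_negatives)
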