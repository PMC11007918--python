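"""Dataset construction rules for the KO / non-KO corpus.

Quality filters (length window, undefined amino acids), de-duplication with
K-number-wins conflict resolution, KO vs non-KO length-distribution balancing,
held-out-species exclusion, and the seeded 8:2 train/test split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .records import SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetConfig",
    "BalanceReport",
    "filter_by_length",
    "remove_undefined",
    "deduplicate",
    "check_length_balance",
    "rebalance_by_downsampling",
    "split_train_test",
    "exclude_species",
]


@dataclass(frozen=True)
class DatasetConfig:
    """Filtering and splitting parameters.

    Lengths outside ``[min_len, max_len]`` residues are discarded (100-600 by
    default: short sequences annotate poorly and long ones are rarely KO).
    ``balance_tolerance`` is the maximum allowed per-bin difference between
    the KO and non-KO length distributions; ``length_bin_width`` sets the
    histogram resolution of that comparison.
    """

    min_len: int = 100
    max_len: int = 600
    split_fraction: float = 0.8
    balance_tolerance: float = 0.05
    length_bin_width: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.balance_tolerance <= 0:
            raise ValueError("balance_tolerance must be positive")
        if self.length_bin_width < 1:
            raise ValueError("length_bin_width must be >= 1")

    @property
    def n_bins(self) -> int:
        # Bins cover [min_len, max_len]; the final bin is closed above so a
        # boundary-length sequence does not get a bin of its own.
        span = self.max_len - self.min_len
        return max(1, math.ceil(span / self.length_bin_width))

    def bin_of(self, length: int) -> int:
        return min((length - self.min_len) // self.length_bin_width, self.n_bins - 1)


@dataclass(frozen=True)
class BalanceReport:
    """Outcome of a KO vs non-KO length-distribution comparison."""

    deviation: float
    per_bin: tuple[float, ...]
    passed: bool


def filter_by_length(
    records: list[SequenceRecord], cfg: DatasetConfig
) -> list[SequenceRecord]:
    """Keep records with min_len <= length <= max_len, preserving order."""
    kept = [r for r in records if cfg.min_len <= len(r.sequence) <= cfg.max_len]
    logger.info("length filter: kept %d of %d records", len(kept), len(records))
    return kept


def remove_undefined(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Drop records containing letters outside the 20 standard amino acids."""
    kept = [r for r in records if not r.has_undefined_aa()]
    logger.info("undefined-AA filter: kept %d of %d records", len(kept), len(records))
    return kept


def deduplicate(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse identical sequences into one record.

    The surviving record keeps the id of the first occurrence and the union
    of all K numbers seen for that sequence, so an annotated copy always
    wins over an unannotated one.
    """
    by_seq: dict[str, SequenceRecord] = {}
    for rec in records:
        prev = by_seq.get(rec.sequence)
        if prev is None:
            by_seq[rec.sequence] = rec
        elif rec.annotations - prev.annotations:
            by_seq[rec.sequence] = SequenceRecord(
                prev.id, prev.sequence, prev.annotations | rec.annotations
            )
    out = list(by_seq.values())
    logger.info("deduplicate: kept %d of %d records", len(out), len(records))
    return out


def _bin_counts(records: list[SequenceRecord], cfg: DatasetConfig) -> np.ndarray:
    counts = np.zeros(cfg.n_bins, dtype=np.int64)
    for rec in records:
        counts[cfg.bin_of(len(rec.sequence))] += 1
    return counts


def check_length_balance(
    ko_records: list[SequenceRecord],
    nonko_records: list[SequenceRecord],
    cfg: DatasetConfig,
) -> BalanceReport:
    """Compare the two classes' length histograms bin by bin.

    The reported deviation is the maximum over bins of the absolute
    difference between the within-class bin proportions; the check passes
    when it is strictly below ``cfg.balance_tolerance``.
    """
    if not ko_records or not nonko_records:
        raise ValueError("both KO and non-KO classes must be non-empty")
    p_ko = _bin_counts(ko_records, cfg) / len(ko_records)
    p_non = _bin_counts(nonko_records, cfg) / len(nonko_records)
    per_bin = np.abs(p_ko - p_non)
    deviation = float(per_bin.max())
    return BalanceReport(deviation, tuple(per_bin), deviation < cfg.balance_tolerance)


def rebalance_by_downsampling(
    ko_records: list[SequenceRecord],
    nonko_records: list[SequenceRecord],
    cfg: DatasetConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Down-sample the over-represented class per length bin until balanced.

    Greedy: repeatedly find the worst bin, and remove from the class with the
    higher proportion there just enough (seeded, uniform) records to match
    the other class's proportion. Deterministic given ``cfg.seed``. Raises if
    balancing would require emptying a class's bin (e.g. a bin populated in
    only one class beyond tolerance).
    """
    rng = np.random.default_rng(cfg.seed)
    classes = {"ko": list(ko_records), "nonko": list(nonko_records)}

    max_iters = 50 * cfg.n_bins
    for _ in range(max_iters):
        report = check_length_balance(classes["ko"], classes["nonko"], cfg)
        if report.passed:
            break
        worst_bin = int(np.argmax(report.per_bin))
        counts = {
            name: _bin_counts(recs, cfg) for name, recs in classes.items()
        }
        props = {
            name: counts[name][worst_bin] / len(classes[name]) for name in classes
        }
        over = max(props, key=lambda n: props[n])
        under = "nonko" if over == "ko" else "ko"
        n_over_bin = int(counts[over][worst_bin])
        p_under = props[under]
        total_over = len(classes[over])
        if n_over_bin == 0 or p_under >= 1.0:
            raise ValueError(
                f"cannot balance length bin {worst_bin}: populated in only one class"
            )
        # Solve n_bin - k = p_under * (total - k) for the removal count.
        k = math.ceil((n_over_bin - p_under * total_over) / (1.0 - p_under))
        k = max(1, k)
        if k >= n_over_bin:
            raise ValueError(
                f"cannot balance length bin {worst_bin}: "
                f"would exhaust the {over} class in that bin"
            )
        bin_positions = [
            i
            for i, rec in enumerate(classes[over])
            if cfg.bin_of(len(rec.sequence)) == worst_bin
        ]
        drop = set(rng.choice(bin_positions, size=k, replace=False).tolist())
        classes[over] = [r for i, r in enumerate(classes[over]) if i not in drop]
    else:
        raise RuntimeError("rebalancing did not converge")

    logger.info(
        "rebalance: KO %d -> %d, non-KO %d -> %d",
        len(ko_records),
        len(classes["ko"]),
        len(nonko_records),
        len(classes["nonko"]),
    )
    return classes["ko"], classes["nonko"]


def split_train_test(
    records: list[SequenceRecord], cfg: DatasetConfig
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Seeded uniform shuffle, then split at floor(split_fraction * N)."""
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(records))
    cut = int(math.floor(cfg.split_fraction * len(records)))
    train = [records[i] for i in order[:cut]]
    test = [records[i] for i in order[cut:]]
    logger.info("split: %d train / %d test", len(train), len(test))
    return train, test


def exclude_species(
    records: list[SequenceRecord], species_prefixes: list[str]
) -> list[SequenceRecord]:
    """Drop records from held-out species and their exact sequence twins.

    A record is dropped if its id starts with ``<prefix>:`` for any given
    organism prefix, or if its sequence is identical to such a record's.
    """
    if not species_prefixes:
        return list(records)
    prefixes = tuple(f"{p}:" for p in species_prefixes)
    excluded_seqs = {
        r.sequence for r in records if r.id.startswith(prefixes)
    }
    kept = [
        r
        for r in records
        if not r.id.startswith(prefixes) and r.sequence not in excluded_seqs
    ]
    logger.info("exclude_species: kept %d of %d records", len(kept), len(records))
    return kept
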