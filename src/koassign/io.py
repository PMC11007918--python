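"""Readers and writers for the pipeline's on-disk formats.

FASTA for sequences, a two-column TSV (``id``, ``ko``) for annotations where
``ko`` is a K number or the literal ``none``, an ``.npz`` container for
embedding matrices, and a PDB subset (first model, first chain, CA atoms,
altloc blank/"A") for alpha-carbon traces.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .records import CATrace, EmbeddingVector, SequenceRecord, is_k_number

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_annotation_table",
    "write_annotation_table",
    "read_embeddings",
    "write_embeddings",
    "read_ca_trace",
    "write_ca_trace",
]

_FASTA_WRAP = 60


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into records with empty annotation sets.

    The id is the header token up to the first whitespace; sequence letters
    are uppercased. An empty file yields an empty list. Sequence data before
    the first header raises :class:`FastaParseError` naming the line number.
    """
    records: list[SequenceRecord] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is not None:
            seq = "".join(chunks)
            if not seq:
                raise FastaParseError(f"entry {current_id!r} has no sequence")
            records.append(SequenceRecord(current_id, seq))

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before first '>' header"
                    )
                chunks.append(line.upper())
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA with 60-column-wrapped sequence lines."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for start in range(0, len(rec.sequence), _FASTA_WRAP):
                handle.write(rec.sequence[start : start + _FASTA_WRAP] + "\n")


def read_annotation_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read an ``id``/``ko`` TSV into a map id -> set of K numbers.

    ``none`` maps to the empty set; multiple rows for one id accumulate.
    A ko value that is neither a K number nor ``none`` raises ``ValueError``
    with the offending row number (1-based, excluding the header).
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"id", "ko"} - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing column(s): {sorted(missing)}")
    annotations: dict[str, set[str]] = {}
    for row_number, (seq_id, ko) in enumerate(
        zip(table["id"], table["ko"]), start=1
    ):
        if pd.isna(seq_id) or not str(seq_id):
            raise ValueError(f"row {row_number}: empty id")
        seq_id = str(seq_id)
        ko = "" if pd.isna(ko) else str(ko)
        bucket = annotations.setdefault(seq_id, set())
        if ko == "none":
            continue
        if not is_k_number(ko):
            raise ValueError(
                f"row {row_number}: ko value {ko!r} is neither a K number nor 'none'"
            )
        bucket.add(ko)
    return {seq_id: frozenset(kos) for seq_id, kos in annotations.items()}


def write_annotation_table(
    annotations: Mapping[str, Iterable[str]], path: str | Path
) -> None:
    """Write a map id -> K numbers as an ``id``/``ko`` TSV (``none`` if empty)."""
    rows: list[tuple[str, str]] = []
    for seq_id in annotations:
        kos = sorted(annotations[seq_id])
        if not kos:
            rows.append((seq_id, "none"))
        else:
            rows.extend((seq_id, ko) for ko in kos)
    pd.DataFrame(rows, columns=["id", "ko"]).to_csv(path, sep="\t", index=False)


def write_embeddings(vectors: Iterable[EmbeddingVector], path: str | Path) -> None:
    """Store embeddings as an ``.npz`` with ``ids`` and a float64 ``values`` matrix."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("cannot write an empty embedding collection")
    dims = {v.dim for v in vectors}
    if len(dims) > 1:
        raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
    ids = np.array([v.id for v in vectors])
    values = np.stack([v.values for v in vectors]).astype(np.float64)
    np.savez(path, ids=ids, values=values)


def read_embeddings(path: str | Path) -> list[EmbeddingVector]:
    """Load an embedding container written by :func:`write_embeddings`."""
    with np.load(path, allow_pickle=False) as data:
        ids = [str(i) for i in data["ids"]]
        values = np.asarray(data["values"], dtype=np.float64)
    if values.ndim != 2 or values.shape[0] != len(ids):
        raise ValueError("embedding container ids/values are misaligned")
    return [EmbeddingVector(i, row) for i, row in zip(ids, values)]


def read_ca_trace(path: str | Path, trace_id: str | None = None) -> CATrace:
    """Extract the CA trace of the first model's first chain from a PDB file.

    Alternate locations other than blank or "A" are skipped. Raises
    ``ValueError("empty trace")`` when no CA atom survives.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(trace_id or path.stem, str(path))
    try:
        model = next(structure.get_models())
        chain = next(model.get_chains())
    except StopIteration:
        raise ValueError("empty trace") from None
    coords: list[np.ndarray] = []
    for residue in chain:
        if "CA" not in residue:
            continue
        atom = residue["CA"]
        if atom.is_disordered():
            if atom.disordered_has_id("A"):
                atom = atom.disordered_get("A")
            else:
                continue
        coords.append(np.asarray(atom.coord, dtype=np.float64))
    if not coords:
        raise ValueError("empty trace")
    return CATrace(trace_id or path.stem, np.stack(coords))


def write_ca_trace(trace: CATrace, path: str | Path) -> None:
    """Write a CA trace as minimal single-chain PDB ATOM records."""
    with open(path, "w") as handle:
        for i, (x, y, z) in enumerate(trace.coords, start=1):
            handle.write(
                f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        handle.write("END\n")
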