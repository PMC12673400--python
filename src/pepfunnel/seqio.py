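"""FASTA input/output, protein records and sliding-window training pairs.

Training examples are built with a sliding window of length ``window``
(default 35): the first 34 residues of each window are the context and the
35th is the prediction target, so a sequence of length L yields
``max(0, L - window + 1)`` windows.  Sequences shorter than the window are
skipped with a warning — the 20-symbol vocabulary has no pad token.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from pepfunnel.alphabet import ALPHABET, ResidueAlphabet, SequenceError, encode, validate_sequence

logger = logging.getLogger(__name__)

Role = Literal["base", "finetune", "generated", "candidate"]
ROLES = ("base", "finetune", "generated", "candidate")

#: Context length used throughout the package (window 35 = 34 context + 1 target).
DEFAULT_WINDOW = 35


@dataclass
class ProteinRecord:
    """One identified sequence with its provenance in the pipeline."""

    id: str
    sequence: str
    role: Role = "base"
    source: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrainingWindow:
    """A 34-residue integer context and the integer identity of the next residue."""

    context: tuple[int, ...]
    target: int

    def __post_init__(self) -> None:
        if any(not 0 <= v < 20 for v in self.context) or not 0 <= self.target < 20:
            raise ValueError("window values must lie in 0..19")


def read_fasta(
    path: str | Path,
    role: Role = "base",
    alphabet: ResidueAlphabet = ALPHABET,
    skip_invalid: bool = False,
) -> list[ProteinRecord]:
    """Parse a FASTA file into validated :class:`ProteinRecord` objects.

    Ids are the header token up to the first whitespace; order is preserved.
    Records with non-canonical residues raise :class:`SequenceError` (or are
    dropped with a warning when ``skip_invalid``).  An empty file is an error.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = validate_sequence(str(rec.seq), alphabet)
        except SequenceError as exc:
            if skip_invalid:
                logger.warning("skipping record %s: %s", rec.id, exc)
                continue
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
        records.append(ProteinRecord(id=rec.id, sequence=seq, role=role, source=str(path)))
    if not records:
        raise SequenceError(f"no FASTA records parsed from {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to *path* in FASTA format, wrapping lines at *width*."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def make_windows(encoded: Sequence[int], window: int = DEFAULT_WINDOW) -> list[TrainingWindow]:
    """Slide a length-``window`` frame over an encoded sequence.

    Returns one :class:`TrainingWindow` per start offset (0-based, half-open
    [i, i + window)): context = first ``window - 1`` codes, target = the last.
    Sequences shorter than the window give an empty list and a warning.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    L = len(encoded)
    if L < window:
        logger.warning("sequence of length %d shorter than window %d; no training pairs", L, window)
        return []
    return [
        TrainingWindow(context=tuple(int(v) for v in encoded[i : i + window - 1]), target=int(encoded[i + window - 1]))
        for i in range(L - window + 1)
    ]


def windows_from_records(
    records: Iterable[ProteinRecord], window: int = DEFAULT_WINDOW
) -> tuple[np.ndarray, np.ndarray]:
    """Encode records and stack their sliding windows into model-ready arrays.

    Returns ``(X, y)`` with ``X`` of shape (n_windows, window - 1) and ``y``
    of shape (n_windows,), both int64.
    """
    ctxs: list[list[int]] = []
    tgts: list[int] = []
    for rec in records:
        enc = encode(rec.sequence)
        for w in make_windows(enc, window):
            ctxs.append(list(w.context))
            tgts.append(w.target)
    if not ctxs:
        return np.empty((0, window - 1), dtype=np.int64), np.empty((0,), dtype=np.int64)
    return np.asarray(ctxs, dtype=np.int64), np.asarray(tgts, dtype=np.int64)


def corpus_summary(records: Iterable[ProteinRecord], window: int = DEFAULT_WINDOW):
    """Per-record (id, length, n_windows) table as a pandas DataFrame."""
    import pandas as pd

    rows = [
        {"id": r.id, "length": len(r), "n_windows": max(0, len(r) - window + 1)}
        for r in records
    ]
    return pd.DataFrame(rows, columns=["id", "length", "n_windows"])
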