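"""Synthetic corpora with known, learnable structure.

Two generators make every pipeline stage testable without any downloads:

* :func:`motif_corpus` emulates the real training data's shape — a base set
  of long sequences (default 7 sequences, 230–1019 residues, the envelope
  of the curated full-length proteins) and a fine-tune set of short
  peptides (default 6, <= 100 residues) — as uniform-random residues with a
  short deterministic motif (default the Abeta-core ``KLVFF``) planted at a
  controlled rate, so that a trained model has a recoverable signal.
* :func:`deterministic_successor_corpus` draws a random residue permutation
  as a first-order successor map and emits sequences that follow it, so
  next-residue prediction has an exact oracle (accuracy 1.0 is attainable).

Both are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pepfunnel.alphabet import ALPHABET, decode, validate_sequence
from pepfunnel.seqio import ProteinRecord

__all__ = ["MotifCorpusSpec", "motif_corpus", "deterministic_successor_corpus"]


@dataclass
class MotifCorpusSpec:
    """Shape and motif parameters of the synthetic two-corpus dataset."""

    n_base: int = 7
    base_len_range: tuple[int, int] = (230, 1019)
    n_finetune: int = 6
    finetune_len_range: tuple[int, int] = (40, 100)
    motif: str = "KLVFF"
    motif_rate: float = 2.0  # planted insertions per 100 residues
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.motif = validate_sequence(self.motif)
        if self.motif_rate < 0:
            raise ValueError("motif_rate must be non-negative")
        for lo, hi in (self.base_len_range, self.finetune_len_range):
            if not 1 <= lo <= hi:
                raise ValueError("length ranges must be ordered and positive")


def _random_sequence(rng: np.random.Generator, length: int) -> list[int]:
    return list(rng.integers(0, 20, size=length))


def _plant_motif(rng: np.random.Generator, codes: list[int], motif: list[int], rate: float) -> list[int]:
    L = len(codes)
    m = len(motif)
    if L < m or rate <= 0:
        return codes
    n_insert = int(rng.binomial(L, min(rate / 100.0, 1.0)))
    starts = rng.integers(0, L - m + 1, size=n_insert)
    for s in starts:
        codes[s : s + m] = motif
    return codes


def motif_corpus(spec: MotifCorpusSpec = MotifCorpusSpec()) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Generate (base, finetune) record lists for a MotifCorpusSpec, deterministically."""
    rng = np.random.default_rng(spec.rng_seed)
    from pepfunnel.alphabet import encode

    motif_codes = encode(spec.motif)

    def make(n: int, len_range: tuple[int, int], role: str, prefix: str) -> list[ProteinRecord]:
        out = []
        for i in range(n):
            L = int(rng.integers(len_range[0], len_range[1] + 1))
            codes = _plant_motif(rng, _random_sequence(rng, L), motif_codes, spec.motif_rate)
            out.append(
                ProteinRecord(
                    id=f"{prefix}_{i + 1:03d}",
                    sequence=decode(codes),
                    role=role,  # type: ignore[arg-type]
                    source="synthetic-motif-corpus",
                )
            )
        return out

    base = make(spec.n_base, spec.base_len_range, "base", "SYNBASE")
    finetune = make(spec.n_finetune, spec.finetune_len_range, "finetune", "SYNFT")
    return base, finetune


def deterministic_successor_corpus(
    rng_seed: int = 0, n: int = 20, length: int = 60
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Sequences following a random one-to-one residue successor map.

    Returns (records, map) where ``map[letter]`` is the unique letter that
    always follows it, so any 34-residue context determines the next residue
    exactly (the oracle for memorisation tests).
    """
    if length < 35:
        raise ValueError("length must be >= 35 so that training windows exist")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(20)
    succ = {ALPHABET.letters[i]: ALPHABET.letters[perm[i]] for i in range(20)}
    records = []
    for i in range(n):
        cur = int(rng.integers(0, 20))
        codes = [cur]
        for _ in range(length - 1):
            cur = int(perm[cur])
            codes.append(cur)
        records.append(
            ProteinRecord(
                id=f"SUCC_{i + 1:03d}",
                sequence=decode(codes),
                role="base",
                source="synthetic-successor-corpus",
            )
        )
    return records, succ
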