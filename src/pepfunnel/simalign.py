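"""Pairwise global-alignment percent identity and the novelty shortlist.

Candidates are scored against each fine-tuning reference peptide by
end-to-end (Needleman–Wunsch-style) global alignment with BLOSUM62 and
affine gaps (open 10, extend 0.5 — needle-like defaults).  Percent identity
is 100 x identical aligned columns / alignment length *including gap
columns* — tools differ here, and shorter-sequence denominators inflate
identity, so the convention is fixed and documented.

The final shortlist keeps the ``keep`` candidates with the highest
similarity statistic (default: maximum identity over the references) among
those below a ``novelty_ceiling`` — high enough similarity to suggest
shared function, low enough to guarantee novelty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from pepfunnel.alphabet import SequenceError
from pepfunnel.seqio import ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AlignerParams",
    "IdentityTable",
    "ShortlistConfig",
    "percent_identity",
    "identity_table",
    "shortlist",
]


@dataclass(frozen=True)
class AlignerParams:
    """Substitution matrix and affine gap penalties for global alignment."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class IdentityTable:
    """Candidates x references percent-identity matrix with its parameters."""

    values: pd.DataFrame  # rows: candidate ids, cols: reference ids
    params: AlignerParams

    @property
    def rows(self) -> list[str]:
        return list(self.values.index)

    @property
    def cols(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ShortlistConfig:
    """Final-shortlist selection rule."""

    keep: int = 11
    novelty_ceiling: float = 60.0
    rank_by: str = "max_identity"  # or mean_identity

    def __post_init__(self) -> None:
        if self.keep <= 0:
            raise ValueError("keep must be positive")
        if not 0 < self.novelty_ceiling <= 100:
            raise ValueError("novelty_ceiling must lie in (0, 100]")
        if self.rank_by not in ("max_identity", "mean_identity"):
            raise ValueError("rank_by must be max_identity or mean_identity")


def _make_aligner(params: AlignerParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # first gap position costs -open, each further position -extend
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def percent_identity(a: str, b: str, params: AlignerParams = AlignerParams()) -> float:
    """Percent identity of the optimal global alignment of *a* and *b*."""
    if not a or not b:
        raise SequenceError("cannot align empty sequences")
    aligner = _make_aligner(params)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(row_a, row_b))
    return 100.0 * matches / len(row_a)


def identity_table(
    candidates: Sequence[ProteinRecord],
    refs: Sequence[ProteinRecord],
    params: AlignerParams = AlignerParams(),
) -> IdentityTable:
    """Full candidates x references identity matrix (deterministic)."""
    if not candidates or not refs:
        raise ValueError("need at least one candidate and one reference")
    data = {
        ref.id: [percent_identity(c.sequence, ref.sequence, params) for c in candidates]
        for ref in refs
    }
    df = pd.DataFrame(data, index=[c.id for c in candidates])
    return IdentityTable(values=df, params=params)


def shortlist(
    candidates: Sequence[ProteinRecord],
    table: IdentityTable,
    config: ShortlistConfig = ShortlistConfig(),
) -> list[ProteinRecord]:
    """Select the final candidates by similarity rank under a novelty ceiling.

    The per-candidate statistic (max or mean identity over references) must
    be strictly below ``novelty_ceiling``; qualifying candidates are sorted
    by the statistic descending (ties by id) and truncated to ``keep``.
    """
    missing = [c.id for c in candidates if c.id not in table.values.index]
    if missing:
        raise ValueError(f"identity table missing candidates: {missing}")
    if config.rank_by == "max_identity":
        stat = table.values.max(axis=1)
    else:
        stat = table.values.mean(axis=1)
    df = pd.DataFrame({"stat": [stat[c.id] for c in candidates], "id": [c.id for c in candidates]})
    qual = df[df["stat"] < config.novelty_ceiling]
    if len(qual) < config.keep:
        logger.warning(
            "only %d of %d candidates fall below the novelty ceiling %.1f (keep=%d)",
            len(qual), len(df), config.novelty_ceiling, config.keep,
        )
    chosen = qual.sort_values(["stat", "id"], ascending=[False, True], kind="mergesort").head(config.keep)
    keep_ids = set(chosen["id"])
    return [c for c in candidates if c.id in keep_ids]
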