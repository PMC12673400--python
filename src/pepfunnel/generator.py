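"""Candidate-pool generation by seeded greedy autoregressive decoding.

Each peptide starts from a random contiguous 34-residue window drawn from
the seed corpus; the model then repeatedly emits
``argmax P(next | last 34 tokens)`` until the target length is reached.
Greedy decoding is deterministic, so all pool diversity comes from seed
sampling; target lengths are drawn uniformly from [min_len, max_len]
(default 80..100).  By default the emitted peptide consists of generated
residues only — the seed window is not part of the output — so candidates
are wholly model-generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from pepfunnel.alphabet import decode
from pepfunnel.model import BiLSTMNextResidue
from pepfunnel.seqio import ProteinRecord

__all__ = ["GenerationConfig", "make_seed", "generate_one", "generate_pool"]


@dataclass
class GenerationConfig:
    """Pool size, length range and seeding policy for generation."""

    n_sequences: int = 1000
    min_len: int = 80
    max_len: int = 100
    seed_source: str = "finetune"    # finetune | base | both
    rng_seed: int = 0
    dedupe: bool = False
    include_seed: bool = False

    def __post_init__(self) -> None:
        if not 2 <= self.min_len <= self.max_len:
            raise ValueError("need 2 <= min_len <= max_len")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.seed_source not in ("finetune", "base", "both"):
            raise ValueError("seed_source must be finetune, base or both")


def _eligible(corpus: Sequence[ProteinRecord], seed_source: str, context: int):
    if seed_source == "both":
        pool = list(corpus)
    else:
        pool = [r for r in corpus if r.role == seed_source]
        if not pool:  # corpus may carry no role labels matching; fall back to all
            pool = list(corpus)
    pool = [r for r in pool if len(r) >= context]
    if not pool:
        raise ValueError(f"no sequence of length >= {context} available for seeding")
    return pool


def make_seed(
    corpus: Sequence[ProteinRecord],
    rng: np.random.Generator,
    context: int = 34,
    seed_source: str = "both",
) -> np.ndarray:
    """Draw a contiguous *context*-residue window, uniform over all
    (sequence, start-offset) pairs in the eligible corpus."""
    from pepfunnel.alphabet import encode

    pool = _eligible(corpus, seed_source, context)
    counts = np.array([len(r) - context + 1 for r in pool])
    cum = np.cumsum(counts)
    pick = int(rng.integers(cum[-1]))
    seq_idx = int(np.searchsorted(cum, pick, side="right"))
    offset = pick - (cum[seq_idx - 1] if seq_idx else 0)
    window = pool[seq_idx].sequence[offset : offset + context]
    return np.asarray(encode(window), dtype=np.int64)


def _greedy_extend(model: BiLSTMNextResidue, contexts: np.ndarray, n_steps: int) -> np.ndarray:
    """Batched greedy decoding: returns (B, n_steps) emitted tokens."""
    ctx = contexts.copy()
    out = np.empty((ctx.shape[0], n_steps), dtype=np.int64)
    for t in range(n_steps):
        probs = model.predict_proba(ctx)
        nxt = probs.argmax(axis=1)
        out[:, t] = nxt
        ctx = np.concatenate([ctx[:, 1:], nxt[:, None]], axis=1)
    return out


def generate_one(
    model: BiLSTMNextResidue,
    seed: np.ndarray,
    target_len: int,
    record_id: str = "GEN_0001",
    include_seed: bool = False,
) -> ProteinRecord:
    """Generate one peptide of exactly *target_len* residues from a seed context."""
    seed = np.asarray(seed, dtype=np.int64)
    if seed.ndim != 1 or seed.shape[0] != model.context_length:
        raise ValueError(f"seed must have length {model.context_length}")
    emitted = _greedy_extend(model, seed[None, :], target_len)[0]
    tokens = np.concatenate([seed, emitted]) if include_seed else emitted
    return ProteinRecord(id=record_id, sequence=decode(tokens), role="generated", source="greedy-decode")


def generate_pool(
    model: BiLSTMNextResidue,
    corpus: Sequence[ProteinRecord],
    config: GenerationConfig = GenerationConfig(),
) -> list[ProteinRecord]:
    """Generate ``config.n_sequences`` peptides (ids GEN_0001, GEN_0002, ...)."""
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_sequences
    ctx_len = model.context_length
    seeds = np.stack(
        [make_seed(corpus, rng, ctx_len, config.seed_source) for _ in range(n)]
    )
    lengths = rng.integers(config.min_len, config.max_len + 1, size=n)
    emitted = _greedy_extend(model, seeds, int(config.max_len))
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    width = max(4, len(str(n)))
    for i in range(n):
        tokens = emitted[i, : lengths[i]]
        if config.include_seed:
            tokens = np.concatenate([seeds[i], tokens])
        seq = decode(tokens)
        if config.dedupe:
            if seq in seen:
                continue
            seen.add(seq)
        records.append(
            ProteinRecord(
                id=f"GEN_{i + 1:0{width}d}",
                sequence=seq,
                role="generated",
                source="greedy-decode",
            )
        )
    return records
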