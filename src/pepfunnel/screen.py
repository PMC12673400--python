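"""Two-stage physicochemical screening funnel.

Stage 1: the generated pool is split into contiguous batches (default 5).
Within each batch every peptide is ranked per metric — Shannon entropy
descending, GRAVY ascending, instability ascending — and the composite
score is the sum of the three 1-based ranks; the ``stage1_keep`` (default
10) lowest-composite peptides per batch survive.  Stage 2 computes the
Euclidean distance in the raw (GRAVY, instability) plane to the centroid of
the fine-tuning reference peptides and keeps the ``stage2_keep`` (default
5) closest per batch.  With the defaults and a 1000-peptide pool the funnel
yields 1000 -> 50 -> 25.

All ties are broken by original generation order, so the funnel is fully
deterministic.  Features are not standardised by default (the distance is
taken in raw units, letting instability dominate GRAVY numerically); an
optional z-score mode is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from pepfunnel.biophys import BiophysProfile, profile
from pepfunnel.seqio import ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "ReferenceCentroid",
    "FunnelReport",
    "FunnelScreen",
    "partition",
    "stage1_rank",
    "stage1_select",
    "reference_centroid",
    "centroid_distance",
    "stage2_select",
]


@dataclass
class ScreenConfig:
    """Funnel geometry: batch count and per-batch survivor counts."""

    n_batches: int = 5
    stage1_keep: int = 10
    stage2_keep: int = 5
    standardize_features: bool = False

    def __post_init__(self) -> None:
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.stage2_keep > self.stage1_keep:
            raise ValueError("stage2_keep must not exceed stage1_keep")


@dataclass(frozen=True)
class ReferenceCentroid:
    """Mean (GRAVY, instability) of the fine-tuning reference peptides."""

    gravy_mean: float
    instability_mean: float
    n_refs: int
    gravy_sd: float = 1.0
    instability_sd: float = 1.0


@dataclass
class FunnelReport:
    """Survivor counts plus the full per-candidate provenance table."""

    n_input: int
    n_stage1: int
    n_stage2: int
    table: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_stage1": self.n_stage1,
            "n_stage2": self.n_stage2,
            "candidates": self.table.to_dict(orient="records"),
        }


def partition(pool: Sequence[ProteinRecord], n_batches: int = 5) -> list[list[ProteinRecord]]:
    """Split the pool into contiguous batches in generation order.

    Sizes differ by at most one; earlier batches take the remainder.
    """
    n = len(pool)
    if n == 0:
        raise ValueError("cannot partition an empty pool")
    if n_batches > n:
        raise ValueError(f"n_batches ({n_batches}) exceeds pool size ({n})")
    base, rem = divmod(n, n_batches)
    batches = []
    start = 0
    for b in range(n_batches):
        size = base + (1 if b < rem else 0)
        batches.append(list(pool[start : start + size]))
        start += size
    return batches


def _profiles(batch: Sequence[ProteinRecord]) -> list[BiophysProfile]:
    return [profile(r.sequence) for r in batch]


def stage1_rank(
    batch: Sequence[ProteinRecord],
    gen_index: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Composite rank-sum ordering of one batch.

    Per-metric 1-based ranks (entropy descending, GRAVY ascending,
    instability ascending; per-metric ties resolved by generation order)
    are summed into a composite score; rows are sorted by composite
    ascending, ties again by generation order.
    """
    idx = list(gen_index) if gen_index is not None else list(range(len(batch)))
    profs = _profiles(batch)
    df = pd.DataFrame(
        {
            "id": [r.id for r in batch],
            "gen_index": idx,
            "entropy": [p.entropy for p in profs],
            "gravy": [p.gravy for p in profs],
            "instability": [p.instability for p in profs],
        }
    )
    def ordinal_rank(keys: pd.Series, ascending: bool) -> pd.Series:
        order = df.assign(_k=keys).sort_values(
            ["_k", "gen_index"], ascending=[ascending, True], kind="mergesort"
        ).index
        ranks = pd.Series(0, index=df.index)
        ranks.loc[order] = range(1, len(df) + 1)
        return ranks

    df["rank_entropy"] = ordinal_rank(df["entropy"], ascending=False)
    df["rank_gravy"] = ordinal_rank(df["gravy"], ascending=True)
    df["rank_instability"] = ordinal_rank(df["instability"], ascending=True)
    df["composite_rank"] = df["rank_entropy"] + df["rank_gravy"] + df["rank_instability"]
    return df.sort_values(["composite_rank", "gen_index"], kind="mergesort").reset_index(drop=True)


def stage1_select(ranked_batches: Sequence[pd.DataFrame], stage1_keep: int = 10) -> list[pd.DataFrame]:
    """Keep the top ``stage1_keep`` rows of each ranked batch."""
    if stage1_keep == 0:
        logger.warning("stage1_keep=0: empty shortlist")
    out = []
    for b, df in enumerate(ranked_batches):
        if len(df) < stage1_keep:
            logger.warning("batch %d has only %d candidates (< keep=%d)", b, len(df), stage1_keep)
        out.append(df.head(stage1_keep).copy())
    return out


def reference_centroid(refs: Sequence[ProteinRecord]) -> ReferenceCentroid:
    """Arithmetic-mean (GRAVY, instability) over the reference peptides."""
    if not refs:
        raise ValueError("reference set is empty")
    profs = _profiles(refs)
    g = [p.gravy for p in profs]
    i = [p.instability for p in profs]
    n = len(profs)
    gm = sum(g) / n
    im = sum(i) / n
    gsd = math.sqrt(sum((x - gm) ** 2 for x in g) / n) if n > 1 else 1.0
    isd = math.sqrt(sum((x - im) ** 2 for x in i) / n) if n > 1 else 1.0
    return ReferenceCentroid(
        gravy_mean=gm, instability_mean=im, n_refs=n,
        gravy_sd=gsd or 1.0, instability_sd=isd or 1.0,
    )


def centroid_distance(
    p: BiophysProfile, c: ReferenceCentroid, standardize: bool = False
) -> float:
    """Euclidean distance in the (GRAVY, instability) plane."""
    dg = p.gravy - c.gravy_mean
    di = p.instability - c.instability_mean
    if standardize:
        dg /= c.gravy_sd
        di /= c.instability_sd
    return math.sqrt(dg * dg + di * di)


def stage2_select(
    stage1_groups: Sequence[pd.DataFrame],
    centroid: ReferenceCentroid,
    stage2_keep: int = 5,
    standardize: bool = False,
) -> list[pd.DataFrame]:
    """Per batch, keep the ``stage2_keep`` candidates closest to the centroid."""
    out = []
    for df in stage1_groups:
        df = df.copy()
        df["centroid_distance"] = [
            centroid_distance(
                BiophysProfile(row.entropy, row.gravy, row.instability), centroid, standardize
            )
            for row in df.itertuples()
        ]
        df = df.sort_values(["centroid_distance", "gen_index"], kind="mergesort")
        out.append(df.head(stage2_keep).reset_index(drop=True))
    return out


class FunnelScreen:
    """Sklearn-style transformer over the full two-stage funnel.

    ``fit(refs)`` computes the reference centroid from fine-tuning peptides;
    ``transform(pool)`` runs both stages and returns the surviving records.
    Fitted attributes: ``centroid_``; after transform: ``report_``.
    """

    def __init__(self, config: ScreenConfig = ScreenConfig()):
        self.config = config

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "FunnelScreen":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, refs: Sequence[ProteinRecord]) -> "FunnelScreen":
        self.centroid_ = reference_centroid(refs)
        return self

    def transform(self, pool: Sequence[ProteinRecord]) -> list[ProteinRecord]:
        if not hasattr(self, "centroid_"):
            raise ValueError("FunnelScreen must be fitted on reference peptides first")
        cfg = self.config
        batches = partition(pool, cfg.n_batches)
        by_id = {r.id: r for r in pool}
        ranked = []
        offset = 0
        for b, batch in enumerate(batches):
            df = stage1_rank(batch, gen_index=range(offset, offset + len(batch)))
            df.insert(1, "batch", b)
            ranked.append(df)
            offset += len(batch)
        kept1 = stage1_select(ranked, cfg.stage1_keep)
        kept2 = stage2_select(
            kept1, self.centroid_, cfg.stage2_keep, cfg.standardize_features
        )
        stage1_ids = {i for df in kept1 for i in df["id"]}
        stage2_ids = {i for df in kept2 for i in df["id"]}
        full = pd.concat(ranked, ignore_index=True)
        full["survived_stage1"] = full["id"].isin(stage1_ids)
        full["survived_stage2"] = full["id"].isin(stage2_ids)
        # distances exist only for stage-1 survivors; NaN elsewhere
        dist1 = {
            row.id: centroid_distance(
                BiophysProfile(row.entropy, row.gravy, row.instability),
                self.centroid_,
                cfg.standardize_features,
            )
            for df in kept1
            for row in df.itertuples()
        }
        full["centroid_distance"] = full["id"].map(dist1)
        survivors = [
            by_id[i] for df in kept2 for i in df.sort_values("gen_index")["id"]
        ]
        self.report_ = FunnelReport(
            n_input=len(pool),
            n_stage1=int(full["survived_stage1"].sum()),
            n_stage2=int(full["survived_stage2"].sum()),
            table=full.sort_values("gen_index").reset_index(drop=True),
        )
        for r in survivors:
            r.role = "candidate"
        return survivors

    def fit_transform(self, refs, pool) -> list[ProteinRecord]:
        return self.fit(refs).transform(pool)
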