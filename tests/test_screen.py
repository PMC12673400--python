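"""Two-stage funnel: partition, rank-sum stage 1, centroid-distance stage 2.

The stage-1 and stage-2 selections are checked against brute-force oracles
that recompute ranks and distances from first principles on toy batches.
"""

import math

import numpy as np
import pytest

from pepfunnel.alphabet import decode
from pepfunnel.biophys import BiophysProfile, profile
from pepfunnel.screen import (
    FunnelScreen,
    ReferenceCentroid,
    ScreenConfig,
    centroid_distance,
    partition,
    reference_centroid,
    stage1_rank,
    stage1_select,
    stage2_select,
)
from pepfunnel.seqio import ProteinRecord


def random_records(n, rng_seed=0, min_len=20, max_len=60, prefix="P"):
    rng = np.random.default_rng(rng_seed)
    return [
        ProteinRecord(f"{prefix}{i:03d}", decode(rng.integers(0, 20, size=int(rng.integers(min_len, max_len)))))
        for i in range(n)
    ]


# --- independent oracles ----------------------------------------------------

def oracle_stage1_order(batch):
    """Recompute composite rank-sum ordering by explicit rank counting."""
    profs = [profile(r.sequence) for r in batch]
    keys = {
        "entropy": [(-p.entropy, i) for i, p in enumerate(profs)],
        "gravy": [(p.gravy, i) for i, p in enumerate(profs)],
        "instability": [(p.instability, i) for i, p in enumerate(profs)],
    }
    composite = [0] * len(batch)
    for key in keys.values():
        for rank, (_, i) in enumerate(sorted(key), start=1):
            composite[i] += rank
    return [i for _, i in sorted((c, i) for i, c in enumerate(composite))], composite


def oracle_stage2_ids(df, centroid, keep):
    dist = [
        (math.hypot(row.gravy - centroid.gravy_mean, row.instability - centroid.instability_mean), row.gen_index, row.id)
        for row in df.itertuples()
    ]
    return [i for _, _, i in sorted(dist)[:keep]]


class TestPartition:
    @pytest.mark.parametrize(
        "n,k,sizes",
        [(1000, 5, [200] * 5), (10, 5, [2] * 5), (11, 5, [3, 2, 2, 2, 2]), (7, 3, [3, 2, 2])],
    )
    def test_contiguous_near_even_split(self, n, k, sizes):
        pool = random_records(n)
        batches = partition(pool, k)
        assert [len(b) for b in batches] == sizes
        flat = [r.id for b in batches for r in b]
        assert flat == [r.id for r in pool]

    def test_errors(self):
        with pytest.raises(ValueError):
            partition([], 2)
        with pytest.raises(ValueError):
            partition(random_records(3), 5)


class TestStage1:
    def test_dominant_sequence_ranks_first_with_composite_3(self):
        # "dom" beats both on all three metrics: highest entropy, lowest
        # GRAVY, lowest instability (DT/TG dipeptides carry negative weights)
        batch = [
            ProteinRecord("dull", "AAAAAAAAAA"),      # zero entropy
            ProteinRecord("oily", "IIIIIVVVVV"),      # very hydrophobic
            ProteinRecord("dom", "DTGDTGDTG"),
        ]
        profs = {r.id: profile(r.sequence) for r in batch}
        assert profs["dom"].entropy == max(p.entropy for p in profs.values())
        assert profs["dom"].gravy == min(p.gravy for p in profs.values())
        assert profs["dom"].instability == min(p.instability for p in profs.values())
        df = stage1_rank(batch)
        assert df.iloc[0]["id"] == "dom"
        assert df.iloc[0]["composite_rank"] == 3

    def test_identical_sequences_keep_generation_order(self):
        batch = [ProteinRecord("a", "KLVFFAEDV"), ProteinRecord("b", "KLVFFAEDV")]
        df = stage1_rank(batch)
        assert list(df["id"]) == ["a", "b"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_rank_sums(self, seed):
        batch = random_records(8, rng_seed=seed)
        df = stage1_rank(batch)
        order, composite = oracle_stage1_order(batch)
        assert list(df["id"]) == [batch[i].id for i in order]
        got = dict(zip(df["id"], df["composite_rank"]))
        assert got == {batch[i].id: composite[i] for i in range(len(batch))}

    def test_select_clamps_and_warns(self):
        df = stage1_rank(random_records(4))
        kept = stage1_select([df], stage1_keep=10)
        assert len(kept[0]) == 4
        empty = stage1_select([df], stage1_keep=0)
        assert len(empty[0]) == 0


class TestCentroid:
    def test_mean_of_reference_profiles(self):
        refs = random_records(5, rng_seed=2)
        c = reference_centroid(refs)
        profs = [profile(r.sequence) for r in refs]
        assert c.gravy_mean == pytest.approx(sum(p.gravy for p in profs) / 5)
        assert c.instability_mean == pytest.approx(sum(p.instability for p in profs) / 5)
        assert c.n_refs == 5

    def test_single_reference_is_its_own_centroid(self):
        (ref,) = random_records(1, rng_seed=3)
        c = reference_centroid([ref])
        p = profile(ref.sequence)
        assert (c.gravy_mean, c.instability_mean) == (p.gravy, p.instability)

    def test_order_invariance(self):
        refs = random_records(6, rng_seed=4)
        a = reference_centroid(refs)
        b = reference_centroid(refs[::-1])
        assert a.gravy_mean == pytest.approx(b.gravy_mean)
        assert a.instability_mean == pytest.approx(b.instability_mean)

    def test_empty_refs_error(self):
        with pytest.raises(ValueError):
            reference_centroid([])

    @pytest.mark.parametrize(
        "p,c,expected",
        [
            (BiophysProfile(0, 1.0, 40.0), ReferenceCentroid(1.0, 40.0, 1), 0.0),
            (BiophysProfile(0, 0.0, 0.0), ReferenceCentroid(3.0, 4.0, 1), 5.0),
            (BiophysProfile(0, -3.0, -4.0), ReferenceCentroid(0.0, 0.0, 1), 5.0),
        ],
    )
    def test_distance_closed_forms(self, p, c, expected):
        assert centroid_distance(p, c) == pytest.approx(expected)


class TestStage2:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_distance_sort(self, seed):
        batch = random_records(10, rng_seed=seed)
        df = stage1_rank(batch)
        centroid = reference_centroid(random_records(4, rng_seed=seed + 50))
        (kept,) = stage2_select([df], centroid, stage2_keep=5)
        assert sorted(kept["id"]) == sorted(oracle_stage2_ids(df, centroid, 5))

    def test_keep_equal_to_group_size_passes_through(self):
        df = stage1_rank(random_records(4))
        centroid = ReferenceCentroid(0.0, 40.0, 1)
        (kept,) = stage2_select([df], centroid, stage2_keep=4)
        assert sorted(kept["id"]) == sorted(df["id"])


class TestFunnelScreen:
    def test_default_funnel_counts_on_full_pool(self, random_pool):
        refs = random_records(6, rng_seed=9, min_len=40, max_len=100)
        fs = FunnelScreen(ScreenConfig()).fit(refs)
        survivors = fs.transform(random_pool)
        report = fs.report_
        assert (report.n_input, report.n_stage1, report.n_stage2) == (1000, 50, 25)
        assert len(survivors) == 25

    def test_funnel_conservation_and_no_duplicates(self, random_pool):
        refs = random_records(6, rng_seed=9, min_len=40, max_len=100)
        fs = FunnelScreen(ScreenConfig()).fit(refs)
        survivors = fs.transform(random_pool)
        t = fs.report_.table
        pool_ids = {r.id for r in random_pool}
        s2 = set(t[t["survived_stage2"]]["id"])
        s1 = set(t[t["survived_stage1"]]["id"])
        assert s2 <= s1 <= pool_ids
        ids = [r.id for r in survivors]
        assert len(ids) == len(set(ids))

    def test_report_metrics_match_biophys_exactly(self, random_pool):
        refs = random_records(6, rng_seed=9, min_len=40, max_len=100)
        fs = FunnelScreen(ScreenConfig()).fit(refs)
        fs.transform(random_pool[:50])
        by_id = {r.id: r for r in random_pool[:50]}
        for row in fs.report_.table.head(20).itertuples():
            p = profile(by_id[row.id].sequence)
            assert (row.entropy, row.gravy, row.instability) == (p.entropy, p.gravy, p.instability)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScreenConfig(stage1_keep=3, stage2_keep=5)
        with pytest.raises(ValueError):
            ScreenConfig(n_batches=0)
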