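"""Global-alignment percent identity against an exhaustive enumeration
oracle, plus the novelty shortlist rules."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from pepfunnel.alphabet import SequenceError, decode
from pepfunnel.seqio import ProteinRecord
from pepfunnel.simalign import (
    AlignerParams,
    ShortlistConfig,
    identity_table,
    percent_identity,
    shortlist,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


# --- exhaustive alignment oracle -------------------------------------------

def all_alignments(a, b):
    """Every global alignment of a and b as (row_a, row_b) gapped strings."""
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for ra, rb in all_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb
    if a:
        for ra, rb in all_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in all_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb


def affine_score(ra, rb, gap_open=10.0, gap_extend=0.5):
    """Score one alignment: BLOSUM62 matches; a length-k gap run in either
    row costs open + (k-1)*extend."""
    s = 0.0
    for k, (x, y) in enumerate(zip(ra, rb)):
        if x == "-":
            s -= gap_extend if k > 0 and ra[k - 1] == "-" else gap_open
        elif y == "-":
            s -= gap_extend if k > 0 and rb[k - 1] == "-" else gap_open
        else:
            s += BLOSUM62[x, y]
    return s


def oracle_identities(a, b):
    """(best score, set of percent identities among co-optimal alignments)."""
    scored = [(affine_score(ra, rb), ra, rb) for ra, rb in all_alignments(a, b)]
    best = max(s for s, _, _ in scored)
    idents = {
        100.0 * sum(x == y and x != "-" for x, y in zip(ra, rb)) / len(ra)
        for s, ra, rb in scored
        if s > best - 1e-9
    }
    return best, idents


class TestPercentIdentity:
    @pytest.mark.parametrize("seq", ["KLVFF", "A", "ACDEFGHIKLMNPQRSTVWY"])
    def test_self_identity_is_100(self, seq):
        assert percent_identity(seq, seq) == 100.0

    def test_disjoint_homopolymers_score_zero(self):
        assert percent_identity("AAAA", "CCCC") == 0.0

    def test_single_gapless_mismatch(self):
        assert percent_identity("ACDE", "ACDF") == 75.0

    def test_empty_input_is_error(self):
        with pytest.raises(SequenceError):
            percent_identity("", "ACD")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration_on_short_sequences(self, seed):
        """Optimal score and identity agree with brute-force enumeration of
        all global alignments (length <= 6)."""
        rng = np.random.default_rng(seed)
        a = decode(rng.integers(0, 20, size=int(rng.integers(2, 7))))
        b = decode(rng.integers(0, 20, size=int(rng.integers(2, 7))))
        best, idents = oracle_identities(a, b)
        from pepfunnel.simalign import _make_aligner

        aligner = _make_aligner(AlignerParams())
        assert aligner.score(a, b) == pytest.approx(best, abs=1e-9)
        pid = percent_identity(a, b)
        assert any(abs(pid - x) < 1e-9 for x in idents)

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_within_tiebreak_tolerance(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = decode(rng.integers(0, 20, size=30))
        b = decode(rng.integers(0, 20, size=int(rng.integers(20, 40))))
        assert abs(percent_identity(a, b) - percent_identity(b, a)) <= 0.5


class TestIdentityTable:
    def _records(self, n, seed, prefix, length=30):
        rng = np.random.default_rng(seed)
        return [
            ProteinRecord(f"{prefix}{i}", decode(rng.integers(0, 20, size=length)), "candidate")
            for i in range(n)
        ]

    def test_identical_pair_gives_100(self):
        c = ProteinRecord("c", "KLVFFAEDV", "candidate")
        r = ProteinRecord("r", "KLVFFAEDV", "finetune")
        table = identity_table([c], [r])
        assert table.values.shape == (1, 1)
        assert table.values.iloc[0, 0] == 100.0

    def test_full_cartesian_matrix(self):
        cands = self._records(5, 0, "c")
        refs = self._records(3, 1, "r")
        table = identity_table(cands, refs)
        assert table.values.shape == (5, 3)
        assert table.rows == [c.id for c in cands]
        assert table.cols == [r.id for r in refs]
        assert ((table.values >= 0) & (table.values <= 100)).all().all()

    def test_row_permutation_invariance(self):
        cands = self._records(4, 2, "c")
        refs = self._records(2, 3, "r")
        t1 = identity_table(cands, refs)
        t2 = identity_table(cands[::-1], refs)
        assert t1.values.loc[cands[0].id].equals(t2.values.loc[cands[0].id])


class TestShortlist:
    def _setup(self, seed=0, n=25):
        rng = np.random.default_rng(seed)
        cands = [
            ProteinRecord(f"c{i:02d}", decode(rng.integers(0, 20, size=40)), "candidate")
            for i in range(n)
        ]
        refs = [
            ProteinRecord(f"r{i}", decode(rng.integers(0, 20, size=50)), "finetune")
            for i in range(4)
        ]
        return cands, identity_table(cands, refs)

    def test_default_shortlist_size_and_ceiling(self):
        cands, table = self._setup()
        final = shortlist(cands, table)
        assert len(final) <= 11
        mx = table.values.max(axis=1)
        assert all(mx[r.id] < 60.0 for r in final)
        assert {r.id for r in final} <= {c.id for c in cands}

    def test_exact_match_excluded_by_novelty_ceiling(self):
        ref = ProteinRecord("r", "KLVFFAEDVGSNKGAIIGLMV", "finetune")
        clone = ProteinRecord("clone", ref.sequence, "candidate")
        rng = np.random.default_rng(5)
        others = [
            ProteinRecord(f"c{i}", decode(rng.integers(0, 20, size=21)), "candidate")
            for i in range(3)
        ]
        cands = [clone] + others
        table = identity_table(cands, [ref])
        final = shortlist(cands, table)
        assert all(r.id != "clone" for r in final)

    def test_keep_one_matches_exhaustive_max(self):
        cands, table = self._setup(seed=7, n=3)
        final = shortlist(cands, table, ShortlistConfig(keep=1))
        stats = table.values.max(axis=1)
        qualifying = {i: v for i, v in stats.items() if v < 60.0}
        best_val = max(qualifying.values())
        expected_id = sorted(i for i, v in qualifying.items() if v == best_val)[0]
        assert [r.id for r in final] == [expected_id]

    def test_missing_candidate_in_table_is_error(self):
        cands, table = self._setup(n=4)
        stranger = ProteinRecord("zz", "KLVFFKLVFF", "candidate")
        with pytest.raises(ValueError, match="zz"):
            shortlist(cands + [stranger], table)
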