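import numpy as np
import pytest

from oracles import naive_fitting_score, rc
from puffalign import build_index, simulate_genome
from puffalign.alignment import AlignmentResult, ScoringScheme
from puffalign.io_formats import ReadRecord
from puffalign.pairing import (
    PairingParams,
    finalize_read,
    is_concordant,
    join_ends,
    recover_orphan,
)

SC = ScoringScheme()
P = PairingParams()


def aln(ref_start, fw, score=200, ref_id=0, read_end=1, length=100):
    return AlignmentResult(ref_id=ref_id, ref_start=ref_start, fw=fw, score=score,
                           cigar=(("M", length),), read_end=read_end)


class TestJoinEnds:
    def test_fr_concordant_pair(self):
        pairs = join_ends([aln(1000, True)], [aln(1200, False, read_end=2)], P)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.status == "concordant" and p.fragment_len == 300
        assert p.pair_score == 400

    def test_same_strand_not_concordant(self):
        pairs = join_ends([aln(1000, True)], [aln(1200, True, read_end=2)], P)
        assert pairs == []

    def test_fragment_length_bound(self):
        far = aln(2500, False, read_end=2)
        assert join_ends([aln(1000, True)], [far], P) == []
        ok = aln(1900, False, read_end=2)
        assert len(join_ends([aln(1000, True)], [ok], P)) == 1

    def test_fr_order_matters(self):
        # reverse mate upstream of forward mate violates FR
        pairs = join_ends([aln(1200, True)], [aln(800, False, read_end=2)], P)
        assert pairs == []

    def test_cross_reference_never_pairs(self):
        pairs = join_ends([aln(0, True, ref_id=0)], [aln(200, False, ref_id=1)], P)
        assert pairs == []

    def test_best_strata_keeps_only_top_score(self):
        params = PairingParams(best_strata=True)
        lefts = [aln(0, True, score=100), aln(5000, True, score=100),
                 aln(10000, True, score=90)]
        rights = [aln(200, False, score=100, read_end=2),
                  aln(5200, False, score=100, read_end=2),
                  aln(10200, False, score=100, read_end=2)]
        pairs = join_ends(lefts, rights, params)
        assert len(pairs) == 2
        assert all(p.pair_score == 200 for p in pairs)

    def test_discordant_only_when_no_concordant_exists(self):
        params = PairingParams(allow_discordant=True)
        # same strand ends: discordant fallback fires
        pairs = join_ends([aln(1000, True)], [aln(1200, True, read_end=2)], params)
        assert len(pairs) == 1 and pairs[0].status == "discordant"
        # one concordant pair suppresses all discordant candidates
        pairs = join_ends(
            [aln(1000, True), aln(3000, True)],
            [aln(1200, False, read_end=2), aln(3100, True, read_end=2)],
            params,
        )
        assert {p.status for p in pairs} == {"concordant"}

    def test_truncation_to_max_alignments(self):
        params = PairingParams(max_alignments_per_read=3)
        lefts = [aln(i * 2000, True) for i in range(6)]
        rights = [aln(i * 2000 + 200, False, read_end=2) for i in range(6)]
        pairs = join_ends(lefts, rights, params)
        assert len(pairs) == 3

    def test_concordance_revalidates(self):
        for p in join_ends(
            [aln(500, True)], [aln(700, False, read_end=2)], P
        ):
            assert is_concordant(p.left, p.right, P)


@pytest.fixture(scope="module")
def orphan_setup():
    refs = simulate_genome(6000, seed=60)
    idx = build_index(refs, 31)
    return refs, idx


class TestRecoverOrphan:
    def test_mate_planted_downstream_recovered_exactly(self, orphan_setup):
        refs, idx = orphan_setup
        ref = refs[0].seq
        mapped = aln(2000, True)
        mate_seq = rc(ref[2300:2400])  # opposite strand, 300 bp downstream
        recs = recover_orphan(mapped, mate_seq, idx, SC, P)
        assert len(recs) == 1
        assert recs[0].ref_start == 2300 and not recs[0].fw
        assert recs[0].cigar == (("M", 100),) and recs[0].score == 200

    def test_mate_outside_window_not_recovered(self, orphan_setup):
        refs, idx = orphan_setup
        ref = refs[0].seq
        mapped = aln(2000, True)
        mate_seq = rc(ref[3200:3300])  # 1200 bp away > max_fragment_len
        assert recover_orphan(mapped, mate_seq, idx, SC, P) == []

    def test_mate_with_substitutions_scores_like_oracle(self, orphan_setup):
        refs, idx = orphan_setup
        ref = refs[0].seq
        mapped = aln(2000, True)
        mate = list(rc(ref[2300:2400]))
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        mate[10] = flip[mate[10]]
        mate[60] = flip[mate[60]]
        mate = "".join(mate)
        recs = recover_orphan(mapped, mate, idx, SC, P)
        assert len(recs) == 1
        window = ref[2000:3000]
        assert recs[0].score == naive_fitting_score(rc(mate), window, 2, -4, -5, -3)

    def test_reverse_mapped_end_searches_upstream(self, orphan_setup):
        refs, idx = orphan_setup
        ref = refs[0].seq
        mapped = aln(4000, False, read_end=2)
        mate_seq = ref[3700:3800]
        recs = recover_orphan(mapped, mate_seq, idx, SC, P)
        assert len(recs) == 1 and recs[0].ref_start == 3700 and recs[0].fw


def _reads():
    r1 = ReadRecord("q", "A" * 100, "I" * 100, mate=1)
    r2 = ReadRecord("q", "C" * 100, "I" * 100, mate=2)
    return r1, r2


class TestFinalizeRead:
    def test_concordant_pair_two_primary_proper_records(self):
        from puffalign.pairing import PairedAlignment

        r1, r2 = _reads()
        pair = PairedAlignment(left=aln(100, True), right=aln(300, False, read_end=2),
                               status="concordant", pair_score=400, fragment_len=300)
        recs = finalize_read(r1, r2, [pair], [], P, ["ref"])
        assert len(recs) == 2
        for rec in recs:
            assert rec.flag & 0x1 and rec.flag & 0x2
            assert not rec.flag & 0x100
        assert recs[0].flag & 0x40 and recs[1].flag & 0x80
        assert recs[0].tlen == 300 and recs[1].tlen == -300
        assert dict((t, v) for t, _, v in recs[0].tags)["NH"] == 1

    def test_secondary_flag_and_nh_for_multiple_pairs(self):
        from puffalign.pairing import PairedAlignment

        r1, r2 = _reads()
        pairs = [
            PairedAlignment(left=aln(100, True), right=aln(300, False, read_end=2),
                            status="concordant", pair_score=400, fragment_len=300),
            PairedAlignment(left=aln(2100, True, score=190),
                            right=aln(2300, False, score=190, read_end=2),
                            status="concordant", pair_score=380, fragment_len=300),
        ]
        recs = finalize_read(r1, r2, pairs, [], P, ["ref"])
        assert len(recs) == 4
        assert [bool(r.flag & 0x100) for r in recs] == [False, False, True, True]
        assert all(dict((t, v) for t, _, v in r.tags)["NH"] == 2 for r in recs)

    def test_no_alignments_gives_two_unmapped(self):
        r1, r2 = _reads()
        recs = finalize_read(r1, r2, [], [], P, ["ref"])
        assert len(recs) == 2
        for rec in recs:
            assert rec.flag & 0x4 and rec.flag & 0x8
            assert rec.rname is None

    def test_reverse_strand_record_revcomps_seq(self):
        from puffalign.pairing import PairedAlignment

        r1 = ReadRecord("q", "AACCGGTT", "IIIIJJJJ", mate=1)
        r2 = ReadRecord("q", "ACGTACGT", "KKKKLLLL", mate=2)
        pair = PairedAlignment(
            left=aln(100, True, length=8), right=aln(300, False, read_end=2, length=8),
            status="concordant", pair_score=400, fragment_len=208,
        )
        recs = finalize_read(r1, r2, [pair], [], P, ["ref"])
        assert recs[0].seq == "AACCGGTT"
        assert recs[1].seq == rc("ACGTACGT")
        assert recs[1].qual == "LLLLKKKK"

    def test_single_end_ranking_and_unmapped(self):
        r1 = ReadRecord("q", "A" * 100, "I" * 100)
        recs = finalize_read(r1, None, [], [aln(5, True, score=150), aln(900, True)], P, ["ref"])
        assert [r.pos for r in recs] == [900, 5]  # ranked by score
        assert not recs[0].flag & 0x100 and recs[1].flag & 0x100
        recs = finalize_read(r1, None, [], [], P, ["ref"])
        assert len(recs) == 1 and recs[0].flag & 0x4
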