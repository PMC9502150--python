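import numpy as np
import pytest

from oracles import (
    naive_extension_score,
    naive_fitting_score,
    naive_global_score,
    rc,
)
from puffalign import build_index, simulate_genome
from puffalign.alignment import (
    AlignmentCache,
    ScoringScheme,
    accept_alignment,
    align_from_chain,
    extension_align,
    extension_buffer,
    fitting_align,
    global_align,
    score_cigar,
)
from puffalign.chaining import Chain
from puffalign.driver import align_read_end
from puffalign import AlignConfig
from puffalign.io_formats import cigar_read_len, cigar_ref_len
from puffalign.seeding import Mem

SC = ScoringScheme()  # match 2, mismatch -4, gap open -5, extend -3


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestGlobalAlign:
    def test_perfect_match(self):
        assert global_align("ACGT", "ACGT", SC) == (8, (("M", 4),))

    def test_single_substitution(self):
        score, cigar = global_align("ACGT", "AGGT", SC)
        assert score == 3 * 2 - 4 and cigar == (("M", 4),)

    def test_empty_cases(self):
        assert global_align("", "", SC) == (0, ())
        assert global_align("", "ACG", SC) == (-5 - 9, (("D", 3),))
        assert global_align("ACG", "", SC) == (-5 - 9, (("I", 3),))

    def test_matches_naive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(101)
        for trial in range(300):
            m = int(rng.integers(1, 51))
            n = int(rng.integers(1, 51))
            q, t = rand_seq(rng, m), rand_seq(rng, n)
            if trial % 3 == 0:  # related pair: mutate t from q
                t = q[: max(1, m - 3)] + rand_seq(rng, 3)
            score, cigar = global_align(q, t, SC)
            assert score == naive_global_score(q, t, 2, -4, -5, -3), f"trial {trial}"
            assert cigar_read_len(cigar) == len(q)
            assert cigar_ref_len(cigar) == len(t)

    def test_cigar_score_coherence(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            q, t = rand_seq(rng, 30), rand_seq(rng, 33)
            score, cigar = global_align(q, t, SC)
            assert score_cigar(q, t, 0, cigar, SC) == score


class TestExtensionAlign:
    def test_empty_tail(self):
        assert extension_align("", "ACGTACGT", SC, "right") == (0, (), 0)

    def test_exact_prefix(self):
        score, cigar, used = extension_align("ACGTA", "ACGTACCCC", SC, "right")
        assert (score, cigar, used) == (10, (("M", 5),), 5)

    def test_exact_suffix_left_side(self):
        score, cigar, used = extension_align("GGTTT", "AAAAGGTTT", SC, "left")
        assert (score, cigar, used) == (10, (("M", 5),), 5)

    def test_matches_bruteforce_over_prefixes(self):
        rng = np.random.default_rng(303)
        for trial in range(60):
            m = int(rng.integers(1, 21))
            tail = rand_seq(rng, m)
            window = tail[: int(rng.integers(0, m + 1))] + rand_seq(rng, int(rng.integers(0, 12)))
            for side in ("right", "left"):
                w = window if side == "right" else window[::-1]
                score, cigar, used = extension_align(tail, w, SC, side)
                oracle = naive_extension_score(tail, w, 2, -4, -5, -3, side)
                assert score == oracle, f"trial {trial} {side}"
                assert cigar_read_len(cigar) == m
                assert cigar_ref_len(cigar) == used

    def test_soft_clip_caps_negative_tails(self):
        # a tail that matches nothing is clipped at score 0 when allowed
        score, cigar, _ = extension_align("AAAA", "TTTT", SC, "right", allow_soft_clip=True)
        assert score >= 0
        assert cigar[-1][0] == "S" or score > 0


class TestFittingAlign:
    def test_finds_planted_position(self):
        rng = np.random.default_rng(7)
        window = rand_seq(rng, 200)
        read = window[73:123]
        score, cigar, off, span = fitting_align(read, window, SC)
        assert score == 100 and off == 73 and span == 50 and cigar == (("M", 50),)

    def test_matches_naive_oracle_with_mismatches(self):
        rng = np.random.default_rng(70)
        window = rand_seq(rng, 120)
        read = list(window[30:80])
        read[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[10]]
        read = "".join(read)
        score, _, _, _ = fitting_align(read, window, SC)
        assert score == naive_fitting_score(read, window, 2, -4, -5, -3)


class TestExtensionBuffer:
    def test_documented_formula(self):
        # floor((0.65 * 2 * 20 + 5) / 3) + 1
        assert extension_buffer(20, SC, 0.65) == int((0.65 * 2 * 20 + 5) / 3) + 1

    def test_empty_tail_needs_no_buffer(self):
        assert extension_buffer(0, SC, 0.65) == 0


@pytest.fixture(scope="module")
def aln_genome_index():
    refs = simulate_genome(4000, seed=33)
    return refs, build_index(refs, 21)


def full_chain(index, ref_id, ref_pos, read_pos, length, fw=True):
    m = Mem(ref_id=ref_id, ref_pos=ref_pos, read_pos=read_pos, length=length, fw=fw)
    return Chain(mems=[m], score=float(length), ref_id=ref_id, fw=fw)


class TestAlignFromChain:
    def test_fully_anchored_read_is_all_match(self, aln_genome_index):
        refs, idx = aln_genome_index
        read = refs[0].seq[500:600]
        res = align_from_chain(read, full_chain(idx, 0, 500, 0, 100), idx, SC)
        assert res.cigar == (("M", 100),)
        assert res.score == 200 and res.ref_start == 500

    def test_stitched_two_anchor_pattern_matches_full_dp(self, aln_genome_index):
        # two MEMs, one bounded middle gap, one right tail: the stitched
        # score equals an independent full-read DP on the same window
        refs, idx = aln_genome_index
        ref = refs[0].seq
        read = list(ref[1000:1100])
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        read[40] = flip[read[40]]  # middle gap (substitution)
        read[95] = flip[read[95]]  # inside right tail
        read = "".join(read)
        mems = [
            Mem(ref_id=0, ref_pos=1000, read_pos=0, length=40, fw=True),
            Mem(ref_id=0, ref_pos=1041, read_pos=41, length=54, fw=True),
        ]
        chain = Chain(mems=mems, score=94.0, ref_id=0, fw=True)
        res = align_from_chain(read, chain, idx, SC)
        oracle = naive_global_score(read, ref[1000:1100], 2, -4, -5, -3)
        assert res.score == oracle
        assert res.ref_start == 1000
        assert score_cigar(read, ref, res.ref_start, res.cigar, SC) == res.score

    def test_left_tail_extension_sets_ref_start(self, aln_genome_index):
        refs, idx = aln_genome_index
        ref = refs[0].seq
        read = list(ref[2000:2100])
        read[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[5]]
        read = "".join(read)
        chain = full_chain(idx, 0, 2006, 6, 94)
        res = align_from_chain(read, chain, idx, SC)
        assert res.ref_start == 2000
        assert res.score == 2 * 99 - 4

    def test_stitched_never_exceeds_full_dp(self, aln_genome_index):
        # anchoring constrains the alignment, so stitched <= oracle, and for
        # substitution-only reads with equal gaps it is always equal
        refs, idx = aln_genome_index
        ref = refs[0].seq
        rng = np.random.default_rng(44)
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        cfg = AlignConfig()
        equal_cases = 0
        for trial in range(30):
            start = int(rng.integers(0, len(ref) - 100))
            read = list(ref[start : start + 100])
            for p in rng.integers(5, 95, size=int(rng.integers(1, 4))):
                read[p] = flip[read[p]]
            read = "".join(read)
            alns = align_read_end(read, idx, cfg)
            target = [a for a in alns if a.ref_start == start and a.fw]
            if not target:
                continue
            oracle = naive_global_score(read, ref[start : start + 100], 2, -4, -5, -3)
            assert target[0].score <= oracle
            equal_cases += target[0].score == oracle
        assert equal_cases >= 25  # substitution-only: equality is the norm

    def test_rc_chain_aligns_revcomp_read(self, aln_genome_index):
        refs, idx = aln_genome_index
        ref = refs[0].seq
        read = rc(ref[3000:3100])
        m = Mem(ref_id=0, ref_pos=3000, read_pos=0, length=100, fw=False)
        chain = Chain(mems=[m], score=100.0, ref_id=0, fw=False)
        res = align_from_chain(read, chain, idx, SC)
        assert not res.fw and res.ref_start == 3000 and res.score == 200

    def test_cache_is_transparent_and_hit_on_repeat(self, aln_genome_index):
        refs, idx = aln_genome_index
        ref = refs[0].seq
        read = list(ref[600:700])
        read[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[50]]
        read = "".join(read)
        mems = [
            Mem(ref_id=0, ref_pos=600, read_pos=0, length=50, fw=True),
            Mem(ref_id=0, ref_pos=651, read_pos=51, length=49, fw=True),
        ]
        chain = Chain(mems=mems, score=99.0, ref_id=0, fw=True)
        no_cache = align_from_chain(read, chain, idx, SC, cache=None)
        cache = AlignmentCache(100)
        first = align_from_chain(read, chain, idx, SC, cache=cache)
        second = align_from_chain(read, chain, idx, SC, cache=cache)
        assert first == no_cache == second
        assert cache.hits >= 1


class TestAcceptAlignment:
    def _res(self, score):
        from puffalign.alignment import AlignmentResult

        return AlignmentResult(ref_id=0, ref_start=0, fw=True, score=score,
                               cigar=(("M", 100),))

    def test_perfect_alignment_accepted(self):
        assert accept_alignment(self._res(200), 100, SC, 0.65)

    def test_boundary_is_inclusive(self):
        assert accept_alignment(self._res(130), 100, SC, 0.65)
        assert not accept_alignment(self._res(129), 100, SC, 0.65)

    def test_zero_threshold_accepts_everything(self):
        assert accept_alignment(self._res(-500), 100, SC, 0.0)
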