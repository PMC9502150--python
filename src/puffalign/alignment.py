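"""Between-MEM alignment: DP pieces, stitching, and the alignment cache.

A selected chain pins exact-match anchors to the reference; only the read
intervals *between* anchors are ever re-aligned.  Bounded gaps (flanked by
two anchors) get a global affine-gap alignment against the corresponding
reference interval; the read prefix/suffix outside the outermost anchors get
an extension alignment whose reference end is free, over a window sized by
the longest indel that could still yield an acceptable score.  Pieces are
stitched into one CIGAR whose score is the sum of piece scores plus the
match bonus over anchor bases.

DP results are memoized by substring content (not coordinates), so repeated
reference regions — the common case for redundant reference collections —
share cache entries.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from typing import List, Optional, Tuple

import numpy as np

from ._kernel import OP_D, OP_I, OP_M, affine_dp
from ._seq import revcomp
from .chaining import Chain
from .index import CcdbgIndex

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "AlignmentCache",
    "global_align",
    "extension_align",
    "fitting_align",
    "align_from_chain",
    "accept_alignment",
    "extension_buffer",
    "score_cigar",
]

Cigar = Tuple[Tuple[str, int], ...]

_OPCHAR = {OP_M: "M", OP_I: "I", OP_D: "D"}


@dataclasses.dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; a gap of length L costs gap_open + L*gap_extend."""

    match: int = 2
    mismatch: int = -4
    gap_open: int = -5
    gap_extend: int = -3

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch/gap penalties must be negative")


@dataclasses.dataclass(frozen=True)
class AlignmentResult:
    """A stitched base-to-base alignment of one read end."""

    ref_id: int
    ref_start: int  # 0-based on the reference forward strand
    fw: bool  # read forward strand aligned to reference forward strand
    score: int
    cigar: Cigar  # in the orientation of the aligned (possibly revcomp'd) read
    read_end: Optional[int] = None

    @property
    def ref_span(self) -> int:
        return sum(length for op, length in self.cigar if op in "MD")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span


class AlignmentCache:
    """Bounded LRU memo of DP piece results, keyed by substring content."""

    def __init__(self, capacity: int = 10000):
        self.capacity = capacity
        self._d: OrderedDict = OrderedDict()
        self.hits = 0
        self.misses = 0

    def get(self, key):
        if self.capacity <= 0:
            return None
        try:
            val = self._d[key]
        except KeyError:
            self.misses += 1
            return None
        self._d.move_to_end(key)
        self.hits += 1
        return val

    def put(self, key, value):
        if self.capacity <= 0:
            return
        self._d[key] = value
        self._d.move_to_end(key)
        if len(self._d) > self.capacity:
            self._d.popitem(last=False)


def _to_arr(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _runs(ops: np.ndarray, nops: int) -> List[Tuple[str, int]]:
    # kernel emits ops backwards
    out: List[Tuple[str, int]] = []
    for idx in range(nops - 1, -1, -1):
        op = _OPCHAR[int(ops[idx])]
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


def global_align(read_iv: str, ref_iv: str, scoring: ScoringScheme) -> Tuple[int, Cigar]:
    """Optimal end-to-end affine alignment of two (possibly empty) strings."""
    if not read_iv and not ref_iv:
        return 0, ()
    if not read_iv:
        return scoring.gap_open + len(ref_iv) * scoring.gap_extend, (("D", len(ref_iv)),)
    if not ref_iv:
        return scoring.gap_open + len(read_iv) * scoring.gap_extend, (("I", len(read_iv)),)
    score, _ie, _js, _je, ops, nops = affine_dp(
        _to_arr(read_iv), _to_arr(ref_iv),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
        False, False, False,
    )
    return int(score), tuple(_runs(ops, nops))


def extension_align(
    read_tail: str,
    ref_window: str,
    scoring: ScoringScheme,
    side: str,
    allow_soft_clip: bool = False,
) -> Tuple[int, Cigar, int]:
    """Align a read tail end-to-end against a prefix (side='right') or
    suffix (side='left') of the reference window; the reference end is free.

    Returns (score, cigar in read orientation, reference bases consumed).
    With ``allow_soft_clip`` the outer read end may also be left unaligned
    (reported as an S run at score 0).
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if not read_tail:
        return 0, (), 0
    q, t = read_tail, ref_window
    if side == "left":
        q, t = q[::-1], t[::-1]
    if not t:
        score = scoring.gap_open + len(q) * scoring.gap_extend
        cigar: List[Tuple[str, int]] = [("I", len(q))]
        if allow_soft_clip and score < 0:
            score, cigar = 0, [("S", len(q))]
        if side == "left":
            cigar.reverse()
        return score, tuple(cigar), 0
    score, i_end, _js, j_end, ops, nops = affine_dp(
        _to_arr(q), _to_arr(t),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
        False, True, allow_soft_clip,
    )
    cigar = _runs(ops, nops)
    if i_end < len(q):  # soft-clipped read suffix (outer end)
        cigar.append(("S", len(q) - i_end))
    if side == "left":
        cigar.reverse()
    return int(score), tuple(cigar), int(j_end)


def fitting_align(
    read_seq: str, ref_window: str, scoring: ScoringScheme
) -> Tuple[int, Cigar, int, int]:
    """Best placement of the whole read inside the window (both reference
    ends free).  Returns (score, cigar, window offset, reference span)."""
    if not read_seq:
        return 0, (), 0, 0
    if not ref_window:
        return scoring.gap_open + len(read_seq) * scoring.gap_extend, (("I", len(read_seq)),), 0, 0
    score, _ie, j_start, j_end, ops, nops = affine_dp(
        _to_arr(read_seq), _to_arr(ref_window),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
        True, True, False,
    )
    return int(score), tuple(_runs(ops, nops)), int(j_start), int(j_end - j_start)


def extension_buffer(tail_len: int, scoring: ScoringScheme, min_score_fraction: float) -> int:
    """Reference padding for an ending sub-sequence alignment: the maximum
    indel length that could still leave the tail's score acceptable."""
    if tail_len == 0:
        return 0
    budget = min_score_fraction * scoring.match * tail_len + abs(scoring.gap_open)
    return int(budget / abs(scoring.gap_extend)) + 1


def _merge_cigar(pieces: List[Tuple[str, int]]) -> Cigar:
    out: List[Tuple[str, int]] = []
    for op, length in pieces:
        if length == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + length)
        else:
            out.append((op, length))
    return tuple(out)


class ChainGeometryError(RuntimeError):
    """Chain anchors are mutually inconsistent after normalization."""


def align_from_chain(
    read_seq: str,
    chain: Chain,
    index: CcdbgIndex,
    scoring: ScoringScheme,
    cache: Optional[AlignmentCache] = None,
    min_score_fraction: float = 0.65,
    allow_soft_clip: bool = False,
) -> AlignmentResult:
    """Stitch a full alignment from a chain: exact anchors stay as M runs
    with no recomputation, gaps get DP pieces, tails get extension pieces."""
    n = len(read_seq)
    r = read_seq if chain.fw else revcomp(read_seq)
    ref = index.ref_seq(chain.ref_id)

    # anchor intervals in oriented-read coordinates, overlap-trimmed
    anchors: List[Tuple[int, int, int]] = []  # (oread_start, ref_start, length)
    for m in chain.mems:
        orp = m.read_pos if chain.fw else n - m.read_pos - m.length
        t, L = m.ref_pos, m.length
        if anchors:
            pr, pt, pL = anchors[-1]
            trim = max(pr + pL - orp, pt + pL - t, 0)
            orp += trim
            t += trim
            L -= trim
            if L <= 0:
                continue  # anchor fully covered by its predecessor
            if orp < pr + pL or t < pt + pL:
                raise ChainGeometryError("overlapping anchors after normalization")
        anchors.append((orp, t, L))

    score = 0
    pieces: List[Tuple[str, int]] = []

    first_r, first_t, _ = anchors[0]
    ref_start = first_t
    if first_r > 0:
        tail = r[:first_r]
        buf = extension_buffer(len(tail), scoring, min_score_fraction)
        w0 = max(0, first_t - (len(tail) + buf))
        window = ref[w0:first_t]
        key = ("ext-left", tail, window)
        res = cache.get(key) if cache else None
        if res is None:
            res = extension_align(tail, window, scoring, "left", allow_soft_clip)
            if cache:
                cache.put(key, res)
        sc, cig, consumed = res
        score += sc
        pieces.extend(cig)
        ref_start = first_t - consumed

    prev_r = prev_t = None
    for orp, t, L in anchors:
        if prev_r is not None:
            read_gap = r[prev_r:orp]
            ref_gap = ref[prev_t:t]
            if read_gap or ref_gap:
                key = ("global", read_gap, ref_gap)
                res = cache.get(key) if cache else None
                if res is None:
                    res = global_align(read_gap, ref_gap, scoring)
                    if cache:
                        cache.put(key, res)
                sc, cig = res
                score += sc
                pieces.extend(cig)
        pieces.append(("M", L))
        score += scoring.match * L
        prev_r, prev_t = orp + L, t + L

    if prev_r < n:
        tail = r[prev_r:]
        buf = extension_buffer(len(tail), scoring, min_score_fraction)
        window = ref[prev_t : prev_t + len(tail) + buf]
        key = ("ext-right", tail, window)
        res = cache.get(key) if cache else None
        if res is None:
            res = extension_align(tail, window, scoring, "right", allow_soft_clip)
            if cache:
                cache.put(key, res)
        sc, cig, _consumed = res
        score += sc
        pieces.extend(cig)

    cigar = _merge_cigar(pieces)
    consumed = sum(length for op, length in cigar if op in "MIS")
    if consumed != n:
        raise ChainGeometryError(
            f"stitched CIGAR consumes {consumed} read bases, expected {n}"
        )
    return AlignmentResult(
        ref_id=chain.ref_id,
        ref_start=ref_start,
        fw=chain.fw,
        score=score,
        cigar=cigar,
        read_end=chain.read_end,
    )


def accept_alignment(
    result: AlignmentResult,
    read_len: int,
    scoring: ScoringScheme,
    min_score_fraction: float = 0.65,
) -> bool:
    """Score floor: at least min_score_fraction of a perfect score.

    A zero fraction disables the filter entirely (everything is accepted,
    even negative scores)."""
    if min_score_fraction <= 0:
        return True
    return result.score >= min_score_fraction * scoring.match * read_len


def score_cigar(
    oriented_read: str, ref_seq: str, ref_start: int, cigar: Cigar, scoring: ScoringScheme
) -> int:
    """Re-score a CIGAR against the sequences (coherence checks)."""
    i, j = 0, ref_start
    total = 0
    for op, length in cigar:
        if op == "M":
            for x in range(length):
                total += (
                    scoring.match
                    if oriented_read[i + x] == ref_seq[j + x]
                    else scoring.mismatch
                )
            i += length
            j += length
        elif op == "I":
            total += scoring.gap_open + length * scoring.gap_extend
            i += length
        elif op == "D":
            total += scoring.gap_open + length * scoring.gap_extend
            j += length
        elif op == "S":
            i += length
        else:
            raise ValueError(f"unknown CIGAR op {op!r}")
    return total
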