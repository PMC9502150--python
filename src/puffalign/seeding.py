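"""Uni-MEM seeding and MEM compaction.

A *uni-MEM* is a maximal exact match between the read and a single unitig:
extension never crosses a unitig boundary, which makes greedy extension safe
(no k-mer inside a uni-MEM can occur in any other unitig, by the uniqueness
of k-mer locations in the compacted graph).  Uni-MEMs are projected onto
every reference occurrence of their unitig and compacted across unitig
junctions — consecutive projections overlapping by exactly k-1 on both read
and reference — into full read-vs-reference MEMs, the anchors for chaining.

The read is scanned once in its given orientation; canonical k-mer lookup
tracks strand, so reverse-complement matches fall out of the same scan.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Tuple

from ._seq import ACGT
from .index import CcdbgIndex, lookup_kmer, project_occurrence

__all__ = [
    "UniMem",
    "Mem",
    "collect_unimems",
    "filter_repetitive",
    "compact_to_mems",
    "DEFAULT_MAX_OCCS",
]

DEFAULT_MAX_OCCS = 1000

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclasses.dataclass(frozen=True)
class UniMem:
    """Maximal exact match between a read interval and a unitig interval."""

    read_pos: int  # 0-based start on the read as given
    uid: int
    unitig_pos: int  # 0-based start of the matched interval on the unitig
    length: int  # >= k
    same_orientation: bool  # read forward strand matches unitig strand
    n_ref_occs: int  # occurrence count of the unitig across references


@dataclasses.dataclass(frozen=True)
class Mem:
    """A uni-MEM projected/compacted onto one (reference, orientation)."""

    ref_id: int
    ref_pos: int  # 0-based start on the reference forward strand
    read_pos: int  # 0-based start on the read as given (forward coordinates)
    length: int
    fw: bool  # read forward strand matches reference forward strand

    @property
    def ref_end(self) -> int:
        return self.ref_pos + self.length

    @property
    def read_end(self) -> int:
        return self.read_pos + self.length


def collect_unimems(read_seq: str, index: CcdbgIndex, skip: int = 1) -> List[UniMem]:
    """Scan the read left to right collecting uni-MEMs.

    At each probe position the k-mer is queried; on a hit the match is
    extended along read and unitig in both directions until a mismatch, the
    read boundary, or the unitig boundary.  The probe then advances to
    ``match_end - k + skip`` — with skip=1 this is the first k-mer start not
    contained in the match, which (with maximal bidirectional extension)
    collects every uni-MEM of the read.
    """
    if skip < 1:
        raise ValueError(f"skip must be >= 1, got {skip}")
    k = index.k
    n = len(read_seq)
    out: List[UniMem] = []
    i = 0
    while i + k <= n:
        window = read_seq[i : i + k]
        bad = next((j for j, c in enumerate(window) if c not in ACGT), None)
        if bad is not None:
            i += bad + 1  # skip every k-mer containing the offending base
            continue
        hit = lookup_kmer(index, window)
        if hit is None:
            i += 1
            continue
        u = index.unitigs[hit.uid]
        useq = u.seq
        off = hit.offset
        if hit.same_orientation:
            room_r = min(n - (i + k), len(useq) - (off + k))
            j = 0
            while j < room_r and read_seq[i + k + j] == useq[off + k + j]:
                j += 1
            room_l = min(i, off)
            l = 0
            while l < room_l and read_seq[i - 1 - l] == useq[off - 1 - l]:
                l += 1
            start, end = i - l, i + k + j
            upos = off - l
        else:
            # read k-mer equals revcomp(unitig[off:off+k]); moving right on
            # the read moves left on the unitig (complemented).
            room_r = min(n - (i + k), off)
            j = 0
            while j < room_r and read_seq[i + k + j] == _COMP1[useq[off - 1 - j]]:
                j += 1
            room_l = min(i, len(useq) - (off + k))
            l = 0
            while l < room_l and read_seq[i - 1 - l] == _COMP1[useq[off + k + l]]:
                l += 1
            start, end = i - l, i + k + j
            upos = off - j
        out.append(
            UniMem(
                read_pos=start,
                uid=hit.uid,
                unitig_pos=upos,
                length=end - start,
                same_orientation=hit.same_orientation,
                n_ref_occs=len(u.occs),
            )
        )
        i = max(end - k + skip, i + 1)
    return out


def filter_repetitive(
    unimems: List[UniMem],
    max_occs: int = DEFAULT_MAX_OCCS,
    allow_high_multimappers: bool = False,
) -> List[UniMem]:
    """Drop uni-MEMs whose unitig occurs more than ``max_occs`` times.

    With ``allow_high_multimappers``, a read end whose seeds were *all*
    dropped gets them back (threshold lifted for that end only), so reads
    from highly repetitive regions remain alignable at extra cost.
    """
    kept = [u for u in unimems if u.n_ref_occs <= max_occs]
    if not kept and unimems and allow_high_multimappers:
        return list(unimems)
    return kept


def compact_to_mems(
    unimems: List[UniMem], index: CcdbgIndex
) -> Dict[Tuple[int, bool], List[Mem]]:
    """Project uni-MEMs to references and merge across unitig junctions.

    Per (reference, orientation), projections on the same diagonal that
    overlap by exactly k-1 on both read and reference (the junction
    signature) are merged; exact duplicates and same-diagonal containments
    (from small branched unitigs) are dropped.  Returned lists are sorted by
    reference position.
    """
    k = index.k
    # (ref_id, fw) -> diagonal key -> list of (ref_pos, read_pos, length)
    groups: Dict[Tuple[int, bool], Dict[int, List[Tuple[int, int, int]]]] = {}
    for um in unimems:
        for ref_id, ref_pos, fw in project_occurrence(
            index, um.uid, um.unitig_pos, um.length, um.same_orientation
        ):
            # fw: ref_pos - read_pos constant along a continuing match;
            # rc: ref_pos + read_pos + length constant (anti-diagonal).
            diag = ref_pos - um.read_pos if fw else ref_pos + um.read_pos + um.length
            groups.setdefault((ref_id, fw), {}).setdefault(diag, []).append(
                (ref_pos, um.read_pos, um.length)
            )

    result: Dict[Tuple[int, bool], List[Mem]] = {}
    for (ref_id, fw), diags in groups.items():
        mems: List[Mem] = []
        for diag, items in diags.items():
            items.sort()
            merged: List[List[int]] = []
            for t, r, L in items:
                if merged:
                    mt, mr, mL = merged[-1]
                    if t >= mt and t + L <= mt + mL:
                        continue  # duplicate or contained on this diagonal
                    if t == mt and t + L > mt + mL:
                        merged[-1] = [t, r, L]  # supersedes a contained interval
                        continue
                    if t == mt + mL - (k - 1):
                        if fw and r == mr + mL - (k - 1):
                            merged[-1][2] = mL + L - (k - 1)
                            continue
                        if not fw and r + L == mr + (k - 1):
                            merged[-1][1] = r
                            merged[-1][2] = mL + L - (k - 1)
                            continue
                merged.append([t, r, L])
            mems.extend(
                Mem(ref_id=ref_id, ref_pos=t, read_pos=r, length=L, fw=fw)
                for t, r, L in merged
            )
        mems.sort(key=lambda m: (m.ref_pos, m.read_pos, m.length))
        result[(ref_id, fw)] = mems
    return result
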