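"""Paired-end joining, orphan recovery, and SAM record finalization.

Two per-end alignments form a *concordant* pair when they sit on the same
reference, on opposite strands in the library's expected order (FR by
default), within the maximum fragment length.  If no concordant pair exists
anywhere, discordant pairs (same reference, geometry violated) may be
reported when allowed.  When one end has no accepted alignment at all —
typically because its seeds fell in a repeat and were filtered — the mate's
placement implies a small reference window in which the missing end is
searched by a fitting alignment (orphan recovery).
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

from ._seq import revcomp
from .alignment import (
    AlignmentResult,
    ScoringScheme,
    accept_alignment,
    fitting_align,
)
from .index import CcdbgIndex
from .io_formats import (
    FLAG_FIRST,
    FLAG_MATE_REVERSE,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_REVERSE,
    FLAG_SECOND,
    FLAG_SECONDARY,
    FLAG_UNMAPPED,
    ReadRecord,
    SamRecord,
)

__all__ = [
    "PairingParams",
    "PairedAlignment",
    "join_ends",
    "recover_orphan",
    "finalize_read",
]


@dataclasses.dataclass(frozen=True)
class PairingParams:
    max_fragment_len: int = 1000
    library_orientation: str = "FR"  # FR, RF or FF
    allow_discordant: bool = False
    max_alignments_per_read: int = 20
    best_strata: bool = False

    def __post_init__(self):
        if self.max_fragment_len <= 0:
            raise ValueError("max_fragment_len must be positive")
        if self.library_orientation not in ("FR", "RF", "FF"):
            raise ValueError("library_orientation must be FR, RF or FF")
        if self.max_alignments_per_read < 1:
            raise ValueError("max_alignments_per_read must be >= 1")


@dataclasses.dataclass
class PairedAlignment:
    left: Optional[AlignmentResult]  # mate 1
    right: Optional[AlignmentResult]  # mate 2
    status: str  # concordant | discordant | orphan-recovered
    pair_score: int
    fragment_len: Optional[int]


def _fragment_len(a: AlignmentResult, b: AlignmentResult) -> int:
    return max(a.ref_end, b.ref_end) - min(a.ref_start, b.ref_start)


def is_concordant(
    a: AlignmentResult, b: AlignmentResult, params: PairingParams
) -> bool:
    """Same reference, expected relative orientation and order, in range."""
    if a.ref_id != b.ref_id:
        return False
    if params.library_orientation == "FF":
        if a.fw != b.fw:
            return False
    else:
        if a.fw == b.fw:
            return False
        fw_end, rc_end = (a, b) if a.fw else (b, a)
        if params.library_orientation == "FR" and fw_end.ref_start > rc_end.ref_start:
            return False
        if params.library_orientation == "RF" and rc_end.ref_start > fw_end.ref_start:
            return False
    return _fragment_len(a, b) <= params.max_fragment_len


def _rank_and_truncate(
    pairs: List[PairedAlignment], params: PairingParams
) -> List[PairedAlignment]:
    def key(p: PairedAlignment):
        anchor = p.left or p.right
        left_pos = min(
            x.ref_start for x in (p.left, p.right) if x is not None
        )
        return (-p.pair_score, anchor.ref_id, left_pos, p.status)

    pairs.sort(key=key)
    if params.best_strata and pairs:
        best = pairs[0].pair_score
        pairs = [p for p in pairs if p.pair_score == best]
    return pairs[: params.max_alignments_per_read]


def join_ends(
    left_alns: Sequence[AlignmentResult],
    right_alns: Sequence[AlignmentResult],
    params: PairingParams,
) -> List[PairedAlignment]:
    """Enumerate concordant pairs; fall back to discordant only when no
    concordant pair exists anywhere and discordant pairs are allowed."""
    concordant: List[PairedAlignment] = []
    for l in left_alns:
        for r in right_alns:
            if is_concordant(l, r, params):
                concordant.append(
                    PairedAlignment(
                        left=l,
                        right=r,
                        status="concordant",
                        pair_score=l.score + r.score,
                        fragment_len=_fragment_len(l, r),
                    )
                )
    if concordant:
        return _rank_and_truncate(concordant, params)
    if not params.allow_discordant:
        return []
    discordant = [
        PairedAlignment(
            left=l,
            right=r,
            status="discordant",
            pair_score=l.score + r.score,
            fragment_len=_fragment_len(l, r) if l.ref_id == r.ref_id else None,
        )
        for l in left_alns
        for r in right_alns
        if l.ref_id == r.ref_id
    ]
    return _rank_and_truncate(discordant, params)


def recover_orphan(
    mapped: AlignmentResult,
    mate_seq: str,
    index: CcdbgIndex,
    scoring: ScoringScheme,
    params: PairingParams,
    min_score_fraction: float = 0.65,
) -> List[AlignmentResult]:
    """Search the mate inside the fragment-length window implied by a mapped
    end, on the strand/side the library orientation dictates."""
    ref = index.ref_seq(mapped.ref_id)
    if params.library_orientation == "FF":
        mate_fw = mapped.fw
    else:
        mate_fw = not mapped.fw
    # which side of the mapped end the mate is expected on
    if params.library_orientation == "RF":
        downstream = not mapped.fw
    elif params.library_orientation == "FF":
        downstream = mapped.fw
    else:  # FR
        downstream = mapped.fw
    if downstream:
        w0 = mapped.ref_start
        w1 = min(len(ref), mapped.ref_start + params.max_fragment_len)
    else:
        w0 = max(0, mapped.ref_end - params.max_fragment_len)
        w1 = mapped.ref_end
    window = ref[w0:w1]
    query = mate_seq if mate_fw else revcomp(mate_seq)
    score, cigar, off, _span = fitting_align(query, window, scoring)
    result = AlignmentResult(
        ref_id=mapped.ref_id,
        ref_start=w0 + off,
        fw=mate_fw,
        score=score,
        cigar=cigar,
        read_end=None,
    )
    if accept_alignment(result, len(mate_seq), scoring, min_score_fraction):
        return [result]
    return []


# --- SAM record construction ------------------------------------------------


def _mapped_record(
    read: ReadRecord,
    aln: AlignmentResult,
    ref_names: Sequence[str],
    *,
    secondary: bool,
    nh: int,
    paired: bool,
    proper: bool,
    mate: Optional[AlignmentResult],
    mate_unmapped: bool,
) -> SamRecord:
    flag = 0
    if paired:
        flag |= FLAG_PAIRED
        flag |= FLAG_FIRST if read.mate == 1 else FLAG_SECOND
        if proper:
            flag |= FLAG_PROPER
        if mate_unmapped:
            flag |= FLAG_MATE_UNMAPPED
        elif mate is not None and not mate.fw:
            flag |= FLAG_MATE_REVERSE
    if not aln.fw:
        flag |= FLAG_REVERSE
    if secondary:
        flag |= FLAG_SECONDARY
    seq = read.seq if aln.fw else revcomp(read.seq)
    qual = read.qual if aln.fw else read.qual[::-1]
    rnext, pnext, tlen = None, -1, 0
    if paired and mate is not None and not mate_unmapped:
        rnext = "=" if mate.ref_id == aln.ref_id else ref_names[mate.ref_id]
        pnext = mate.ref_start
        if mate.ref_id == aln.ref_id:
            lo = min(aln.ref_start, mate.ref_start)
            hi = max(aln.ref_end, mate.ref_end)
            if aln.ref_start < mate.ref_start or (
                aln.ref_start == mate.ref_start and read.mate == 1
            ):
                tlen = hi - lo
            else:
                tlen = -(hi - lo)
    mapq = 0 if secondary else (60 if nh == 1 else 1)
    return SamRecord(
        qname=read.name,
        flag=flag,
        rname=ref_names[aln.ref_id],
        pos=aln.ref_start,
        mapq=mapq,
        cigar=aln.cigar,
        rnext=rnext,
        pnext=pnext,
        tlen=tlen,
        seq=seq,
        qual=qual,
        tags=(("AS", "i", aln.score), ("NH", "i", nh)),
    )


def _unmapped_record(
    read: ReadRecord, *, paired: bool, mate_mapped: Optional[AlignmentResult],
    ref_names: Sequence[str],
) -> SamRecord:
    flag = FLAG_UNMAPPED
    rnext, pnext = None, -1
    pos = 0
    rname = None
    if paired:
        flag |= FLAG_PAIRED
        flag |= FLAG_FIRST if read.mate == 1 else FLAG_SECOND
        if mate_mapped is None:
            flag |= FLAG_MATE_UNMAPPED
        else:
            if not mate_mapped.fw:
                flag |= FLAG_MATE_REVERSE
            # convention: place the unmapped mate at its partner's position
            rname = ref_names[mate_mapped.ref_id]
            pos = mate_mapped.ref_start
            rnext = "="
            pnext = mate_mapped.ref_start
    return SamRecord(
        qname=read.name,
        flag=flag,
        rname=rname,
        pos=pos,
        mapq=0,
        cigar=(),
        rnext=rnext,
        pnext=pnext,
        tlen=0,
        seq=read.seq,
        qual=read.qual,
    )


def finalize_read(
    read1: ReadRecord,
    read2: Optional[ReadRecord],
    pairs: Sequence[PairedAlignment],
    singles: Sequence[AlignmentResult],
    params: PairingParams,
    ref_names: Sequence[str],
) -> List[SamRecord]:
    """Turn ranked pairs (or single-end alignments) into SAM records.

    The top-ranked record is primary, the rest secondary; NH is the number
    of reported alignments.  For paired input with no reportable pair, both
    ends are emitted unmapped unless discordant/single reporting is allowed,
    in which case a mapped end is reported as a single-mapped record.
    """
    records: List[SamRecord] = []
    if read2 is not None:
        if pairs:
            nh = len(pairs)
            for rank, p in enumerate(pairs):
                proper = p.status in ("concordant", "orphan-recovered")
                records.append(
                    _mapped_record(
                        read1, p.left, ref_names,
                        secondary=rank > 0, nh=nh, paired=True, proper=proper,
                        mate=p.right, mate_unmapped=False,
                    )
                )
                records.append(
                    _mapped_record(
                        read2, p.right, ref_names,
                        secondary=rank > 0, nh=nh, paired=True, proper=proper,
                        mate=p.left, mate_unmapped=False,
                    )
                )
            return records
        if params.allow_discordant and singles:
            ranked = sorted(
                singles, key=lambda a: (-a.score, a.ref_id, a.ref_start, not a.fw)
            )[: params.max_alignments_per_read]
            nh = len(ranked)
            end = ranked[0].read_end or 1
            mapped_read = read1 if end == 1 else read2
            other_read = read2 if end == 1 else read1
            for rank, a in enumerate(ranked):
                records.append(
                    _mapped_record(
                        mapped_read, a, ref_names,
                        secondary=rank > 0, nh=nh, paired=True, proper=False,
                        mate=None, mate_unmapped=True,
                    )
                )
            records.append(
                _unmapped_record(
                    other_read, paired=True, mate_mapped=ranked[0], ref_names=ref_names
                )
            )
            return records
        records.append(
            _unmapped_record(read1, paired=True, mate_mapped=None, ref_names=ref_names)
        )
        records.append(
            _unmapped_record(read2, paired=True, mate_mapped=None, ref_names=ref_names)
        )
        return records

    # single-end
    if singles:
        ranked = sorted(
            singles, key=lambda a: (-a.score, a.ref_id, a.ref_start, not a.fw)
        )
        if params.best_strata:
            ranked = [a for a in ranked if a.score == ranked[0].score]
        ranked = ranked[: params.max_alignments_per_read]
        nh = len(ranked)
        for rank, a in enumerate(ranked):
            records.append(
                _mapped_record(
                    read1, a, ref_names,
                    secondary=rank > 0, nh=nh, paired=False, proper=False,
                    mate=None, mate_unmapped=False,
                )
            )
        return records
    records.append(
        _unmapped_record(read1, paired=False, mate_mapped=None, ref_names=ref_names)
    )
    return records
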