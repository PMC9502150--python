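"""FASTA/FASTQ input and SAM v1 output.

Internal coordinates are 0-based half-open everywhere in the package; the
single conversion to SAM's 1-based POS happens inside :func:`write_sam` /
:meth:`SamRecord.to_line`.
"""

from __future__ import annotations

import dataclasses
from typing import IO, Iterable, Iterator, Optional, Sequence, Tuple

from Bio import SeqIO

__all__ = [
    "ReferenceRecord",
    "ReadRecord",
    "SamRecord",
    "FormatError",
    "read_fasta",
    "read_fastq",
    "read_fastq_pairs",
    "write_sam",
    "cigar_to_str",
    "cigar_read_len",
    "cigar_ref_len",
    # SAM flag bits
    "FLAG_PAIRED",
    "FLAG_PROPER",
    "FLAG_UNMAPPED",
    "FLAG_MATE_UNMAPPED",
    "FLAG_REVERSE",
    "FLAG_MATE_REVERSE",
    "FLAG_FIRST",
    "FLAG_SECOND",
    "FLAG_SECONDARY",
]


class FormatError(ValueError):
    """Malformed input file or internally inconsistent output record."""


@dataclasses.dataclass(frozen=True)
class ReferenceRecord:
    """A reference sequence (chromosome, transcript, genome)."""

    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class ReadRecord:
    """A sequencing read; ``mate`` is 1/2 for paired input, ``None`` otherwise."""

    name: str
    seq: str
    qual: str
    mate: Optional[int] = None

    def __post_init__(self):
        if len(self.qual) != len(self.seq):
            raise FormatError(
                f"read {self.name!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


def read_fasta(path) -> list[ReferenceRecord]:
    """Read references from FASTA, uppercased, names truncated at whitespace."""
    records = []
    seen = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        name = rec.id  # SeqIO already truncates at first whitespace
        seq = str(rec.seq).upper()
        if not name:
            raise FormatError(f"{path}: record {i + 1} has an empty header")
        if not seq:
            raise FormatError(f"{path}: record {i + 1} ({name!r}) has an empty sequence")
        if name in seen:
            raise FormatError(f"{path}: duplicate reference name {name!r}")
        seen.add(name)
        records.append(ReferenceRecord(name=name, seq=seq))
    if not records:
        # distinguish an empty/garbage file from a valid empty FASTA is moot here:
        # an index needs at least one reference, caller checks; plain text that is
        # not FASTA yields zero records from SeqIO.
        pass
    return records


def read_fastq(path, mate: Optional[int] = None) -> Iterator[ReadRecord]:
    """Iterate reads from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield ReadRecord(name=rec.id, seq=str(rec.seq).upper(), qual=qual, mate=mate)


def read_fastq_pairs(
    path1, path2=None
) -> Iterator[Tuple[ReadRecord, Optional[ReadRecord]]]:
    """Yield (mate1, mate2) pairs; mate2 is ``None`` for single-end input.

    Paired files must contain the same number of records in matching order.
    """
    if path2 is None:
        for rec in read_fastq(path1):
            yield rec, None
        return
    it1 = read_fastq(path1, mate=1)
    it2 = read_fastq(path2, mate=2)
    sentinel = object()
    idx = 0
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            raise FormatError(
                f"paired FASTQ files differ in length: record index {idx} "
                f"missing from {'first' if r1 is sentinel else 'second'} file"
            )
        yield r1, r2
        idx += 1


# --- SAM output -------------------------------------------------------------

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100

Cigar = Sequence[Tuple[str, int]]


def cigar_to_str(cigar: Cigar) -> str:
    if not cigar:
        return "*"
    return "".join(f"{length}{op}" for op, length in cigar)


def cigar_read_len(cigar: Cigar) -> int:
    """Read bases consumed by a CIGAR (M, I and S consume the read)."""
    return sum(length for op, length in cigar if op in "MIS")


def cigar_ref_len(cigar: Cigar) -> int:
    """Reference bases spanned by a CIGAR (M and D consume the reference)."""
    return sum(length for op, length in cigar if op in "MD")


@dataclasses.dataclass
class SamRecord:
    """One alignment line; ``pos`` is 0-based (converted on serialization)."""

    qname: str
    flag: int
    rname: Optional[str]  # None => unmapped ('*')
    pos: int  # 0-based leftmost; ignored when unmapped
    mapq: int
    cigar: Tuple[Tuple[str, int], ...]
    rnext: Optional[str]
    pnext: int  # 0-based; -1 => unavailable
    tlen: int
    seq: str
    qual: str
    tags: Tuple[Tuple[str, str, object], ...] = ()  # (TAG, TYPE, value)

    def to_line(self) -> str:
        mapped = not (self.flag & FLAG_UNMAPPED)
        fields = [
            self.qname,
            str(self.flag),
            self.rname if self.rname is not None else "*",
            str(self.pos + 1) if mapped else ("0" if self.rname is None else str(self.pos + 1)),
            str(self.mapq),
            cigar_to_str(self.cigar) if mapped else "*",
            self.rnext if self.rnext is not None else "*",
            str(self.pnext + 1) if self.pnext >= 0 else "0",
            str(self.tlen),
            self.seq if self.seq else "*",
            self.qual if self.qual else "*",
        ]
        fields.extend(f"{tag}:{typ}:{val}" for tag, typ, val in self.tags)
        return "\t".join(fields)


def write_sam(
    header_refs: Sequence[Tuple[str, int]],
    alignments: Iterable[SamRecord],
    out: IO[str],
) -> int:
    """Write a SAM file: @HD, one @SQ per reference, then the records.

    Mapped records are checked for internal consistency (reference present in
    the header, CIGAR consumes the read, alignment within the reference).
    Returns the number of alignment lines written.
    """
    lengths = dict(header_refs)
    out.write("@HD\tVN:1.6\tSO:unsorted\n")
    for name, length in header_refs:
        out.write(f"@SQ\tSN:{name}\tLN:{length}\n")
    out.write("@PG\tID:puffalign\tPN:puffalign\n")
    n = 0
    for rec in alignments:
        if not (rec.flag & FLAG_UNMAPPED):
            if rec.rname not in lengths:
                raise FormatError(f"{rec.qname}: unknown reference {rec.rname!r}")
            span = cigar_ref_len(rec.cigar)
            if rec.pos < 0 or rec.pos + span > lengths[rec.rname]:
                raise FormatError(
                    f"{rec.qname}: alignment [{rec.pos}, {rec.pos + span}) outside "
                    f"reference {rec.rname!r} of length {lengths[rec.rname]}"
                )
            if rec.seq and cigar_read_len(rec.cigar) != len(rec.seq):
                raise FormatError(
                    f"{rec.qname}: CIGAR consumes {cigar_read_len(rec.cigar)} bases "
                    f"but SEQ has {len(rec.seq)}"
                )
        out.write(rec.to_line() + "\n")
        n += 1
    return n
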