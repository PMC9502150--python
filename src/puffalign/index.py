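"""Colored compacted de Bruijn graph (ccdBg) index over reference sequences.

The index is the searchable representation of the references: nodes of the
k-mer de Bruijn graph (canonical k-mers, odd k) are compacted into *unitigs* —
maximal non-branching paths that additionally occur identically everywhere
(every junction inside a unitig is traversed by *all* occurrences of both of
its k-mers).  This second condition is the "monochromatic" path restriction:
it guarantees that each unitig occurrence spells the full unitig sequence, so
each reference is an exact tiling of unitig occurrences overlapping by k-1.

Lookup maps a canonical k-mer to its unique (unitig, offset, orientation);
the unitig's occurrence table then "unpacks" a match to every reference
position where it appears.  Space-efficient encodings (perfect hashing,
bit-packed sequence vectors) are deliberately not used: the query contract is
served by an ordinary exact map.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from ._seq import acgt_segments, canonical, revcomp
from .io_formats import ReferenceRecord

__all__ = [
    "Occurrence",
    "Unitig",
    "KmerHit",
    "CcdbgIndex",
    "IndexError_",
    "build_index",
    "lookup_kmer",
    "project_occurrence",
    "serialize_index",
    "load_index",
]

FORMAT_VERSION = 1

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


class IndexError_(ValueError):
    """Invalid index construction input or corrupted serialized index."""


@dataclasses.dataclass(frozen=True)
class Occurrence:
    """One placement of a unitig on a reference forward strand."""

    ref_id: int
    pos: int  # 0-based start on the reference
    fw: bool  # unitig (stored orientation) appears forward on the reference


@dataclasses.dataclass
class Unitig:
    uid: int
    seq: str  # stored in canonical orientation: min(seq, revcomp(seq))
    occs: List[Occurrence]


@dataclasses.dataclass(frozen=True)
class KmerHit:
    """Unique location of a queried k-mer in the unitig set."""

    uid: int
    offset: int  # 0-based offset of the k-mer in the unitig sequence
    same_orientation: bool  # query strand equals stored unitig strand


class CcdbgIndex:
    """k-mer -> unitig lookup plus unitig -> reference occurrence table."""

    def __init__(
        self,
        k: int,
        unitigs: List[Unitig],
        refs: Sequence[ReferenceRecord],
    ):
        self.k = k
        self.unitigs = unitigs
        self.refs = list(refs)
        # canonical k-mer -> (uid, offset, instance_is_canonical)
        self.kmer_map: Dict[str, Tuple[int, int, bool]] = {}
        for u in unitigs:
            seq = u.seq
            for off in range(len(seq) - k + 1):
                inst = seq[off : off + k]
                c = canonical(inst)
                if c in self.kmer_map:
                    raise IndexError_(
                        f"k-mer {c} occurs in two unitig locations; "
                        "compaction invariant violated"
                    )
                self.kmer_map[c] = (u.uid, off, inst == c)

    @property
    def ref_names(self) -> List[str]:
        return [r.name for r in self.refs]

    def ref_seq(self, ref_id: int) -> str:
        return self.refs[ref_id].seq


def build_index(references: Sequence[ReferenceRecord], k: int) -> CcdbgIndex:
    """Compact the de Bruijn graph of all reference k-mers into unitigs.

    k must be odd (canonicalization is otherwise ambiguous for palindromic
    k-mers) and at least one reference must be of length >= k.
    """
    if k % 2 == 0:
        raise IndexError_(f"k must be odd, got {k}")
    if not 3 <= k <= 31:
        raise IndexError_(f"k must be in [3, 31], got {k}")
    if not any(len(r.seq) >= k for r in references):
        raise IndexError_(f"no reference of length >= k={k}")

    # Pass 1: canonical k-mer occurrence counts and strand-adjusted
    # left/right extension-base counts.
    node_count: Dict[str, int] = {}
    right: Dict[str, Dict[str, int]] = {}
    left: Dict[str, Dict[str, int]] = {}

    def _segments():
        for ref_id, rec in enumerate(references):
            for s, e in acgt_segments(rec.seq, k):
                yield ref_id, rec.seq, s, e

    for _ref_id, seq, s, e in _segments():
        for i in range(s, e - k + 1):
            km = seq[i : i + k]
            c = canonical(km)
            o = km == c
            node_count[c] = node_count.get(c, 0) + 1
            if i + k < e:
                nb = seq[i + k]
                d = right if o else left
                key = nb if o else _COMP1[nb]
                d.setdefault(c, {})[key] = d.setdefault(c, {}).get(key, 0) + 1
            if i > s:
                pb = seq[i - 1]
                d = left if o else right
                key = pb if o else _COMP1[pb]
                d.setdefault(c, {})[key] = d.setdefault(c, {}).get(key, 0) + 1

    def _simple_junction(c1: str, o1: bool, c2: str, o2: bool) -> bool:
        # The junction c1->c2 is internal to a unitig iff c1 has exactly one
        # outgoing extension, c2 exactly one incoming, and the edge is taken
        # by every occurrence of both k-mers (count equality).  A unitig may
        # contain each k-mer only once, so equal nodes (hairpin centers of
        # reverse-complement palindromes, homopolymer self-loops) always cut.
        if c1 == c2:
            return False
        out = right.get(c1) if o1 else left.get(c1)
        if out is None or len(out) != 1:
            return False
        inc = left.get(c2) if o2 else right.get(c2)
        if inc is None or len(inc) != 1:
            return False
        n1, n2 = node_count[c1], node_count[c2]
        ecnt = next(iter(out.values()))
        return ecnt == n1 == n2 and next(iter(inc.values())) == ecnt

    # Pass 2: walk every reference segment, cutting at non-simple junctions;
    # each maximal uncut run spells one unitig occurrence.
    occ_table: Dict[str, List[Occurrence]] = {}

    def _emit(ref_id: int, seq: str, kstart: int, kend: int):
        # occurrence spans k-mer starts [kstart, kend] -> bases [kstart, kend+k)
        sub = seq[kstart : kend + k]
        canon = canonical(sub)
        occ_table.setdefault(canon, []).append(
            Occurrence(ref_id=ref_id, pos=kstart, fw=(sub == canon))
        )

    for ref_id, seq, s, e in _segments():
        run_start = s
        prev_c = prev_o = None
        for i in range(s, e - k + 1):
            km = seq[i : i + k]
            c = canonical(km)
            o = km == c
            if prev_c is not None and not _simple_junction(prev_c, prev_o, c, o):
                _emit(ref_id, seq, run_start, i - 1)
                run_start = i
            prev_c, prev_o = c, o
        _emit(ref_id, seq, run_start, e - k)

    # Deterministic uids: sorted canonical unitig sequence order.
    unitigs = []
    for uid, useq in enumerate(sorted(occ_table)):
        occs = sorted(occ_table[useq], key=lambda oc: (oc.ref_id, oc.pos, not oc.fw))
        unitigs.append(Unitig(uid=uid, seq=useq, occs=occs))
    return CcdbgIndex(k=k, unitigs=unitigs, refs=references)


def lookup_kmer(index: CcdbgIndex, kmer: str) -> Optional[KmerHit]:
    """Locate a k-mer; ``None`` when absent or containing non-ACGT letters."""
    if len(kmer) != index.k:
        raise ValueError(f"query length {len(kmer)} != k={index.k}")
    rc = revcomp(kmer)
    if "N" in kmer or not kmer.isalpha():
        return None
    c = kmer if kmer <= rc else rc
    entry = index.kmer_map.get(c)
    if entry is None:
        return None
    uid, off, inst_is_canon = entry
    return KmerHit(uid=uid, offset=off, same_orientation=(kmer == c) == inst_is_canon)


def project_occurrence(
    index: CcdbgIndex, uid: int, offset: int, length: int, fw_query: bool
) -> List[Tuple[int, int, bool]]:
    """Unpack a unitig interval to (ref_id, ref_pos, orientation) tuples.

    ``fw_query`` says whether the query matches the stored unitig strand; the
    returned orientation composes it with each occurrence's strand and is
    True when the query matches the reference forward strand.
    """
    if not 0 <= uid < len(index.unitigs):
        raise IndexError_(f"unknown unitig uid {uid}")
    u = index.unitigs[uid]
    if offset < 0 or offset + length > len(u.seq):
        raise IndexError_(
            f"interval [{offset}, {offset + length}) outside unitig {uid} "
            f"of length {len(u.seq)}"
        )
    out = []
    for occ in u.occs:
        if occ.fw:
            out.append((occ.ref_id, occ.pos + offset, fw_query))
        else:
            out.append(
                (occ.ref_id, occ.pos + len(u.seq) - offset - length, not fw_query)
            )
    return out


# --- serialization ----------------------------------------------------------


def serialize_index(index: CcdbgIndex, directory) -> None:
    """Write the index as plain-text files under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "k": index.k,
        "n_unitigs": len(index.unitigs),
        "n_refs": len(index.refs),
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    with open(d / "refs.fa", "w") as fh:
        for rec in index.refs:
            fh.write(f">{rec.name}\n{rec.seq}\n")
    with open(d / "unitigs.tsv", "w") as fh:
        for u in index.unitigs:
            fh.write(f"{u.uid}\t{u.seq}\n")
    with open(d / "occs.tsv", "w") as fh:
        for u in index.unitigs:
            for occ in u.occs:
                fh.write(f"{u.uid}\t{occ.ref_id}\t{occ.pos}\t{int(occ.fw)}\n")


def load_index(directory) -> CcdbgIndex:
    d = Path(directory)
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise IndexError_(f"{d}: not an index directory (missing meta.json)")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise IndexError_(f"{meta_path}: corrupted metadata: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise IndexError_(
            f"{d}: index format version {meta.get('format_version')} "
            f"unsupported (expected {FORMAT_VERSION})"
        )
    from .io_formats import read_fasta

    refs = read_fasta(d / "refs.fa")
    if len(refs) != meta["n_refs"]:
        raise IndexError_(f"{d}: reference count mismatch")
    unitig_seqs: Dict[int, str] = {}
    for line in (d / "unitigs.tsv").read_text().splitlines():
        uid_s, seq = line.split("\t")
        unitig_seqs[int(uid_s)] = seq
    if len(unitig_seqs) != meta["n_unitigs"]:
        raise IndexError_(f"{d}: unitig count mismatch")
    occs: Dict[int, List[Occurrence]] = {uid: [] for uid in unitig_seqs}
    for line in (d / "occs.tsv").read_text().splitlines():
        uid_s, ref_s, pos_s, fw_s = line.split("\t")
        occs[int(uid_s)].append(
            Occurrence(ref_id=int(ref_s), pos=int(pos_s), fw=bool(int(fw_s)))
        )
    unitigs = [
        Unitig(uid=uid, seq=unitig_seqs[uid], occs=occs[uid])
        for uid in sorted(unitig_seqs)
    ]
    if any(not u.occs for u in unitigs):
        raise IndexError_(f"{d}: unitig with empty occurrence list")
    return CcdbgIndex(k=meta["k"], unitigs=unitigs, refs=refs)
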