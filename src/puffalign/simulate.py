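"""Synthetic references and reads with known truth.

The generator emulates a paired-end short-read DNA sequencing experiment at
desk scale: i.i.d. uniform reference sequence (optionally with a planted
repeat, or as a set of diverged copies to mimic highly similar genomes),
fragments of clamped-normal length in FR orientation, per-base substitution
errors and short (1-3 bp) indels.  Everything is deterministic under an
explicit seed, and a truth table records where each read came from so
alignments can be scored against it.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._seq import revcomp
from .io_formats import ReadRecord, ReferenceRecord

__all__ = [
    "TruthRecord",
    "RepeatSpec",
    "simulate_genome",
    "simulate_reads",
    "write_fastq",
    "write_truth",
    "read_truth",
    "evaluate_against_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass(frozen=True)
class RepeatSpec:
    """Plant ``count`` copies of one random ``length``-bp substring,
    regularly spaced with at least ``spacer`` unique bases in between."""

    length: int
    count: int
    spacer: int = 300


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    name: str
    mate: int  # 1 or 2
    ref_id: int
    pos: int  # 0-based start of the error-free source interval
    fw: bool
    n_sub: int
    n_ins: int
    n_del: int


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def simulate_genome(
    length: int,
    seed: int,
    repeat_spec: Optional[RepeatSpec] = None,
    n_copies: int = 1,
    copy_mutation_rate: float = 0.0,
    name_prefix: str = "ref",
) -> List[ReferenceRecord]:
    """Generate one uniform-random reference, optionally with a planted
    repeat, optionally as ``n_copies`` diverged copies (highly similar
    genomes; each copy mutated at ``copy_mutation_rate`` per base)."""
    rng = np.random.default_rng(seed)
    if repeat_spec is None:
        base = _random_seq(rng, length)
    else:
        unit = _random_seq(rng, repeat_spec.length)
        period = repeat_spec.length + repeat_spec.spacer
        need = repeat_spec.count * period + repeat_spec.spacer
        total = max(length, need)
        arr = np.frombuffer(_random_seq(rng, total).encode(), dtype=np.uint8).copy()
        unit_arr = np.frombuffer(unit.encode(), dtype=np.uint8)
        for i in range(repeat_spec.count):
            start = repeat_spec.spacer + i * period
            arr[start : start + repeat_spec.length] = unit_arr
        base = arr.tobytes().decode("ascii")
    records = []
    for c in range(n_copies):
        seq = base
        if c > 0 and copy_mutation_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hits = np.nonzero(rng.random(len(arr)) < copy_mutation_rate)[0]
            for p in hits:
                choices = _BASES[_BASES != arr[p]]
                arr[p] = rng.choice(choices)
            seq = arr.tobytes().decode("ascii")
        name = name_prefix if n_copies == 1 else f"{name_prefix}{c}"
        records.append(ReferenceRecord(name=name, seq=seq))
    return records


def _apply_errors(
    seq: str, rng: np.random.Generator, sub_rate: float, indel_rate: float
) -> Tuple[str, int, int, int]:
    n_sub = n_ins = n_del = 0
    out = []
    i = 0
    n = len(seq)
    while i < n:
        c = seq[i]
        if indel_rate > 0 and rng.random() < indel_rate:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion into the read
                ins = rng.choice(_BASES, size=length).tobytes().decode("ascii")
                out.append(ins)
                n_ins += 1
                out.append(c)
                i += 1
            else:  # deletion from the read
                n_del += 1
                i += length
            continue
        if sub_rate > 0 and rng.random() < sub_rate:
            alt = chr(rng.choice(_BASES[_BASES != ord(c)]))
            out.append(alt)
            n_sub += 1
        else:
            out.append(c)
        i += 1
    return "".join(out), n_sub, n_ins, n_del


def simulate_reads(
    refs: Sequence[ReferenceRecord],
    n_pairs: int,
    read_len: int,
    frag_mean: float,
    frag_sd: float,
    sub_rate: float,
    indel_rate: float,
    seed: int,
) -> Tuple[List[ReadRecord], List[ReadRecord], List[TruthRecord]]:
    """Simulate FR paired-end reads; returns (mates1, mates2, truth).

    Fragment lengths are normal(frag_mean, frag_sd) clamped to
    [read_len, 2*frag_mean] so pairs stay joinable under the default
    maximum fragment length.  Errors are applied to the read copies only;
    truth positions refer to the error-free source interval.
    """
    rng = np.random.default_rng(seed)
    lengths = np.array([len(r.seq) for r in refs], dtype=float)
    weights = lengths / lengths.sum()
    reads1: List[ReadRecord] = []
    reads2: List[ReadRecord] = []
    truth: List[TruthRecord] = []
    for i in range(n_pairs):
        ref_id = int(rng.choice(len(refs), p=weights))
        ref_seq = refs[ref_id].seq
        frag = int(round(rng.normal(frag_mean, frag_sd)))
        frag = max(read_len, min(frag, int(2 * frag_mean), len(ref_seq)))
        start = int(rng.integers(0, len(ref_seq) - frag + 1))
        fragment = ref_seq[start : start + frag]
        name = f"sim{i}"
        m1_src = fragment[:read_len]
        m2_src = revcomp(fragment[-read_len:])
        m1, s1, i1, d1 = _apply_errors(m1_src, rng, sub_rate, indel_rate)
        m2, s2, i2, d2 = _apply_errors(m2_src, rng, sub_rate, indel_rate)
        reads1.append(ReadRecord(name=name, seq=m1, qual="I" * len(m1), mate=1))
        reads2.append(ReadRecord(name=name, seq=m2, qual="I" * len(m2), mate=2))
        truth.append(TruthRecord(name, 1, ref_id, start, True, s1, i1, d1))
        truth.append(
            TruthRecord(name, 2, ref_id, start + frag - read_len, False, s2, i2, d2)
        )
    return reads1, reads2, truth


def write_fastq(reads: Sequence[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


def write_truth(truth: Sequence[TruthRecord], path, seed: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        fh.write("#name\tmate\tref_id\tpos\tstrand\tn_sub\tn_ins\tn_del")
        fh.write(f"\t#seed={seed}\n" if seed is not None else "\n")
        for t in truth:
            fh.write(
                f"{t.name}\t{t.mate}\t{t.ref_id}\t{t.pos}\t"
                f"{'+' if t.fw else '-'}\t{t.n_sub}\t{t.n_ins}\t{t.n_del}\n"
            )


def read_truth(path) -> List[TruthRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    f[0], int(f[1]), int(f[2]), int(f[3]), f[4] == "+",
                    int(f[5]), int(f[6]), int(f[7]),
                )
            )
    return out


def evaluate_against_truth(
    sam_path, truth: Sequence[TruthRecord], ref_names: Sequence[str],
    tolerance_bp: int = 5,
) -> dict:
    """Score a SAM file against simulation truth.

    ``accuracy``: fraction of all read ends whose primary alignment matches
    the true (reference, orientation) with |pos - true pos| <= tolerance_bp.
    ``concordant_rate``: fraction of pairs whose primary records carry the
    proper-pair flag.  ``pair_accuracy``: fraction of pairs concordant with
    *both* ends placed within tolerance.
    """
    import pysam

    want = {(t.name, t.mate): t for t in truth}
    names = list(ref_names)
    good = set()
    proper = set()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            mate = 2 if (rec.is_paired and rec.is_read2) else 1
            t = want.get((rec.query_name, mate))
            if t is None:
                continue
            if rec.is_paired and rec.is_proper_pair:
                proper.add((rec.query_name, mate))
            if (
                names[t.ref_id] == rec.reference_name
                and t.fw == (not rec.is_reverse)
                and abs(rec.reference_start - t.pos) <= tolerance_bp
            ):
                good.add((rec.query_name, mate))
    n_ends = len(want)
    pair_names = {t.name for t in truth}
    n_pairs = len(pair_names)
    conc_pairs = {
        n for n in pair_names if (n, 1) in proper and (n, 2) in proper
    }
    good_pairs = {
        n for n in conc_pairs if (n, 1) in good and (n, 2) in good
    }
    return {
        "accuracy": len(good) / n_ends if n_ends else 0.0,
        "concordant_rate": len(conc_pairs) / n_pairs if n_pairs else 0.0,
        "pair_accuracy": len(good_pairs) / n_pairs if n_pairs else 0.0,
    }
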