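"""Low-level nucleotide string helpers shared across the package.

All coordinates in the package are 0-based, half-open; sequences are plain
Python ``str`` over the DNA alphabet (upper case).  Only ``A C G T`` are ever
indexed; ``N`` (or any other letter) is retained in sequences but treated as
a hard break for k-mer purposes.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ACGT = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement.

    For odd k a k-mer can never equal its own reverse complement, so the
    canonical form plus an orientation bit losslessly encodes the k-mer.
    """
    rc = kmer.translate(_COMP)[::-1]
    return kmer if kmer <= rc else rc


def is_acgt(seq: str) -> bool:
    return not (set(seq) - ACGT)


def acgt_segments(seq: str, min_len: int):
    """Yield (start, end) of maximal runs of ACGT characters of length >= min_len.

    K-mers are only ever formed inside such runs, so k-mers spanning an ``N``
    are never created.
    """
    start = None
    for i, c in enumerate(seq):
        if c in ACGT:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_len:
                yield start, i
            start = None
    if start is not None and len(seq) - start >= min_len:
        yield start, len(seq)
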