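"""Colinear chaining of MEM anchors.

A chain is an ordered subset of the MEMs between one read end and one
(reference, orientation), strictly increasing in both read and reference
coordinates, scored by the number of newly covered read bases minus a gap
penalty.  The dynamic program follows the minimap2 anchor-chaining recursion,
adapted to interval anchors: for anchor i with predecessor j,

    f(i) = max( w_i,  max_j  f(j) + min(w_i, w_i + d_r, w_i + d_t) - beta )

where d_r and d_t are the (possibly negative = overlapping) read/reference
gaps between the end of j and the start of i, and the penalty depends only on
the gap *difference* g = |d_r - d_t|:

    beta(g) = +inf                                   if g > C
            = 0                                      if g == 0
            = 0.01 * avg_seed_len * g + 0.5 * log2(g)  otherwise.

Anchors whose gap difference exceeds the maximum allowed gap C, or that
overlap the predecessor by more than k-1 on the reference, are never chained.
Reverse-complement matches are chained in the coordinates of the reverse-
complemented read so that read and reference both increase along a chain.

Two post-filters keep only promising chains: a *valid* chain scores more than
consensus_fraction times the read length, and per reference only chains
within ``subopt_fraction`` of that reference's best score survive.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Sequence

from .seeding import Mem

__all__ = ["ChainingParams", "Chain", "gap_penalty_beta", "chain_mems", "select_valid_chains"]

INF = math.inf


@dataclasses.dataclass(frozen=True)
class ChainingParams:
    """Knobs of the chaining DP and its filters.

    ``h`` is the predecessor-search heuristic: after the first extendable
    predecessor of an anchor is found, at most ``h`` further candidates are
    evaluated (``None`` disables the heuristic).  ``avg_seed_len`` enters the
    gap-cost coefficient and is conventionally set to k.
    """

    max_allowed_gap: int = 100  # C
    h: Optional[int] = 2
    avg_seed_len: int = 31
    consensus_fraction: float = 0.65
    subopt_fraction: float = 0.90

    def __post_init__(self):
        if self.max_allowed_gap <= 0:
            raise ValueError("max_allowed_gap must be positive")
        if not 0 < self.consensus_fraction <= 1:
            raise ValueError("consensus_fraction must be in (0, 1]")
        if not 0 < self.subopt_fraction <= 1:
            raise ValueError("subopt_fraction must be in (0, 1]")
        if self.h is not None and self.h < 1:
            raise ValueError("h must be >= 1 (or None for exhaustive search)")


@dataclasses.dataclass
class Chain:
    """A scored colinear sequence of MEMs on one (reference, orientation)."""

    mems: List[Mem]  # in chain order (increasing oriented read/ref coords)
    score: float
    ref_id: int
    fw: bool
    read_end: Optional[int] = None  # 1 or 2 for paired input

    @property
    def ref_start(self) -> int:
        return min(m.ref_pos for m in self.mems)

    @property
    def ref_span_end(self) -> int:
        return max(m.ref_end for m in self.mems)


def _beta(g: int, params: ChainingParams) -> float:
    if g > params.max_allowed_gap:
        return INF
    if g == 0:
        return 0.0
    return 0.01 * params.avg_seed_len * g + 0.5 * math.log2(g)


def gap_penalty_beta(d_r: int, d_t: int, params: ChainingParams) -> float:
    """Gap penalty between consecutive chained MEMs (non-negative gaps)."""
    if d_r < 0 or d_t < 0:
        raise ValueError(f"gaps must be non-negative, got d_r={d_r}, d_t={d_t}")
    return _beta(abs(d_r - d_t), params)


def chain_mems(
    mems: Sequence[Mem],
    read_len: int,
    params: ChainingParams,
    k: Optional[int] = None,
) -> List[Chain]:
    """Run the chaining DP over the MEMs of one (reference, orientation).

    Returns anchor-disjoint chains via best-first backtracking, sorted by
    score descending.  ``k`` bounds the allowed reference overlap between
    chained anchors (defaults to ``avg_seed_len``).
    """
    if not mems:
        return []
    if k is None:
        k = params.avg_seed_len
    ref_id, fw = mems[0].ref_id, mems[0].fw
    if any(m.ref_id != ref_id or m.fw != fw for m in mems):
        raise ValueError("chain_mems expects MEMs of a single (reference, orientation)")

    # oriented read coordinates: on the reverse-complemented read for rc
    def oread(m: Mem) -> int:
        return m.read_pos if fw else read_len - m.read_pos - m.length

    anchors = sorted(mems, key=lambda m: (m.ref_end, m.ref_pos, oread(m)))
    n = len(anchors)
    starts_t = [m.ref_pos for m in anchors]
    ends_t = [m.ref_end for m in anchors]
    starts_r = [oread(m) for m in anchors]
    ends_r = [oread(m) + m.length for m in anchors]
    w = [m.length for m in anchors]

    f = [float(x) for x in w]
    parent = [-1] * n
    budget = None if params.h is None else 1 + params.h
    for i in range(n):
        examined = 0
        for j in range(i - 1, -1, -1):
            if starts_t[j] >= starts_t[i] or starts_r[j] >= starts_r[i]:
                continue
            d_t = starts_t[i] - ends_t[j]
            d_r = starts_r[i] - ends_r[j]
            if d_t < -(k - 1):  # reference overlap beyond the junction signature
                continue
            g = abs(d_r - d_t)
            if g > params.max_allowed_gap:
                continue
            examined += 1
            gain = min(w[i], w[i] + d_r, w[i] + d_t)
            cand = f[j] + gain - _beta(g, params)
            if cand > f[i]:
                f[i] = cand
                parent[i] = j
            if budget is not None and examined >= budget:
                break

    order = sorted(range(n), key=lambda i: (-f[i], starts_t[i], starts_r[i]))
    used = [False] * n
    chains: List[Chain] = []
    for i in order:
        if used[i]:
            continue
        path = []
        j = i
        shared = False
        while j != -1:
            if used[j]:
                shared = True
                break
            path.append(j)
            j = parent[j]
        if shared:
            continue  # a prefix of an already-reported, higher-scoring chain
        for j in path:
            used[j] = True
        chains.append(
            Chain(
                mems=[anchors[j] for j in reversed(path)],
                score=f[i],
                ref_id=ref_id,
                fw=fw,
            )
        )
    return chains


def select_valid_chains(
    chains: Sequence[Chain], read_len: int, params: ChainingParams
) -> List[Chain]:
    """Apply the validity and per-reference sub-optimality filters.

    A chain is valid when its score exceeds consensus_fraction * read length;
    among valid chains, each reference keeps those within subopt_fraction of
    its best (boundary inclusive).  Output is sorted by score descending with
    deterministic tie-breaking.
    """
    valid = [c for c in chains if c.score > params.consensus_fraction * read_len]
    best_per_ref: dict[int, float] = {}
    for c in valid:
        best_per_ref[c.ref_id] = max(best_per_ref.get(c.ref_id, -INF), c.score)
    kept = [
        c
        for c in valid
        if c.score >= params.subopt_fraction * best_per_ref[c.ref_id]
    ]
    kept.sort(key=lambda c: (-c.score, c.ref_id, c.ref_start, not c.fw))
    return kept
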