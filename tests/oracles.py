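"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives an expected result by a different algorithm than the
implementation under test: naive quadratic DP for alignment scores, k-mer
dictionary + diagonal extension for maximal exact matches, oriented-digraph
walking + string search for de Bruijn compaction, and exhaustive subset
enumeration for chaining.
"""

from __future__ import annotations

import math
from itertools import combinations

COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


# --- alignment --------------------------------------------------------------


def naive_global_score(q: str, t: str, match, mismatch, gap_open, gap_extend) -> int:
    """Plain Gotoh affine-gap global alignment score, no traceback."""
    NEG = -(10**9)
    m, n = len(q), len(t)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0
    for j in range(1, n + 1):
        E[0][j] = max(E[0][j - 1] + gap_extend, H[0][j - 1] + gap_open + gap_extend)
        H[0][j] = E[0][j]
    for i in range(1, m + 1):
        F[i][0] = max(F[i - 1][0] + gap_extend, H[i - 1][0] + gap_open + gap_extend)
        H[i][0] = F[i][0]
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open + gap_extend)
            s = match if q[i - 1] == t[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return H[m][n]


def naive_extension_score(tail, window, match, mismatch, gap_open, gap_extend, side):
    """Best end-to-end-on-the-tail score over all reference end positions."""
    if not tail:
        return 0
    if side == "right":
        cands = [window[:j] for j in range(len(window) + 1)]
    else:
        cands = [window[j:] for j in range(len(window) + 1)]
    return max(
        naive_global_score(tail, c, match, mismatch, gap_open, gap_extend)
        for c in cands
    )


def naive_fitting_score(read, window, match, mismatch, gap_open, gap_extend):
    """Best placement of read inside window (both window ends free).

    Separately written pure-Python Gotoh DP with a free first and last
    reference row, used where the prefix-loop oracle would be too slow.
    """
    NEG = -(10**9)
    m, n = len(read), len(window)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        H[0][j] = 0  # free reference prefix
    for i in range(1, m + 1):
        F[i][0] = max(F[i - 1][0] + gap_extend, H[i - 1][0] + gap_open + gap_extend)
        H[i][0] = F[i][0]
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open + gap_extend)
            s = match if read[i - 1] == window[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return max(H[m])  # free reference suffix


# --- maximal exact matches --------------------------------------------------


def brute_mems(read: str, ref: str, k: int):
    """All maximal exact matches of length >= k between read and ref, both
    orientations.  Returns {(fw): set of (ref_pos, read_pos_fwd_coords, len)}.
    """

    def _one(q, t):
        pos = {}
        for j in range(len(t) - k + 1):
            pos.setdefault(t[j : j + k], []).append(j)
        found = set()
        for i in range(len(q) - k + 1):
            for j in pos.get(q[i : i + k], ()):
                ii, jj = i, j
                while ii > 0 and jj > 0 and q[ii - 1] == t[jj - 1]:
                    ii -= 1
                    jj -= 1
                ei, ej = i + k, j + k
                while ei < len(q) and ej < len(t) and q[ei] == t[ej]:
                    ei += 1
                    ej += 1
                found.add((jj, ii, ei - ii))
        return found

    fw = _one(read, ref)
    rcm = {
        (j, len(read) - (i + L), L) for (j, i, L) in _one(rc(read), ref)
    }
    return {True: fw, False: rcm}


# --- chaining ---------------------------------------------------------------


def oracle_beta(g: int, C: int, avg_seed_len: int) -> float:
    if g > C:
        return math.inf
    if g == 0:
        return 0.0
    return 0.01 * avg_seed_len * g + 0.5 * math.log2(g)


def brute_best_chain_score(anchors, C, avg_seed_len, k) -> float:
    """Exhaustive maximum over all valid colinear subsets of anchors.

    ``anchors``: list of (read_start, ref_start, length).  A subset is valid
    when, ordered by (ref_end, ref_start, read_start), consecutive anchors
    strictly increase in both start coordinates, overlap the reference by at
    most k-1, and have gap difference at most C.  Score: first anchor length
    plus, per transition, min(w, w+d_r, w+d_t) - beta(|d_r-d_t|).
    """
    order = sorted(anchors, key=lambda a: (a[1] + a[2], a[1], a[0]))
    best = -math.inf
    n = len(order)
    for size in range(1, n + 1):
        for combo in combinations(range(n), size):
            score = float(order[combo[0]][2])
            ok = True
            for prev, cur in zip(combo, combo[1:]):
                r1, t1, w1 = order[prev]
                r2, t2, w2 = order[cur]
                if t2 <= t1 or r2 <= r1:
                    ok = False
                    break
                d_t = t2 - (t1 + w1)
                d_r = r2 - (r1 + w1)
                if d_t < -(k - 1):
                    ok = False
                    break
                g = abs(d_r - d_t)
                if g > C:
                    ok = False
                    break
                score += min(w2, w2 + d_r, w2 + d_t) - oracle_beta(g, C, avg_seed_len)
            if ok:
                best = max(best, score)
    return best


# --- de Bruijn compaction ---------------------------------------------------


def brute_compact_dbg(ref_seqs, k):
    """Compact the dBg by walking an explicit oriented-k-mer digraph.

    Returns {canonical_unitig_seq: sorted list of (ref_id, pos, fw)}.
    Conditions for extending a path x -> y: unique successor of x, unique
    predecessor of y, edge multiplicity equals both node multiplicities, and
    canonical(y) != canonical(x) (a unitig holds each k-mer once).
    """
    node = {}
    edge = {}
    streams = []
    for s in ref_seqs:
        streams.append(s)
        streams.append(rc(s))
    for s in streams:
        for i in range(len(s) - k + 1):
            x = s[i : i + k]
            node[x] = node.get(x, 0) + 1
            if i + k < len(s):
                e = s[i : i + k + 1]
                edge[e] = edge.get(e, 0) + 1

    def succs(x):
        return [x[1:] + b for b in "ACGT" if (x + b) in edge]

    def preds(y):
        return [b + y[:-1] for b in "ACGT" if (b + y) in edge]

    def canon(x):
        y = rc(x)
        return x if x <= y else y

    def ncount(x):
        # both-strand scan counts each canonical occurrence once as x and
        # once as rc(x); node[x] is already the canonical multiplicity
        return node[x]

    def extendable(x):
        nxt = succs(x)
        if len(nxt) != 1:
            return None
        y = nxt[0]
        if canon(y) == canon(x):
            return None
        if len(preds(y)) != 1:
            return None
        if edge[x + y[-1]] != ncount(x) or ncount(x) != ncount(y):
            return None
        return y

    def back_extendable(y):
        prv = preds(y)
        if len(prv) != 1:
            return None
        x = prv[0]
        if extendable(x) != y:
            return None
        return x

    unitigs = set()
    for start in list(node):
        if back_extendable(start) is not None:
            continue  # not a path start
        spelled = start
        x = start
        seen = {canon(start)}
        while True:
            y = extendable(x)
            if y is None or canon(y) in seen:
                break
            spelled += y[-1]
            seen.add(canon(y))
            x = y
        unitigs.add(canon(spelled))

    occs = {}
    for u in unitigs:
        hits = []
        for ref_id, s in enumerate(ref_seqs):
            for probe, fw in ((u, True), (rc(u), False)):
                start = 0
                while True:
                    p = s.find(probe, start)
                    if p < 0:
                        break
                    hits.append((ref_id, p, fw))
                    start = p + 1
        occs[u] = sorted(hits)
    return occs
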