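"""Affine-gap alignment DP kernel (numba-compiled).

One Gotoh-style three-matrix DP serves all alignment modes used by the
aligner, selected by flags:

* global:            no free ends (end-to-end on both sequences)
* extension (right): ``free_t_end``  — best alignment to a *prefix* of t
* fitting:           ``free_t_start`` and ``free_t_end`` — best placement of
                     q anywhere inside t
* soft-clip variants: ``free_q_end`` additionally leaves the query suffix
                     unaligned (the caller emits an S run).

The query is otherwise always consumed end-to-end.  Gap of length L costs
``gap_open + L * gap_extend``.  Traceback ties are broken deterministically,
match/mismatch over deletion over insertion.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)

# op codes in the traceback output
OP_M, OP_I, OP_D = 0, 1, 2


@njit(cache=True)
def affine_dp(q, t, match, mismatch, gap_open, gap_extend,
              free_t_start, free_t_end, free_q_end):  # pragma: no cover - numba
    m = q.shape[0]
    n = t.shape[0]
    H = np.empty((m + 1, n + 1), np.int64)
    E = np.empty((m + 1, n + 1), np.int64)  # ending in D (ref consumed)
    F = np.empty((m + 1, n + 1), np.int64)  # ending in I (read consumed)
    pH = np.zeros((m + 1, n + 1), np.uint8)  # 0 diag, 1 from E, 2 from F
    pE = np.zeros((m + 1, n + 1), np.uint8)  # 0 opened from H, 1 extended
    pF = np.zeros((m + 1, n + 1), np.uint8)

    H[0, 0] = 0
    E[0, 0] = NEG
    F[0, 0] = NEG
    for j in range(1, n + 1):
        open_sc = H[0, j - 1] + gap_open + gap_extend
        ext_sc = E[0, j - 1] + gap_extend
        if ext_sc >= open_sc:
            E[0, j] = ext_sc
            pE[0, j] = 1
        else:
            E[0, j] = open_sc
            pE[0, j] = 0
        H[0, j] = 0 if free_t_start else E[0, j]
        pH[0, j] = 1
        F[0, j] = NEG
    for i in range(1, m + 1):
        open_sc = H[i - 1, 0] + gap_open + gap_extend
        ext_sc = F[i - 1, 0] + gap_extend
        if ext_sc >= open_sc:
            F[i, 0] = ext_sc
            pF[i, 0] = 1
        else:
            F[i, 0] = open_sc
            pF[i, 0] = 0
        H[i, 0] = F[i, 0]
        pH[i, 0] = 2
        E[i, 0] = NEG

    for i in range(1, m + 1):
        qc = q[i - 1]
        for j in range(1, n + 1):
            open_sc = H[i, j - 1] + gap_open + gap_extend
            ext_sc = E[i, j - 1] + gap_extend
            if ext_sc >= open_sc:
                E[i, j] = ext_sc
                pE[i, j] = 1
            else:
                E[i, j] = open_sc
                pE[i, j] = 0
            open_sc = H[i - 1, j] + gap_open + gap_extend
            ext_sc = F[i - 1, j] + gap_extend
            if ext_sc >= open_sc:
                F[i, j] = ext_sc
                pF[i, j] = 1
            else:
                F[i, j] = open_sc
                pF[i, j] = 0
            diag = H[i - 1, j - 1] + (match if qc == t[j - 1] else mismatch)
            if diag >= E[i, j] and diag >= F[i, j]:
                H[i, j] = diag
                pH[i, j] = 0
            elif E[i, j] >= F[i, j]:
                H[i, j] = E[i, j]
                pH[i, j] = 1
            else:
                H[i, j] = F[i, j]
                pH[i, j] = 2

    # pick the end cell
    i_end = m
    j_end = n
    if free_q_end:
        best = NEG
        for i in range(m, -1, -1):  # prefer consuming more of the read
            jhi = n if free_t_end else n
            for j in range(0, jhi + 1):
                if H[i, j] > best:
                    best = H[i, j]
                    i_end = i
                    j_end = j
    elif free_t_end:
        best = NEG
        for j in range(0, n + 1):
            if H[i_end, j] > best:
                best = H[i_end, j]
                j_end = j
    score = H[i_end, j_end]

    ops = np.empty(m + n + 2, np.uint8)
    nops = 0
    i = i_end
    j = j_end
    state = 0
    while True:
        if state == 0:
            if i == 0 and j == 0:
                break
            if i == 0 and free_t_start:
                break
            p = pH[i, j]
            if p == 0:
                ops[nops] = OP_M
                nops += 1
                i -= 1
                j -= 1
            elif p == 1:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[nops] = OP_D
            nops += 1
            if pE[i, j] == 0:
                state = 0
            j -= 1
        else:
            ops[nops] = OP_I
            nops += 1
            if pF[i, j] == 0:
                state = 0
            i -= 1
    return score, i_end, j, j_end, ops, nops
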