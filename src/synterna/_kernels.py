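"""Numba-compiled inner loops for local alignment and energy folding.

Kept free of Python objects: plain uint8/int32/float64 arrays in, tuples out.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# traceback states
_DIAG, _LEFT, _UP = 1, 2, 3

INF = 1e9


@njit(cache=True)
def sw_fill(q, s, match, mismatch, gap_open, gap_extend):
    """Affine-gap Smith-Waterman over code arrays (0..3, 4 = N always-mismatch).

    A gap of length L costs gap_open + L * gap_extend.
    Returns (H, E, F, best_score, best_i, best_j) with 1-based matrix indices.
    """
    n = q.shape[0]
    m = s.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), -10**9, np.int32)
    F = np.full((n + 1, m + 1), -10**9, np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            e = H[i, j - 1] - gap_open - gap_extend
            if E[i, j - 1] - gap_extend > e:
                e = E[i, j - 1] - gap_extend
            f = H[i - 1, j] - gap_open - gap_extend
            if F[i - 1, j] - gap_extend > f:
                f = F[i - 1, j] - gap_extend
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def sw_traceback(q, s, H, E, F, bi, bj, match, mismatch, gap_open, gap_extend):
    """Walk back from (bi, bj); preference order diag > left-gap > up-gap.

    Returns (qstart, sstart, n_ident, aln_len, n_mismatch, n_gapopen) with
    0-based starts; (bi, bj) are the exclusive 1-based ends.
    """
    i, j = bi, bj
    n_ident = 0
    aln_len = 0
    n_mm = 0
    n_go = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        qi = q[i - 1]
        sub = match if (qi == s[j - 1] and qi < 4) else mismatch
        h = H[i, j]
        if h == H[i - 1, j - 1] + sub:
            if qi == s[j - 1] and qi < 4:
                n_ident += 1
            else:
                n_mm += 1
            aln_len += 1
            i -= 1
            j -= 1
        elif h == E[i, j]:
            # gap in the query (consumes subject); walk the E chain
            n_go += 1
            while True:
                aln_len += 1
                if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                    j -= 1
                    break
                j -= 1
        elif h == F[i, j]:
            n_go += 1
            while True:
                aln_len += 1
                if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                    i -= 1
                    break
                i -= 1
        else:  # pragma: no cover - defensive
            break
    return i, j, n_ident, aln_len, n_mm, n_go


@njit(cache=True)
def zuker_fill(seq, can_pair, stackE, hairpinE, interiorE,
               ml_close, ml_branch, ml_unpaired, min_loop, max_interior):
    """Fill V / WM / WM2 tables of the reduced nearest-neighbour model.

    seq: codes 0..3 (A,C,G,U); can_pair: 4x4 bool; stackE: 4x4x4x4 energies of
    stacking (i,j) on (i+1,j-1); hairpinE/interiorE: loop-size penalty lookups.
    """
    n = seq.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    WM2 = np.full((n, n), INF)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            # --- V[i,j]: best structure closed by pair (i,j)
            if can_pair[seq[i], seq[j]] and span > min_loop:
                best = hairpinE[span - 1]  # hairpin of size j-i-1
                # stack on (i+1, j-1)
                if span - 2 > min_loop and can_pair[seq[i + 1], seq[j - 1]]:
                    v = stackE[seq[i], seq[j], seq[i + 1], seq[j - 1]] + V[i + 1, j - 1]
                    if v < best:
                        best = v
                # bulge / interior loops (size >= 1, capped)
                for k in range(i + 1, j):
                    n1 = k - i - 1
                    if n1 > max_interior:
                        break
                    for l in range(j - 1, k, -1):
                        n2 = j - l - 1
                        sz = n1 + n2
                        if sz > max_interior:
                            break
                        if sz == 0:
                            continue
                        if can_pair[seq[k], seq[l]] and V[k, l] < INF / 2:
                            v = interiorE[sz] + V[k, l]
                            if v < best:
                                best = v
                # multiloop closed by (i,j)
                if j - i > 4 and WM2[i + 1, j - 1] < INF / 2:
                    v = ml_close + ml_branch + WM2[i + 1, j - 1]
                    if v < best:
                        best = v
                V[i, j] = best
            # --- WM2[i,j]: >= 2 branches
            b2 = INF
            for k in range(i + 1, j):
                if WM[i, k] < INF / 2 and WM[k + 1, j] < INF / 2:
                    v = WM[i, k] + WM[k + 1, j]
                    if v < b2:
                        b2 = v
            WM2[i, j] = b2
            # --- WM[i,j]: >= 1 branch, unpaired bases cost ml_unpaired
            b = INF
            if V[i, j] < INF / 2:
                b = V[i, j] + ml_branch
            if WM[i + 1, j] + ml_unpaired < b:
                b = WM[i + 1, j] + ml_unpaired
            if WM[i, j - 1] + ml_unpaired < b:
                b = WM[i, j - 1] + ml_unpaired
            if b2 < b:
                b = b2
            WM[i, j] = b
    # external loop
    W = np.zeros(n + 1)
    for j in range(1, n + 1):
        w = W[j - 1]
        for i in range(0, j):
            if V[i, j - 1] < INF / 2:
                v = W[i] + V[i, j - 1]
                if v < w:
                    w = v
        W[j] = w
    return V, WM, WM2, W
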