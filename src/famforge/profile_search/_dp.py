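"""Affine-gap dynamic-programming kernels (numba-compiled).

All kernels share the gap convention: a gap of length ``k`` costs
``gap_open + k * gap_extend``.  Matrices are (m+1) x (n+1) with row/column 0
as the boundary.  ``NEG`` stands in for minus infinity.
"""
from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def sw_fill(a, b, sub, gap_open, gap_ext):
    """Smith-Waterman fill for two index-encoded sequences.

    Returns (H, E, F) where H[i, j] is the best local alignment score ending
    at a[:i] / b[:j]; E holds gap-in-a (horizontal) states, F gap-in-b.
    """
    m, n = a.shape[0], b.shape[0]
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - gap_open - gap_ext, E[i, j - 1] - gap_ext)
            f = max(H[i - 1, j] - gap_open - gap_ext, F[i - 1, j] - gap_ext)
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def sw_score(a, b, sub, gap_open, gap_ext):
    """Score-only Smith-Waterman (two linear rows; used for all-vs-all)."""
    m, n = a.shape[0], b.shape[0]
    Hp = np.zeros(n + 1)
    Ep = np.full(n + 1, NEG)
    Fp = np.full(n + 1, NEG)
    best = 0.0
    for i in range(1, m + 1):
        Hc = np.zeros(n + 1)
        Ec = np.full(n + 1, NEG)
        Fc = np.full(n + 1, NEG)
        for j in range(1, n + 1):
            e = max(Hc[j - 1] - gap_open - gap_ext, Ec[j - 1] - gap_ext)
            f = max(Hp[j] - gap_open - gap_ext, Fp[j] - gap_ext)
            Ec[j] = e
            Fc[j] = f
            h = Hp[j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            Hc[j] = h
            if h > best:
                best = h
        Hp, Ep, Fp = Hc, Ec, Fc
    return best


@njit(cache=True)
def profile_sw_fill(scores, b, gap_open, gap_ext):
    """Smith-Waterman fill of a profile (L x n_alphabet scores) vs sequence."""
    m, n = scores.shape[0], b.shape[0]
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - gap_open - gap_ext, E[i, j - 1] - gap_ext)
            f = max(H[i - 1, j] - gap_open - gap_ext, F[i - 1, j] - gap_ext)
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + scores[i - 1, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def profile_sw_score(scores, b, gap_open, gap_ext):
    m, n = scores.shape[0], b.shape[0]
    Hp = np.zeros(n + 1)
    Ep = np.full(n + 1, NEG)
    Fp = np.full(n + 1, NEG)
    best = 0.0
    for i in range(1, m + 1):
        Hc = np.zeros(n + 1)
        Ec = np.full(n + 1, NEG)
        Fc = np.full(n + 1, NEG)
        for j in range(1, n + 1):
            e = max(Hc[j - 1] - gap_open - gap_ext, Ec[j - 1] - gap_ext)
            f = max(Hp[j] - gap_open - gap_ext, Fp[j] - gap_ext)
            Ec[j] = e
            Fc[j] = f
            h = Hp[j - 1] + scores[i - 1, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            Hc[j] = h
            if h > best:
                best = h
        Hp, Ep, Fp = Hc, Ec, Fc
    return best


@njit(cache=True)
def nw_identity(a, b, sub, gap_open, gap_ext):
    """Global-alignment identity: number of identical aligned residue pairs.

    Traceback preference mirrors the python traceback (diagonal, then gap in
    b, then gap in a) so the two routes agree exactly.
    """
    H, E, F = nw_fill(a, b, sub, gap_open, gap_ext)
    i, j = a.shape[0], b.shape[0]
    matches = 0
    state = 0  # 0 = H, 1 = F (gap in b), 2 = E (gap in a)
    while i > 0 or j > 0:
        if state == 0:
            if (
                i > 0
                and j > 0
                and abs(H[i, j] - (H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]])) < 1e-9
            ):
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            leave = (j == 0 and i == 1) or abs(
                F[i, j] - (H[i - 1, j] - gap_open - gap_ext)
            ) < 1e-9
            i -= 1
            if leave:
                state = 0
        else:
            leave = (i == 0 and j == 1) or abs(
                E[i, j] - (H[i, j - 1] - gap_open - gap_ext)
            ) < 1e-9
            j -= 1
            if leave:
                state = 0
    return matches


@njit(cache=True)
def nw_fill(a, b, sub, gap_open, gap_ext):
    """Global (Needleman-Wunsch) affine fill; H[m, n] is the optimum."""
    m, n = a.shape[0], b.shape[0]
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -gap_open - gap_ext * j
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -gap_open - gap_ext * i
        H[i, 0] = F[i, 0]
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - gap_open - gap_ext, E[i, j - 1] - gap_ext)
            f = max(H[i - 1, j] - gap_open - gap_ext, F[i - 1, j] - gap_ext)
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    return H, E, F
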