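"""Numba-jitted dynamic-programming fills for global alignment.

Sequences arrive as 4-bit IUPAC masks (A=1, C=2, G=4, T=8; ambiguity codes
are bit unions).  Two residues score as a match iff their expansions
intersect, i.e. the masks share a bit.  Traceback pointers encode
0=diagonal, 1=up (gap in second sequence), 2=left (gap in first); ties are
broken diagonal > up > left, fixed for reproducibility.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def nw_fill(a, b, match, mismatch, gap):
    n = a.shape[0]
    m = b.shape[0]
    H = np.empty((n + 1, m + 1), np.float64)
    P = np.zeros((n + 1, m + 1), np.int8)
    H[0, 0] = 0.0
    for i in range(1, n + 1):
        H[i, 0] = i * gap
        P[i, 0] = 1
    for j in range(1, m + 1):
        H[0, j] = j * gap
        P[0, j] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai & b[j - 1]) != 0 else mismatch
            best = H[i - 1, j - 1] + s
            ptr = 0
            up = H[i - 1, j] + gap
            if up > best:
                best = up
                ptr = 1
            left = H[i, j - 1] + gap
            if left > best:
                best = left
                ptr = 2
            H[i, j] = best
            P[i, j] = ptr
    return H[n, m], P


@njit(cache=True)
def profile_nw_fill(fa, fb, occ_a, occ_b, match, mismatch, gap):
    """Profile-profile fill; fa/fb are (columns, 4) base-frequency matrices.

    Column-column score is the expected pairwise residue score.  Gap costs are
    weighted by the occupancy (non-gap fraction) of the column being gapped,
    so fresh gaps gravitate toward columns that are already gap-rich and
    indel blocks stay coalesced across progressive merges.
    """
    n = fa.shape[0]
    m = fb.shape[0]
    H = np.empty((n + 1, m + 1), np.float64)
    P = np.zeros((n + 1, m + 1), np.int8)
    H[0, 0] = 0.0
    for i in range(1, n + 1):
        H[i, 0] = H[i - 1, 0] + gap * occ_a[i - 1]
        P[i, 0] = 1
    for j in range(1, m + 1):
        H[0, j] = H[0, j - 1] + gap * occ_b[j - 1]
        P[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 0.0
            for x in range(4):
                fx = fa[i - 1, x]
                if fx == 0.0:
                    continue
                for y in range(4):
                    fy = fb[j - 1, y]
                    if fy == 0.0:
                        continue
                    if x == y:
                        s += fx * fy * match
                    else:
                        s += fx * fy * mismatch
            best = H[i - 1, j - 1] + s
            ptr = 0
            up = H[i - 1, j] + gap * occ_a[i - 1]
            if up > best:
                best = up
                ptr = 1
            left = H[i, j - 1] + gap * occ_b[j - 1]
            if left > best:
                best = left
                ptr = 2
            H[i, j] = best
            P[i, j] = ptr
    return H[n, m], P


def traceback(P: np.ndarray) -> list[tuple[bool, bool]]:
    """Walk pointers from the corner; yields (consume_a, consume_b) per column, 5'→3'."""
    i, j = P.shape[0] - 1, P.shape[1] - 1
    steps: list[tuple[bool, bool]] = []
    while i > 0 or j > 0:
        p = P[i, j]
        if p == 0 and i > 0 and j > 0:
            steps.append((True, True))
            i -= 1
            j -= 1
        elif p == 1 and i > 0:
            steps.append((True, False))
            i -= 1
        else:
            steps.append((False, True))
            j -= 1
    steps.reverse()
    return steps
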