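"""Numba inner loops for the two dynamic programs.

Both kernels fill full DP matrices so that the (cheap) tracebacks can be
done in Python only for the handful of cells that survive thresholding.
All floating-point work is straight-line and single-threaded, so results
are bit-identical regardless of how the surrounding work is chunked.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30

# transition column layout in the (L-1, 9) matrix
MM, MI, MD, IM, II, ID, DM, DI, DD = range(9)


@njit(cache=True)
def viterbi_fill(x, mlo, ilo, t):
    """Fill local-alignment Viterbi matrices for a profile HMM.

    x    : int8[n]   residue codes (A=0 C=1 G=2 T=3, anything else 4)
    mlo  : f8[L, 4]  match emission log-odds (bits vs uniform background)
    ilo  : f8[L-1,4] insert emission log-odds
    t    : f8[L-1,9] transition log2-probabilities (MM MI MD IM II ID DM DI DD)

    Local semantics: free entry into any match state at any position,
    free exit after any match state; code-4 residues emit at background
    (log-odds 0).  Returns (VM, VI, VD).
    """
    n = x.shape[0]
    L = mlo.shape[0]
    VM = np.full((n, L), NEG)
    VI = np.full((n, max(L - 1, 1)), NEG)
    VD = np.full((n, L), NEG)
    for i in range(n):
        c = x[i]
        for k in range(L):
            e = mlo[k, c] if c < 4 else 0.0
            best = 0.0  # free local entry
            if i > 0 and k > 0:
                v = VM[i - 1, k - 1] + t[k - 1, MM]
                if v > best:
                    best = v
                v = VI[i - 1, k - 1] + t[k - 1, IM]
                if v > best:
                    best = v
                v = VD[i - 1, k - 1] + t[k - 1, DM]
                if v > best:
                    best = v
            VM[i, k] = e + best
        if i > 0:
            for k in range(L - 1):
                e = ilo[k, c] if c < 4 else 0.0
                b = VM[i - 1, k] + t[k, MI]
                v = VI[i - 1, k] + t[k, II]
                if v > b:
                    b = v
                v = VD[i - 1, k] + t[k, DI]
                if v > b:
                    b = v
                VI[i, k] = e + b
        for k in range(1, L):
            b = VM[i, k - 1] + t[k - 1, MD]
            v = VI[i, k - 1] + t[k - 1, ID]
            if v > b:
                b = v
            v = VD[i, k - 1] + t[k - 1, DD]
            if v > b:
                b = v
            VD[i, k] = b
    return VM, VI, VD


# pointer codes for the banded Smith-Waterman
P_STOP = 0
P_DIAG = 1
P_E = 2  # gap in query (consumes subject)
P_F = 3  # gap in subject (consumes query)
PE_OPEN = 1
PE_EXT = 2


@njit(cache=True)
def banded_sw_fill(q, s, d0, band, match, mismatch, gap_open, gap_extend):
    """Banded local affine-gap alignment around diagonal ``d0``.

    q, s : int8 residue codes (code 4 = ambiguous, always a mismatch)
    d0   : center diagonal (subject offset minus query offset)
    band : half-width; cells with |(j - i) - d0| > band are outside

    A gap of length g costs gap_open + g * gap_extend (both negative).
    Returns (H, PH, PE, PF) where H[i, b] is the best local score of an
    alignment ending with q[:i] vs s[:j], j = i + d0 + b - band.
    """
    m = q.shape[0]
    n = s.shape[0]
    W = 2 * band + 1
    H = np.full((m + 1, W), NEG)
    E = np.full((m + 1, W), NEG)
    F = np.full((m + 1, W), NEG)
    PH = np.zeros((m + 1, W), dtype=np.uint8)
    PE = np.zeros((m + 1, W), dtype=np.uint8)
    PF = np.zeros((m + 1, W), dtype=np.uint8)
    for b in range(W):
        j0 = 0 + d0 + b - band
        if 0 <= j0 <= n:
            H[0, b] = 0.0
    for i in range(1, m + 1):
        for b in range(W):
            j = i + d0 + b - band
            if j < 0 or j > n:
                continue
            # E: gap in query, from (i, j-1) = (i, b-1)
            e_val = NEG
            e_ptr = 0
            if j > 0 and b > 0:
                v = H[i, b - 1] + gap_open + gap_extend
                if v > e_val:
                    e_val = v
                    e_ptr = PE_OPEN
                v = E[i, b - 1] + gap_extend
                if v > e_val:
                    e_val = v
                    e_ptr = PE_EXT
            E[i, b] = e_val
            PE[i, b] = e_ptr
            # F: gap in subject, from (i-1, j) = (i-1, b+1)
            f_val = NEG
            f_ptr = 0
            if b + 1 < W:
                v = H[i - 1, b + 1] + gap_open + gap_extend
                if v > f_val:
                    f_val = v
                    f_ptr = PE_OPEN
                v = F[i - 1, b + 1] + gap_extend
                if v > f_val:
                    f_val = v
                    f_ptr = PE_EXT
            F[i, b] = f_val
            PF[i, b] = f_ptr
            # H: local, tie-break preference diag > E > F > fresh start
            best = 0.0
            ptr = P_STOP
            if j > 0:
                qa = q[i - 1]
                sa = s[j - 1]
                sub = match if (qa == sa and qa < 4) else mismatch
                v = H[i - 1, b] + sub
                if v > best:
                    best = v
                    ptr = P_DIAG
            if e_val > best:
                best = e_val
                ptr = P_E
            if f_val > best:
                best = f_val
                ptr = P_F
            H[i, b] = best
            PH[i, b] = ptr
    return H, PH, PE, PF
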