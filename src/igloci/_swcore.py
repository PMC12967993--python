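"""Band-compressed affine-gap Smith-Waterman kernel (numba).

The DP matrices are stored band-compressed: row i keeps only the columns j
with dlo <= j - i <= dhi, indexed by b = j - i - dlo.  A diagonal move keeps b
fixed, a target-consuming gap moves to b-1 in the same row, a query-consuming
gap moves to b+1 in the previous row, so the recurrences are purely local in
(row, b) space.  With dlo = -n, dhi = m the kernel is unconstrained
Smith-Waterman.

Gap convention: a gap of length L scores gap_open + L * gap_extend, i.e. the
first gapped base costs ``go1 = gap_open + gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(1 << 28)


@njit(cache=False)
def sw_band_score(q, t, dlo, dhi, ma, mi, go1, ge):  # pragma: no cover
    """Score-only variant: two rolling rows, no traceback storage."""
    n = q.shape[0]
    m = t.shape[0]
    W = dhi - dlo + 1
    half = NEG // 2
    Hp = np.full(W, NEG, np.int32)   # previous row
    Fp = np.full(W, NEG, np.int32)
    Hc = np.full(W, NEG, np.int32)   # current row
    Fc = np.full(W, NEG, np.int32)
    for b in range(W):
        j = dlo + b
        if 0 <= j <= m:
            Hp[b] = 0
    best = 0
    for i in range(1, n + 1):
        e = NEG
        for b in range(W):
            j = i + dlo + b
            if j < 0 or j > m:
                Hc[b] = NEG
                Fc[b] = NEG
                e = NEG
                continue
            if j == 0:
                Hc[b] = 0
                Fc[b] = NEG
                e = NEG
                continue
            # E carried along the row (left neighbour is b-1)
            if b >= 1:
                hl = Hc[b - 1]
                eo = hl + go1 if hl > half else NEG
                ee = e + ge if e > half else NEG
                e = eo if eo >= ee else ee
            else:
                e = NEG
            f = NEG
            if b + 1 < W:
                hu = Hp[b + 1]
                if hu > half:
                    f = hu + go1
                fu = Fp[b + 1]
                if fu > half and fu + ge > f:
                    f = fu + ge
            Fc[b] = f
            hd = Hp[b]
            if hd > half:
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    s = hd + ma
                else:
                    s = hd + mi
            else:
                s = NEG
            h = 0
            if s > h:
                h = s
            if e > h:
                h = e
            if f > h:
                h = f
            Hc[b] = h
            if h > best:
                best = h
        Hp, Hc = Hc, Hp
        Fp, Fc = Fc, Fp
    return best


@njit(cache=False)
def sw_band(q, t, dlo, dhi, ma, mi, go1, ge):  # pragma: no cover - numba
    n = q.shape[0]
    m = t.shape[0]
    W = dhi - dlo + 1
    H = np.full((n + 1, W), NEG, np.int32)
    E = np.full((n + 1, W), NEG, np.int32)
    F = np.full((n + 1, W), NEG, np.int32)
    PH = np.zeros((n + 1, W), np.uint8)  # 0 stop, 1 diag, 2 from E, 3 from F
    PE = np.zeros((n + 1, W), np.uint8)  # 1 gap-open, 0 gap-extend
    PF = np.zeros((n + 1, W), np.uint8)
    half = NEG // 2

    for b in range(W):
        j = dlo + b
        if 0 <= j <= m:
            H[0, b] = 0
    best = 0
    bi = -1
    bb = -1
    for i in range(1, n + 1):
        for b in range(W):
            j = i + dlo + b
            if j < 0 or j > m:
                continue
            if j == 0:
                H[i, b] = 0
                continue
            e = NEG
            pe = np.uint8(0)
            if b - 1 >= 0:
                ho = H[i, b - 1]
                if ho > half:
                    e = ho + go1
                    pe = np.uint8(1)
                ee = E[i, b - 1]
                if ee > half and ee + ge > e:
                    e = ee + ge
                    pe = np.uint8(0)
            E[i, b] = e
            PE[i, b] = pe
            f = NEG
            pf = np.uint8(0)
            if b + 1 < W:
                ho = H[i - 1, b + 1]
                if ho > half:
                    f = ho + go1
                    pf = np.uint8(1)
                fe = F[i - 1, b + 1]
                if fe > half and fe + ge > f:
                    f = fe + ge
                    pf = np.uint8(0)
            F[i, b] = f
            PF[i, b] = pf
            hd = H[i - 1, b]
            if hd > half:
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    s = hd + ma
                else:
                    s = hd + mi
            else:
                s = NEG
            h = 0
            p = np.uint8(0)
            if s > h:
                h = s
                p = np.uint8(1)
            if e > h:
                h = e
                p = np.uint8(2)
            if f > h:
                h = f
                p = np.uint8(3)
            H[i, b] = h
            PH[i, b] = p
            if h > best:
                best = h
                bi = i
                bb = b

    ops = np.empty(n + m + 2, np.uint8)  # 0 '=', 1 'X', 2 'I', 3 'D'
    no = 0
    if bi < 0:
        return 0, 0, 0, 0, 0, ops[:0]
    i = bi
    b = bb
    state = 0
    while True:
        if state == 0:
            p = PH[i, b]
            if p == 0:
                break
            if p == 1:
                j = i + dlo + b
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    ops[no] = 0
                else:
                    ops[no] = 1
                no += 1
                i -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:  # E: gap in query, consumes target column j
            ops[no] = 3
            no += 1
            opened = PE[i, b]
            b -= 1
            if opened == 1:
                state = 0
        else:  # F: gap in target, consumes query row i
            ops[no] = 2
            no += 1
            opened = PF[i, b]
            i -= 1
            b += 1
            if opened == 1:
                state = 0
    qs = i
    ts = i + dlo + b
    te = bi + dlo + bb
    rev = ops[:no][::-1].copy()
    return best, qs, bi, ts, te, rev
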