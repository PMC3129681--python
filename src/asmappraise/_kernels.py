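"""Numba kernels for the banded affine-gap local alignment core.

Sequences are uint8-encoded (A=0, C=1, G=2, T=3, N=4); any column involving N
scores as a mismatch. Gap of length g costs gap_open + g * gap_extend.
The band is expressed in diagonals d = j - i (target minus query position),
d in [dlo, dhi]; the kernel performs Smith-Waterman-style local alignment
restricted to that band, with full traceback.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(2**30)

# traceback op codes emitted by the kernel (5' -> 3' after reversal)
OP_COLUMN = 0  # one query base aligned to one target base
OP_TGAP_DEL = 1  # target base absent from query (deletion when query=assembly)
OP_QGAP_INS = 2  # query base absent from target (insertion when query=assembly)


@njit(cache=True)
def banded_local_align(q, t, dlo, dhi, match, mismatch, gap_open, gap_extend):
    """Banded local alignment with affine gaps and traceback.

    Returns (score, q_start, q_end, t_start, t_end, ops) with 0-based
    half-open coordinates; ops is a uint8 array of per-column op codes in
    alignment order. score <= 0 means no alignment was found.
    """
    n = q.shape[0]
    m = t.shape[0]
    W = dhi - dlo + 1
    goe = gap_open + gap_extend

    ptr = np.zeros((n + 1, W + 2), np.uint8)
    Hp = np.full(W + 2, NEG, np.int64)
    Fp = np.full(W + 2, NEG, np.int64)
    Hc = np.full(W + 2, NEG, np.int64)
    Fc = np.full(W + 2, NEG, np.int64)
    # row 0: local start anywhere along valid diagonals
    for w in range(W + 2):
        j = 0 + dlo + w - 1
        Hp[w] = 0 if 0 <= j <= m else NEG
        Fp[w] = NEG

    best = 0
    bi = -1
    bw = -1
    ilo = max(1, 1 - dhi)
    ihi = min(n, m - dlo)
    for i in range(ilo, ihi + 1):
        Hc[0] = NEG
        Fc[0] = NEG
        e_prev = NEG
        h_left = NEG  # H(i, w-1)
        jbase = i + dlo - 1
        for w in range(1, W + 1):
            j = jbase + w
            if j < 1 or j > m:
                Hc[w] = 0 if j == 0 else NEG
                Fc[w] = NEG
                e_prev = NEG
                h_left = Hc[w]
                ptr[i, w] = 0
                continue
            qa = q[i - 1]
            tb = t[j - 1]
            s = match if (qa == tb and qa < 4 and tb < 4) else mismatch
            code = np.uint8(0)
            # E: gap consuming target base j (from (i, j-1) == (i, w-1))
            e_open = h_left + goe
            e_ext = e_prev + gap_extend
            if e_open >= e_ext:
                e = e_open
                code |= np.uint8(4)
            else:
                e = e_ext
            # F: gap consuming query base i (from (i-1, j) == (i-1, w+1))
            f_open = Hp[w + 1] + goe
            f_ext = Fp[w + 1] + gap_extend
            if f_open >= f_ext:
                f = f_open
                code |= np.uint8(8)
            else:
                f = f_ext
            diag = Hp[w] + s
            h = 0
            src = np.uint8(0)
            if diag > h:
                h = diag
                src = np.uint8(1)
            if e > h:
                h = e
                src = np.uint8(2)
            if f > h:
                h = f
                src = np.uint8(3)
            ptr[i, w] = code | src
            Hc[w] = h
            Fc[w] = f
            e_prev = e
            h_left = h
            if h > best:
                best = h
                bi = i
                bw = w
        # swap rows
        for w in range(W + 2):
            Hp[w] = Hc[w]
            Fp[w] = Fc[w]
            Hc[w] = NEG
            Fc[w] = NEG

    ops = np.empty(n + m, np.uint8)
    k = 0
    if best <= 0:
        return 0, 0, 0, 0, 0, ops[:0]
    i = bi
    w = bw
    q_end = bi
    t_end = bi + dlo + bw - 1
    state = 0  # 0=H, 1=E, 2=F
    while True:
        p = ptr[i, w]
        if state == 0:
            src = p & np.uint8(3)
            if src == 0:
                break
            if src == 1:
                ops[k] = OP_COLUMN
                k += 1
                i -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = OP_TGAP_DEL
            k += 1
            opened = (p >> 2) & np.uint8(1)
            w -= 1
            if opened:
                state = 0
        else:
            ops[k] = OP_QGAP_INS
            k += 1
            opened = (p >> 3) & np.uint8(1)
            i -= 1
            w += 1
            if opened:
                state = 0
    q_start = i
    t_start = i + dlo + w - 1
    return best, q_start, q_end, t_start, t_end, ops[:k][::-1].copy()


@njit(cache=True)
def process_ops(ops, q, t, q0, t0):
    """Left-shift gap runs through homopolymers, then tally the alignment.

    A gap run moves one base left while the column immediately before it is a
    match whose base equals the last base of the gap run (score-preserving).
    Returns (matches, mismatches, qgap, tgap, blocks, events) where blocks is
    an (n,3) array of (q_start, t_start, length) and events an (n,4) array of
    (kind 0=sub 1=del 2=ins, t_pos, q_pos, length).
    """
    n = ops.shape[0]
    # --- left-shift gap runs -------------------------------------------
    qi = np.empty(n, np.int64)
    ti = np.empty(n, np.int64)
    i = q0
    j = t0
    for x in range(n):
        qi[x] = i
        ti[x] = j
        op = ops[x]
        if op == OP_COLUMN:
            i += 1
            j += 1
        elif op == OP_TGAP_DEL:
            j += 1
        else:
            i += 1
    x = 0
    while x < n:
        op = ops[x]
        if op == OP_COLUMN:
            x += 1
            continue
        end = x
        while end < n and ops[end] == op:
            end += 1
        start = x
        while start > 0 and ops[start - 1] == OP_COLUMN:
            pi = qi[start - 1]
            pj = ti[start - 1]
            if q[pi] != t[pj]:
                break
            if op == OP_TGAP_DEL:
                last = t[ti[end - 1]]
                prev = t[pj]
            else:
                last = q[qi[end - 1]]
                prev = q[pi]
            if prev != last:
                break
            # rotate the match column over the gap run
            tmp = ops[start - 1]
            for y in range(start - 1, end - 1):
                ops[y] = ops[y + 1]
            ops[end - 1] = tmp
            i2 = qi[start - 1]
            j2 = ti[start - 1]
            for y in range(start - 1, end):
                qi[y] = i2
                ti[y] = j2
                if ops[y] == OP_COLUMN:
                    i2 += 1
                    j2 += 1
                elif ops[y] == OP_TGAP_DEL:
                    j2 += 1
                else:
                    i2 += 1
            start -= 1
            end -= 1
        x = end if end > x else x + 1
    # --- tally ----------------------------------------------------------
    max_feat = n + 1
    blocks = np.empty((max_feat, 3), np.int64)
    events = np.empty((max_feat, 4), np.int64)
    nb = 0
    ne = 0
    matches = 0
    mismatches = 0
    qgap = 0
    tgap = 0
    i = q0
    j = t0
    blk_open = False
    x = 0
    while x < n:
        op = ops[x]
        if op == OP_COLUMN:
            if not blk_open:
                blocks[nb, 0] = i
                blocks[nb, 1] = j
                blocks[nb, 2] = 0
                blk_open = True
            blocks[nb, 2] += 1
            if q[i] == t[j] and q[i] < 4:
                matches += 1
            else:
                mismatches += 1
                events[ne, 0] = 0
                events[ne, 1] = j
                events[ne, 2] = i
                events[ne, 3] = 1
                ne += 1
            i += 1
            j += 1
            x += 1
        else:
            if blk_open:
                nb += 1
                blk_open = False
            run = 0
            y = x
            while y < n and ops[y] == op:
                run += 1
                y += 1
            if op == OP_TGAP_DEL:
                qgap += run
                events[ne, 0] = 1
                events[ne, 1] = j
                events[ne, 2] = i
                events[ne, 3] = run
                ne += 1
                j += run
            else:
                tgap += run
                events[ne, 0] = 2
                events[ne, 1] = j
                events[ne, 2] = i
                events[ne, 3] = run
                ne += 1
                i += run
            x = y
    if blk_open:
        nb += 1
    return matches, mismatches, qgap, tgap, blocks[:nb].copy(), events[:ne].copy()


@njit(cache=True)
def kmer_codes(enc, k, step):
    """Base-4 codes of k-mers at positions 0, step, 2*step, ...; N-containing
    k-mers get code -1."""
    n = enc.shape[0]
    if n < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    npos = (n - k) // step + 1
    codes = np.empty(npos, np.int64)
    pos = np.empty(npos, np.int64)
    for idx in range(npos):
        p = idx * step
        c = np.int64(0)
        valid = True
        for j in range(k):
            b = enc[p + j]
            if b > 3:
                valid = False
                break
            c = (c << 2) | b
        codes[idx] = c if valid else -1
        pos[idx] = p
    return codes, pos


@njit(cache=True)
def all_kmer_codes(enc, k):
    """Codes of every k-mer position via a rolling window (for index build)."""
    n = enc.shape[0]
    out = np.full(max(n - k + 1, 0), np.int64(-1), np.int64)
    if n < k:
        return out
    mask = (np.int64(1) << np.int64(2 * k)) - np.int64(1)
    c = np.int64(0)
    run = 0  # valid bases accumulated
    for p in range(n):
        b = enc[p]
        if b > 3:
            run = 0
            c = np.int64(0)
            continue
        c = ((c << 2) | b) & mask
        run += 1
        if run >= k:
            out[p - k + 1] = c
    return out
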