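"""Numba kernels for seed-and-extend local alignment.

The search follows the classic BLAST/LAST recipe: exact-match seeds located
through a sorted k-mer index of the target, ungapped X-drop extension around
each seed (with a per-diagonal skip so one island is not re-extended from every
seed it contains), and gapped X-drop extension for seeds whose ungapped score
clears a rescue trigger.  Scores are integer; all arithmetic is int64.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(2**62)


@njit(cache=False)
def xdrop_gapped(q, t, q0, t0, dirn, mat, go, ge, X, wcap):
    """Gapped X-drop extension from an anchor, affine gaps (open+len*extend).

    Extends rightward (dirn=+1, consuming q[q0:], t[t0:]) or leftward
    (dirn=-1, consuming q[:q0], t[:t0] backwards).  Returns (best score of the
    extension, query chars consumed, target chars consumed) at the best cell.
    Cells whose score falls more than X below the running best are pruned;
    the live window per row is bounded by ~2*X/|ge| and clamped at wcap.
    """
    nq = len(q)
    nt = len(t)
    lim_i = (nq - q0) if dirn == 1 else q0
    lim_j = (nt - t0) if dirn == 1 else t0

    Hp = np.full(wcap, NEG, np.int64)
    Fp = np.full(wcap, NEG, np.int64)
    Hc = np.full(wcap, NEG, np.int64)
    Fc = np.full(wcap, NEG, np.int64)

    best = 0
    bi = 0
    bj = 0

    # row 0: leading gap in the query (target chars only)
    lo_p = 0
    hi_p = 0
    Hp[0] = 0
    Fp[0] = NEG
    e = go
    j = 1
    while j <= lim_j and j < wcap:
        e += ge
        if e < best - X:
            break
        Hp[j] = e
        Fp[j] = NEG
        hi_p = j
        j += 1

    for i in range(1, lim_i + 1):
        qc = q[q0 + i - 1] if dirn == 1 else q[q0 - i]
        lo_c = -1
        hi_c = -2
        e = NEG
        j = lo_p
        jmax = hi_p + 1
        while j <= lim_j:
            if j > jmax and e < best - X:
                break
            # sources from previous row
            if lo_p <= j - 1 <= hi_p:
                hd = Hp[j - 1 - lo_p]
            else:
                hd = NEG
            if lo_p <= j <= hi_p:
                hv = Hp[j - lo_p]
                fv = Fp[j - lo_p]
            else:
                hv = NEG
                fv = NEG
            if j >= 1 and hd > NEG // 2:
                tc = t[t0 + j - 1] if dirn == 1 else t[t0 - j]
                m = hd + mat[qc, tc]
            else:
                m = NEG
            f = hv + go + ge
            f2 = fv + ge
            if f2 > f:
                f = f2
            h = m
            if e > h:
                h = e
            if f > h:
                h = f
            if h >= best - X or f >= best - X:
                if lo_c < 0:
                    lo_c = j
                idx = j - lo_c
                if idx >= wcap:
                    break
                Hc[idx] = h
                Fc[idx] = f
                hi_c = j
                if h > best:
                    best = h
                    bi = i
                    bj = j
            elif lo_c >= 0:
                idx = j - lo_c
                if idx >= wcap:
                    break
                Hc[idx] = NEG
                Fc[idx] = NEG
            # E for next cell in this row
            e2 = h + go + ge
            ee = e + ge
            if ee > e2:
                e2 = ee
            e = e2
            j += 1
        if lo_c < 0:
            break
        # swap rows
        tmpH = Hp
        Hp = Hc
        Hc = tmpH
        tmpF = Fp
        Fp = Fc
        Fc = tmpF
        lo_p = lo_c
        hi_p = hi_c

    return best, bi, bj


@njit(cache=False)
def seed_search(q, t, qpos, qcode, tstarts, tpos, k, mat, go, ge, X, Xu,
                min_score, trigger, gapped, diag_skip, wcap, out):
    """Scan all exact k-mer seed matches and extend; record hits >= min_score.

    out is an (max_hits, 5) int64 buffer receiving rows
    (q_start, q_end, t_start, t_end, score).  Returns the number of hits
    found (may exceed the buffer; the caller must then retry with a larger
    buffer).
    """
    nq = len(q)
    nt = len(t)
    maxout = out.shape[0]
    cnt = 0
    diag_end = np.full(nq + nt, -1, np.int64)

    for si in range(len(qpos)):
        qi = qpos[si]
        code = qcode[si]
        for ix in range(tstarts[code], tstarts[code + 1]):
            ti = tpos[ix]
            d = qi - ti + nt
            if diag_skip and diag_end[d] > qi:
                continue
            s0 = np.int64(0)
            for z in range(k):
                b = q[qi + z]
                s0 += mat[b, b]
            # ungapped right of seed
            best_r = np.int64(0)
            cur = np.int64(0)
            off_r = 0
            i = qi + k
            j = ti + k
            while i < nq and j < nt:
                cur += mat[q[i], t[j]]
                if cur > best_r:
                    best_r = cur
                    off_r = i - (qi + k) + 1
                elif best_r - cur > Xu:
                    break
                i += 1
                j += 1
            # ungapped left of seed
            best_l = np.int64(0)
            cur = np.int64(0)
            off_l = 0
            i = qi - 1
            j = ti - 1
            while i >= 0 and j >= 0:
                cur += mat[q[i], t[j]]
                if cur > best_l:
                    best_l = cur
                    off_l = qi - i
                elif best_l - cur > Xu:
                    break
                i -= 1
                j -= 1
            ung = s0 + best_l + best_r
            diag_end[d] = qi + k + off_r
            if gapped:
                if ung < trigger and ung < min_score:
                    continue
                sl, li, lj = xdrop_gapped(q, t, qi, ti, -1, mat, go, ge, X, wcap)
                sr, ri, rj = xdrop_gapped(q, t, qi + k, ti + k, 1, mat, go, ge, X, wcap)
                score = s0 + sl + sr
                qs = qi - li
                qe = qi + k + ri
                ts = ti - lj
                te = ti + k + rj
            else:
                score = ung
                qs = qi - off_l
                qe = qi + k + off_r
                ts = ti - off_l
                te = ti + k + off_r
            if score >= min_score:
                if cnt < maxout:
                    out[cnt, 0] = qs
                    out[cnt, 1] = qe
                    out[cnt, 2] = ts
                    out[cnt, 3] = te
                    out[cnt, 4] = score
                cnt += 1
    return cnt


@njit(cache=False)
def dedup_hits(rows, order, keep):
    """Mark one hit per island: hits overlapping in both coordinates collapse
    onto the highest score (ties: smaller t_start, then smaller q_start).

    rows: (n,5) int64 as produced by seed_search; order: candidate visiting
    order (by descending score / ascending t_start, q_start); keep: bool out.
    """
    n = rows.shape[0]
    kept = np.empty(n, np.int64)
    nk = 0
    for oi in range(n):
        r = order[oi]
        qs = rows[r, 0]
        qe = rows[r, 1]
        ts = rows[r, 2]
        te = rows[r, 3]
        ok = True
        for z in range(nk):
            s = kept[z]
            if rows[s, 2] < te and ts < rows[s, 3] and rows[s, 0] < qe and qs < rows[s, 1]:
                ok = False
                break
        if ok:
            keep[r] = True
            kept[nk] = r
            nk += 1
    return nk


@njit(cache=False)
def affine_global(q, t, mat, go, ge):
    """Global affine-gap alignment with traceback, for re-deriving the
    gap-free blocks of an already-located hit.  Returns (score, blocks)
    with blocks an (nb,3) array of (q_start, t_start, length)."""
    n = len(q)
    m = len(t)
    NEG32 = -(2**30)
    H = np.full((n + 1, m + 1), NEG32, np.int64)
    E = np.full((n + 1, m + 1), NEG32, np.int64)
    F = np.full((n + 1, m + 1), NEG32, np.int64)
    # pointers: bit 0-1 of ptrH: 0=diag,1=E,2=F ; ptrE: 1 if extend; ptrF: 1 if extend
    ptrH = np.zeros((n + 1, m + 1), np.uint8)
    ptrE = np.zeros((n + 1, m + 1), np.uint8)
    ptrF = np.zeros((n + 1, m + 1), np.uint8)
    H[0, 0] = 0
    for j in range(1, m + 1):
        op = H[0, j - 1] + go + ge
        ex = E[0, j - 1] + ge
        if ex > op:
            E[0, j] = ex
            ptrE[0, j] = 1
        else:
            E[0, j] = op
        H[0, j] = E[0, j]
        ptrH[0, j] = 1
    for i in range(1, n + 1):
        op = H[i - 1, 0] + go + ge
        ex = F[i - 1, 0] + ge
        if ex > op:
            F[i, 0] = ex
            ptrF[i, 0] = 1
        else:
            F[i, 0] = op
        H[i, 0] = F[i, 0]
        ptrH[i, 0] = 2
        for j in range(1, m + 1):
            op = H[i, j - 1] + go + ge
            ex = E[i, j - 1] + ge
            if ex > op:
                E[i, j] = ex
                ptrE[i, j] = 1
            else:
                E[i, j] = op
            op = H[i - 1, j] + go + ge
            ex = F[i - 1, j] + ge
            if ex > op:
                F[i, j] = ex
                ptrF[i, j] = 1
            else:
                F[i, j] = op
            d = H[i - 1, j - 1] + mat[q[i - 1], t[j - 1]]
            h = d
            p = np.uint8(0)
            if E[i, j] > h:
                h = E[i, j]
                p = np.uint8(1)
            if F[i, j] > h:
                h = F[i, j]
                p = np.uint8(2)
            H[i, j] = h
            ptrH[i, j] = p
    # traceback
    moves = np.empty(n + m + 2, np.uint8)  # 0 diag, 1 right (gap in q), 2 down (gap in t)
    nm = 0
    i = n
    j = m
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 or j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                moves[nm] = 0
                nm += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 1:
            moves[nm] = 1
            nm += 1
            if ptrE[i, j] == 0:
                state = 0
            j -= 1
        else:
            moves[nm] = 2
            nm += 1
            if ptrF[i, j] == 0:
                state = 0
            i -= 1
    # moves are reversed; build blocks walking forward
    blocks = np.empty((nm, 3), np.int64)
    nb = 0
    qi = 0
    ti = 0
    run = 0
    for z in range(nm - 1, -1, -1):
        mv = moves[z]
        if mv == 0:
            if run == 0:
                blocks[nb, 0] = qi
                blocks[nb, 1] = ti
            run += 1
            qi += 1
            ti += 1
        else:
            if run > 0:
                blocks[nb, 2] = run
                nb += 1
                run = 0
            if mv == 1:
                ti += 1
            else:
                qi += 1
    if run > 0:
        blocks[nb, 2] = run
        nb += 1
    return H[n, m], blocks[:nb]
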