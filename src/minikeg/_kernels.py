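"""Numba kernels for gap-free (x-drop) and gapped (y-drop) extension.

Both kernels work on uint8-encoded sequences (A=0..T=3, other=4) and a
5x5 int64 substitution matrix (row/col 4 holds the worst score of the
matrix so ambiguous bases behave like mismatches).

The y-drop kernel runs a banded affine-gap dynamic program away from a
start pair toward increasing indices.  Cells whose best state falls more
than ``ydrop`` below the running maximum are pruned; a row whose window
empties terminates the extension.  The live window is additionally capped
at ``cap`` columns (callers size the cap from ``ydrop/gap_extend`` so the
cap only binds when the drop threshold is effectively infinite).
Tie-breaking is fixed: on equal scores an aligned column is preferred over
a target-gap column over a query-gap column, and closing a gap is
preferred over extending it.  All choices are made during the left-to-right
fill, so for a given start pair the traced path is fully deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(2**60))

# op codes in traceback output
OP_ALIGN = 0  # consume target and query
OP_TGAP = 1  # consume target only (gap in query)
OP_QGAP = 2  # consume query only (gap in target)


@njit(cache=True)
def xdrop_ungapped(t, q, ti, qi, k, sub, xdrop):
    """Gap-free x-drop extension of an exact seed.

    Returns ``(score, left, right)``: the maximal-scoring gap-free span
    ``[ti - left, ti + k + right)`` on the target (same offsets on the
    query axis), where each direction stops once its running score falls
    more than ``xdrop`` below that direction's maximum.
    """
    seed_score = np.int64(0)
    for l in range(k):
        seed_score += sub[t[ti + l], q[qi + l]]
    # right
    best_r = np.int64(0)
    right = 0
    run = np.int64(0)
    l = 0
    n_r = min(t.shape[0] - ti - k, q.shape[0] - qi - k)
    while l < n_r:
        run += sub[t[ti + k + l], q[qi + k + l]]
        if run > best_r:
            best_r = run
            right = l + 1
        if run < best_r - xdrop:
            break
        l += 1
    # left
    best_l = np.int64(0)
    left = 0
    run = np.int64(0)
    l = 1
    n_l = min(ti, qi)
    while l <= n_l:
        run += sub[t[ti - l], q[qi - l]]
        if run > best_l:
            best_l = run
            left = l
        if run < best_l - xdrop:
            break
        l += 1
    return seed_score + best_l + best_r, left, right


@njit(cache=True)
def ydrop_one_sided(t, q, t0, q0, sub, gap_open, gap_extend, ydrop, cap):
    """Affine y-drop extension from aligned start pair ``(t0, q0)`` rightward.

    Returns ``(best_score, best_i, best_j, ops)`` where ``(best_i, best_j)``
    is the max-scoring aligned cell as offsets from the start (the start
    pair itself is cell (0, 0) and scores its substitution), and ``ops``
    is the traceback from the start to that cell, start pair included.
    """
    n = t.shape[0] - t0
    m = q.shape[0] - q0
    # state rows, indexed by absolute j offset
    curM = np.full(m, NEG, np.int64)
    curIx = np.full(m, NEG, np.int64)
    curIy = np.full(m, NEG, np.int64)
    prvM = np.full(m, NEG, np.int64)
    prvIx = np.full(m, NEG, np.int64)
    prvIy = np.full(m, NEG, np.int64)

    ptr = np.zeros((n, cap), np.uint8)
    base = np.zeros(n, np.int64)

    go_ge = gap_open + gap_extend

    # row 0: the start pair, then an optional rightward query-gap run
    best = sub[t[t0], q[q0]]
    best_i = 0
    best_j = 0
    curM[0] = best
    lo = 0
    hi = 0
    j = 1
    while j < m and j < cap:
        open_s = curM[j - 1] - go_ge
        ext_s = curIy[j - 1] - gap_extend if curIy[j - 1] > NEG // 2 else NEG
        if open_s >= ext_s:
            curIy[j] = open_s
            ptr[0, j] = 0 << 3
        else:
            curIy[j] = ext_s
            ptr[0, j] = 1 << 3
        if curIy[j] < best - ydrop:
            curIy[j] = NEG
            break
        hi = j
        j += 1

    # hand row 0 over to the previous-row arrays; prv was all-NEG
    tmpM = prvM
    prvM = curM
    curM = tmpM
    tmpX = prvIx
    prvIx = curIx
    curIx = tmpX
    tmpY = prvIy
    prvIy = curIy
    curIy = tmpY

    for i in range(1, n):
        scan_lo = lo
        scan_cap = min(m - 1, scan_lo + cap - 1)
        base[i] = scan_lo
        new_lo = -1
        new_hi = -1
        row_best = NEG
        tc = t[t0 + i]
        j = scan_lo
        while j <= scan_cap:
            # M: diagonal predecessors at (i-1, j-1)
            if j - 1 >= 0:
                pm = prvM[j - 1]
                px = prvIx[j - 1]
                py = prvIy[j - 1]
            else:
                pm = NEG
                px = NEG
                py = NEG
            pbits = np.uint8(0)
            d = pm
            if px > d:
                d = px
                pbits = np.uint8(1)
            if py > d:
                d = py
                pbits = np.uint8(2)
            mij = d + sub[tc, q[q0 + j]] if d > NEG // 2 else NEG
            # Ix: from (i-1, j)
            xo = prvM[j] - go_ge if prvM[j] > NEG // 2 else NEG
            xe = prvIx[j] - gap_extend if prvIx[j] > NEG // 2 else NEG
            if xo >= xe:
                xij = xo
                xbit = np.uint8(0)
            else:
                xij = xe
                xbit = np.uint8(1)
            # Iy: from (i, j-1) in the current row
            if j - 1 >= 0:
                yo = curM[j - 1] - go_ge if curM[j - 1] > NEG // 2 else NEG
                ye = curIy[j - 1] - gap_extend if curIy[j - 1] > NEG // 2 else NEG
            else:
                yo = NEG
                ye = NEG
            if yo >= ye:
                yij = yo
                ybit = np.uint8(0)
            else:
                yij = ye
                ybit = np.uint8(1)

            cell_best = mij
            if xij > cell_best:
                cell_best = xij
            if yij > cell_best:
                cell_best = yij
            if cell_best < best - ydrop:
                curM[j] = NEG
                curIx[j] = NEG
                curIy[j] = NEG
                # beyond the reach of the previous row, a dead query-gap
                # chain can never revive: stop scanning
                if j > new_hi and j - 1 > hi:
                    break
            else:
                curM[j] = mij
                curIx[j] = xij
                curIy[j] = yij
                ptr[i, j - scan_lo] = pbits | (xbit << 2) | (ybit << 3)
                if new_lo < 0:
                    new_lo = j
                new_hi = j
                if mij > row_best:
                    row_best = mij
                if mij > best:
                    best = mij
                    best_i = i
                    best_j = j
            j += 1

        if new_lo < 0:
            break  # window empty: extension terminated
        # reset previous-row arrays over the old window, then swap
        for jj in range(lo, hi + 1):
            prvM[jj] = NEG
            prvIx[jj] = NEG
            prvIy[jj] = NEG
        tmpM = prvM
        prvM = curM
        curM = tmpM
        tmpX = prvIx
        prvIx = curIx
        curIx = tmpX
        tmpY = prvIy
        prvIy = curIy
        curIy = tmpY
        # clear the region of the new current row that the next scan may touch
        nlo = new_lo
        ncap = min(m - 1, nlo + cap - 1)
        for jj in range(nlo, ncap + 1):
            curM[jj] = NEG
            curIx[jj] = NEG
            curIy[jj] = NEG
        lo = new_lo
        hi = new_hi
        if lo >= m:
            break

    # traceback from (best_i, best_j) in state M
    ops = np.empty(best_i + best_j + 1, np.uint8)
    k = 0
    i = best_i
    j = best_j
    state = 0
    while True:
        p = ptr[i, j - base[i]]
        if state == 0:
            ops[k] = OP_ALIGN
            k += 1
            if i == 0 and j == 0:
                break
            state = p & np.uint8(3)
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = OP_TGAP
            k += 1
            state = np.uint8(0) if (p >> 2) & np.uint8(1) == 0 else np.uint8(1)
            i -= 1
        else:
            ops[k] = OP_QGAP
            k += 1
            state = np.uint8(0) if (p >> 3) & np.uint8(1) == 0 else np.uint8(2)
            j -= 1
    return best, best_i, best_j, ops[:k][::-1].copy()
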