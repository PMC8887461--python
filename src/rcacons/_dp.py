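"""Numba-compiled dynamic-programming kernels.

Integer match/mismatch/linear-gap scoring for sequence-vs-sequence
alignment, plus a float kernel for profile-vs-sequence alignment used by
the progressive MSA. 'N' (ASCII 78) never matches anything, including
another 'N'.
"""
from __future__ import annotations

import numpy as np
from numba import njit

N_CODE = 78  # ASCII 'N'


@njit(cache=True)
def fill_matrix(q, t, match, mismatch, gap, free_target_ends):
    """Fill the (m+1)x(n+1) score matrix.

    ``free_target_ends=True`` gives semiglobal alignment (full query vs any
    substring of the target); ``False`` gives Needleman-Wunsch.
    """
    m = q.shape[0]
    n = t.shape[0]
    H = np.empty((m + 1, n + 1), np.int64)
    for j in range(n + 1):
        H[0, j] = 0 if free_target_ends else gap * j
    for i in range(1, m + 1):
        H[i, 0] = H[i - 1, 0] + gap
        qi = q[i - 1]
        for j in range(1, n + 1):
            s = match if (qi == t[j - 1] and qi != N_CODE) else mismatch
            best = H[i - 1, j - 1] + s
            v = H[i - 1, j] + gap
            if v > best:
                best = v
            h = H[i, j - 1] + gap
            if h > best:
                best = h
            H[i, j] = best
    return H


@njit(cache=True)
def traceback(H, q, t, match, mismatch, gap, j_end):
    """Trace one optimal path from (m, j_end) back to row 0.

    Move preference on ties: diagonal, then query-base-vs-gap (deletion),
    then target-base-vs-gap (insertion); deterministic.

    Returns (start_col, matches, mismatches, insertions, deletions).
    Remaining target columns left of ``start_col`` are the caller's concern
    (free prefix for semiglobal; leading insertions for global).
    """
    i = q.shape[0]
    j = j_end
    matches = 0
    mismatches = 0
    ins = 0
    dels = 0
    while i > 0:
        qi = q[i - 1]
        moved = False
        if j > 0:
            s = match if (qi == t[j - 1] and qi != N_CODE) else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                if qi == t[j - 1] and qi != N_CODE:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
                moved = True
        if not moved:
            if H[i, j] == H[i - 1, j] + gap:
                dels += 1
                i -= 1
            else:
                ins += 1
                j -= 1
    return j, matches, mismatches, ins, dels


@njit(cache=True)
def profile_fill(sub, gap):
    """Global DP of a profile (rows of ``sub``) against a sequence (cols)."""
    p = sub.shape[0]
    s = sub.shape[1]
    H = np.empty((p + 1, s + 1), np.float64)
    H[0, 0] = 0.0
    for j in range(1, s + 1):
        H[0, j] = H[0, j - 1] + gap
    for i in range(1, p + 1):
        H[i, 0] = H[i - 1, 0] + gap
        for j in range(1, s + 1):
            best = H[i - 1, j - 1] + sub[i - 1, j - 1]
            v = H[i - 1, j] + gap
            if v > best:
                best = v
            h = H[i, j - 1] + gap
            if h > best:
                best = h
            H[i, j] = best
    return H


@njit(cache=True)
def profile_traceback(H, sub, gap):
    """Ops for one optimal profile-vs-sequence path, 5'->3'.

    0 = aligned column, 1 = profile column vs gap, 2 = new gap column vs
    sequence base. Tie preference mirrors :func:`traceback`.
    """
    i = sub.shape[0]
    j = sub.shape[1]
    ops = np.empty(i + j, np.int8)
    k = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
            ops[k] = 0
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            ops[k] = 1
            i -= 1
        else:
            ops[k] = 2
            j -= 1
        k += 1
    return ops[:k][::-1].copy()


@njit(cache=True)
def fill_matrix_matches(q, t, match, mismatch, gap):
    """Global DP returning (H, M): score matrix and, per cell, the maximum
    number of matched columns over all score-optimal paths to that cell.

    M canonicalises among co-optimal alignments in a way that is symmetric
    under swapping query and target, which pins down a unique
    (matches, mismatches, insertions, deletions) count vector.
    """
    m = q.shape[0]
    n = t.shape[0]
    H = np.empty((m + 1, n + 1), np.int64)
    M = np.zeros((m + 1, n + 1), np.int64)
    for j in range(n + 1):
        H[0, j] = gap * j
    for i in range(1, m + 1):
        H[i, 0] = H[i - 1, 0] + gap
        qi = q[i - 1]
        for j in range(1, n + 1):
            is_match = qi == t[j - 1] and qi != N_CODE
            s = match if is_match else mismatch
            diag = H[i - 1, j - 1] + s
            up = H[i - 1, j] + gap
            left = H[i, j - 1] + gap
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            mbest = -1
            if diag == best:
                cand = M[i - 1, j - 1] + (1 if is_match else 0)
                if cand > mbest:
                    mbest = cand
            if up == best:
                if M[i - 1, j] > mbest:
                    mbest = M[i - 1, j]
            if left == best:
                if M[i, j - 1] > mbest:
                    mbest = M[i, j - 1]
            H[i, j] = best
            M[i, j] = mbest
    return H, M
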