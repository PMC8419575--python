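"""Compiled inner loops for the epoch scheduler.

These kernels are exact reimplementations of the corresponding numpy
expressions; they exist because the novelty scan admits early exits (the
newest memory entry blocks most tutor songs, and entries further back are
older, so the expiry check can stop the scan) that vectorised reductions
cannot exploit.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def novelty_scan(
    mem, mem_epoch, mem_pos, mem_len, sup_flat, sup_start, code, n_codes, oldest_live
):
    """Per (agent, tutor) novelty: no live remembered song is a superset.

    ``sup_flat[sup_start[c]:sup_start[c+1]]`` holds the sorted song ids
    that are supersets of the tutor song with dense code ``c``; codes
    outside [0, n_codes) mark invalid or never-novel tutor slots.  Memory
    is scanned newest-first; entries learned before ``oldest_live`` are
    expired, and since learning epochs decrease walking back, the scan
    stops at the first expired entry.
    """
    n, T = code.shape
    M = mem.shape[1]
    out = np.zeros((n, T), dtype=np.bool_)
    for j in range(n):
        for t in range(T):
            c = code[j, t]
            if c < 0 or c >= n_codes:
                continue
            # the same song is often heard from several tutors: reuse
            # the verdict computed for an earlier slot of this row
            memo = False
            for x in range(t):
                if code[j, x] == c:
                    out[j, t] = out[j, x]
                    memo = True
                    break
            if memo:
                continue
            lo0 = sup_start[c]
            hi0 = sup_start[c + 1]
            novel = True
            for s0 in range(mem_len[j]):
                s = (mem_pos[j] - 1 - s0) % M
                if mem_epoch[j, s] < oldest_live:
                    break
                sid = mem[j, s]
                lo = lo0
                hi = hi0
                while lo < hi:
                    mid = (lo + hi) // 2
                    v = sup_flat[mid]
                    if v == sid:
                        novel = False
                        break
                    if v < sid:
                        lo = mid + 1
                    else:
                        hi = mid
                if not novel:
                    break
            out[j, t] = novel
    return out


@njit(cache=True)
def build_contains(arr, lens):
    """contains[c, h, slot]: theme ``slot`` of song ``c`` occurs in song ``h``.

    Rows of ``arr`` are sorted theme ids (zero-padded); the last ``h``
    column is an all-false pad for empty tutor positions.
    """
    V, S = arr.shape
    out = np.zeros((V, V + 1, S), dtype=np.bool_)
    for c in range(V):
        lc = lens[c]
        for h in range(V):
            lh = lens[h]
            i = 0
            j = 0
            while i < lc and j < lh:
                a = arr[c, i]
                b = arr[h, j]
                if a == b:
                    out[c, h, i] = True
                    i += 1
                    j += 1
                elif a < b:
                    i += 1
                else:
                    j += 1
    return out


@njit(cache=True)
def copy_retention(contains, ccode, hcode, u_ret, P_d):
    """Stage-1 retention for a batch of learners.

    For each learner i and slot s of its chosen song, tallies k (number
    of heard tutor songs containing the theme) and keeps the theme with
    probability 1/(1 + 0.5**(k + P_d)).  Returns the keep mask and the
    per-learner kept count.
    """
    L, T = hcode.shape
    S = contains.shape[2]
    keep = np.zeros((L, S), dtype=np.bool_)
    kept = np.zeros(L, dtype=np.int64)
    for i in range(L):
        c = ccode[i]
        for s in range(S):
            k = 0
            for t in range(T):
                if contains[c, hcode[i, t], s]:
                    k += 1
            if k > 0:  # k == 0 only on padding slots (no theme)
                if u_ret[i, s] < 1.0 / (1.0 + 0.5 ** (k + P_d)):
                    keep[i, s] = True
                    kept[i] += 1
    return keep, kept


@njit(cache=True)
def kcount_scan(contains, ccode, hcode):
    """k[i, slot]: number of heard tutor songs containing each chosen theme."""
    L, T = hcode.shape
    S = contains.shape[2]
    out = np.zeros((L, S), dtype=np.int64)
    for i in range(L):
        c = ccode[i]
        for t in range(T):
            h = hcode[i, t]
            for s in range(S):
                if contains[c, h, s]:
                    out[i, s] += 1
    return out


@njit(cache=True)
def floyd_sample(u, c):
    """Row-wise Floyd sampling: T distinct integers from [0, c) per row."""
    n, T = u.shape
    res = np.empty((n, T), dtype=np.int64)
    for j in range(n):
        for t in range(T):
            i = c - T + t
            cand = int(u[j, t] * (i + 1))
            if cand > i:
                cand = i
            dup = False
            for x in range(t):
                if res[j, x] == cand:
                    dup = True
                    break
            res[j, t] = i if dup else cand
    return res
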