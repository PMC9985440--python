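"""Numba kernels for the dynamic-programming inner loops.

Everything here is a plain-array function so it can be jit-compiled and
cached; the public modules wrap these with typed containers.  Python
reference implementations of the same recurrences (used as independent
cross-checks in the tests) live in :mod:`threadfold.reference`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def nw_linear(S, gap):
    """Global Needleman–Wunsch with linear gap penalty.

    Returns (best score, pairs) where pairs is an (n, 2) int array of
    0-based matched indices in order.  Ties prefer diagonal, then up
    (gap in second sequence), then left.
    """
    La, Lb = S.shape
    H = np.empty((La + 1, Lb + 1))
    ptr = np.zeros((La + 1, Lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    H[0, 0] = 0.0
    for i in range(1, La + 1):
        H[i, 0] = H[i - 1, 0] - gap
        ptr[i, 0] = 1
    for j in range(1, Lb + 1):
        H[0, j] = H[0, j - 1] - gap
        ptr[0, j] = 2
    for i in range(1, La + 1):
        for j in range(1, Lb + 1):
            d = H[i - 1, j - 1] + S[i - 1, j - 1]
            u = H[i - 1, j] - gap
            l = H[i, j - 1] - gap
            best = d
            p = 0
            if u > best:
                best = u
                p = 1
            if l > best:
                best = l
                p = 2
            H[i, j] = best
            ptr[i, j] = p
    # traceback
    pairs = np.empty((min(La, Lb), 2), dtype=np.int64)
    k = 0
    i, j = La, Lb
    while i > 0 or j > 0:
        p = ptr[i, j]
        if i > 0 and j > 0 and p == 0:
            pairs[k, 0] = i - 1
            pairs[k, 1] = j - 1
            k += 1
            i -= 1
            j -= 1
        elif i > 0 and (p == 1 or j == 0):
            i -= 1
        else:
            j -= 1
    out = pairs[:k][::-1].copy()
    return H[La, Lb], out


@njit(cache=True)
def nw_affine(M, gap_open, gap_ext):
    """Global alignment with affine gaps, maximizing sum(M) - penalties.

    A gap run of length g costs gap_open + gap_ext * g.  Terminal gaps
    are penalized.  Returns (best score, pairs, n_gap_runs, n_gap_pos).
    Tie-breaking prefers match, then gap-in-b (up), then gap-in-a.
    """
    La, Lb = M.shape
    H = np.full((La + 1, Lb + 1), NEG)  # ends in match
    X = np.full((La + 1, Lb + 1), NEG)  # ends in gap consuming a (up)
    Y = np.full((La + 1, Lb + 1), NEG)  # ends in gap consuming b (left)
    pH = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    pX = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    pY = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for i in range(1, La + 1):
        X[i, 0] = -(gap_open + gap_ext * i)
        pX[i, 0] = 1 if i > 1 else 0
    for j in range(1, Lb + 1):
        Y[0, j] = -(gap_open + gap_ext * j)
        pY[0, j] = 2 if j > 1 else 0
    for i in range(1, La + 1):
        for j in range(1, Lb + 1):
            # H: match i-1,j-1
            b0 = H[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > b0:
                b0 = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > b0:
                b0 = Y[i - 1, j - 1]
                p = 2
            H[i, j] = b0 + M[i - 1, j - 1]
            pH[i, j] = p
            # X: gap consuming a_i
            open_ = H[i - 1, j] - gap_open - gap_ext
            p = 0
            b1 = open_
            if X[i - 1, j] - gap_ext > b1:
                b1 = X[i - 1, j] - gap_ext
                p = 1
            if Y[i - 1, j] - gap_open - gap_ext > b1:
                b1 = Y[i - 1, j] - gap_open - gap_ext
                p = 2
            X[i, j] = b1
            pX[i, j] = p
            # Y: gap consuming b_j
            b2 = H[i, j - 1] - gap_open - gap_ext
            p = 0
            if X[i, j - 1] - gap_open - gap_ext > b2:
                b2 = X[i, j - 1] - gap_open - gap_ext
                p = 1
            if Y[i, j - 1] - gap_ext > b2:
                b2 = Y[i, j - 1] - gap_ext
                p = 2
            Y[i, j] = b2
            pY[i, j] = p
    # terminal state
    best = H[La, Lb]
    state = 0
    if X[La, Lb] > best:
        best = X[La, Lb]
        state = 1
    if Y[La, Lb] > best:
        best = Y[La, Lb]
        state = 2
    # traceback
    pairs = np.empty((min(La, Lb), 2), dtype=np.int64)
    k = 0
    n_runs = 0
    n_gap = 0
    i, j = La, Lb
    while i > 0 or j > 0:
        if state == 0:
            prev = pH[i, j]
            pairs[k, 0] = i - 1
            pairs[k, 1] = j - 1
            k += 1
            i -= 1
            j -= 1
            state = prev
        elif state == 1:
            prev = pX[i, j]
            n_gap += 1
            if prev != 1:
                n_runs += 1
            i -= 1
            state = prev
        else:
            prev = pY[i, j]
            n_gap += 1
            if prev != 2:
                n_runs += 1
            j -= 1
            state = prev
    out = pairs[:k][::-1].copy()
    return best, out, n_runs, n_gap


@njit(cache=True, inline="always")
def _w_seq(sep, b1, b2, v1, v2, v3):
    if sep < b1:
        return v1
    elif sep < b2:
        return v2
    return v3


@njit(cache=True, inline="always")
def _w_dist(dd, b1, b2, v1, v2, v3):
    if dd <= b1:
        return v1
    elif dd <= b2:
        return v2
    return v3


@njit(cache=True, inline="always")
def _pair_term(
    qd, qp, nq, td, tp, nt, Dq, Dt, sep, lam,
    sb1, sb2, sv1, sv2, sv3, db1, db2, dv1, dv2, dv3,
):
    """max over peak pairs of p_i * q_j * w_seq * w_dist * w_cut."""
    if nq == 0 or nt == 0:
        return 0.0
    if Dq >= lam or Dt >= lam:
        return 0.0
    ws = _w_seq(sep, sb1, sb2, sv1, sv2, sv3)
    best = 0.0
    for i in range(nq):
        for j in range(nt):
            wd = _w_dist(abs(qd[i] - td[j]), db1, db2, dv1, dv2, dv3)
            v = qp[i] * tp[j] * ws * wd
            if v > best:
                best = v
    return best


@njit(cache=True)
def build_contacts(npk, D, lam):
    """CSR contact lists: partners m of each residue n with peaks and D < lam."""
    L = npk.shape[0]
    ptr = np.zeros(L + 1, dtype=np.int64)
    for n in range(L):
        c = 0
        for m in range(L):
            if m != n and npk[n, m] > 0 and D[n, m] < lam:
                c += 1
        ptr[n + 1] = ptr[n] + c
    idx = np.empty(ptr[L], dtype=np.int64)
    k = 0
    for n in range(L):
        for m in range(L):
            if m != n and npk[n, m] > 0 and D[n, m] < lam:
                idx[k] = m
                k += 1
    return ptr, idx


@njit(cache=True)
def score_matrix(
    q_dist, q_prob, q_npk, q_D, q_ptr, q_idx,
    t_dist, t_prob, t_npk, t_D, t_ptr, t_idx,
    lam, sb1, sb2, sv1, sv2, sv3, db1, db2, dv1, dv2, dv3,
):
    """Protein-specific score matrix M[n, n'].

    M[n, n'] is the optimal monotone (gap-free-penalty) alignment of the
    contact partners of query residue n against those of template
    residue n', with cell scores given by the peak-product term.
    """
    Lq = q_npk.shape[0]
    Lt = t_npk.shape[0]
    M = np.zeros((Lq, Lt))
    # scratch DP table sized to the largest contact lists
    max_q = 0
    for n in range(Lq):
        c = q_ptr[n + 1] - q_ptr[n]
        if c > max_q:
            max_q = c
    max_t = 0
    for n in range(Lt):
        c = t_ptr[n + 1] - t_ptr[n]
        if c > max_t:
            max_t = c
    H = np.zeros((max_q + 1, max_t + 1))
    for n in range(Lq):
        cq0, cq1 = q_ptr[n], q_ptr[n + 1]
        nq_c = cq1 - cq0
        if nq_c == 0:
            continue
        for n2 in range(Lt):
            ct0, ct1 = t_ptr[n2], t_ptr[n2 + 1]
            nt_c = ct1 - ct0
            if nt_c == 0:
                continue
            for u in range(nq_c + 1):
                H[u, 0] = 0.0
            for v in range(nt_c + 1):
                H[0, v] = 0.0
            for u in range(1, nq_c + 1):
                m = q_idx[cq0 + u - 1]
                sep = abs(n - m)
                for v in range(1, nt_c + 1):
                    m2 = t_idx[ct0 + v - 1]
                    s = _pair_term(
                        q_dist[n, m], q_prob[n, m], q_npk[n, m],
                        t_dist[n2, m2], t_prob[n2, m2], t_npk[n2, m2],
                        q_D[n, m], t_D[n2, m2], sep, lam,
                        sb1, sb2, sv1, sv2, sv3, db1, db2, dv1, dv2, dv3,
                    )
                    best = H[u - 1, v - 1] + s
                    if H[u - 1, v] > best:
                        best = H[u - 1, v]
                    if H[u, v - 1] > best:
                        best = H[u, v - 1]
                    H[u, v] = best
            M[n, n2] = H[nq_c, nt_c]
    return M


@njit(cache=True)
def s_align_sum(
    pairs,
    q_dist, q_prob, q_npk, q_D,
    t_dist, t_prob, t_npk, t_D,
    lam, sb1, sb2, sv1, sv2, sv3, db1, db2, dv1, dv2, dv3,
):
    """Alignment score: sum of peak-product terms over ordered aligned pairs."""
    n_pairs = pairs.shape[0]
    total = 0.0
    for a in range(n_pairs):
        n, n2 = pairs[a, 0], pairs[a, 1]
        for b in range(n_pairs):
            if a == b:
                continue
            m, m2 = pairs[b, 0], pairs[b, 1]
            total += _pair_term(
                q_dist[n, m], q_prob[n, m], q_npk[n, m],
                t_dist[n2, m2], t_prob[n2, m2], t_npk[n2, m2],
                q_D[n, m], t_D[n2, m2], abs(n - m), lam,
                sb1, sb2, sv1, sv2, sv3, db1, db2, dv1, dv2, dv3,
            )
    return total


@njit(cache=True)
def s_tot_sum(pmax, npk, D, lam, sb1, sb2, sv1, sv2, sv3):
    """Reference score: sum over ordered query pairs of p_max * w_seq * w_cut.

    The cut weight is evaluated on the query side only.
    """
    L = pmax.shape[0]
    total = 0.0
    for n in range(L):
        for m in range(L):
            if n == m:
                continue
            if npk[n, m] == 0 or D[n, m] >= lam:
                continue
            total += pmax[n, m] * _w_seq(abs(n - m), sb1, sb2, sv1, sv2, sv3)
    return total
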