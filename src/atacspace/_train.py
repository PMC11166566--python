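"""Streaming SGD kernel for the joint cell / k-mer embedding.

Training examples are generated on the fly: per epoch, every usable event
contributes `examples_per_event` slots, consumed in random order. Each slot
samples an L-bp subsequence of its event, featurizes it (canonical k-mers +
hashed context pairs), draws one positive cell and K negative cells (cells
lacking the event, restricted to the positive's dataset and, when batch-aware,
its batch), and applies one hinge-ranking gradient step. Memory is constant in
the number of examples.

Optimizer: per-row Adagrad accumulator with a base learning rate decaying
linearly to zero over the total planned examples. Negative cells with zero
hinge are not updated; an example with zero loss updates nothing.

Compiled with numba; bit-reproducible for a fixed seed (single-threaded).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-6


@njit(cache=False, fastmath=True)
def _accessible(cell, pos_cells, lo, hi):
    """Binary search: is `cell` in the sorted slice pos_cells[lo:hi]?"""
    while lo < hi:
        mid = (lo + hi) // 2
        v = pos_cells[mid]
        if v == cell:
            return True
        if v < cell:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=False, fastmath=True)
def _apply_example(
    cell_emb, feat_emb, feat_rows, n_feat, rhs, negbuf, n_neg,
    margin, lr, cell_acc, feat_acc, adagrad,
):
    """One hinge-ranking SGD step. Returns (loss, n_zero_norm_pairs).

    Gradients are taken w.r.t. the un-normalized feature sum; because cosine
    similarity is scale-invariant this equals the chain through the
    1/M**P-normalized entity embedding.
    """
    d = cell_emb.shape[1]
    svec = np.zeros(d, dtype=np.float64)
    for i in range(n_feat):
        row = feat_rows[i]
        for j in range(d):
            svec[j] += feat_emb[row, j]
    s_norm = 0.0
    for j in range(d):
        s_norm += svec[j] * svec[j]
    s_norm = np.sqrt(s_norm)

    zero_flags = 0
    # cosine with positive
    p = cell_emb[rhs]
    p_norm = 0.0
    dot_p = 0.0
    for j in range(d):
        p_norm += p[j] * p[j]
        dot_p += svec[j] * p[j]
    p_norm = np.sqrt(p_norm)
    if s_norm == 0.0 or p_norm == 0.0:
        cos_p = 0.0
        zero_flags += 1
    else:
        cos_p = dot_p / (s_norm * p_norm)

    cos_n = np.empty(n_neg, dtype=np.float64)
    n_norms = np.empty(n_neg, dtype=np.float64)
    loss = 0.0
    n_active = 0
    for t in range(n_neg):
        c = cell_emb[negbuf[t]]
        nn = 0.0
        dt = 0.0
        for j in range(d):
            nn += c[j] * c[j]
            dt += svec[j] * c[j]
        nn = np.sqrt(nn)
        n_norms[t] = nn
        if s_norm == 0.0 or nn == 0.0:
            cos_n[t] = 0.0
            zero_flags += 1
        else:
            cos_n[t] = dt / (s_norm * nn)
        hinge = margin - cos_p + cos_n[t]
        if hinge > 0.0:
            loss += hinge
            n_active += 1
    loss /= n_neg
    if n_active == 0 or s_norm == 0.0:
        return loss, zero_flags

    inv_k = 1.0 / n_neg
    # gradient w.r.t. the feature sum s
    gs = np.zeros(d, dtype=np.float64)
    coef_p = -n_active * inv_k
    if p_norm > 0.0:
        a1 = coef_p / (s_norm * p_norm)
        a2 = -coef_p * cos_p / (s_norm * s_norm)
        for j in range(d):
            gs[j] += a1 * p[j] + a2 * svec[j]
        # gradient w.r.t. the positive cell
        b1 = coef_p / (s_norm * p_norm)
        b2 = -coef_p * cos_p / (p_norm * p_norm)
        gnorm2 = 0.0
        for j in range(d):
            gnorm2 += (b1 * svec[j] + b2 * p[j]) ** 2
        cell_acc[rhs] += gnorm2
        step = lr / np.sqrt(cell_acc[rhs] + _EPS) if adagrad else lr
        for j in range(d):
            cell_emb[rhs, j] -= np.float32(step * (b1 * svec[j] + b2 * p[j]))

    for t in range(n_neg):
        hinge = margin - cos_p + cos_n[t]
        if hinge <= 0.0 or n_norms[t] == 0.0:
            continue  # zero-hinge negatives are not updated
        c = cell_emb[negbuf[t]]
        a1 = inv_k / (s_norm * n_norms[t])
        a2 = -inv_k * cos_n[t] / (s_norm * s_norm)
        for j in range(d):
            gs[j] += a1 * c[j] + a2 * svec[j]
        b1 = inv_k / (s_norm * n_norms[t])
        b2 = -inv_k * cos_n[t] / (n_norms[t] * n_norms[t])
        gnorm2 = 0.0
        for j in range(d):
            gnorm2 += (b1 * svec[j] + b2 * c[j]) ** 2
        r = negbuf[t]
        cell_acc[r] += gnorm2
        step = lr / np.sqrt(cell_acc[r] + _EPS) if adagrad else lr
        for j in range(d):
            cell_emb[r, j] -= np.float32(step * (b1 * svec[j] + b2 * c[j]))

    # every feature occurrence receives the same gradient gs
    gnorm2 = 0.0
    for j in range(d):
        gnorm2 += gs[j] * gs[j]
    for i in range(n_feat):
        r = feat_rows[i]
        feat_acc[r] += gnorm2
        step = lr / np.sqrt(feat_acc[r] + _EPS) if adagrad else lr
        for j in range(d):
            feat_emb[r, j] -= np.float32(step * gs[j])
    return loss, zero_flags


@njit(cache=False)
def _shuffle(arr):
    for i in range(len(arr) - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = arr[i]
        arr[i] = arr[j]
        arr[j] = tmp


@njit(cache=False, fastmath=True)
def train_kernel(
    cell_emb, feat_emb,
    canon_table, rc_table,
    seq_codes, seq_off,
    pos_indptr, pos_cells,
    group_of_cell, pool_indptr, pool_cells,
    k, N, bucket, kmer_rows,
    L, epochs, examples_per_event, K_neg,
    margin, lr0, seed, adagrad,
):
    """Run the full streaming optimization in place.

    Returns (per-epoch mean loss, per-epoch skipped-example count,
    zero-norm-cosine flag count).
    """
    np.random.seed(seed)
    n_events = len(seq_off) - 1
    slots_per_epoch = n_events * examples_per_event
    total = epochs * slots_per_epoch

    codemask = (1 << (2 * k)) - 1
    shift2k = 2 * k
    maxm = L - k + 1
    max_pairs = 0
    if N >= 2:
        max_pairs = (maxm - N + 1) * (N * (N - 1)) // 2 if maxm >= N else 0
    rbuf = np.empty(maxm, dtype=np.int64)
    feat_rows = np.empty(maxm + max_pairs, dtype=np.int64)
    negbuf = np.empty(K_neg, dtype=np.int32)
    order = np.empty(slots_per_epoch, dtype=np.int64)

    cell_acc = np.zeros(cell_emb.shape[0], dtype=np.float64)
    feat_acc = np.zeros(feat_emb.shape[0], dtype=np.float64)

    epoch_loss = np.zeros(epochs, dtype=np.float64)
    epoch_skipped = np.zeros(epochs, dtype=np.int64)
    zero_flags = 0
    t_global = 0

    for epoch in range(epochs):
        idx = 0
        for e in range(n_events):
            for _ in range(examples_per_event):
                order[idx] = e
                idx += 1
        _shuffle(order)

        loss_sum = 0.0
        n_done = 0
        for slot in range(slots_per_epoch):
            e = order[slot]
            lr = lr0 * (1.0 - t_global / total)
            t_global += 1

            s0 = seq_off[e]
            slen = seq_off[e + 1] - s0
            if slen <= L:
                start = 0
                wlen = slen
            else:
                start = np.random.randint(0, slen - L + 1)
                wlen = L
            # rolling k-mer codes; windows with ambiguous bases skipped
            m = 0
            code = 0
            valid = 0
            for pos in range(wlen):
                c = seq_codes[s0 + start + pos]
                if c >= 4:
                    valid = 0
                    code = 0
                else:
                    code = ((code << 2) | c) & codemask
                    valid += 1
                    if valid >= k:
                        rbuf[m] = code
                        m += 1
            if m == 0:
                epoch_skipped[epoch] += 1
                continue
            n_feat = 0
            for i in range(m):
                feat_rows[n_feat] = canon_table[rbuf[i]]
                n_feat += 1
            if N >= 2 and m >= N:
                for i in range(m - N + 1):
                    for p in range(N - 1):
                        for q in range(p + 1, N):
                            a = rbuf[i + p]
                            b = rbuf[i + q]
                            c1 = (a << shift2k) | b
                            c2 = (rc_table[b] << shift2k) | rc_table[a]
                            pc = c1 if c1 < c2 else c2
                            feat_rows[n_feat] = kmer_rows + pc % bucket
                            n_feat += 1

            e0 = pos_indptr[e]
            e1 = pos_indptr[e + 1]
            npos = e1 - e0
            if npos == 0:
                epoch_skipped[epoch] += 1
                continue
            rhs = pos_cells[e0 + np.random.randint(0, npos)]

            g = group_of_cell[rhs]
            p0 = pool_indptr[g]
            p1 = pool_indptr[g + 1]
            psize = p1 - p0
            npos_in_pool = 0
            for j in range(e0, e1):
                if group_of_cell[pos_cells[j]] == g:
                    npos_in_pool += 1
            eligible = psize - npos_in_pool
            if eligible <= 0:
                epoch_skipped[epoch] += 1
                continue
            if eligible <= K_neg:
                nn = 0
                for j in range(p0, p1):
                    c = pool_cells[j]
                    if not _accessible(c, pos_cells, e0, e1):
                        negbuf[nn] = c
                        nn += 1
            else:
                nn = 0
                while nn < K_neg:
                    c = pool_cells[p0 + np.random.randint(0, psize)]
                    if _accessible(c, pos_cells, e0, e1):
                        continue
                    dup = False
                    for u in range(nn):
                        if negbuf[u] == c:
                            dup = True
                            break
                    if not dup:
                        negbuf[nn] = c
                        nn += 1

            loss, zf = _apply_example(
                cell_emb, feat_emb, feat_rows, n_feat, rhs, negbuf, nn,
                margin, lr, cell_acc, feat_acc, adagrad,
            )
            zero_flags += zf
            loss_sum += loss
            n_done += 1
        if n_done > 0:
            epoch_loss[epoch] = loss_sum / n_done
    return epoch_loss, epoch_skipped, zero_flags
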