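"""Independent straight-line oracles used to cross-check the implementation.

Everything here is written as plain index loops / brute force, deliberately
avoiding the vectorized code paths (and, for AUROC/AP, the sklearn-backed
implementations) they are used to verify.
"""

from __future__ import annotations

import math

import numpy as np


def squash_oracle(x):
    """Scalar transcription of the squash function."""
    n2 = sum(float(v) ** 2 for v in x)
    if n2 == 0:
        return [0.0 for _ in x]
    n = math.sqrt(n2)
    return [(n2 / (1 + n2)) * (float(v) / n) for v in x]


def routing_oracle(u, W, iterations):
    """Scalar-loop transcription of dynamic routing by agreement.

    u: (N_P, O_P) nested lists/array; W: (N_P, N_S, O_S, O_P).
    Returns (v, s, c) as nested lists; c is the scalar coupling table.
    """
    u = [list(map(float, row)) for row in np.asarray(u)]
    W = np.asarray(W, dtype=float)
    n_p = len(u)
    n_s, o_s, o_p = W.shape[1], W.shape[2], W.shape[3]
    # predictions u_hat[i][j] = W_ij @ u_i
    u_hat = [[[sum(W[i][j][k][p] * u[i][p] for p in range(o_p))
               for k in range(o_s)] for j in range(n_s)] for i in range(n_p)]
    logits = [[0.0] * n_s for _ in range(n_p)]
    v = s = c = None
    for it in range(iterations):
        c = []
        for i in range(n_p):
            mx = max(logits[i])
            exps = [math.exp(l - mx) for l in logits[i]]
            tot = sum(exps)
            c.append([e / tot for e in exps])
        s = [[sum(c[i][j] * u_hat[i][j][k] for i in range(n_p))
              for k in range(o_s)] for j in range(n_s)]
        v = [squash_oracle(s[j]) for j in range(n_s)]
        if it < iterations - 1:
            for i in range(n_p):
                for j in range(n_s):
                    logits[i][j] += sum(u_hat[i][j][k] * v[j][k] for k in range(o_s))
    return v, s, c


def gini_pairwise_oracle(z):
    """Gini as the normalized mean absolute pairwise difference."""
    z = [float(v) for v in z]
    n = len(z)
    mean = sum(z) / n
    total = 0.0
    for a in z:
        for b in z:
            total += abs(a - b)
    return total / (2 * n * n * mean)


def quantile_oracle(z, q):
    """Rank-interpolated quantile, written independently of numpy."""
    zs = sorted(float(v) for v in z)
    n = len(zs)
    if n == 1:
        return zs[0]
    pos = q * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return zs[lo] * (1 - frac) + zs[hi] * frac


def palma_oracle(z):
    return quantile_oracle(z, 0.9) / quantile_oracle(z, 0.4)


def auroc_pair_oracle(scores, labels):
    """Exhaustive pair counting with half-credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def average_precision_oracle(scores, labels):
    """Step-wise precision-recall summation over distinct score thresholds.

    AP = sum_k (R_k - R_{k-1}) * P_k over thresholds descending; tied scores
    enter together (the convention average_precision_score uses).
    """
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    n_pos = sum(labels)
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            j += 1
        for k in range(i, j):
            if labels[order[k]] == 1:
                tp += 1
            else:
                fp += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def cd1_oracle(weights, vbias, hbias, batch, sign, lr, seed):
    """Loop transcription of the single-step contrastive divergence update."""
    rng = np.random.default_rng(seed)
    batch = np.asarray(batch, dtype=float)
    n, nv = batch.shape
    nh = len(hbias)
    sig = lambda t: 1.0 / (1.0 + math.exp(-t))
    ph0 = [[sig(sum(batch[b][i] * weights[i][j] for i in range(nv)) + hbias[j])
            for j in range(nh)] for b in range(n)]
    # the implementation samples h0 with one vectorized rng.random call
    unif = rng.random((n, nh))
    h0 = [[1.0 if unif[b][j] < ph0[b][j] else 0.0 for j in range(nh)] for b in range(n)]
    pv1 = [[sig(sum(h0[b][j] * weights[i][j] for j in range(nh)) + vbias[i])
            for i in range(nv)] for b in range(n)]
    ph1 = [[sig(sum(pv1[b][i] * weights[i][j] for i in range(nv)) + hbias[j])
            for j in range(nh)] for b in range(n)]
    dw = [[sum(batch[b][i] * ph0[b][j] - pv1[b][i] * ph1[b][j] for b in range(n)) / n
           for j in range(nh)] for i in range(nv)]
    dvb = [sum(batch[b][i] - pv1[b][i] for b in range(n)) / n for i in range(nv)]
    dhb = [sum(ph0[b][j] - ph1[b][j] for b in range(n)) / n for j in range(nh)]
    w2 = [[weights[i][j] + sign * lr * dw[i][j] for j in range(nh)] for i in range(nv)]
    vb2 = [vbias[i] + sign * lr * dvb[i] for i in range(nv)]
    hb2 = [hbias[j] + sign * lr * dhb[j] for j in range(nh)]
    return np.array(w2), np.array(vb2), np.array(hb2)


def summed_couplings_oracle(c, j):
    """Index-loop version of the M_j contribution vector."""
    n_p, _, o_s = np.asarray(c).shape
    return [sum(float(c[i][j][l]) for l in range(o_s)) for i in range(n_p)]


def nre_oracle(x, x_hat):
    """Elementwise-loop normalized reconstruction error."""
    xf = np.asarray(x, dtype=float).ravel()
    rf = np.asarray(x_hat, dtype=float).ravel()
    mse = sum((a - b) ** 2 for a, b in zip(xf, rf)) / len(xf)
    norm = math.sqrt(sum(a * a for a in xf))
    return mse / norm
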