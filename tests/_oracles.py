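"""Independent straight-line oracles used to cross-check the implementation.

Everything here is written with explicit Python loops and no shared code
with the package, so agreement is evidence of correctness rather than of
shared bugs.
"""

from __future__ import annotations

import math

import numpy as np


def mm(X, Y):
    """Matrix product by explicit triple loop."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    out = np.zeros((X.shape[0], Y.shape[1]))
    for i in range(X.shape[0]):
        for j in range(Y.shape[1]):
            s = 0.0
            for k in range(X.shape[1]):
                s += X[i, k] * Y[k, j]
            out[i, j] = s
    return out


def naive_normalize_bipartite(W):
    W = np.asarray(W, float)
    out = np.zeros_like(W)
    for i in range(W.shape[0]):
        for j in range(W.shape[1]):
            r = W[i, :].sum()
            c = W[:, j].sum()
            if r > 0 and c > 0:
                out[i, j] = W[i, j] / math.sqrt(r * c)
    return out


def naive_normalize_similarity(S):
    S = np.asarray(S, float)
    out = np.zeros_like(S)
    for i in range(S.shape[0]):
        for j in range(S.shape[1]):
            di = S[i, :].sum()
            dj = S[j, :].sum()
            if di > 0 and dj > 0:
                out[i, j] = S[i, j] / math.sqrt(di * dj)
    return out


def naive_propagation(A, B, S_S, S_M, S_D, alpha=0.4, cutoff=1e-6, max_iter=1000):
    """Literal transcription of the two-matrix iterative update."""
    An = naive_normalize_bipartite(A)
    Bn = naive_normalize_bipartite(B)
    Ss = naive_normalize_similarity(S_S)
    Sm = naive_normalize_similarity(S_M)
    Sd = naive_normalize_similarity(S_D)
    w_sm = An.copy()
    w_md = Bn.copy()
    for _ in range(max_iter):
        bracket = mm(mm(mm(Sm, w_md), Sd), w_md.T)
        new_sm = alpha * mm(w_sm, bracket) + (1 - alpha) * An
        bracket2 = mm(mm(mm(w_sm.T, Ss), w_sm), Sm)
        new_md = alpha * mm(bracket2, w_md) + (1 - alpha) * Bn
        d_sm = np.abs(new_sm - w_sm).sum()
        d_md = np.abs(new_md - w_md).sum()
        w_sm, w_md = new_sm, new_md
        if d_sm < cutoff and d_md < cutoff:
            break
    w_sd = mm(mm(w_sm, Sm), w_md)
    return w_sm, w_md, w_sd


def naive_nbi(A, query):
    """Two-step resource allocation traced edge by edge for one query SM."""
    A = np.asarray(A, float)
    ns, nm = A.shape
    resource_mi = {m: A[query, m] for m in range(nm)}
    resource_sm = {s: 0.0 for s in range(ns)}
    for m in range(nm):
        neighbors = [s for s in range(ns) if A[s, m] == 1]
        if neighbors and resource_mi[m] > 0:
            share = resource_mi[m] / len(neighbors)
            for s in neighbors:
                resource_sm[s] += share
    final = {m: 0.0 for m in range(nm)}
    for s in range(ns):
        neighbors = [m for m in range(nm) if A[s, m] == 1]
        if neighbors and resource_sm[s] > 0:
            share = resource_sm[s] / len(neighbors)
            for m in neighbors:
                final[m] += share
    return np.array([final[m] for m in range(nm)])


def pairwise_auc(test_score, candidate_scores):
    """Rank percentile by explicit pairwise comparison with half-credit ties."""
    wins = 0.0
    for c in candidate_scores:
        if test_score > c:
            wins += 1.0
        elif test_score == c:
            wins += 0.5
    return wins / len(candidate_scores)
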