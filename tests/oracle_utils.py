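"""Independent brute-force oracles shared by the unit and acceptance tests.

Each function re-implements a pipeline formula as explicit double loops,
kept deliberately independent of the package implementation.
"""

import numpy as np

from eegcorr.graphs import EPS, TOP_K_NEIGHBORS


def oracle_dist(coords, tau, k):
    N = len(coords)
    A = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            d = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
            A[i, j] = np.exp(-(d**2) / tau) if d <= k else 0.0
    return A


def oracle_pair_corr(X, i, j, normalized):
    ci = X[i] - X[i].mean()
    cj = X[j] - X[j].mean()
    raw = float(ci @ cj)
    if not normalized:
        return raw
    return raw / max(np.linalg.norm(ci) * np.linalg.norm(cj), EPS)


def oracle_topk(w_row, i, k=TOP_K_NEIGHBORS):
    others = [j for j in range(len(w_row)) if j != i]
    return sorted(others, key=lambda j: (-abs(w_row[j]), j))[:k]


def oracle_corr(X):
    N = X.shape[0]
    W = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            if i != j:
                W[i, j] = oracle_pair_corr(X, i, j, normalized=True)
    A = np.zeros((N, N))
    for i in range(N):
        keep = oracle_topk(W[i], i) if N > TOP_K_NEIGHBORS else [j for j in range(N) if j != i]
        for j in keep:
            A[i, j] = W[i, j]
    return A


def oracle_dtf(X):
    N = X.shape[0]
    C = np.zeros((N, N))
    Wn = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            C[i, j] = oracle_pair_corr(X, i, j, normalized=False)
            if i != j:
                Wn[i, j] = oracle_pair_corr(X, i, j, normalized=True)
    A = np.zeros((N, N))
    for i in range(N):
        keep = oracle_topk(Wn[i], i) if N - 1 > TOP_K_NEIGHBORS else [j for j in range(N) if j != i]
        for j in keep:
            denom = sum(C[i, m] ** 2 for m in range(N) if m not in (i, j))
            A[i, j] = C[i, j] / max(denom, EPS)
    return A


def oracle_normalize(A, self_loops=True):
    N = A.shape[0]
    M = A + np.eye(N) if self_loops else A.copy()
    deg = M.sum(axis=1)
    out = np.zeros_like(M)
    for i in range(N):
        for j in range(N):
            out[i, j] = M[i, j] / (np.sqrt(deg[i]) * np.sqrt(deg[j]))
    return out


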