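"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops, deliberately sharing no code
path with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def frobenius_oracle(window) -> float:
    total = 0.0
    for row in window:
        for v in row:
            total += float(v) * float(v)
    return math.sqrt(total)


def features_oracle(pixels: np.ndarray, m: int, stride: int) -> tuple[list, list]:
    """Per-center per-channel window norms by explicit looping."""
    M, N, K = pixels.shape
    vectors, coords = [], []
    for i in range(m, M - m, stride):
        for j in range(m, N - m, stride):
            vec = [
                frobenius_oracle(pixels[i - m : i + m + 1, j - m : j + m + 1, k])
                for k in range(K)
            ]
            vectors.append(vec)
            coords.append((i, j))
    return vectors, coords


def entropy_oracle(U: np.ndarray) -> float:
    L, c = U.shape
    total = 0.0
    for n in range(L):
        for j in range(c):
            u = float(U[n, j])
            if u > 0:
                total += u * math.log(u)
    return -total / L


def maxmin_relation_oracle(U: np.ndarray) -> np.ndarray:
    L, c = U.shape
    R = np.zeros((L, L))
    for a in range(L):
        for b in range(L):
            best = 0.0
            for i in range(c):
                best = max(best, min(float(U[a, i]), float(U[b, i])))
            R[a, b] = best
    for a in range(L):
        R[a, a] = 1.0
    return R


def unweighted_cc_oracle(A: np.ndarray) -> float:
    n = A.shape[0]
    vals = []
    for i in range(n):
        k = sum(int(A[i, j]) for j in range(n))
        if k < 2:
            vals.append(0.0)
            continue
        tri = 0.0
        for j in range(n):
            for l in range(n):
                tri += A[i, j] * A[j, l] * A[l, i]
        vals.append(tri / (k * (k - 1)))
    return sum(vals) / n


def weighted_cc_oracle(W: np.ndarray, tau: float = 0.0) -> float:
    n = W.shape[0]
    vals = []
    for i in range(n):
        k = sum(1 for j in range(n) if W[i, j] > tau)
        if k < 2:
            vals.append(0.0)
            continue
        acc = 0.0
        for j in range(n):
            if W[i, j] <= tau:
                continue
            for l in range(n):
                if W[i, l] <= tau or W[j, l] <= tau:
                    continue
                acc += (float(W[i, j]) * float(W[i, l]) * float(W[j, l])) ** (1.0 / 3.0)
        vals.append(acc / (k * (k - 1)))
    return sum(vals) / n


def floyd_warshall_oracle(
    W: np.ndarray, transform: str = "reciprocal", tau: float = 0.0
) -> np.ndarray:
    n = W.shape[0]
    D = np.full((n, n), math.inf)
    for i in range(n):
        D[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > tau:
                D[i, j] = 1.0 / W[i, j] if transform == "reciprocal" else 1.0 - W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def cp_oracle(W: np.ndarray, transform: str = "reciprocal", tau: float = 0.0) -> float:
    D = floyd_warshall_oracle(W, transform, tau)
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                total += D[i, j]
    return total / (n * (n - 1))


def nearest_center_oracle(X: np.ndarray, V: np.ndarray) -> list[int]:
    labels = []
    for x in X:
        dists = [math.dist(list(x), list(v)) for v in V]
        labels.append(int(np.argmin(dists)))
    return labels
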