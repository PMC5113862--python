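"""Numba kernels for the sequential chain recursions.

All kernels take the transition matrix P with convention P[a, b] = P(next =
a | prev = b) (column-stochastic) and a scaled emission-likelihood matrix B
of shape (M, T): B[:, t] = exp(logB[:, t] - max_a logB[a, t]).  The dropped
per-bin constants are added back by the caller.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def forward(P, B, initial):
    M, T = B.shape
    alpha = np.empty((M, T))
    c = np.empty(T)
    s = 0.0
    for a in range(M):
        alpha[a, 0] = initial[a] * B[a, 0]
        s += alpha[a, 0]
    c[0] = s
    for a in range(M):
        alpha[a, 0] /= s
    for t in range(1, T):
        s = 0.0
        for a in range(M):
            acc = 0.0
            for b in range(M):
                acc += P[a, b] * alpha[b, t - 1]
            alpha[a, t] = B[a, t] * acc
            s += alpha[a, t]
        c[t] = s
        for a in range(M):
            alpha[a, t] /= s
    return alpha, c


@njit(cache=True)
def backward(P, B, c):
    M, T = B.shape
    beta = np.empty((M, T))
    for a in range(M):
        beta[a, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        for b in range(M):
            acc = 0.0
            for a in range(M):
                acc += P[a, b] * B[a, t + 1] * beta[a, t + 1]
            beta[b, t] = acc / c[t + 1]
    return beta


@njit(cache=True)
def xi_sums(P, B, c, alpha, beta):
    """Sum over t of the pairwise posteriors xi_t[a, b] = P(z_{t+1}=a, z_t=b)."""
    M, T = B.shape
    out = np.zeros((M, M))
    for t in range(T - 1):
        for a in range(M):
            w = B[a, t + 1] * beta[a, t + 1] / c[t + 1]
            for b in range(M):
                out[a, b] += P[a, b] * alpha[b, t] * w
    return out


@njit(cache=True)
def viterbi_path(logP, logB, log_initial):
    M, T = logB.shape
    delta = log_initial + logB[:, 0]
    back = np.zeros((T, M), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(M)
        for a in range(M):
            best, arg = -np.inf, 0
            for b in range(M):
                v = delta[b] + logP[a, b]
                if v > best:  # strict: ties keep the lowest prev index
                    best, arg = v, b
            new[a] = best + logB[a, t]
            back[t, a] = arg
        delta = new
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta)
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
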