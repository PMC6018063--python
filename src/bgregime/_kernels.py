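"""Numba-compiled inner loops for the hidden Markov machinery.

The scaled forward/backward recursions and the Viterbi dynamic programme are
O(n k^2) with a sequential dependence over time, which rules out plain numpy
vectorization; these kernels keep the k=1..9 model-selection sweeps over
hundreds of year-long series tractable.

Emission densities enter as a per-row max-shifted matrix: ``b[t, j] =
exp(logb[t, j] - rowmax[t])`` with ``rowmax[t] = max_j logb[t, j]``, so the
scaled recursions never underflow and the exact log-likelihood is recovered
as sum(log c_t) + sum(rowmax).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_backward(b, rowmax, delta, gamma_mat):
    """One E-step: scaled forward-backward over shifted emissions.

    Returns (loglik, posterior (n,k), xi_sum (k,k)) where posterior[t, j] =
    P(state_t = j | data) and xi_sum accumulates expected transition counts.
    """
    n, k = b.shape
    alpha = np.empty((n, k))
    c = np.empty(n)
    # forward
    s = 0.0
    for j in range(k):
        alpha[0, j] = delta[j] * b[0, j]
        s += alpha[0, j]
    c[0] = s
    for j in range(k):
        alpha[0, j] /= s
    for t in range(1, n):
        s = 0.0
        for j in range(k):
            a = 0.0
            for i in range(k):
                a += alpha[t - 1, i] * gamma_mat[i, j]
            a *= b[t, j]
            alpha[t, j] = a
            s += a
        c[t] = s
        for j in range(k):
            alpha[t, j] /= s
    loglik = 0.0
    for t in range(n):
        loglik += np.log(c[t]) + rowmax[t]
    # backward
    beta = np.empty((n, k))
    for j in range(k):
        beta[n - 1, j] = 1.0
    for t in range(n - 2, -1, -1):
        for i in range(k):
            a = 0.0
            for j in range(k):
                a += gamma_mat[i, j] * b[t + 1, j] * beta[t + 1, j]
            beta[t, i] = a / c[t + 1]
    # posteriors and transition counts
    post = np.empty((n, k))
    for t in range(n):
        s = 0.0
        for j in range(k):
            post[t, j] = alpha[t, j] * beta[t, j]
            s += post[t, j]
        for j in range(k):
            post[t, j] /= s
    xi_sum = np.zeros((k, k))
    for t in range(n - 1):
        for i in range(k):
            for j in range(k):
                xi_sum[i, j] += (
                    alpha[t, i] * gamma_mat[i, j] * b[t + 1, j] * beta[t + 1, j] / c[t + 1]
                )
    return loglik, post, xi_sum


@njit(cache=True)
def forward_loglik_kernel(b, rowmax, delta, gamma_mat):
    """Scaled forward recursion returning only the log-likelihood."""
    n, k = b.shape
    prev = np.empty(k)
    cur = np.empty(k)
    s = 0.0
    for j in range(k):
        prev[j] = delta[j] * b[0, j]
        s += prev[j]
    loglik = np.log(s) + rowmax[0]
    for j in range(k):
        prev[j] /= s
    for t in range(1, n):
        s = 0.0
        for j in range(k):
            a = 0.0
            for i in range(k):
                a += prev[i] * gamma_mat[i, j]
            a *= b[t, j]
            cur[j] = a
            s += a
        loglik += np.log(s) + rowmax[t]
        for j in range(k):
            prev[j] = cur[j] / s
    return loglik


@njit(cache=True)
def viterbi_kernel(log_delta, log_gamma, logb):
    """Most probable state path; ties resolved toward the lower state index."""
    n, k = logb.shape
    dp = np.empty(k)
    ptr = np.empty((n, k), dtype=np.int64)
    for j in range(k):
        dp[j] = log_delta[j] + logb[0, j]
    for t in range(1, n):
        new = np.empty(k)
        for j in range(k):
            best = dp[0] + log_gamma[0, j]
            arg = 0
            for i in range(1, k):
                v = dp[i] + log_gamma[i, j]
                if v > best:  # strict: ties keep the lower predecessor
                    best = v
                    arg = i
            new[j] = best + logb[t, j]
            ptr[t, j] = arg
        dp = new
    best = dp[0]
    state = 0
    for j in range(1, k):
        if dp[j] > best:
            best = dp[j]
            state = j
    path = np.empty(n, dtype=np.int64)
    path[n - 1] = state
    for t in range(n - 1, 0, -1):
        state = ptr[t, state]
        path[t - 1] = state
    return path
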