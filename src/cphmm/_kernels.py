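"""Log-domain forward-backward and Viterbi recursions.

Compiled with numba because chains span up to ~10^5 bins and the EM loop
revisits them many times.  All probabilities are handled in log space to
avoid underflow over long chains; state tie-breaks in Viterbi are strict
(the lowest state index wins), so decoding is deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _logsumexp(v):
    m = v[0]
    for i in range(1, v.shape[0]):
        if v[i] > m:
            m = v[i]
    if m == -np.inf:
        return -np.inf
    s = 0.0
    for i in range(v.shape[0]):
        s += np.exp(v[i] - m)
    return m + np.log(s)


@njit(cache=False)
def forward_log(log_a, log_pi, log_e):
    """Forward variables and total data log-likelihood for one chain."""
    T, S = log_e.shape
    alpha = np.empty((T, S))
    for j in range(S):
        alpha[0, j] = log_pi[j] + log_e[0, j]
    work = np.empty(S)
    for t in range(1, T):
        for k in range(S):
            for j in range(S):
                work[j] = alpha[t - 1, j] + log_a[j, k]
            alpha[t, k] = _logsumexp(work) + log_e[t, k]
    return alpha, _logsumexp(alpha[T - 1])


@njit(cache=False)
def backward_log(log_a, log_e):
    T, S = log_e.shape
    beta = np.zeros((T, S))
    work = np.empty(S)
    for t in range(T - 2, -1, -1):
        for j in range(S):
            for k in range(S):
                work[k] = log_a[j, k] + log_e[t + 1, k] + beta[t + 1, k]
            beta[t, j] = _logsumexp(work)
    return beta


@njit(cache=False)
def expected_counts(log_a, log_pi, log_e):
    """E-step sufficient statistics for one chain.

    Returns (xi_sum, gamma0, loglik): expected transition counts summed over
    time, the posterior state distribution at the first bin, and the chain
    log-likelihood.
    """
    T, S = log_e.shape
    alpha, loglik = forward_log(log_a, log_pi, log_e)
    beta = backward_log(log_a, log_e)
    xi = np.zeros((S, S))
    for t in range(T - 1):
        for j in range(S):
            for k in range(S):
                xi[j, k] += np.exp(
                    alpha[t, j] + log_a[j, k] + log_e[t + 1, k]
                    + beta[t + 1, k] - loglik
                )
    gamma0 = np.empty(S)
    for j in range(S):
        gamma0[j] = np.exp(alpha[0, j] + beta[0, j] - loglik)
    return xi, gamma0, loglik


@njit(cache=False)
def viterbi_log(log_a, log_pi, log_e):
    """Most probable state path; ties resolved toward the lower state index."""
    T, S = log_e.shape
    delta = np.empty((T, S))
    psi = np.zeros((T, S), dtype=np.int64)
    for j in range(S):
        delta[0, j] = log_pi[j] + log_e[0, j]
    for t in range(1, T):
        for k in range(S):
            best = delta[t - 1, 0] + log_a[0, k]
            arg = 0
            for j in range(1, S):
                v = delta[t - 1, j] + log_a[j, k]
                if v > best:
                    best = v
                    arg = j
            delta[t, k] = best + log_e[t, k]
            psi[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for j in range(1, S):
        if delta[T - 1, j] > best:
            best = delta[T - 1, j]
            arg = j
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
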