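"""Numba kernels for the ordered three-state Gaussian HMM.

States advance left to right only (1->1, 1->2, 2->2, 2->3, 3->3); the
chain starts in state 1. Missing days contribute a transition-only step
(no emission). All computations are in log space.
"""

import numpy as np
from numba import njit

_LOG2PI = np.log(2.0 * np.pi)


@njit(cache=True, error_model="numpy")
def _log_trans(q1, q2):  # pragma: no cover - numba
    lt = np.full((3, 3), -np.inf)
    lt[0, 0] = np.log1p(-q1)
    lt[0, 1] = np.log(q1)
    lt[1, 1] = np.log1p(-q2)
    lt[1, 2] = np.log(q2)
    lt[2, 2] = 0.0
    return lt


@njit(cache=True, error_model="numpy")
def _emis(y, beta, sigma):  # pragma: no cover - numba
    out = np.empty(3)
    for k in range(3):
        z = (y - beta[k]) / sigma[k]
        out[k] = -0.5 * (z * z + _LOG2PI) - np.log(sigma[k])
    return out


@njit(cache=True, error_model="numpy")
def _lse3(a):  # pragma: no cover - numba
    m = max(a[0], max(a[1], a[2]))
    if m == -np.inf:
        return -np.inf
    return m + np.log(np.exp(a[0] - m) + np.exp(a[1] - m) + np.exp(a[2] - m))


@njit(cache=True, error_model="numpy")
def _lse2(a, b):  # pragma: no cover - numba
    if a == -np.inf and b == -np.inf:
        return -np.inf
    m = a if a > b else b
    return m + np.log(np.exp(a - m) + np.exp(b - m))


@njit(cache=True, error_model="numpy")
def forward_loglik(y, obs, beta, sigma, q1, q2):  # pragma: no cover - numba
    """Marginal log-likelihood by the forward algorithm (left-to-right
    structure exploited: only {1->1, 1->2, 2->2, 2->3, 3->3} transitions)."""
    T = y.shape[0]
    l11 = np.log1p(-q1)
    l12 = np.log(q1)
    l22 = np.log1p(-q2)
    l23 = np.log(q2)
    c0 = -0.5 * _LOG2PI
    ls1 = np.log(sigma[0])
    ls2 = np.log(sigma[1])
    ls3 = np.log(sigma[2])
    a1 = 0.0
    a2 = -np.inf
    a3 = -np.inf
    if obs[0]:
        z = (y[0] - beta[0]) / sigma[0]
        a1 += c0 - 0.5 * z * z - ls1
    for t in range(1, T):
        n1 = a1 + l11
        n2 = _lse2(a1 + l12, a2 + l22)
        n3 = _lse2(a2 + l23, a3)
        if obs[t]:
            z = (y[t] - beta[0]) / sigma[0]
            n1 += c0 - 0.5 * z * z - ls1
            z = (y[t] - beta[1]) / sigma[1]
            n2 += c0 - 0.5 * z * z - ls2
            z = (y[t] - beta[2]) / sigma[2]
            n3 += c0 - 0.5 * z * z - ls3
        a1, a2, a3 = n1, n2, n3
    m = max(a1, max(a2, a3))
    return m + np.log(np.exp(a1 - m) + np.exp(a2 - m) + np.exp(a3 - m))


@njit(cache=True, error_model="numpy")
def forward_backward(y, obs, beta, sigma, q1, q2):  # pragma: no cover - numba
    """Smoothed state probabilities gamma[t, k] = P(state_t = k | y)."""
    T = y.shape[0]
    lt = _log_trans(q1, q2)
    la = np.empty((T, 3))
    alpha = np.full(3, -np.inf)
    alpha[0] = 0.0
    if obs[0]:
        alpha += _emis(y[0], beta, sigma)
    la[0] = alpha
    tmp = np.empty(3)
    for t in range(1, T):
        new = np.empty(3)
        for j in range(3):
            for i in range(3):
                tmp[i] = la[t - 1, i] + lt[i, j]
            new[j] = _lse3(tmp)
        if obs[t]:
            new += _emis(y[t], beta, sigma)
        la[t] = new
    lb = np.zeros((T, 3))
    for t in range(T - 2, -1, -1):
        e = _emis(y[t + 1], beta, sigma) if obs[t + 1] else np.zeros(3)
        for i in range(3):
            for j in range(3):
                tmp[j] = lt[i, j] + e[j] + lb[t + 1, j]
            lb[t, i] = _lse3(tmp)
    gamma = np.empty((T, 3))
    for t in range(T):
        g = la[t] + lb[t]
        norm = _lse3(g)
        for k in range(3):
            gamma[t, k] = np.exp(g[k] - norm)
    return gamma


@njit(cache=True, error_model="numpy")
def ffbs_path(y, obs, beta, sigma, q1, q2, u):  # pragma: no cover - numba
    """One posterior draw of the state path (forward filter, backward
    sample); ``u`` is a vector of T uniforms."""
    T = y.shape[0]
    lt = _log_trans(q1, q2)
    la = np.empty((T, 3))
    alpha = np.full(3, -np.inf)
    alpha[0] = 0.0
    if obs[0]:
        alpha += _emis(y[0], beta, sigma)
    la[0] = alpha
    tmp = np.empty(3)
    for t in range(1, T):
        new = np.empty(3)
        for j in range(3):
            for i in range(3):
                tmp[i] = la[t - 1, i] + lt[i, j]
            new[j] = _lse3(tmp)
        if obs[t]:
            new += _emis(y[t], beta, sigma)
        la[t] = new
    states = np.empty(T, dtype=np.int64)
    # sample final state
    w = la[T - 1] - _lse3(la[T - 1])
    states[T - 1] = _sample3(np.exp(w), u[T - 1])
    for t in range(T - 2, -1, -1):
        j = states[t + 1]
        for i in range(3):
            tmp[i] = la[t, i] + lt[i, j]
        wn = tmp - _lse3(tmp)
        states[t] = _sample3(np.exp(wn), u[t])
    return states


@njit(cache=True, error_model="numpy")
def _sample3(p, u):  # pragma: no cover - numba
    s = p[0] + p[1] + p[2]
    c = 0.0
    for k in range(3):
        c += p[k] / s
        if u <= c:
            return k
    return 2


@njit(cache=True, error_model="numpy")
def _log_posterior(th, y, obs, m0, beta_sd, off_mean,
                   sig_scale, qa, qb):  # pragma: no cover - numba
    """Log posterior density in the unconstrained parameterization.

    th = [beta1, beta3, u, log s1, log s2, log s3, logit q1, logit q2],
    beta2 = max(beta1, beta3) + exp(u). Includes transform Jacobians.
    """
    b1, b3, u = th[0], th[1], th[2]
    b2 = max(b1, b3) + np.exp(u)
    beta = np.array([b1, b2, b3])
    sigma = np.exp(th[3:6])
    q1 = 1.0 / (1.0 + np.exp(-th[6]))
    q2 = 1.0 / (1.0 + np.exp(-th[7]))
    lp = forward_loglik(y, obs, beta, sigma, q1, q2)
    lp += -0.5 * ((b1 - m0) ** 2 + (b3 - m0) ** 2) / beta_sd ** 2
    lp += -0.5 * (b2 - m0 - off_mean) ** 2 / beta_sd ** 2 + u
    for j in range(3, 6):
        s = np.exp(th[j])
        lp += -0.5 * s * s / (sig_scale * sig_scale) + th[j]
    for j in range(6, 8):
        lq = -np.log1p(np.exp(-th[j]))
        l1q = -np.log1p(np.exp(th[j]))
        lp += (qa - 1.0) * lq + (qb - 1.0) * l1q + lq + l1q
    return lp


@njit(cache=True, error_model="numpy")
def run_chain(y, obs, init, m0, beta_sd, off_mean, sig_scale, qa, qb,
              warmup, iters, thin, seed):  # pragma: no cover - numba
    """Component-wise adaptive Metropolis; adaptation during warmup only.

    Per-coordinate proposal scales are tuned toward a 0.44 acceptance
    rate and frozen after warmup, so retained draws target the exact
    posterior. Returns (iters, 8) unconstrained draws.
    """
    np.random.seed(seed)
    d = 8
    th = init.copy()
    lp = _log_posterior(th, y, obs, m0, beta_sd, off_mean, sig_scale, qa, qb)
    scales = np.full(d, 0.2)
    out = np.empty((iters, d))
    total = warmup + iters * thin
    for it in range(total):
        for j in range(d):
            old = th[j]
            th[j] = old + scales[j] * np.random.normal()
            lpp = _log_posterior(th, y, obs, m0, beta_sd, off_mean,
                                 sig_scale, qa, qb)
            if np.log(np.random.random()) < lpp - lp:
                lp = lpp
                a = 1.0
            else:
                th[j] = old
                a = 0.0
            if it < warmup:
                step = min(0.25, 5.0 / np.sqrt(it + 1.0))
                scales[j] *= np.exp(step * (a - 0.44))
        if it >= warmup and (it - warmup) % thin == thin - 1:
            out[(it - warmup) // thin] = th
    return out
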