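"""Continuous-time correlated random walk (integrated Ornstein-Uhlenbeck).

The animal's velocity on each planar axis follows a stationary OU process
with mean-reversion rate ``theta`` (1/h) and stationary SD ``zeta`` (km/h);
position is the integral of velocity. Both axes are independent and share
parameters. Measurement error is fixed at zero: collar GPS error is small
relative to hourly displacements, so observed positions are treated as
exact and the likelihood conditions on the first fix with the velocity at
its stationary distribution.

Exact discretisation over a step of length dt (diffusion sigma^2 = 2*theta*zeta^2):

    F = [[1, (1-e)/theta], [0, e]]                      with e = exp(-theta*dt)
    Q_vv = zeta^2 (1 - e^2)
    Q_xv = (sigma^2 / (2 theta^2)) (1 - e)^2
    Q_xx = (sigma^2 / theta^2) (dt - 2(1-e)/theta + (1-e^2)/(2 theta))

As theta -> infinity with zeta fixed, predicted positions in a gap tend to
the straight line between the bracketing fixes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import minimize

__all__ = ["CtcrwFit", "fit_ctcrw_xy", "kalman_smooth_positions", "ou_loglik_xy"]


@dataclass
class CtcrwFit:
    """ML estimates of the OU-velocity parameters for one individual."""

    theta_per_h: float  # mean-reversion rate, 1/h
    zeta_kmh: float     # stationary velocity SD, km/h
    loglik: float
    converged: bool
    boundary: bool      # zeta pinned at its lower bound (degenerate track)
    n_fixes: int


def _discretise(theta: float, zeta: float, dt: np.ndarray):
    e = np.exp(-theta * dt)
    sig2 = 2.0 * theta * zeta ** 2
    f01 = (1.0 - e) / theta
    qvv = zeta ** 2 * (1.0 - e ** 2)
    qxv = sig2 / (2.0 * theta ** 2) * (1.0 - e) ** 2
    qxx = sig2 / theta ** 2 * (dt - 2.0 * (1.0 - e) / theta + (1.0 - e ** 2) / (2.0 * theta))
    return e, f01, qxx, qxv, qvv


@njit(cache=True)
def _kf_loglik_axis(z, dt, theta, zeta):  # pragma: no cover - numba
    """Exact-observation Kalman log-likelihood of one axis, conditioning on z[0]."""
    n = z.shape[0]
    sig2 = 2.0 * theta * zeta ** 2
    mx = z[0]
    mv = 0.0
    pxx = 0.0
    pxv = 0.0
    pvv = zeta ** 2
    ll = 0.0
    for i in range(1, n):
        d = dt[i - 1]
        e = np.exp(-theta * d)
        f01 = (1.0 - e) / theta
        qvv = zeta ** 2 * (1.0 - e ** 2)
        qxv = sig2 / (2.0 * theta ** 2) * (1.0 - e) ** 2
        qxx = sig2 / theta ** 2 * (d - 2.0 * (1.0 - e) / theta + (1.0 - e ** 2) / (2.0 * theta))
        # predict
        mx_p = mx + f01 * mv
        mv_p = e * mv
        pxx_p = pxx + 2.0 * f01 * pxv + f01 * f01 * pvv + qxx
        pxv_p = e * (pxv + f01 * pvv) + qxv
        pvv_p = e * e * pvv + qvv
        # update with exact position observation
        s = pxx_p
        v = z[i] - mx_p
        ll += -0.5 * (np.log(2.0 * np.pi * s) + v * v / s)
        kx = 1.0
        kv = pxv_p / s
        mx = mx_p + kx * v
        mv = mv_p + kv * v
        pxx = 0.0
        pxv = 0.0
        pvv = pvv_p - kv * kv * s
    return ll


def ou_loglik_xy(x: np.ndarray, y: np.ndarray, t_hours: np.ndarray,
                 theta: float, zeta: float) -> float:
    """Joint log-likelihood of both planar axes given (theta, zeta)."""
    dt = np.diff(t_hours)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return float(_kf_loglik_axis(np.ascontiguousarray(x, dtype=np.float64), dt, theta, zeta)
                 + _kf_loglik_axis(np.ascontiguousarray(y, dtype=np.float64), dt, theta, zeta))


def fit_ctcrw_xy(x: np.ndarray, y: np.ndarray, t_hours: np.ndarray) -> CtcrwFit:
    """Maximum-likelihood fit of (theta, zeta) by L-BFGS on the log scale."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    t = np.asarray(t_hours, float)
    if len(x) < 48:
        raise ValueError("need at least 48 fixes to fit the CTCRW")
    dt = np.diff(t)
    step_speed = np.hypot(np.diff(x), np.diff(y)) / dt
    zeta0 = max(float(np.std(step_speed)), 1e-4)
    lo = np.log(1e-8)

    def nll(p):
        th, ze = np.exp(p)
        return -ou_loglik_xy(x, y, t, th, ze)

    res = minimize(nll, np.array([np.log(0.5), np.log(zeta0)]), method="L-BFGS-B",
                   bounds=[(np.log(1e-4), np.log(50.0)), (lo, np.log(1e3))])
    theta, zeta = np.exp(res.x)
    boundary = bool(res.x[1] <= lo + 1e-6)
    return CtcrwFit(theta_per_h=float(theta), zeta_kmh=float(zeta),
                    loglik=float(-res.fun), converged=bool(res.success),
                    boundary=boundary, n_fixes=len(x))


def kalman_smooth_positions(x: np.ndarray, y: np.ndarray, t_obs: np.ndarray,
                            t_query: np.ndarray, theta: float, zeta: float):
    """RTS-smoothed positions at `t_query` given exact observations.

    Returns (xq, yq). Query times coinciding with observation times return
    the observation exactly (zero measurement error).
    """
    t_obs = np.asarray(t_obs, float)
    t_query = np.asarray(t_query, float)
    t_all = np.union1d(t_obs, t_query)
    obs_idx = np.searchsorted(t_all, t_obs)
    is_obs = np.zeros(len(t_all), dtype=bool)
    is_obs[obs_idx] = True
    zx = np.full(len(t_all), np.nan)
    zy = np.full(len(t_all), np.nan)
    zx[obs_idx] = x
    zy[obs_idx] = y

    n = len(t_all)
    dt = np.diff(t_all)

    def smooth_axis(z):
        m_f = np.zeros((n, 2))
        p_f = np.zeros((n, 2, 2))
        m_p = np.zeros((n, 2))
        p_p = np.zeros((n, 2, 2))
        first = int(np.flatnonzero(~np.isnan(z))[0])
        m = np.array([z[first], 0.0])
        P = np.array([[0.0, 0.0], [0.0, zeta ** 2]])
        # before the first observation there is nothing to anchor on;
        # t_query is always inside the observed span in practice
        for i in range(first):
            m_f[i], p_f[i] = m, P
        m_f[first], p_f[first] = m, P
        m_p[first], p_p[first] = m, P
        for i in range(first + 1, n):
            d = dt[i - 1]
            e, f01, qxx, qxv, qvv = _discretise(theta, zeta, np.array(d))
            F = np.array([[1.0, float(f01)], [0.0, float(e)]])
            Q = np.array([[float(qxx), float(qxv)], [float(qxv), float(qvv)]])
            m = F @ m
            P = F @ P @ F.T + Q
            m_p[i], p_p[i] = m, P
            if not np.isnan(z[i]):
                s = P[0, 0]
                innov = z[i] - m[0]
                K = P[:, 0] / s
                m = m + K * innov
                P = P - np.outer(K, P[0, :])
                P[0, :] = 0.0
                P[:, 0] = 0.0
            m_f[i], p_f[i] = m, P
        # backward pass
        m_s = m_f.copy()
        p_s = p_f.copy()
        for i in range(n - 2, first - 1, -1):
            d = dt[i]
            e, f01, _, _, _ = _discretise(theta, zeta, np.array(d))
            F = np.array([[1.0, float(f01)], [0.0, float(e)]])
            Pp = p_p[i + 1]
            # guard the exactly-observed (singular) corner
            Ppi = np.linalg.pinv(Pp)
            G = p_f[i] @ F.T @ Ppi
            m_s[i] = m_f[i] + G @ (m_s[i + 1] - m_p[i + 1])
            p_s[i] = p_f[i] + G @ (p_s[i + 1] - Pp) @ G.T
        return m_s[:, 0]

    sx = smooth_axis(zx)
    sy = smooth_axis(zy)
    qi = np.searchsorted(t_all, t_query)
    return sx[qi], sy[qi]
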