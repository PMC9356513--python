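"""Numerical kernels for the Koyck DLM likelihood.

The random-walk intercept is a scalar Gaussian state, so it can be
integrated out exactly with a scalar Kalman filter. These kernels evaluate
that marginal log-likelihood for a whole batch of parameter vectors at
once (the ensemble sampler proposes many walkers per step), and run
forward-filter backward-sampling (FFBS) to draw intercept paths
conditional on sampled parameters.

Parameter matrices use one fixed layout:
``[beta, lam, rho, gamma_1..gamma_k, a_1, b_1, ..., a_m, b_m,
sigma_obs, sigma_rw]``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def koyck_batch(x, lams, k0_steady):
    """Koyck state K for each lambda in a batch; (B, T)."""
    B = lams.shape[0]
    T = x.shape[0]
    out = np.empty((B, T))
    for b in range(B):
        lam = lams[b]
        if k0_steady and lam != 0.0:
            k = x[0] / (1.0 - lam)  # = x[0] + lam * (x[0] / (1 - lam))
        else:
            k = x[0]
        out[b, 0] = k
        for t in range(1, T):
            k = x[t] + lam * k
            out[b, t] = k
    return out


@njit(cache=True)
def regression_batch(P, x, y_lag, Z, H, k, m, k0_steady):
    """Non-intercept predictor f_t for each parameter row; (B, T)."""
    B = P.shape[0]
    T = x.shape[0]
    out = np.empty((B, T))
    for b in range(B):
        beta = P[b, 0]
        lam = P[b, 1]
        rho = P[b, 2]
        if k0_steady and lam != 0.0:
            K = x[0] / (1.0 - lam)
        else:
            K = x[0]
        for t in range(T):
            if t > 0:
                K = x[t] + lam * K
            f = beta * K + rho * y_lag[t]
            for j in range(k):
                f += P[b, 3 + j] * Z[t, j]
            for h in range(2 * m):
                f += P[b, 3 + k + h] * H[t, h]
            out[b, t] = f
    return out


@njit(cache=True)
def marginal_loglik_batch(P, y, missing, x, y_lag, Z, H, k, m, k0_steady, m0, C0):
    """Kalman-marginalized log-likelihood of y for each parameter row.

    Observation: r_t = y_t - f_t = mu_t + v_t, v ~ N(0, sigma_obs^2);
    state: mu_t = mu_{t-1} + w_t, w ~ N(0, sigma_rw^2), mu_1 ~ N(m0, C0).
    Missing weeks propagate the state without an update or a likelihood
    contribution.
    """
    B = P.shape[0]
    T = y.shape[0]
    ncol = P.shape[1]
    out = np.empty(B)
    for b in range(B):
        beta = P[b, 0]
        lam = P[b, 1]
        rho = P[b, 2]
        so = P[b, ncol - 2]
        srw = P[b, ncol - 1]
        s2 = so * so
        q = srw * srw
        if k0_steady and lam != 0.0:
            K = x[0] / (1.0 - lam)
        else:
            K = x[0]
        mf = m0
        Cf = C0
        ll = 0.0
        for t in range(T):
            if t > 0:
                K = x[t] + lam * K
            # predict
            if t == 0:
                a = m0
                R = C0
            else:
                a = mf
                R = Cf + q
            if missing[t]:
                mf = a
                Cf = R
                continue
            f = beta * K + rho * y_lag[t]
            for j in range(k):
                f += P[b, 3 + j] * Z[t, j]
            for h in range(2 * m):
                f += P[b, 3 + k + h] * H[t, h]
            r = y[t] - f
            F = R + s2
            e = r - a
            ll += -0.5 * (math.log(TWO_PI * F) + e * e / F)
            g = R / F
            mf = a + g * e
            Cf = R - g * R
        out[b] = ll
    return out


@njit(cache=True)
def marginal_pointwise_batch(P, y, missing, x, y_lag, Z, H, k, m, k0_steady, m0, C0):
    """Per-week one-step-ahead predictive log densities, (B, T).

    Rows sum to the marginal log-likelihood (prediction-error decomposition
    of the Kalman filter); missing weeks contribute 0.
    """
    B = P.shape[0]
    T = y.shape[0]
    ncol = P.shape[1]
    out = np.zeros((B, T))
    for b in range(B):
        beta = P[b, 0]
        lam = P[b, 1]
        rho = P[b, 2]
        so = P[b, ncol - 2]
        srw = P[b, ncol - 1]
        s2 = so * so
        q = srw * srw
        if k0_steady and lam != 0.0:
            K = x[0] / (1.0 - lam)
        else:
            K = x[0]
        mf = m0
        Cf = C0
        for t in range(T):
            if t > 0:
                K = x[t] + lam * K
            if t == 0:
                a = m0
                R = C0
            else:
                a = mf
                R = Cf + q
            if missing[t]:
                mf = a
                Cf = R
                continue
            f = beta * K + rho * y_lag[t]
            for j in range(k):
                f += P[b, 3 + j] * Z[t, j]
            for h in range(2 * m):
                f += P[b, 3 + k + h] * H[t, h]
            r = y[t] - f
            F = R + s2
            e = r - a
            out[b, t] = -0.5 * (math.log(TWO_PI * F) + e * e / F)
            g = R / F
            mf = a + g * e
            Cf = R - g * R
    return out


@njit(cache=True)
def ffbs_batch(P, y, missing, x, y_lag, Z, H, k, m, k0_steady, m0, C0, z):
    """Sample one intercept path per parameter row by FFBS.

    ``z`` is a (B, T) matrix of standard-normal innovations supplied by the
    caller (keeps the kernel deterministic given its inputs).
    """
    B = P.shape[0]
    T = y.shape[0]
    ncol = P.shape[1]
    mu = np.empty((B, T))
    mf_s = np.empty(T)
    Cf_s = np.empty(T)
    for b in range(B):
        beta = P[b, 0]
        lam = P[b, 1]
        rho = P[b, 2]
        so = P[b, ncol - 2]
        srw = P[b, ncol - 1]
        s2 = so * so
        q = srw * srw
        if k0_steady and lam != 0.0:
            K = x[0] / (1.0 - lam)
        else:
            K = x[0]
        mf = m0
        Cf = C0
        for t in range(T):
            if t > 0:
                K = x[t] + lam * K
            if t == 0:
                a = m0
                R = C0
            else:
                a = mf
                R = Cf + q
            if missing[t]:
                mf = a
                Cf = R
            else:
                f = beta * K + rho * y_lag[t]
                for j in range(k):
                    f += P[b, 3 + j] * Z[t, j]
                for h in range(2 * m):
                    f += P[b, 3 + k + h] * H[t, h]
                r = y[t] - f
                F = R + s2
                e = r - a
                g = R / F
                mf = a + g * e
                Cf = R - g * R
            mf_s[t] = mf
            Cf_s[t] = Cf
        # backward sampling
        mu[b, T - 1] = mf_s[T - 1] + math.sqrt(max(Cf_s[T - 1], 0.0)) * z[b, T - 1]
        for t in range(T - 2, -1, -1):
            Rn = Cf_s[t] + q
            if Rn > 0.0:
                J = Cf_s[t] / Rn
            else:
                J = 0.0
            mean = mf_s[t] + J * (mu[b, t + 1] - mf_s[t])
            var = Cf_s[t] * (1.0 - J)
            mu[b, t] = mean + math.sqrt(max(var, 0.0)) * z[b, t]
    return mu
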