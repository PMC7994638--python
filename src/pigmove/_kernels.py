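"""Numba kernels for the movement-HMM likelihood, gradient, and decoding.

All kernels operate on concatenated per-step arrays covering every burst of
every animal in a stratum:

``steps``        step lengths (m), length T
``turns``        turning angles (rad), NaN where undefined (first step of a
                 burst has no turning angle and its angle term is omitted)
``tcov``         T x C transition covariate design matrix; row t multiplies
                 the coefficients of the transition *into* step t
                 (C = 1 intercept-only, 2 intercept+linear hour,
                 3 intercept+cosinor)
``burst_starts`` length n_bursts+1 index fence into the step arrays

Working-scale parameter vector layout (K states, C transition covariates):

    log mu (K) | log sigma (K) | x_muphi (K) | s_rho (K)
    [ | z_pi0 (K) when zero-inflated ]
    | beta (K*(K-1)*C, ordered-pair-major) | delta logits (K-1)

with mu_phi = 2*atan(x), rho = logistic(s), pi0 = logistic(z) and the
initial distribution delta a multinomial logit with state 1 as reference.

The gradient uses the Fisher identity: the score of the observed-data
log-likelihood equals the posterior expectation of the complete-data score,
computed from one scaled forward-backward sweep per burst.
"""

import math

import numpy as np
from numba import njit

BIG_NLL = 1.0e300


@njit(cache=True)
def _digamma(x):
    """Digamma by upward recurrence + asymptotic series (x > 0)."""
    if not (x > 0.0):
        # degenerate shape parameter; the likelihood is already non-finite
        # here and the caller discards the gradient
        return 0.0
    result = 0.0
    while x < 6.0:
        result -= 1.0 / x
        x += 1.0
    inv = 1.0 / x
    inv2 = inv * inv
    result += (
        math.log(x)
        - 0.5 * inv
        - inv2 * (1.0 / 12.0 - inv2 * (1.0 / 120.0 - inv2 / 252.0))
    )
    return result


@njit(cache=True)
def _unpack(theta, K, C, zero_mass):
    mu = np.empty(K)
    sigma = np.empty(K)
    muphi = np.empty(K)
    rho = np.empty(K)
    pi0 = np.zeros(K)
    for k in range(K):
        # clamp exponents so mu, sigma and sigma**2 stay positive finite
        mu[k] = math.exp(min(max(theta[k], -345.0), 345.0))
        sigma[k] = math.exp(min(max(theta[K + k], -345.0), 345.0))
        muphi[k] = 2.0 * math.atan(theta[2 * K + k])
        # clamp away from the rho = 1 boundary (derivatives divide by 1-rho^2)
        r = 1.0 / (1.0 + math.exp(-theta[3 * K + k]))
        rho[k] = min(max(r, 1e-12), 1.0 - 1e-10)
    off = 4 * K
    if zero_mass:
        for k in range(K):
            p0 = 1.0 / (1.0 + math.exp(-theta[off + k]))
            pi0[k] = min(max(p0, 1e-12), 1.0 - 1e-12)
        off += K
    nb = K * (K - 1)
    beta = np.empty((nb, C))
    for p in range(nb):
        for c in range(C):
            beta[p, c] = theta[off + p * C + c]
    off += nb * C
    delta = np.empty(K)
    delta[0] = 1.0
    s = 1.0
    for k in range(K - 1):
        delta[k + 1] = math.exp(theta[off + k])
        s += delta[k + 1]
    for k in range(K):
        delta[k] /= s
    return mu, sigma, muphi, rho, pi0, beta, delta


@njit(cache=True)
def _emission_logB(steps, turns, mu, sigma, muphi, rho, pi0, zero_mass):
    """T x K matrix of per-step log emission densities."""
    T = steps.shape[0]
    K = mu.shape[0]
    logB = np.empty((T, K))
    shape = np.empty(K)
    rate = np.empty(K)
    lgam = np.empty(K)
    lrho = np.empty(K)
    for k in range(K):
        shape[k] = max((mu[k] / sigma[k]) ** 2, 1e-300)
        rate[k] = mu[k] / sigma[k] ** 2
        lgam[k] = math.lgamma(shape[k])
        lrho[k] = math.log(1.0 - rho[k] * rho[k]) - math.log(2.0 * math.pi)
    for t in range(T):
        ell = steps[t]
        phi = turns[t]
        for k in range(K):
            if zero_mass and ell == 0.0:
                v = math.log(pi0[k])
            else:
                v = (
                    shape[k] * math.log(max(rate[k], 1e-308))
                    - lgam[k]
                    + (shape[k] - 1.0) * math.log(ell)
                    - rate[k] * ell
                )
                if zero_mass:
                    v += math.log(1.0 - pi0[k])
            if not np.isnan(phi):
                d = 1.0 + rho[k] * rho[k] - 2.0 * rho[k] * math.cos(phi - muphi[k])
                v += lrho[k] - math.log(max(d, 1e-300))
            logB[t, k] = v
    return logB


@njit(cache=True)
def _gamma_row(beta, tc, K, C, G):
    """Fill G (K x K) with the multinomial-logit transition matrix for one
    covariate row ``tc`` (length C); diagonal is the reference category."""
    p = 0
    for i in range(K):
        denom = 1.0
        for j in range(K):
            if j != i:
                eta = 0.0
                for c in range(C):
                    eta += beta[p, c] * tc[c]
                e = math.exp(min(eta, 500.0))
                G[i, j] = e
                denom += e
                p += 1
        for j in range(K):
            if j == i:
                G[i, j] = 1.0 / denom
            else:
                G[i, j] /= denom


@njit(cache=True)
def forward_nll(theta, K, C, zero_mass, steps, turns, tcov, burst_starts):
    """Negative log-likelihood by the scaled forward algorithm."""
    mu, sigma, muphi, rho, pi0, beta, delta = _unpack(theta, K, C, zero_mass)
    logB = _emission_logB(steps, turns, mu, sigma, muphi, rho, pi0, zero_mass)
    n_bursts = burst_starts.shape[0] - 1
    alpha = np.empty(K)
    tmp = np.empty(K)
    G = np.empty((K, K))
    ll = 0.0
    for b in range(n_bursts):
        t0 = burst_starts[b]
        t1 = burst_starts[b + 1]
        m = logB[t0, 0]
        for k in range(1, K):
            if logB[t0, k] > m:
                m = logB[t0, k]
        c = 0.0
        for k in range(K):
            alpha[k] = delta[k] * math.exp(logB[t0, k] - m)
            c += alpha[k]
        if not (c > 0.0) or not np.isfinite(c):
            return BIG_NLL
        ll += math.log(c) + m
        for k in range(K):
            alpha[k] /= c
        for t in range(t0 + 1, t1):
            _gamma_row(beta, tcov[t], K, C, G)
            m = logB[t, 0]
            for k in range(1, K):
                if logB[t, k] > m:
                    m = logB[t, k]
            c = 0.0
            for j in range(K):
                a = 0.0
                for i in range(K):
                    a += alpha[i] * G[i, j]
                tmp[j] = a * math.exp(logB[t, j] - m)
                c += tmp[j]
            if not (c > 0.0) or not np.isfinite(c):
                return BIG_NLL
            ll += math.log(c) + m
            for k in range(K):
                alpha[k] = tmp[k] / c
    if not np.isfinite(ll):
        return BIG_NLL
    return -ll


@njit(cache=True)
def forward_nll_grad(theta, K, C, zero_mass, steps, turns, tcov, burst_starts):
    """Negative log-likelihood and its gradient on the working scale.

    One forward pass (storing scaled alphas and the shifted emission
    weights), one backward pass accumulating posterior marginals gamma_t and
    pairwise posteriors xi_t, which weight the complete-data score.
    """
    n_par = theta.shape[0]
    grad = np.zeros(n_par)
    mu, sigma, muphi, rho, pi0, beta, delta = _unpack(theta, K, C, zero_mass)
    logB = _emission_logB(steps, turns, mu, sigma, muphi, rho, pi0, zero_mass)
    T = steps.shape[0]

    # per-(t,k) derivatives of log b_k(x_t) wrt working emission parameters
    shape = np.empty(K)
    rate = np.empty(K)
    psi = np.empty(K)
    for k in range(K):
        shape[k] = max((mu[k] / sigma[k]) ** 2, 1e-300)
        rate[k] = mu[k] / sigma[k] ** 2
        psi[k] = _digamma(shape[k])
    d_lmu = np.empty((T, K))
    d_lsig = np.empty((T, K))
    d_x = np.empty((T, K))
    d_s = np.empty((T, K))
    d_z = np.zeros((T, K))
    for t in range(T):
        ell = steps[t]
        phi = turns[t]
        for k in range(K):
            if zero_mass and ell == 0.0:
                d_lmu[t, k] = 0.0
                d_lsig[t, k] = 0.0
                d_z[t, k] = 1.0 - pi0[k]
            else:
                base = math.log(max(rate[k], 1e-308)) - psi[k] + math.log(ell)
                resid = shape[k] - rate[k] * ell
                d_lmu[t, k] = 2.0 * shape[k] * base + resid
                d_lsig[t, k] = -2.0 * shape[k] * base - 2.0 * resid
                if zero_mass:
                    d_z[t, k] = -pi0[k]
            if np.isnan(phi):
                d_x[t, k] = 0.0
                d_s[t, k] = 0.0
            else:
                d = phi - muphi[k]
                den = max(1.0 + rho[k] * rho[k] - 2.0 * rho[k] * math.cos(d), 1e-300)
                dmuphi = 2.0 * rho[k] * math.sin(d) / den
                x = theta[2 * K + k]
                d_x[t, k] = dmuphi * 2.0 / (1.0 + x * x)
                drho = (
                    -2.0 * rho[k] / (1.0 - rho[k] * rho[k])
                    - (2.0 * rho[k] - 2.0 * math.cos(d)) / den
                )
                d_s[t, k] = drho * rho[k] * (1.0 - rho[k])
    off_beta = 5 * K if zero_mass else 4 * K
    off_delta = off_beta + K * (K - 1) * C

    n_bursts = burst_starts.shape[0] - 1
    ll = 0.0
    G = np.empty((K, K))
    alphas = np.empty((T, K))
    evals = np.empty((T, K))  # exp(logB - per-step max)
    cs = np.empty(T)
    beta_back = np.empty(K)
    beta_new = np.empty(K)
    gam = np.empty(K)
    for b in range(n_bursts):
        t0 = burst_starts[b]
        t1 = burst_starts[b + 1]
        # forward
        m = logB[t0, 0]
        for k in range(1, K):
            if logB[t0, k] > m:
                m = logB[t0, k]
        c = 0.0
        for k in range(K):
            evals[t0, k] = math.exp(logB[t0, k] - m)
            alphas[t0, k] = delta[k] * evals[t0, k]
            c += alphas[t0, k]
        if not (c > 0.0) or not np.isfinite(c):
            return BIG_NLL, np.zeros(n_par)
        ll += math.log(c) + m
        cs[t0] = c
        for k in range(K):
            alphas[t0, k] /= c
        for t in range(t0 + 1, t1):
            _gamma_row(beta, tcov[t], K, C, G)
            m = logB[t, 0]
            for k in range(1, K):
                if logB[t, k] > m:
                    m = logB[t, k]
            c = 0.0
            for j in range(K):
                a = 0.0
                for i in range(K):
                    a += alphas[t - 1, i] * G[i, j]
                evals[t, j] = math.exp(logB[t, j] - m)
                alphas[t, j] = a * evals[t, j]
                c += alphas[t, j]
            if not (c > 0.0) or not np.isfinite(c):
                return BIG_NLL, np.zeros(n_par)
            ll += math.log(c) + m
            cs[t] = c
            for k in range(K):
                alphas[t, k] /= c
        # backward, accumulating posterior-weighted scores
        for k in range(K):
            beta_back[k] = 1.0
        for t in range(t1 - 1, t0, -1):
            # gamma_t and emission score at t
            for k in range(K):
                gam[k] = alphas[t, k] * beta_back[k]
                grad[k] -= gam[k] * d_lmu[t, k]
                grad[K + k] -= gam[k] * d_lsig[t, k]
                grad[2 * K + k] -= gam[k] * d_x[t, k]
                grad[3 * K + k] -= gam[k] * d_s[t, k]
                if zero_mass:
                    grad[4 * K + k] -= gam[k] * d_z[t, k]
            _gamma_row(beta, tcov[t], K, C, G)
            # xi_t(i,j) = alpha_{t-1}(i) G_ij e_t(j) beta_t(j) / c_t
            p = 0
            for i in range(K):
                row_sum = 0.0
                xi_row = np.empty(K)
                for j in range(K):
                    xi = (
                        alphas[t - 1, i]
                        * G[i, j]
                        * evals[t, j]
                        * beta_back[j]
                        / cs[t]
                    )
                    xi_row[j] = xi
                    row_sum += xi
                for j in range(K):
                    if j != i:
                        coef = xi_row[j] - G[i, j] * row_sum
                        for c_i in range(C):
                            grad[off_beta + p * C + c_i] -= coef * tcov[t, c_i]
                        p += 1
            # propagate backward variable to t-1
            for i in range(K):
                a = 0.0
                for j in range(K):
                    a += G[i, j] * evals[t, j] * beta_back[j]
                beta_new[i] = a / cs[t]
            for i in range(K):
                beta_back[i] = beta_new[i]
        # t = t0: emission score and initial-distribution score
        for k in range(K):
            gam[k] = alphas[t0, k] * beta_back[k]
            grad[k] -= gam[k] * d_lmu[t0, k]
            grad[K + k] -= gam[k] * d_lsig[t0, k]
            grad[2 * K + k] -= gam[k] * d_x[t0, k]
            grad[3 * K + k] -= gam[k] * d_s[t0, k]
            if zero_mass:
                grad[4 * K + k] -= gam[k] * d_z[t0, k]
        for k in range(1, K):
            grad[off_delta + k - 1] -= gam[k] - delta[k]
    if not np.isfinite(ll):
        return BIG_NLL, np.zeros(n_par)
    return -ll, grad


@njit(cache=True)
def viterbi_path(theta, K, C, zero_mass, steps, turns, tcov, burst_starts):
    """Most probable state path per burst (log-space DP).

    Ties break toward the lowest state index. Returns 0-based states.
    """
    mu, sigma, muphi, rho, pi0, beta, delta = _unpack(theta, K, C, zero_mass)
    logB = _emission_logB(steps, turns, mu, sigma, muphi, rho, pi0, zero_mass)
    T = steps.shape[0]
    path = np.empty(T, dtype=np.int64)
    n_bursts = burst_starts.shape[0] - 1
    G = np.empty((K, K))
    score = np.empty((T, K))
    back = np.empty((T, K), dtype=np.int64)
    for b in range(n_bursts):
        t0 = burst_starts[b]
        t1 = burst_starts[b + 1]
        for k in range(K):
            score[t0, k] = math.log(delta[k]) + logB[t0, k]
        for t in range(t0 + 1, t1):
            _gamma_row(beta, tcov[t], K, C, G)
            for j in range(K):
                best = -np.inf
                arg = 0
                for i in range(K):
                    v = score[t - 1, i] + math.log(G[i, j])
                    if v > best:
                        best = v
                        arg = i
                score[t, j] = best + logB[t, j]
                back[t, j] = arg
        best = -np.inf
        arg = 0
        for k in range(K):
            if score[t1 - 1, k] > best:
                best = score[t1 - 1, k]
                arg = k
        path[t1 - 1] = arg
        for t in range(t1 - 2, t0 - 1, -1):
            path[t] = back[t + 1, path[t + 1]]
    return path
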