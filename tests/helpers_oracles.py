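"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately written against scipy primitives and naive
enumeration, sharing no code with the package's likelihood kernels.
"""

import itertools

import numpy as np
from scipy import integrate, special, stats

from pigmove.hmm import HMMParams
from pigmove.tracks import StepSeries


def oracle_emission_logpdf(step, turn, mean, sd, turn_mean, rho):
    """Per-observation log emission density via scipy distributions."""
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    v = stats.gamma.logpdf(step, shape, scale=scale)
    if not np.isnan(turn):
        if rho == 0:
            v += -np.log(2 * np.pi)
        else:
            x = np.mod(turn - turn_mean, 2 * np.pi)
            v += stats.wrapcauchy.logpdf(x, rho)
    return v


def oracle_transition(params: HMMParams, hour: float) -> np.ndarray:
    """Row-wise multinomial logit transition matrix, built naively."""
    K = params.n_states
    if params.covariate_form == "cosinor":
        tc = np.array([1.0, np.cos(2 * np.pi * hour / 24), np.sin(2 * np.pi * hour / 24)])
    elif params.covariate_form == "hour":
        tc = np.array([1.0, hour / 24.0])
    else:
        tc = np.array([1.0])
    G = np.zeros((K, K))
    p = 0
    for i in range(K):
        eta = np.zeros(K)
        for j in range(K):
            if j != i:
                eta[j] = float(params.beta[p] @ tc)
                p += 1
        w = np.exp(eta - eta[i])
        G[i] = w / w.sum()
    return G


def _path_logprob(params, path, logB, hours):
    lp = np.log(params.delta[path[0]]) + logB[0, path[0]]
    for t in range(1, len(path)):
        G = oracle_transition(params, hours[t])
        lp += np.log(G[path[t - 1], path[t]]) + logB[t, path[t]]
    return lp


def _emissions(params, series):
    T = len(series.steps)
    K = params.n_states
    logB = np.empty((T, K))
    for t in range(T):
        for k in range(K):
            logB[t, k] = oracle_emission_logpdf(
                series.steps[t], series.turns[t],
                params.means[k], params.sds[k],
                params.turn_means[k], params.rhos[k],
            )
    return logB


def oracle_forward_loglik(params: HMMParams, series: StepSeries) -> float:
    """Log-likelihood by exhaustive summation over all K^T state paths."""
    K = params.n_states
    T = len(series.steps)
    logB = _emissions(params, series)
    lps = [
        _path_logprob(params, path, logB, series.hours)
        for path in itertools.product(range(K), repeat=T)
    ]
    return float(special.logsumexp(lps))


def oracle_viterbi(params: HMMParams, series: StepSeries) -> np.ndarray:
    """Most probable path by exhaustive argmax (1-based states)."""
    K = params.n_states
    T = len(series.steps)
    logB = _emissions(params, series)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = _path_logprob(params, path, logB, series.hours)
        if lp > best_lp:
            best, best_lp = path, lp
    return np.asarray(best) + 1


def random_instance(rng, K=None, T=None, covariate_form="cosinor"):
    """A random small HMM instance (params + one-series data)."""
    if K is None:
        K = int(rng.integers(1, 4))
    if T is None:
        T = int(rng.integers(2, 9))
    ncov = {"none": 1, "hour": 2, "cosinor": 3}[covariate_form]
    means = np.sort(np.exp(rng.uniform(1, 5, K)))
    params = HMMParams(
        means=means,
        sds=means * rng.uniform(0.4, 1.5, K),
        turn_means=rng.uniform(-3.1, 3.1, K),
        rhos=rng.uniform(0.0, 0.95, K),
        beta=rng.normal(-1.0, 0.8, (K * (K - 1), ncov)),
        delta=rng.dirichlet(np.ones(K)),
        covariate_form=covariate_form,
    )
    turns = rng.uniform(-np.pi, np.pi, T)
    turns[0] = np.nan
    series = StepSeries(
        animal_id="o", burst_id=0,
        t=np.arange(T),
        steps=np.exp(rng.uniform(0.5, 5.5, T)),
        turns=turns,
        hours=rng.uniform(0, 24, T),
        season="low_forage",
    )
    return params, series


def oracle_mixed_loglik(beta, tau, X, y, groups):
    """Random-intercept logistic marginal log-likelihood by direct
    numerical integration (scipy quad per group)."""
    ll = 0.0
    for g in np.unique(groups):
        idx = groups == g
        eta0 = X[idx] @ beta
        yg = y[idx]

        def logp(u):
            eta = eta0 + tau * u
            return np.sum(yg * eta - np.logaddexp(0.0, eta))

        # factor out the magnitude so quad's absolute tolerance is meaningful
        shift = logp(0.0)

        def integrand(u):
            return np.exp(logp(u) - shift) * stats.norm.pdf(u)

        val, _ = integrate.quad(integrand, -12, 12, limit=400,
                                epsabs=1e-13, epsrel=1e-12)
        ll += np.log(val) + shift
    return float(ll)


def oracle_auc(scores, labels):
    """AUC by exhaustive pair counting, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
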