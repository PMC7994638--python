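"""Movement hidden Markov models with diel transition covariates.

The model: an unobserved K-state Markov chain (states interpreted, in
ascending order of mean step length, as resting, foraging, and traveling)
emits at each step a gamma-distributed step length and a wrapped-Cauchy
turning angle.  Transition probabilities follow a row-wise multinomial
logit with the diagonal as reference; the linear predictor of each
off-diagonal entry can carry the hour of day, by default as a first-order
cosinor (cos/sin pair of period 24 h), since clock hour is circular:

    eta_ij(h) = b0_ij + bc_ij * cos(2 pi h / 24) + bs_ij * sin(2 pi h / 24)
    Gamma_ij(h) = exp(eta_ij) / (1 + sum_{j' != i} exp(eta_ij'))

Estimation maximizes the forward-algorithm log-likelihood over an
unconstrained working scale (log means/SDs, logit concentrations, 2*atan
angular means) by quasi-Newton iteration with analytic gradients, from many
random starting-value sets to guard against local maxima.  Usage follows
the model/results idiom::

    model = MovementHMM(step_series, n_states=3)
    res = model.fit(n_starts=25, seed=1)
    print(res.summary())
    states = res.decode()
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _kernels
from .distributions import ZeroStepError
from .tracks import StepSeries

__all__ = [
    "MovementHMM",
    "HMMParams",
    "HMMResults",
    "transition_matrix",
    "select_states",
    "FitError",
]

COVARIATE_FORMS = ("cosinor", "hour", "none")


class FitError(RuntimeError):
    """No starting-value set converged; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


def _tcov_width(form: str) -> int:
    return {"none": 1, "hour": 2, "cosinor": 3}[form]


def _tcov_design(hours: np.ndarray, form: str) -> np.ndarray:
    T = hours.shape[0]
    if form == "none":
        return np.ones((T, 1))
    if form == "hour":
        return np.column_stack([np.ones(T), hours / 24.0])
    if form == "cosinor":
        w = 2.0 * np.pi * hours / 24.0
        return np.column_stack([np.ones(T), np.cos(w), np.sin(w)])
    raise ValueError(f"unknown transition covariate form {form!r}")


@dataclasses.dataclass
class HMMParams:
    """Natural-scale parameters of a K-state movement HMM.

    ``beta`` has one row per ordered off-diagonal state pair, enumerated
    row-major — (1,2), (1,3), (2,1), ... for K = 3 — and one column per
    transition covariate (intercept[, cos, sin] for the cosinor form).
    """

    means: np.ndarray  # gamma mean step (m), shape (K,)
    sds: np.ndarray  # gamma SD step (m), shape (K,)
    turn_means: np.ndarray  # angular mean (rad), shape (K,)
    rhos: np.ndarray  # wrapped-Cauchy concentration in [0, 1), shape (K,)
    beta: np.ndarray  # transition coefficients, shape (K*(K-1), n_cov)
    delta: np.ndarray  # initial distribution, shape (K,)
    covariate_form: str = "cosinor"
    zero_mass: Optional[np.ndarray] = None  # P(step == 0) per state, or None

    @property
    def n_states(self) -> int:
        return len(self.means)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.turn_means = np.asarray(self.turn_means, dtype=float)
        self.rhos = np.asarray(self.rhos, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        K = self.n_states
        if self.beta.ndim != 2 or self.beta.shape[0] != K * (K - 1):
            raise ValueError(
                f"beta must have K*(K-1)={K * (K - 1)} rows, got {self.beta.shape}"
            )
        if not np.isclose(self.delta.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")

    @classmethod
    def constant_transitions(
        cls, means, sds, turn_means, rhos, tpm, delta=None, covariate_form="none"
    ) -> "HMMParams":
        """Build params from an explicit (hour-free) transition matrix."""
        tpm = np.asarray(tpm, dtype=float)
        K = len(means)
        C = _tcov_width(covariate_form)
        beta = np.zeros((K * (K - 1), C))
        p = 0
        for i in range(K):
            for j in range(K):
                if i != j:
                    beta[p, 0] = np.log(tpm[i, j] / tpm[i, i])
                    p += 1
        if delta is None:
            delta = np.full(K, 1.0 / K)
        return cls(
            means=means, sds=sds, turn_means=turn_means, rhos=rhos,
            beta=beta, delta=delta, covariate_form=covariate_form,
        )

    # -- working-scale transform ------------------------------------------
    def to_working(self) -> np.ndarray:
        K = self.n_states
        rhos = np.clip(self.rhos, 1e-12, 1.0 - 1e-10)
        parts = [
            np.log(self.means),
            np.log(self.sds),
            np.tan(self.turn_means / 2.0),
            np.log(rhos / (1.0 - rhos)),
        ]
        if self.zero_mass is not None:
            zm = np.clip(self.zero_mass, 1e-10, 1 - 1e-10)
            parts.append(np.log(zm / (1.0 - zm)))
        parts.append(self.beta.ravel())
        d = np.clip(self.delta, 1e-12, None)
        parts.append(np.log(d[1:] / d[0]))
        return np.concatenate(parts)

    @classmethod
    def from_working(
        cls, theta: np.ndarray, K: int, covariate_form: str, zero_mass: bool
    ) -> "HMMParams":
        theta = np.asarray(theta, dtype=float)
        C = _tcov_width(covariate_form)
        means = np.exp(theta[:K])
        sds = np.exp(theta[K : 2 * K])
        turn_means = 2.0 * np.arctan(theta[2 * K : 3 * K])
        from scipy.special import expit

        rhos = np.clip(expit(theta[3 * K : 4 * K]), 1e-12, 1.0 - 1e-10)
        off = 4 * K
        zm = None
        if zero_mass:
            zm = 1.0 / (1.0 + np.exp(-theta[off : off + K]))
            off += K
        nb = K * (K - 1)
        beta = theta[off : off + nb * C].reshape(nb, C)
        off += nb * C
        dl = np.concatenate([[0.0], theta[off : off + K - 1]])
        delta = np.exp(dl - dl.max())
        delta /= delta.sum()
        return cls(
            means=means, sds=sds, turn_means=turn_means, rhos=rhos,
            beta=beta, delta=delta, covariate_form=covariate_form, zero_mass=zm,
        )

    def transition_matrix(self, hour: float) -> np.ndarray:
        """K x K stochastic matrix Gamma(hour)."""
        return transition_matrix(self, hour)

    def relabel(self, order: np.ndarray) -> "HMMParams":
        """Permute state labels; ``order[new] = old``."""
        K = self.n_states
        order = np.asarray(order)
        pair_index = {}
        p = 0
        for i in range(K):
            for j in range(K):
                if i != j:
                    pair_index[(i, j)] = p
                    p += 1
        new_beta = np.empty_like(self.beta)
        p = 0
        for i in range(K):
            for j in range(K):
                if i != j:
                    new_beta[p] = self.beta[pair_index[(order[i], order[j])]]
                    p += 1
        return HMMParams(
            means=self.means[order],
            sds=self.sds[order],
            turn_means=self.turn_means[order],
            rhos=self.rhos[order],
            beta=new_beta,
            delta=self.delta[order],
            covariate_form=self.covariate_form,
            zero_mass=None if self.zero_mass is None else self.zero_mass[order],
        )

    def n_parameters(self) -> int:
        """Free parameters: 4 emission parameters per state (+1 with zero
        mass), one transition coefficient per pair and covariate column,
        K-1 for the initial distribution."""
        K = self.n_states
        C = self.beta.shape[1]
        k = 4 * K + K * (K - 1) * C + (K - 1)
        if self.zero_mass is not None:
            k += K
        return k

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "covariate_form": self.covariate_form,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "turn_means": self.turn_means.tolist(),
            "rhos": self.rhos.tolist(),
            "beta": self.beta.tolist(),
            "delta": self.delta.tolist(),
            "zero_mass": None if self.zero_mass is None else self.zero_mass.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            turn_means=np.array(d["turn_means"]),
            rhos=np.array(d["rhos"]),
            beta=np.array(d["beta"]),
            delta=np.array(d["delta"]),
            covariate_form=d["covariate_form"],
            zero_mass=None if d.get("zero_mass") is None else np.array(d["zero_mass"]),
        )


def transition_matrix(params: HMMParams, hour: float) -> np.ndarray:
    """Evaluate the multinomial-logit transition matrix at a clock hour."""
    K = params.n_states
    tc = _tcov_design(np.array([hour % 24.0]), params.covariate_form)[0]
    G = np.empty((K, K))
    p = 0
    for i in range(K):
        etas = np.zeros(K)
        for j in range(K):
            if j != i:
                etas[j] = params.beta[p] @ tc
                p += 1
        ex = np.exp(etas - etas[i])  # eta_ii = 0 reference
        G[i] = ex / ex.sum()
    return G


def _pack_data(series: Sequence[StepSeries]):
    steps = np.concatenate([s.steps for s in series])
    turns = np.concatenate([s.turns for s in series])
    hours = np.concatenate([s.hours for s in series])
    lengths = [len(s) for s in series]
    burst_starts = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
    return steps, turns, hours, burst_starts


class MovementHMM:
    """K-state movement HMM over one or more step series.

    Parameters
    ----------
    data : sequence of StepSeries (or a single StepSeries)
        Observation bursts; the likelihood restarts at each burst with the
        shared initial distribution.
    n_states : int
        Number of behavioral states (2 or 3 in typical use).
    transition_covariate : {"cosinor", "hour", "none"}
        Diel covariate form on the off-diagonal transition logits.
    zero_mass : bool
        If True, fit a per-state point mass at step length 0 (zero-inflated
        gamma).  If False (default), zero steps are an error.
    """

    def __init__(
        self,
        data,
        n_states: int = 3,
        transition_covariate: str = "cosinor",
        zero_mass: bool = False,
    ):
        if isinstance(data, StepSeries):
            data = [data]
        data = list(data)
        if not data:
            raise ValueError("no step series provided")
        if transition_covariate not in COVARIATE_FORMS:
            raise ValueError(
                f"transition_covariate must be one of {COVARIATE_FORMS}"
            )
        self.data = data
        self.n_states = int(n_states)
        self.transition_covariate = transition_covariate
        self.zero_mass = bool(zero_mass)
        self.steps, self.turns, self.hours, self.burst_starts = _pack_data(data)
        if np.any(self.steps < 0) or not np.all(np.isfinite(self.steps)):
            raise ValueError("step lengths must be finite and non-negative")
        if np.any(self.steps == 0) and not zero_mass:
            raise ZeroStepError(
                "data contain zero step lengths; construct the model with "
                "zero_mass=True to add a per-state point mass at zero"
            )
        self.tcov = _tcov_design(self.hours, transition_covariate)
        self._C = self.tcov.shape[1]

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, n_states: int = 3, **kwargs
    ) -> "MovementHMM":
        """Build from a tidy step table (columns animal_id, burst_id, t,
        step_m, turn_rad, hour, season) as written by the tracks module."""
        series = []
        for (aid, bid), grp in frame.groupby(["animal_id", "burst_id"], sort=True):
            series.append(
                StepSeries(
                    animal_id=str(aid),
                    burst_id=int(bid),
                    t=grp["t"].to_numpy(),
                    steps=grp["step_m"].to_numpy(dtype=float),
                    turns=grp["turn_rad"].to_numpy(dtype=float),
                    hours=grp["hour"].to_numpy(dtype=float),
                    season=str(grp["season"].iloc[0]) if "season" in grp else "",
                )
            )
        return cls(series, n_states=n_states, **kwargs)

    @property
    def n_obs(self) -> int:
        return len(self.steps)

    # -- likelihood --------------------------------------------------------
    def loglike(self, params: HMMParams) -> float:
        """Forward-algorithm log-likelihood at natural-scale parameters."""
        theta = params.to_working()
        nll = _kernels.forward_nll(
            theta, self.n_states, self._C, self.zero_mass,
            self.steps, self.turns, self.tcov, self.burst_starts,
        )
        return -nll

    def _nll_grad(self, theta: np.ndarray):
        return _kernels.forward_nll_grad(
            theta, self.n_states, self._C, self.zero_mass,
            self.steps, self.turns, self.tcov, self.burst_starts,
        )

    # -- starting values ---------------------------------------------------
    def _random_start(self, rng: np.random.Generator, start_ranges=None) -> np.ndarray:
        """One random starting-value set on the working scale.

        Gamma means are drawn log-uniformly within a factor of 3 of
        quantile anchors of the observed step lengths (state ranks spread
        from the 25th to the 90th percentile), SDs proportional to the
        drawn means, concentrations uniform on [0.05, 0.9], angular means
        at 0 or pi, transition intercepts mildly diagonal-dominant, and
        diel coefficients at zero.
        """
        K = self.n_states
        pos = self.steps[self.steps > 0]
        if start_ranges is not None:
            lo, hi = np.asarray(start_ranges["mean"], dtype=float).T
            anchors = np.sqrt(lo * hi)
            factors = hi / anchors
        else:
            qs = np.linspace(25, 90, K)
            anchors = np.percentile(pos, qs)
            factors = np.full(K, 3.0)
        means = anchors * np.exp(rng.uniform(-np.log(factors), np.log(factors)))
        means = np.sort(means)
        sds = means * rng.uniform(0.5, 1.5, K)
        rhos = rng.uniform(0.05, 0.9, K)
        mu_phi = np.where(rng.random(K) < 0.5, 0.0, np.pi * 0.999)
        p = HMMParams(
            means=means, sds=sds, turn_means=mu_phi, rhos=rhos,
            beta=np.column_stack(
                [rng.uniform(-2.0, -1.0, K * (K - 1))]
                + [np.zeros(K * (K - 1))] * (self._C - 1)
            ),
            delta=np.full(K, 1.0 / K),
            covariate_form=self.transition_covariate,
            zero_mass=np.full(K, np.mean(self.steps == 0) + 1e-6)
            if self.zero_mass else None,
        )
        return p.to_working()

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        n_starts: int = 25,
        seed: Optional[int] = None,
        start_ranges=None,
        maxiter: int = 500,
        gtol: float = 1e-4,
        ftol: float = 1e-8,
    ) -> "HMMResults":
        """Maximize the likelihood from ``n_starts`` random starting sets.

        Returns the best converged start, with states relabeled by
        ascending gamma mean so state 1 is always the shortest-step
        (resting) state.  Raises :class:`FitError` if no start converges.
        """
        rng = np.random.default_rng(seed)
        diagnostics = []
        best = None
        for s in range(n_starts):
            theta0 = self._random_start(rng, start_ranges)
            res = minimize(
                self._nll_grad,
                theta0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol},
            )
            ok = bool(res.success) and res.fun < _kernels.BIG_NLL / 2
            diagnostics.append(
                {"start": s, "converged": ok, "nll": float(res.fun),
                 "n_iter": int(res.nit), "message": str(res.message)}
            )
            if ok and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise FitError(
                f"none of {n_starts} starting-value sets converged",
                diagnostics=diagnostics,
            )
        params = HMMParams.from_working(
            best.x, self.n_states, self.transition_covariate, self.zero_mass
        )
        order = np.argsort(params.means, kind="stable")
        params = params.relabel(order)
        return HMMResults(
            model=self,
            params=params,
            loglik=-float(best.fun),
            n_starts=n_starts,
            diagnostics=diagnostics,
            seed=seed,
        )


class HMMResults:
    """Fitted movement HMM: parameters, fit statistics, and decoding."""

    def __init__(self, model, params, loglik, n_starts, diagnostics, seed=None):
        self.model = model
        self.params = params
        self.loglik = float(loglik)
        self.n_starts = n_starts
        self.diagnostics = diagnostics
        self.seed = seed

    @property
    def n_params(self) -> int:
        return self.params.n_parameters()

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def decode(self) -> np.ndarray:
        """Viterbi-decode the model's own data: the jointly most probable
        state path per burst (1-based states, sorted by mean step)."""
        return self.decode_series(None)

    def decode_series(self, series) -> np.ndarray:
        """Viterbi-decode a step series (or the training data if None)."""
        if series is None:
            steps, turns, tcov, bs = (
                self.model.steps, self.model.turns,
                self.model.tcov, self.model.burst_starts,
            )
        else:
            if isinstance(series, StepSeries):
                series = [series]
            steps, turns, hours, bs = _pack_data(series)
            tcov = _tcov_design(hours, self.params.covariate_form)
        theta = self.params.to_working()
        path = _kernels.viterbi_path(
            theta, self.params.n_states, tcov.shape[1],
            self.params.zero_mass is not None, steps, turns, tcov, bs,
        )
        return path + 1

    def state_probabilities(self, hour: float) -> np.ndarray:
        return self.params.transition_matrix(hour)

    def summary(self) -> str:
        p = self.params
        K = p.n_states
        lines = [
            f"Movement HMM: {K} states, "
            f"transition covariate = {p.covariate_form}",
            f"log-likelihood = {self.loglik:.3f}   "
            f"AIC = {self.aic:.3f}   k = {self.n_params}",
            f"n steps = {self.model.n_obs}, n bursts = "
            f"{len(self.model.burst_starts) - 1}, starts = {self.n_starts} "
            f"({sum(d['converged'] for d in self.diagnostics)} converged)",
            "",
            f"{'state':>5} {'mean step (m)':>14} {'SD step (m)':>12} "
            f"{'turn mean (rad)':>16} {'concentration':>14}",
        ]
        for k in range(K):
            lines.append(
                f"{k + 1:>5} {p.means[k]:>14.3f} {p.sds[k]:>12.3f} "
                f"{p.turn_means[k]:>16.3f} {p.rhos[k]:>14.3f}"
            )
        lines.append("")
        lines.append("initial distribution: "
                     + " ".join(f"{d:.3f}" for d in p.delta))
        lines.append("transition matrix at hour 0:")
        G = p.transition_matrix(0.0)
        for i in range(K):
            lines.append("  " + " ".join(f"{G[i, j]:.3f}" for j in range(K)))
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize the fit (parameters, fit statistics, diagnostics) as JSON."""
        payload = {
            "params": self.params.to_dict(),
            "working": self.params.to_working().tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "diagnostics": self.diagnostics,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def plot_state_distributions(self, ax=None):
        """Plot fitted per-state step-length densities."""
        import matplotlib.pyplot as plt
        from scipy import stats as sps

        if ax is None:
            _, ax = plt.subplots()
        p = self.params
        xmax = np.percentile(self.model.steps, 99.5)
        x = np.linspace(1e-3, xmax, 400)
        for k in range(p.n_states):
            a = (p.means[k] / p.sds[k]) ** 2
            scale = p.sds[k] ** 2 / p.means[k]
            ax.plot(x, sps.gamma.pdf(x, a, scale=scale), label=f"state {k + 1}")
        ax.set_xlabel("step length (m)")
        ax.set_ylabel("density")
        ax.legend()
        return ax


def aic(fit: HMMResults) -> float:
    """Akaike information criterion, -2 logL + 2 k."""
    return fit.aic


def select_states(fits: Sequence[HMMResults]) -> HMMResults:
    """Pick the minimum-AIC fit; ties break toward fewer states."""
    fits = sorted(fits, key=lambda f: (round(f.aic, 9), f.params.n_states))
    return fits[0]


def load_results(path, data=None) -> HMMParams:
    """Load serialized fit parameters (the natural-scale HMMParams)."""
    with open(path) as fh:
        payload = json.load(fh)
    return HMMParams.from_dict(payload["params"])
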