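"""Resource selection functions for used-available designs.

A resource selection function (RSF) models the relative intensity of use
as ``w(x) = exp(beta' x)`` and is estimated by logistic regression
contrasting used points (1) against availability points (0); the intercept
absorbs the used:available sampling ratio and is not interpreted.

Two estimators are provided in the model/results idiom:

* :class:`UsedAvailableLogit` — ordinary logistic GLM (second-order,
  population-level selection), fitted by IRLS via statsmodels.
* :class:`MixedUsedAvailableLogit` — logistic GLMM with a per-animal
  normal random intercept (third-order, within-home-range selection),
  fitted by maximizing the marginal likelihood with adaptive Gauss-Hermite
  quadrature over the random effect.

Standardized coefficients are reported as odds ratios per natural
increment — 100 m for distance covariates, 10 percentage points for canopy
cover — with Wald 95% confidence intervals; an interval crossing 1 marks
the covariate not significant.  Model discrimination is summarized by the
rank-based AUC.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats as sps
from scipy.stats import rankdata

from .landscape import StandardizationStats

__all__ = [
    "UsedAvailableDesign",
    "UsedAvailableLogit",
    "MixedUsedAvailableLogit",
    "RSFResults",
    "MixedRSFResults",
    "OddsEntry",
    "odds_per_increment",
    "odds_report",
    "auc",
    "DISTANCE_INCREMENT",
    "CANOPY_INCREMENT",
]

DISTANCE_INCREMENT = 100.0  # metres
CANOPY_INCREMENT = 10.0  # percentage points


def default_increment(name: str) -> float:
    return CANOPY_INCREMENT if name.startswith("canopy") else DISTANCE_INCREMENT


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class AliasingError(ValueError):
    """Rank-deficient design; carries the aliased column names."""


@dataclasses.dataclass
class UsedAvailableDesign:
    """Binary used (1) / available (0) design with standardized covariates.

    ``groups`` (animal ids per row) are required for mixed fits.  ``stats``
    holds the standardization mean/SD used to build ``X``, needed to report
    odds per natural-unit increment.
    """

    y: np.ndarray
    X: pd.DataFrame  # standardized covariates (no intercept column)
    groups: Optional[np.ndarray] = None
    stats: Optional[StandardizationStats] = None
    stratum: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if set(np.unique(self.y)) - {0.0, 1.0}:
            raise ValueError("response must be binary 0/1")
        if self.y.min() == self.y.max():
            raise ValueError("both used and available rows are required")
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if len(self.groups) != len(self.y):
                raise ValueError("groups and y lengths differ")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        covariates: Sequence[str],
        label_col: str = "used",
        group_col: Optional[str] = None,
        stats: Optional[StandardizationStats] = None,
        **stratum,
    ) -> "UsedAvailableDesign":
        """Build a design from a tidy covariate table.

        If ``stats`` is None the covariates are standardized here on the
        combined used+available set (the conventional fitting set).
        """
        from .landscape import standardize

        covariates = list(covariates)
        if stats is None:
            _, stats = standardize(frame, columns=covariates)
        X = stats.transform(frame[covariates])[covariates]
        groups = frame[group_col].to_numpy() if group_col else None
        return cls(
            y=frame[label_col].to_numpy(dtype=float),
            X=X,
            groups=groups,
            stats=stats,
            stratum=stratum,
        )

    def design_matrix(self) -> np.ndarray:
        return np.column_stack([np.ones(len(self.y)), self.X.to_numpy(dtype=float)])

    @property
    def exog_names(self) -> list[str]:
        return ["const"] + list(self.X.columns)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    full_rank = np.linalg.matrix_rank(X)
    if full_rank < X.shape[1]:
        # identify aliased columns: those whose removal does not lower rank
        aliased = []
        for j in range(X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == full_rank:
                aliased.append(names[j])
        raise AliasingError(
            f"design is rank deficient; aliased column(s): {aliased}"
        )


class UsedAvailableLogit:
    """Second-order RSF: plain logistic regression on a used-available design."""

    def __init__(self, design: UsedAvailableDesign):
        self.design = design

    def fit(self, maxiter: int = 100) -> "RSFResults":
        X = self.design.design_matrix()
        _check_rank(X, self.design.exog_names)
        model = sm.GLM(self.design.y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=maxiter, tol=1e-10)
        except Exception as exc:  # statsmodels PerfectSeparationError etc.
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 50):
            raise SeparationError(
                "non-finite standard errors or runaway coefficients; "
                "the design is likely separated"
            )
        return RSFResults(self, res)


class RSFResults:
    """Fitted second-order RSF (wraps the statsmodels GLM results)."""

    def __init__(self, model: UsedAvailableLogit, glm_results):
        self.model = model
        self._res = glm_results
        self.names = model.design.exog_names

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._res.params, index=self.names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._res.bse, index=self.names)

    @property
    def cov_params(self) -> np.ndarray:
        return np.asarray(self._res.cov_params())

    @property
    def deviance(self) -> float:
        return float(self._res.deviance)

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    def predict_linear(self, X: Optional[np.ndarray] = None) -> np.ndarray:
        if X is None:
            X = self.model.design.design_matrix()
        return X @ np.asarray(self._res.params)

    def auc(self) -> float:
        """Rank-based AUC of the fitted scores against the labels."""
        return auc(self.predict_linear(), self.model.design.y)

    def odds_report(self, increments: Optional[dict] = None) -> pd.DataFrame:
        return odds_report(
            self.params, self.bse, self.model.design.stats, increments
        )

    def summary(self) -> str:
        rep = self.odds_report()
        head = (
            f"Used-available logistic RSF   n = {self.nobs}  "
            f"deviance = {self.deviance:.2f}  AUC = {self.auc():.3f}\n"
        )
        return head + rep.to_string(float_format=lambda v: f"{v:.4f}")


# -- mixed model -----------------------------------------------------------

def _group_index(groups: np.ndarray):
    uniq, inv = np.unique(groups, return_inverse=True)
    return uniq, inv


def _group_mode(eta_fixed, y, tau, max_newton=50):
    """Posterior mode and curvature of the random intercept for one group.

    Maximizes g(u) = sum_j [y eta - log(1+exp(eta))] - u^2/2 with
    eta = eta_fixed + tau * u, by Newton iteration (g is strictly concave).
    """
    u = 0.0
    for _ in range(max_newton):
        eta = eta_fixed + tau * u
        p = special.expit(eta)
        g1 = tau * np.sum(y - p) - u
        g2 = -(tau**2) * np.sum(p * (1 - p)) - 1.0
        step = g1 / g2
        u_new = u - step
        if abs(u_new - u) < 1e-10:
            u = u_new
            break
        u = u_new
    eta = eta_fixed + tau * u
    p = special.expit(eta)
    g2 = -(tau**2) * np.sum(p * (1 - p)) - 1.0
    return u, g2


def _mixed_loglik(beta, tau, X, y, inv, n_groups, nodes, weights):
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    Random intercepts are standardized (u ~ N(0,1), entering as tau*u).
    Nodes are recentred at each group's posterior mode and rescaled by the
    local curvature; one node reproduces the Laplace approximation.
    """
    eta_fixed = X @ beta
    ll = 0.0
    for g in range(n_groups):
        idx = inv == g
        ef = eta_fixed[idx]
        yg = y[idx]
        uhat, g2 = _group_mode(ef, yg, tau)
        shat = 1.0 / np.sqrt(-g2)
        z = uhat + np.sqrt(2.0) * shat * nodes
        eta = ef[:, None] + tau * z[None, :]
        logp = np.sum(yg[:, None] * eta - np.logaddexp(0.0, eta), axis=0)
        integrand = logp - 0.5 * z**2 - 0.5 * np.log(2 * np.pi)
        logw = np.log(weights) + nodes**2 + np.log(np.sqrt(2.0) * shat)
        ll += special.logsumexp(integrand + logw)
    return ll


class MixedUsedAvailableLogit:
    """Third-order RSF: logistic regression with a per-animal random intercept.

    The marginal likelihood integrates the normal random intercept out by
    adaptive Gauss-Hermite quadrature (default 15 nodes; 1 node gives the
    Laplace approximation); fixed effects and the random-intercept SD tau
    are maximized jointly.
    """

    def __init__(self, design: UsedAvailableDesign, n_quad: int = 15):
        if design.groups is None:
            raise ValueError("mixed fit requires group ids")
        self.design = design
        uniq, inv = _group_index(design.groups)
        if len(uniq) < 2:
            raise ValueError("mixed fit requires at least 2 groups")
        self.group_labels = uniq
        self._inv = inv
        if n_quad < 1:
            raise ValueError("n_quad must be >= 1")
        self.n_quad = int(n_quad)
        nodes, weights = np.polynomial.hermite.hermgauss(self.n_quad)
        self._nodes = nodes
        self._weights = weights

    def loglike(self, beta: np.ndarray, tau: float) -> float:
        """Marginal log-likelihood at given fixed effects and intercept SD."""
        X = self.design.design_matrix()
        return float(
            _mixed_loglik(
                np.asarray(beta, dtype=float), float(tau), X, self.design.y,
                self._inv, len(self.group_labels), self._nodes, self._weights,
            )
        )

    def fit(self, maxiter: int = 200) -> "MixedRSFResults":
        X = self.design.design_matrix()
        _check_rank(X, self.design.exog_names)
        y = self.design.y
        # warm start at the plain GLM solution, tau at a modest positive value
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        x0 = np.append(np.asarray(glm.params), 0.5)
        n_groups = len(self.group_labels)

        def negll(par):
            beta, tau = par[:-1], par[-1]
            return -_mixed_loglik(
                beta, tau, X, y, self._inv, n_groups,
                self._nodes, self._weights,
            )

        bounds = [(None, None)] * (X.shape[1]) + [(0.0, None)]
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11},
        )
        if not res.success and res.nit >= maxiter:
            raise RuntimeError(
                f"mixed logistic fit did not converge: {res.message} "
                f"(nit={res.nit}, nll={res.fun:.4f})"
            )
        # observed-information standard errors via numerical Hessian
        hess = _numerical_hessian(negll, res.x)
        return MixedRSFResults(self, res.x[:-1], float(res.x[-1]),
                               -float(res.fun), hess)


def _numerical_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


class MixedRSFResults:
    """Fitted mixed RSF: fixed effects, random-intercept SD, uncertainty."""

    def __init__(self, model, beta, tau, loglik, hessian):
        self.model = model
        self.names = model.design.exog_names
        self._beta = np.asarray(beta, dtype=float)
        self.tau = float(tau)
        self.loglik = float(loglik)
        self._hess = hessian
        k = len(self._beta)
        try:
            cov = np.linalg.inv(hessian)
            self._cov_beta = cov[:k, :k]
            self.tau_se = float(np.sqrt(max(cov[k, k], 0.0)))
        except np.linalg.LinAlgError:
            self._cov_beta = np.full((k, k), np.nan)
            self.tau_se = np.nan

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._beta, index=self.names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.clip(np.diag(self._cov_beta), 0, None)),
                         index=self.names)

    @property
    def integration(self) -> str:
        n = self.model.n_quad
        return "laplace" if n == 1 else f"adaptive Gauss-Hermite ({n} nodes)"

    def predict_linear(self) -> np.ndarray:
        """Population-level (random effect at 0) linear predictor."""
        return self.model.design.design_matrix() @ self._beta

    def auc(self) -> float:
        return auc(self.predict_linear(), self.model.design.y)

    def odds_report(self, increments: Optional[dict] = None) -> pd.DataFrame:
        return odds_report(self.params, self.bse,
                           self.model.design.stats, increments)

    def summary(self) -> str:
        head = (
            f"Mixed used-available logistic RSF "
            f"({self.integration})\n"
            f"groups = {len(self.model.group_labels)}  "
            f"random-intercept SD tau = {self.tau:.4f}  "
            f"logL = {self.loglik:.2f}  AUC = {self.auc():.3f}\n"
        )
        return head + self.odds_report().to_string(
            float_format=lambda v: f"{v:.4f}"
        )


# -- odds ratios and AUC ---------------------------------------------------

@dataclasses.dataclass
class OddsEntry:
    covariate: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    increment: float
    significant: bool


def odds_per_increment(
    beta_std: float,
    se_std: float,
    sd: float,
    increment: float,
    name: str = "",
) -> OddsEntry:
    """Back-transform a standardized coefficient to an odds ratio per increment.

    The per-unit coefficient is ``beta_std / sd``; the odds ratio per
    ``increment`` natural units is ``exp(increment * beta_std / sd)``
    (100 m for distances, 10 percentage points for canopy).  The 95% CI
    transforms the Wald interval ``beta_std ± 1.96 SE`` the same way.
    """
    if sd <= 0:
        raise ValueError("standardization SD must be positive")
    scale = increment / sd
    orr = float(np.exp(beta_std * scale))
    lo = float(np.exp((beta_std - 1.96 * se_std) * scale))
    hi = float(np.exp((beta_std + 1.96 * se_std) * scale))
    lo, hi = min(lo, hi), max(lo, hi)
    return OddsEntry(
        covariate=name,
        odds_ratio=orr,
        ci_low=lo,
        ci_high=hi,
        increment=increment,
        significant=not (lo <= 1.0 <= hi),
    )


def odds_report(
    params: pd.Series,
    bse: pd.Series,
    stats: Optional[StandardizationStats],
    increments: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-covariate odds table (intercept excluded from interpretation)."""
    rows = []
    for name in params.index:
        if name == "const":
            continue
        sd = float(stats.sd[name]) if stats is not None else 1.0
        inc = (increments or {}).get(name, default_increment(name))
        e = odds_per_increment(params[name], bse[name], sd, inc, name=name)
        row = dataclasses.asdict(e)
        row["beta_std"] = float(params[name])
        row["se"] = float(bse[name])
        rows.append(row)
    if not rows:
        return pd.DataFrame()
    cols = ["beta_std", "se", "odds_ratio", "ci_low", "ci_high",
            "increment", "significant"]
    return pd.DataFrame(rows).set_index("covariate")[cols]


def auc(scores, labels) -> float:
    """Rank-based (concordance) AUC.

    The fraction of used-available pairs in which the used point scores
    higher, ties counted one half — the Mann-Whitney statistic divided by
    n1 * n0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both used and available rows")
    ranks = rankdata(scores)  # midranks handle ties as 1/2
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))
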