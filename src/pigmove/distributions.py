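"""Emission distributions for movement HMMs.

Step lengths are modelled with a gamma distribution parameterised by its
mean ``mu`` and standard deviation ``sigma`` (the parameterisation movement
ecologists report), turning angles with a wrapped Cauchy distribution with
angular mean ``mu_phi`` and concentration ``rho``.

The mean/SD gamma maps onto the shape/rate form as

    shape = (mu / sigma)**2,   rate = mu / sigma**2
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "gamma_shape_rate",
    "gamma_logpdf",
    "wcauchy_logpdf",
    "wcauchy_rvs",
    "circular_mean",
    "wrap_angle",
]


class ZeroStepError(ValueError):
    """A zero step length reached the gamma density.

    The gamma density is undefined at 0 for shape > 1 and infinite for
    shape < 1.  Enable the zero-inflated option (``zero_mass``) on the HMM
    if the data contain exact zeros.
    """


def gamma_shape_rate(mu, sigma):
    """Convert mean/SD gamma parameters to (shape, rate)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(mu <= 0) or np.any(sigma <= 0):
        raise ValueError("gamma mean and SD must be positive")
    shape = (mu / sigma) ** 2
    rate = mu / sigma**2
    return shape, rate


def gamma_logpdf(length, mu, sigma):
    """Log-density of step length under the mean/SD gamma.

    Parameters
    ----------
    length : array_like
        Step length(s) in metres, strictly positive.
    mu, sigma : float
        Mean and standard deviation of the gamma, in metres.

    Raises
    ------
    ZeroStepError
        If any step length is exactly zero.  Zeros carry no gamma density;
        use the HMM's zero-mass (zero-inflated gamma) option instead.
    """
    length = np.asarray(length, dtype=float)
    if np.any(length == 0):
        raise ZeroStepError(
            "step length 0 has no gamma density; enable zero_mass to model "
            "exact zeros with a per-state point mass"
        )
    if np.any(length < 0):
        raise ValueError("step lengths must be non-negative")
    shape, rate = gamma_shape_rate(mu, sigma)
    return stats.gamma.logpdf(length, a=shape, scale=1.0 / rate)


def wrap_angle(phi):
    """Wrap angle(s) to (-pi, pi], with +pi chosen at the boundary."""
    phi = np.asarray(phi, dtype=float)
    out = -(np.mod(-phi + np.pi, 2 * np.pi) - np.pi)
    return out


def wcauchy_logpdf(phi, mu_phi, rho):
    """Log-density of the wrapped Cauchy on (-pi, pi].

    f(phi) = (1/2pi) * (1 - rho^2) / (1 + rho^2 - 2 rho cos(phi - mu_phi))

    ``rho = 0`` is the circular uniform; ``rho -> 1`` concentrates at
    ``mu_phi``.
    """
    phi = np.asarray(phi, dtype=float)
    rho = float(rho)
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"wrapped Cauchy concentration must be in [0, 1), got {rho}")
    denom = 1.0 + rho**2 - 2.0 * rho * np.cos(phi - mu_phi)
    return np.log1p(-(rho**2)) - np.log(2.0 * np.pi) - np.log(denom)


def wcauchy_rvs(mu_phi, rho, size, rng):
    """Draw wrapped Cauchy variates on (-pi, pi].

    Uses the scipy wrapped Cauchy (supported on [0, 2pi)) shifted to the
    signed-angle convention.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"wrapped Cauchy concentration must be in [0, 1), got {rho}")
    if rho == 0.0:
        return rng.uniform(-np.pi, np.pi, size)
    draws = stats.wrapcauchy.rvs(c=rho, size=size, random_state=rng)
    return wrap_angle(draws + mu_phi)


def circular_mean(phi):
    """Circular mean direction in (-pi, pi] (atan2 of mean sine/cosine)."""
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise ValueError("circular mean of empty sample")
    ang = np.arctan2(np.mean(np.sin(phi)), np.mean(np.cos(phi)))
    # atan2 returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] convention
    if ang == -np.pi:
        ang = np.pi
    return float(ang)
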