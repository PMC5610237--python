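"""Closed-form distributions behind the TWO-NN estimator.

For a locally homogeneous Poisson sample in dimension ``d``, the volume of the
hyperspherical shell between consecutive neighbors is exponentially
distributed with rate equal to the density rho, so the ratio of two shell
volumes ``R = dv2/dv1`` has density ``g(R) = 1/(1+R)^2`` independent of both
``d`` and rho.  In terms of the observable ratio ``mu = r2/r1`` of the first
two neighbor distances, ``R = mu^d - 1``, which gives the Pareto law

    f(mu) = d * mu^(-d-1),        F(mu) = 1 - mu^(-d),    mu >= 1.

The density cancels, so ``-log(1 - F(mu)) / log(mu) = d`` exactly: the basis
of the estimator in :mod:`twonn.estimator`.  These closed forms are used for
quantile injection, goodness-of-fit testing and property tests.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gamma

from .exceptions import InvalidParameterError

__all__ = [
    "pdf_mu",
    "cdf_mu",
    "quantile_mu",
    "pdf_ratio",
    "mu_of_ratio",
    "unit_ball_volume",
    "shell_volumes",
]


def _check_d(d: float) -> float:
    d = float(d)
    if not np.isfinite(d) or d <= 0:
        raise InvalidParameterError(f"intrinsic dimension must be > 0, got {d}")
    return d


def pdf_mu(mu, d):
    """Density f(mu) = d * mu^(-d-1) on [1, inf); zero below 1."""
    d = _check_d(d)
    mu = np.asarray(mu, dtype=float)
    out = np.where(mu >= 1.0, d * np.power(np.maximum(mu, 1.0), -d - 1.0), 0.0)
    return out if out.ndim else float(out)


def cdf_mu(mu, d):
    """Cumulative distribution F(mu) = 1 - mu^(-d) on [1, inf); zero below 1."""
    d = _check_d(d)
    mu = np.asarray(mu, dtype=float)
    out = np.where(mu >= 1.0, 1.0 - np.power(np.maximum(mu, 1.0), -d), 0.0)
    return out if out.ndim else float(out)


def quantile_mu(p, d):
    """Inverse of :func:`cdf_mu`: mu = (1 - p)^(-1/d) for p in [0, 1)."""
    d = _check_d(d)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise InvalidParameterError("quantile probability must lie in [0, 1)")
    out = np.power(1.0 - p, -1.0 / d)
    return out if out.ndim else float(out)


def pdf_ratio(R):
    """Density g(R) = 1/(1+R)^2 of the shell-volume ratio, R >= 0."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise InvalidParameterError("shell-volume ratio R must be >= 0")
    out = 1.0 / (1.0 + R) ** 2
    return out if out.ndim else float(out)


def mu_of_ratio(R, d):
    """Invert R = mu^d - 1: mu = (1+R)^(1/d)."""
    d = _check_d(d)
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise InvalidParameterError("shell-volume ratio R must be >= 0")
    out = np.power(1.0 + R, 1.0 / d)
    return out if out.ndim else float(out)


def unit_ball_volume(d) -> float:
    """Volume omega_d = pi^(d/2) / Gamma(d/2 + 1) of the unit ball in R^d."""
    d = _check_d(d)
    return float(np.pi ** (d / 2.0) / gamma(d / 2.0 + 1.0))


def shell_volumes(radii, d):
    """Volumes of hyperspherical shells between consecutive neighbor radii.

    Parameters
    ----------
    radii : array-like
        Nondecreasing, nonnegative radii r_1 <= ... <= r_k (r_0 = 0 is
        implicit).
    d : int
        Ambient dimension, >= 1.

    Returns
    -------
    ndarray
        dv_l = omega_d * (r_l^d - r_{l-1}^d), one value per radius.
    """
    d = int(d)
    if d < 1:
        raise InvalidParameterError("dimension d must be an integer >= 1")
    r = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(r < 0):
        raise InvalidParameterError("radii must be nonnegative")
    if np.any(np.diff(r) < 0):
        raise InvalidParameterError("radii must be sorted in nondecreasing order")
    powers = np.concatenate([[0.0], r**d])
    return unit_ball_volume(d) * np.diff(powers)
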