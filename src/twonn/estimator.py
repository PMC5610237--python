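"""The TWO-NN intrinsic dimension estimator.

The pipeline: for every point take the distances r1, r2 to its two nearest
neighbors, form mu = r2/r1, build the empirical cumulate F(mu_(i)) = i/N on
the sorted ratios, and fit the set {(log mu, -log(1 - F))} with a straight
line through the origin.  Under local homogeneity the ratios are Pareto
distributed with shape equal to the intrinsic dimension (see
:mod:`twonn.theory`), so the slope estimates d.

The fit by default discards the 10% of points with the highest mu, which
tames heavy tails (for heavy-tailed data a few extreme ratios otherwise
dominate the least-squares slope).  The point with F = 1 has infinite
ordinate; with a positive discard fraction it is always among the discarded
points, and with discard_fraction = 0 it is excluded from the fit with a
warning, the only finite-valued reading of the cumulate convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidParameterError,
)
from .neighbors import (
    NeighborDistances,
    two_nearest,
    two_nearest_from_matrix,
)

__all__ = [
    "MuSample",
    "IdEstimate",
    "compute_mu",
    "empirical_cumulate",
    "fit_through_origin",
    "estimate_id",
    "estimate_id_from_mu",
]


@dataclass
class MuSample:
    """Neighbor-distance ratios mu = r2/r1 with their source row indices."""

    mu: np.ndarray
    source_index: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.source_index = np.asarray(self.source_index, dtype=int)

    def __len__(self) -> int:
        return len(self.mu)


@dataclass
class IdEstimate:
    """Result of the TWO-NN fit.

    ``fit_x``/``fit_y`` are the (log mu, -log(1 - F)) pairs actually used in
    the origin-constrained fit, sorted by increasing mu; ``n_used`` is the
    number of smallest-mu points retained by the discard rule, i.e.
    ``floor(n_total * (1 - discard_fraction))`` (with ``discard_fraction = 0``
    the top point has F = 1 and is additionally excluded from the fit).
    """

    d_hat: float
    discard_fraction: float
    n_total: int
    n_used: int
    fit_x: np.ndarray
    fit_y: np.ndarray
    residual_rms: float

    def __repr__(self) -> str:  # compact, the arrays can be large
        return (
            f"IdEstimate(d_hat={self.d_hat:.4g}, n_total={self.n_total}, "
            f"n_used={self.n_used}, discard_fraction={self.discard_fraction})"
        )


def compute_mu(nd: NeighborDistances) -> MuSample:
    """Per-point ratio mu = r2/r1 (requires all r1 > 0)."""
    r1 = np.asarray(nd.r1, dtype=float)
    r2 = np.asarray(nd.r2, dtype=float)
    if np.any(r1 <= 0.0):
        raise InvalidParameterError(
            "mu = r2/r1 is undefined where r1 = 0 (coincident points)"
        )
    return MuSample(mu=r2 / r1, source_index=np.asarray(nd.kept, dtype=int))


def empirical_cumulate(sample) -> tuple[np.ndarray, np.ndarray]:
    """Sorted mu values and their empirical cumulate F = i/M, i = 1..M.

    Ties receive consecutive ranks in source order (stable sort).
    """
    mu = sample.mu if isinstance(sample, MuSample) else np.asarray(sample, dtype=float)
    M = len(mu)
    if M < 2:
        raise InsufficientDataError("need at least 2 mu values for the cumulate")
    order = np.argsort(mu, kind="stable")
    mu_sorted = mu[order]
    F = np.arange(1, M + 1, dtype=float) / M
    return mu_sorted, F


def fit_through_origin(x, y) -> float:
    """Least-squares slope of y = s*x constrained through the origin.

    Minimizes sum (y - s x)^2, i.e. s = sum(x y) / sum(x^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("x and y must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidParameterError("fit input contains non-finite values")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise DegenerateFitError("all abscissae are zero; slope is undefined")
    return float(np.dot(x, y) / sxx)


def estimate_id_from_mu(
    mu,
    discard_fraction: float = 0.10,
) -> IdEstimate:
    """Run the cumulate-linearization fit on a sample of mu ratios."""
    if not (0.0 <= discard_fraction < 1.0):
        raise InvalidParameterError("discard_fraction must lie in [0, 1)")
    mu = mu.mu if isinstance(mu, MuSample) else np.asarray(mu, dtype=float)
    n_total = len(mu)
    mu_sorted, F = empirical_cumulate(mu)
    n_used = math.floor(n_total * (1.0 - discard_fraction))
    if n_used < 2:
        raise InsufficientDataError(
            f"only {n_used} point(s) retained by discard_fraction={discard_fraction}"
        )
    mu_kept, F_kept = mu_sorted[:n_used], F[:n_used]
    if F_kept[-1] >= 1.0:
        # only reachable with discard_fraction = 0: drop the infinite-y point
        warnings.warn(
            "discard_fraction=0: excluding the maximal-mu point (F=1, infinite "
            "ordinate) from the fit",
            stacklevel=2,
        )
        mu_kept, F_kept = mu_kept[:-1], F_kept[:-1]
    x = np.log(mu_kept)
    y = -np.log1p(-F_kept)
    d_hat = fit_through_origin(x, y)
    resid = y - d_hat * x
    return IdEstimate(
        d_hat=d_hat,
        discard_fraction=float(discard_fraction),
        n_total=n_total,
        n_used=n_used,
        fit_x=x,
        fit_y=y,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def estimate_id(
    data,
    discard_fraction: float = 0.10,
    box=None,
    metric: str = "euclidean",
    on_duplicates: str = "error",
) -> IdEstimate:
    """Estimate the intrinsic dimension of a dataset with TWO-NN.

    Parameters
    ----------
    data : array-like
        Either an N x D coordinate matrix (``metric="euclidean"``) or an
        N x N distance matrix (``metric="precomputed"``).
    discard_fraction : float in [0, 1)
        Fraction of highest-mu points excluded from the fit (default 0.10).
    box : PeriodicBox, sequence of side lengths, or None
        Periodic boundary conditions for the Euclidean metric.
    metric : {"euclidean", "precomputed"}
    on_duplicates : {"error", "drop"}
        Behavior on coincident points (see :func:`twonn.neighbors.two_nearest`).

    Returns
    -------
    IdEstimate
        The fitted slope d_hat with the fit points and diagnostics.
    """
    if metric == "euclidean":
        nd = two_nearest(data, box=box, on_duplicates=on_duplicates)
    elif metric == "precomputed":
        if box is not None:
            raise InvalidParameterError("box is meaningless for a precomputed matrix")
        nd = two_nearest_from_matrix(data, on_duplicates=on_duplicates)
    else:
        raise InvalidParameterError("metric must be 'euclidean' or 'precomputed'")
    sample = compute_mu(nd)
    return estimate_id_from_mu(sample, discard_fraction=discard_fraction)
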