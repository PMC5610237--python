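"""Scale-dependent intrinsic dimension by block (decimation) analysis.

Nearest-neighbor estimators probe the dataset at the scale of the typical
second-neighbor distance, which shrinks as the sample grows.  Estimating the
dimension on disjoint subsamples of decreasing size therefore sweeps the
length scale: on a low-dimensional manifold blurred by small high-dimensional
noise, the estimate rises towards the ambient dimension at large subsample
sizes (the noise gets resolved) and sits at the manifold dimension over a
plateau of smaller sizes.  The plateau value counts the "soft" directions.

For each requested size n the rows are shuffled once with the seeded
generator and partitioned into floor(N/n) disjoint blocks of exactly n
points (the remainder is discarded); the TWO-NN estimate runs on every block
and the mean and dispersion across blocks are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import estimate_id
from .exceptions import InvalidParameterError

__all__ = [
    "DecimationCurve",
    "Plateau",
    "auto_sizes",
    "decimation_curve",
    "plateau_report",
]


@dataclass
class DecimationCurve:
    """d_hat versus block size: per size, the mean and dispersion over the
    disjoint blocks of that size (dispersion is the population standard
    deviation across blocks, 0 for a single block)."""

    block_size: np.ndarray
    d_mean: np.ndarray
    d_std: np.ndarray
    n_blocks: np.ndarray
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.block_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block_size": self.block_size,
                "d_mean": self.d_mean,
                "d_std": self.d_std,
                "n_blocks": self.n_blocks,
            }
        )


@dataclass
class Plateau:
    """Advisory plateau candidate: the longest flat run of a curve."""

    size_min: int
    size_max: int
    d_value: float
    n_sizes: int


def auto_sizes(n_total: int, n_min: int = 10, per_decade: int = 10) -> list[int]:
    """Geometric grid of block sizes, ~``per_decade`` sizes per decade from
    ``n_min`` up to and including ``n_total``."""
    n_total = int(n_total)
    if n_total < 3:
        raise InvalidParameterError("n_total must be >= 3")
    n_min = max(3, min(int(n_min), n_total))
    sizes = {n_min, n_total}
    k = 0
    while True:
        s = int(round(n_min * 10.0 ** (k / per_decade)))
        if s >= n_total:
            break
        sizes.add(s)
        k += 1
    return sorted(sizes)


def decimation_curve(
    data,
    sizes=None,
    seed=None,
    discard_fraction: float = 0.10,
    box=None,
    metric: str = "euclidean",
    on_duplicates: str = "error",
) -> DecimationCurve:
    """Estimate d_hat on disjoint blocks for each requested block size.

    Parameters
    ----------
    data : array-like
        Coordinate matrix (``metric="euclidean"``) or square distance matrix
        (``metric="precomputed"``; blocks then index principal submatrices).
    sizes : iterable of int, optional
        Block sizes, each in [3, N].  Default: :func:`auto_sizes`.
    seed : int, optional
        Seed for the per-size shuffles.
    discard_fraction, box, on_duplicates :
        Passed through to :func:`twonn.estimator.estimate_id`.
    """
    data = np.asarray(data, dtype=float)
    n_total = data.shape[0]
    if sizes is None:
        sizes = auto_sizes(n_total)
    sizes = sorted(int(s) for s in sizes)
    for s in sizes:
        if s < 3:
            raise InvalidParameterError(f"block size {s} < 3")
        if s > n_total:
            raise InvalidParameterError(f"block size {s} exceeds dataset size {n_total}")

    rng = np.random.default_rng(seed)
    mean, std, blocks = [], [], []
    for s in sizes:
        m = n_total // s
        perm = rng.permutation(n_total)
        vals = np.empty(m)
        for b in range(m):
            idx = perm[b * s : (b + 1) * s]
            if metric == "precomputed":
                idx = np.sort(idx)
                sub = data[np.ix_(idx, idx)]
            else:
                sub = data[idx]
            vals[b] = estimate_id(
                sub,
                discard_fraction=discard_fraction,
                box=box,
                metric=metric,
                on_duplicates=on_duplicates,
            ).d_hat
        mean.append(vals.mean())
        std.append(vals.std())  # population std: well defined for m = 1
        blocks.append(m)
    return DecimationCurve(
        block_size=np.array(sizes, dtype=int),
        d_mean=np.array(mean),
        d_std=np.array(std),
        n_blocks=np.array(blocks, dtype=int),
        seed=None if seed is None or isinstance(seed, np.random.Generator) else int(seed),
    )


def plateau_report(curve: DecimationCurve, flatness_tol: float = 0.10) -> Plateau | None:
    """Longest consecutive run of sizes whose mean d_hat is flat.

    A run [i..j] is flat when (max - min) of the means over the run is below
    ``flatness_tol`` relative to the run's mean.  Runs must span at least two
    sizes; among equally long runs the one at larger block sizes wins (larger
    blocks give the less noisy estimates).  Advisory only — inspect the curve.
    """
    if len(curve) < 3:
        raise InvalidParameterError("plateau detection needs a curve with >= 3 sizes")
    if flatness_tol <= 0:
        raise InvalidParameterError("flatness_tol must be > 0")
    means = np.asarray(curve.d_mean, dtype=float)
    n = len(means)
    best: tuple[int, int] | None = None
    for i in range(n):
        lo = hi = means[i]
        for j in range(i + 1, n):
            lo, hi = min(lo, means[j]), max(hi, means[j])
            center = (
                np.mean(means[i : j + 1])
            )
            if center <= 0 or (hi - lo) / center >= flatness_tol:
                break
            length = j - i + 1
            if best is None or length >= (best[1] - best[0] + 1):
                best = (i, j)
    if best is None:
        return None
    i, j = best
    return Plateau(
        size_min=int(curve.block_size[i]),
        size_max=int(curve.block_size[j]),
        d_value=float(np.mean(means[i : j + 1])),
        n_sizes=j - i + 1,
    )
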