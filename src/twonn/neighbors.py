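"""First- and second-nearest-neighbor distances.

Supports three metrics: plain Euclidean, Euclidean with periodic boundary
conditions (minimum-image convention on a rectangular box), and a precomputed
square distance matrix (the route by which non-Euclidean metrics such as RMSD
enter the pipeline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import (
    DuplicatePointsError,
    InsufficientDataError,
    InvalidMatrixError,
    InvalidParameterError,
)

__all__ = [
    "PeriodicBox",
    "NeighborDistances",
    "as_data_matrix",
    "two_nearest",
    "two_nearest_from_matrix",
    "validate_distance_matrix",
]

#: symmetry tolerance for distance matrices
SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class PeriodicBox:
    """Rectangular box with toroidal topology (minimum-image distances)."""

    side_lengths: tuple[float, ...]

    def __post_init__(self):
        sides = tuple(float(s) for s in np.atleast_1d(np.asarray(self.side_lengths, dtype=float)))
        if len(sides) == 0 or any(not np.isfinite(s) or s <= 0 for s in sides):
            raise InvalidParameterError("box side lengths must all be positive and finite")
        object.__setattr__(self, "side_lengths", sides)

    @property
    def ndim(self) -> int:
        return len(self.side_lengths)


@dataclass
class NeighborDistances:
    """Per-point first and second neighbor distances with audit indices."""

    r1: np.ndarray
    r2: np.ndarray
    index_1: np.ndarray
    index_2: np.ndarray
    #: row indices of the original input that survived deduplication
    kept: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.kept is None:
            self.kept = np.arange(len(self.r1))

    def __len__(self) -> int:
        return len(self.r1)


def as_data_matrix(X) -> np.ndarray:
    """Validate and return an N x D float coordinate matrix (N >= 3, finite)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidParameterError(f"expected a 2-D coordinate matrix, got ndim={X.ndim}")
    if X.shape[0] < 3:
        raise InsufficientDataError(
            f"need at least 3 points to find two neighbors, got {X.shape[0]}"
        )
    if not np.all(np.isfinite(X)):
        raise InvalidParameterError("coordinate matrix contains non-finite entries")
    return X


def _coerce_box(box, ndim: int) -> PeriodicBox | None:
    if box is None:
        return None
    if not isinstance(box, PeriodicBox):
        sides = np.atleast_1d(np.asarray(box, dtype=float))
        if sides.size == 1:
            sides = np.repeat(sides, ndim)
        box = PeriodicBox(tuple(sides))
    if box.ndim != ndim:
        raise InvalidParameterError(
            f"box dimension {box.ndim} does not match data dimension {ndim}"
        )
    return box


def _drop_duplicate_rows(X: np.ndarray) -> np.ndarray:
    """Indices of first occurrences of each distinct row, in original order."""
    _, first = np.unique(X, axis=0, return_index=True)
    return np.sort(first)


def two_nearest(
    X,
    box=None,
    on_duplicates: str = "error",
) -> NeighborDistances:
    """Two smallest positive neighbor distances for every point.

    Parameters
    ----------
    X : array-like, shape (N, D)
        Coordinate matrix, N >= 3.
    box : PeriodicBox, sequence of side lengths, or None
        If given, distances use the minimum-image convention
        ``min(|dx|, L - |dx|)`` per coordinate.
    on_duplicates : {"error", "drop"}
        Exact duplicate points make r1 = 0 and mu undefined.  ``"error"``
        (default) raises; ``"drop"`` keeps the first occurrence of each
        distinct point, warns, and records the surviving row indices in
        ``NeighborDistances.kept``.
    """
    if on_duplicates not in ("error", "drop"):
        raise InvalidParameterError("on_duplicates must be 'error' or 'drop'")
    X = as_data_matrix(X)
    kept = np.arange(X.shape[0])
    if on_duplicates == "drop":
        first = _drop_duplicate_rows(X)
        if len(first) < len(X):
            warnings.warn(
                f"dropped {len(X) - len(first)} duplicate point(s) before neighbor search",
                stacklevel=2,
            )
            kept = first
            X = X[first]
            if X.shape[0] < 3:
                raise InsufficientDataError(
                    "fewer than 3 distinct points after duplicate removal"
                )
    box = _coerce_box(box, X.shape[1])

    if box is None:
        tree = cKDTree(X)
        dist, idx = tree.query(X, k=3)
    else:
        sides = np.asarray(box.side_lengths)
        wrapped = np.mod(X, sides)
        # guard against wrapped == L from floating-point mod of negatives
        wrapped = np.where(wrapped >= sides, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=sides)
        dist, idx = tree.query(wrapped, k=3)

    r1, r2 = dist[:, 1].copy(), dist[:, 2].copy()
    if on_duplicates == "error" and np.any(r1 == 0.0):
        n_dup = int(np.count_nonzero(r1 == 0.0))
        raise DuplicatePointsError(
            f"{n_dup} point(s) have a coincident neighbor (r1 = 0); "
            "pass on_duplicates='drop' to remove duplicates first"
        )
    return NeighborDistances(r1=r1, r2=r2, index_1=idx[:, 1].copy(), index_2=idx[:, 2].copy(), kept=kept)


def validate_distance_matrix(D, tol: float = SYMMETRY_TOL) -> np.ndarray:
    """Validate a square, symmetric, zero-diagonal, nonnegative matrix."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InvalidMatrixError(f"distance matrix must be square, got shape {D.shape}")
    if D.shape[0] < 3:
        raise InsufficientDataError(
            f"need at least 3 points to find two neighbors, got {D.shape[0]}"
        )
    if not np.all(np.isfinite(D)):
        raise InvalidMatrixError("distance matrix contains non-finite entries")
    neg = np.argwhere(D < 0)
    if len(neg):
        i, j = neg[0]
        raise InvalidMatrixError(f"negative distance at entry ({i}, {j}): {D[i, j]}")
    bad_diag = np.nonzero(np.abs(np.diag(D)) > 0)[0]
    if len(bad_diag):
        i = bad_diag[0]
        raise InvalidMatrixError(f"nonzero diagonal at entry ({i}, {i}): {D[i, i]}")
    asym = np.abs(D - D.T)
    worst = np.unravel_index(np.argmax(asym), asym.shape)
    if asym[worst] > tol:
        i, j = worst
        raise InvalidMatrixError(
            f"asymmetry {asym[i, j]:.3g} at entry ({i}, {j}) exceeds tolerance {tol:.1g}"
        )
    return D


def two_nearest_from_matrix(D, on_duplicates: str = "error") -> NeighborDistances:
    """Row-wise two smallest off-diagonal entries of a distance matrix."""
    if on_duplicates not in ("error", "drop"):
        raise InvalidParameterError("on_duplicates must be 'error' or 'drop'")
    D = validate_distance_matrix(D)
    kept = np.arange(D.shape[0])
    work = D.copy()
    np.fill_diagonal(work, np.inf)

    if on_duplicates == "drop":
        # coincident pairs are entries with zero off-diagonal distance;
        # greedily keep the lower-index member of each such pair
        drop: set[int] = set()
        zi, zj = np.nonzero(work == 0.0)
        for i, j in zip(zi, zj):
            if i < j and i not in drop:
                drop.add(int(j))
        if drop:
            warnings.warn(
                f"dropped {len(drop)} duplicate point(s) before neighbor search",
                stacklevel=2,
            )
            kept = np.array([i for i in range(D.shape[0]) if i not in drop])
            if len(kept) < 3:
                raise InsufficientDataError(
                    "fewer than 3 distinct points after duplicate removal"
                )
            work = work[np.ix_(kept, kept)]

    part = np.argpartition(work, (0, 1), axis=1)
    i1, i2 = part[:, 0], part[:, 1]
    rows = np.arange(work.shape[0])
    r1, r2 = work[rows, i1], work[rows, i2]
    swap = r2 < r1
    r1[swap], r2[swap] = r2[swap], r1[swap]
    i1[swap], i2[swap] = i2[swap], i1[swap]
    if on_duplicates == "error" and np.any(r1 == 0.0):
        n_dup = int(np.count_nonzero(r1 == 0.0))
        raise DuplicatePointsError(
            f"{n_dup} point(s) have a coincident neighbor (r1 = 0); "
            "pass on_duplicates='drop' to remove duplicates first"
        )
    return NeighborDistances(r1=r1, r2=r2, index_1=i1, index_2=i2, kept=kept)
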