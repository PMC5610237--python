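"""Synthetic benchmark dataset generators.

Every family used in the benchmark experiments is generated here so that all
tests and analyses run without downloads: uniform hypercubes (with or without
periodic analysis downstream), Gaussian clouds, heavy-tailed "Cauchy"
datasets whose norms follow the density 1/(1+x^2), uniform hyperspheres,
Swiss rolls sampled uniformly by surface area or with a Gaussian profile in
the parameter plane, and manifolds perturbed by Gaussian noise appended
along extra orthogonal directions.

All generators are deterministic given a seed (or an already-constructed
:class:`numpy.random.Generator`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "GeneratorSpec",
    "generate",
    "gen_hypercube",
    "gen_gaussian",
    "gen_cauchy",
    "gen_hypersphere",
    "gen_swiss_roll",
    "add_orthogonal_noise",
    "SWISS_T_RANGE",
    "SWISS_Y_RANGE",
]

#: Swiss-roll parameter window: t in [1.5 pi, 4.5 pi], y in [0, 21].  The
#: window is a convention (a standard choice in manifold-learning benchmarks);
#: both bounds are overridable in :func:`gen_swiss_roll`.
SWISS_T_RANGE = (1.5 * math.pi, 4.5 * math.pi)
SWISS_Y_RANGE = (0.0, 21.0)

#: A standard normal in the (t, y) parameter plane is scaled so ~99% of its
#: mass falls inside the window: std = half-window / z_{0.995}.
_Z995 = 2.5758293035489004

FAMILIES = (
    "hypercube",
    "gaussian",
    "cauchy",
    "hypersphere",
    "swiss_roll",
    "swiss_gaussian",
    "noisy_plane",
    "noisy_swiss_gaussian",
)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_counts(n: int, d: int) -> tuple[int, int]:
    n, d = int(n), int(d)
    if n < 3:
        raise InvalidParameterError(f"need n >= 3 points, got {n}")
    if d < 1:
        raise InvalidParameterError(f"need dimension d >= 1, got {d}")
    return n, d


def gen_hypercube(n: int, d: int, seed=None) -> np.ndarray:
    """n points i.i.d. uniform on the unit hypercube [0, 1]^d."""
    n, d = _check_counts(n, d)
    return _rng(seed).random((n, d))


def gen_gaussian(n: int, d: int, seed=None) -> np.ndarray:
    """n points i.i.d. standard normal in dimension d."""
    n, d = _check_counts(n, d)
    return _rng(seed).standard_normal((n, d))


def gen_cauchy(n: int, d: int, seed=None) -> np.ndarray:
    """Isotropic heavy-tailed cloud: norms follow the density (2/pi)/(1+x^2).

    Each point is a half-Cauchy radius times a direction drawn uniformly on
    the unit (d-1)-sphere — the isotropic reading of "norms distributed
    according to 1/(1+x^2)".
    """
    n, d = _check_counts(n, d)
    rng = _rng(seed)
    radius = np.abs(rng.standard_cauchy(n))
    direction = rng.standard_normal((n, d))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    return radius[:, None] * direction


def gen_hypersphere(n: int, d: int, seed=None) -> np.ndarray:
    """n points uniform on the surface of the unit d-sphere in R^(d+1).

    The intrinsic dimension of the support is d (ambient dimension d+1).
    """
    n, d = _check_counts(n, d)
    rng = _rng(seed)
    v = rng.standard_normal((n, d + 1))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _sample_t_uniform_area(rng: np.random.Generator, n: int, t_range) -> np.ndarray:
    """Draw t with density proportional to sqrt(1 + t^2) on t_range.

    This is the arc-length weight of the spiral (t cos t, t sin t), so the
    resulting surface sampling is uniform in area.  Simple rejection against
    the bounding constant is exact and cheap for the default window.
    """
    a, b = t_range
    ceiling = math.sqrt(1.0 + max(abs(a), abs(b)) ** 2)
    out = np.empty(0)
    while out.size < n:
        cand = rng.uniform(a, b, size=2 * n)
        u = rng.uniform(0.0, ceiling, size=2 * n)
        out = np.concatenate([out, cand[u < np.sqrt(1.0 + cand**2)]])
    return out[:n]


def gen_swiss_roll(
    n: int,
    seed=None,
    gaussian_profile: bool = False,
    t_range: tuple[float, float] = SWISS_T_RANGE,
    y_range: tuple[float, float] = SWISS_Y_RANGE,
) -> np.ndarray:
    """Two-dimensional Swiss roll (t cos t, y, t sin t) embedded in R^3.

    With ``gaussian_profile=False`` the surface is sampled uniformly by area
    (t carries the arc-length weight sqrt(1+t^2), y is uniform).  With
    ``gaussian_profile=True`` the (t, y) parameters follow a bivariate
    normal centered mid-window and scaled so ~99% of the mass lies inside
    the window — a curved, non-uniform-density test manifold.
    """
    n = int(n)
    if n < 3:
        raise InvalidParameterError(f"need n >= 3 points, got {n}")
    a, b = float(t_range[0]), float(t_range[1])
    y_lo, y_hi = float(y_range[0]), float(y_range[1])
    if not (b > a and y_hi > y_lo):
        raise InvalidParameterError("parameter ranges must be nonempty intervals")
    rng = _rng(seed)
    if gaussian_profile:
        t = rng.normal((a + b) / 2.0, (b - a) / 2.0 / _Z995, size=n)
        y = rng.normal((y_lo + y_hi) / 2.0, (y_hi - y_lo) / 2.0 / _Z995, size=n)
    else:
        t = _sample_t_uniform_area(rng, n, (a, b))
        y = rng.uniform(y_lo, y_hi, size=n)
    return np.column_stack([t * np.cos(t), y, t * np.sin(t)])


def add_orthogonal_noise(X, sigma: float, k_dims: int, seed=None) -> np.ndarray:
    """Append k_dims coordinates of i.i.d. N(0, sigma^2) noise to every point.

    The original coordinates are untouched; the ambient dimension grows by
    ``k_dims``.  ``sigma = 0`` appends exact zeros.
    """
    X = np.asarray(X, dtype=float)
    sigma = float(sigma)
    k_dims = int(k_dims)
    if sigma < 0:
        raise InvalidParameterError(f"noise sigma must be >= 0, got {sigma}")
    if k_dims < 0:
        raise InvalidParameterError(f"number of noise dimensions must be >= 0, got {k_dims}")
    if k_dims == 0:
        return X.copy()
    if sigma == 0.0:
        noise = np.zeros((X.shape[0], k_dims))
    else:
        noise = _rng(seed).normal(0.0, sigma, size=(X.shape[0], k_dims))
    return np.hstack([X, noise])


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic dataset.

    Parameters
    ----------
    family : str
        One of ``hypercube, gaussian, cauchy, hypersphere, swiss_roll,
        swiss_gaussian, noisy_plane, noisy_swiss_gaussian``.
    n_points : int
        Sample size N (>= 3).
    intrinsic_dim : int
        Manifold dimension where applicable (ignored by the Swiss-roll and
        plane families, whose dimension is fixed at 2).
    noise_sigma : float
        Standard deviation of the appended Gaussian noise per direction.
    n_noise_dims : int
        Number of appended orthogonal noise directions.
    seed : int
        Seed for the pseudo-random generator.
    """

    family: str
    n_points: int
    intrinsic_dim: int = 2
    noise_sigma: float = 0.0
    n_noise_dims: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidParameterError(
                f"unknown family {self.family!r}; choose from {FAMILIES}"
            )
        if int(self.n_points) < 3:
            raise InvalidParameterError("n_points must be >= 3")
        if int(self.intrinsic_dim) < 1:
            raise InvalidParameterError("intrinsic_dim must be >= 1")
        if float(self.noise_sigma) < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        if int(self.n_noise_dims) < 0:
            raise InvalidParameterError("n_noise_dims must be >= 0")

    def generate(self) -> np.ndarray:
        return generate(self)


def generate(spec: GeneratorSpec) -> np.ndarray:
    """Materialize a :class:`GeneratorSpec` into an N x D coordinate matrix."""
    rng = np.random.default_rng(spec.seed)
    fam = spec.family
    n, d = int(spec.n_points), int(spec.intrinsic_dim)
    if fam == "hypercube":
        X = gen_hypercube(n, d, rng)
    elif fam == "gaussian":
        X = gen_gaussian(n, d, rng)
    elif fam == "cauchy":
        X = gen_cauchy(n, d, rng)
    elif fam == "hypersphere":
        X = gen_hypersphere(n, d, rng)
    elif fam == "swiss_roll":
        X = gen_swiss_roll(n, rng, gaussian_profile=False)
    elif fam == "swiss_gaussian":
        X = gen_swiss_roll(n, rng, gaussian_profile=True)
    elif fam == "noisy_plane":
        X = gen_hypercube(n, 2, rng)
    elif fam == "noisy_swiss_gaussian":
        X = gen_swiss_roll(n, rng, gaussian_profile=True)
    else:  # pragma: no cover - guarded by GeneratorSpec
        raise InvalidParameterError(f"unknown family {fam!r}")
    if spec.n_noise_dims > 0 or fam in ("noisy_plane", "noisy_swiss_gaussian"):
        X = add_orthogonal_noise(X, spec.noise_sigma, spec.n_noise_dims, rng)
    return X
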