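"""Generator contracts: shapes, supports, reproducibility, distributions."""

import numpy as np
import pytest
from scipy import stats

from twonn import (
    GeneratorSpec,
    InvalidParameterError,
    add_orthogonal_noise,
    gen_cauchy,
    gen_gaussian,
    gen_hypercube,
    gen_hypersphere,
    gen_swiss_roll,
    generate,
)
from twonn.datasets import SWISS_T_RANGE, SWISS_Y_RANGE


@pytest.mark.parametrize(
    "gen, kwargs, shape",
    [
        (gen_hypercube, dict(n=5, d=3), (5, 3)),
        (gen_gaussian, dict(n=4, d=2), (4, 2)),
        (gen_cauchy, dict(n=10, d=20), (10, 20)),
        (gen_hypersphere, dict(n=4, d=1), (4, 2)),  # circle lives in the plane
        (gen_swiss_roll, dict(n=7), (7, 3)),
    ],
)
def test_shapes_and_finiteness(gen, kwargs, shape):
    X = gen(seed=0, **kwargs)
    assert X.shape == shape
    assert np.all(np.isfinite(X))


@pytest.mark.parametrize(
    "gen, kwargs",
    [
        (gen_hypercube, dict(n=100, d=4)),
        (gen_gaussian, dict(n=100, d=4)),
        (gen_cauchy, dict(n=100, d=4)),
        (gen_hypersphere, dict(n=100, d=4)),
        (gen_swiss_roll, dict(n=100)),
        (gen_swiss_roll, dict(n=100, gaussian_profile=True)),
    ],
)
def test_seed_reproducibility(gen, kwargs):
    a = gen(seed=42, **kwargs)
    b = gen(seed=42, **kwargs)
    c = gen(seed=43, **kwargs)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


@pytest.mark.parametrize("gen", [gen_hypercube, gen_gaussian, gen_cauchy, gen_hypersphere])
def test_invalid_counts_rejected(gen):
    with pytest.raises(InvalidParameterError):
        gen(2, 3, seed=0)
    with pytest.raises(InvalidParameterError):
        gen(10, 0, seed=0)


def test_hypercube_support_and_mean():
    n = 100_000
    X = gen_hypercube(n, 3, seed=7)
    assert X.min() >= 0.0 and X.max() <= 1.0
    # uniform law: mean 1/2, sd of the empirical mean = (12 n)^{-1/2}
    tol = 3.0 / np.sqrt(12 * n)
    assert np.all(np.abs(X.mean(axis=0) - 0.5) < tol)


def test_gaussian_moments():
    X = gen_gaussian(100_000, 3, seed=8)
    cov = np.cov(X.T)
    assert np.allclose(cov, np.eye(3), atol=0.02)
    assert np.allclose(X.mean(axis=0), 0.0, atol=0.02)


def test_cauchy_norm_distribution():
    """Norms follow the half-Cauchy law with cdf (2/pi) arctan(x)."""
    X = gen_cauchy(10_000, 5, seed=9)
    norms = np.linalg.norm(X, axis=1)
    assert np.all(norms > 0)
    res = stats.kstest(norms, stats.halfcauchy.cdf)
    assert res.pvalue > 1e-3
    # directions are isotropic: mean unit vector close to zero
    units = X / norms[:, None]
    assert np.all(np.abs(units.mean(axis=0)) < 0.05)


def test_hypersphere_norms_one():
    X = gen_hypersphere(1000, 6, seed=10)
    assert np.allclose(np.linalg.norm(X, axis=1), 1.0, atol=1e-12)


def test_swiss_roll_parametrization():
    """Rows obey x^2 + z^2 = t^2 with t inside the parameter window, and the
    area-uniform t law has density proportional to sqrt(1 + t^2)."""
    X = gen_swiss_roll(20_000, seed=11)
    t = np.hypot(X[:, 0], X[:, 2])
    a, b = SWISS_T_RANGE
    assert np.all((t >= a - 1e-10) & (t <= b + 1e-10))
    assert np.all((X[:, 1] >= SWISS_Y_RANGE[0]) & (X[:, 1] <= SWISS_Y_RANGE[1]))
    # closed-form cdf of the arc-length-weighted t law
    anti = lambda u: 0.5 * (u * np.hypot(1.0, u) + np.arcsinh(u))
    cdf = lambda u: (anti(np.clip(u, a, b)) - anti(a)) / (anti(b) - anti(a))
    res = stats.kstest(t, cdf)
    assert res.pvalue > 1e-3


def test_swiss_roll_gaussian_profile_centered():
    X = gen_swiss_roll(50_000, seed=12, gaussian_profile=True)
    t = np.hypot(X[:, 0], X[:, 2])
    a, b = SWISS_T_RANGE
    # ~99% of t-mass inside the window by construction
    inside = np.mean((t >= a) & (t <= b))
    assert inside > 0.97
    assert abs(X[:, 1].mean() - 10.5) < 0.1


def test_orthogonal_noise_contract():
    X = gen_hypercube(50_000, 2, seed=13)
    Y = add_orthogonal_noise(X, sigma=1e-4, k_dims=20, seed=14)
    assert Y.shape == (50_000, 22)
    np.testing.assert_array_equal(Y[:, :2], X)
    stds = Y[:, 2:].std(axis=0)
    assert np.all(np.abs(stds - 1e-4) < 0.05e-4)

    Z = add_orthogonal_noise(X[:10], sigma=0.0, k_dims=3)
    assert np.all(Z[:, 2:] == 0.0)

    with pytest.raises(InvalidParameterError):
        add_orthogonal_noise(X[:10], sigma=-1.0, k_dims=2)


def test_generator_spec_dispatch_and_validation():
    spec = GeneratorSpec("noisy_plane", 100, noise_sigma=1e-4, n_noise_dims=20, seed=5)
    X = generate(spec)
    assert X.shape == (100, 22)
    np.testing.assert_array_equal(X, spec.generate())

    with pytest.raises(InvalidParameterError):
        GeneratorSpec("donut", 100)
    with pytest.raises(InvalidParameterError):
        GeneratorSpec("hypercube", 2)
    with pytest.raises(InvalidParameterError):
        GeneratorSpec("hypercube", 100, noise_sigma=-0.1)
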