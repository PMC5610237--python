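# Methods

## Model

Let *i* be a point of an N-point sample on a *d*-dimensional manifold, and
*r₁ ≤ r₂* its distances to its first two neighbors. If the density ρ is
constant on the scale of *r₂*, the volumes of the hyperspherical shells
between consecutive neighbors,

    Δv_l = ω_d (r_l^d − r_{l−1}^d),        ω_d = π^{d/2} / Γ(d/2 + 1),  r₀ = 0,

are i.i.d. Exp(ρ). Their ratio R = Δv₂/Δv₁ then has density
g(R) = (1+R)^{−2} independent of both *d* and ρ, and substituting
R = μ^d − 1 with μ = r₂/r₁ gives the Pareto pair

    f(μ) = d μ^{−d−1},   F(μ) = 1 − μ^{−d}   on [1, ∞),

so −log(1−F(μ))/log μ = d identically. The estimator replaces F by the
empirical cumulate F^emp(μ₍ᵢ₎) = i/N on the sorted ratios and takes *d̂* as
the least-squares slope, constrained through the origin, of
{(log μ, −log(1−F^emp))}. The only assumption is *local* homogeneity —
constant density within the second-neighbor range — which becomes exact as
N → ∞; curvature and global density variation enter only at second order.

All of this lives in `twonn.theory` (closed forms), `twonn.neighbors`
(distances) and `twonn.estimator` (pipeline).

## Estimator conventions

- **Cumulate.** F^emp = i/N exactly, ties ranked consecutively in input
  order (stable sort). The largest-μ point has F = 1 and infinite ordinate;
  with a positive discard fraction it is always discarded, and with
  `discard_fraction=0` it is excluded from the fit with a warning. This is
  the only convention under which a "full-sample" slope is finite; an
  alternative i/(N+1) cumulate that keeps all points finite was considered
  and rejected because it departs from the plain rank definition. The choice
  matters visibly only in the extreme tail (heavy-tailed data, or blocks of
  fewer than ~10 points).
- **Discard rule.** `n_used = floor(N · (1 − discard_fraction))` smallest-μ
  points are retained, lower-index points kept on μ-ties (deterministic).
  Default `discard_fraction = 0.10`: heavy tails put a handful of extreme μ
  values at the largest abscissae, where the quadratic x-weight of least
  squares lets them dominate the slope; trimming 10% removes them while
  barely moving estimates on well-behaved data (hypercube: < 1% shift).
- **Fit.** Ordinary least squares of vertical residuals through the origin,
  s = Σxy/Σx², in natural logarithms. No maximum-likelihood variant is
  substituted: the cumulate-linearization fit *is* the estimator.
- **Degenerate inputs.** Fewer than 3 points, all-zero abscissae, or fewer
  than 2 retained points raise typed errors. Coincident points (r₁ = 0,
  μ undefined) raise by default; `on_duplicates="drop"` removes duplicates
  first, warns, and records the surviving indices — silent infinities would
  corrupt the fit, so there is no quiet mode.

## Metrics

- **Euclidean**: `scipy.spatial.cKDTree`, k = 3 query (self + two
  neighbors). Ties are broken arbitrarily by the tree; only distances enter
  the estimator, so ties are harmless.
- **Periodic (minimum image)**: the same kd-tree with `boxsize`, after
  mapping coordinates into the box. This is the exact per-coordinate
  min(|Δ|, L − |Δ|) metric; the test suite checks it against an exhaustive
  O(N²) minimum-image oracle. Periodic analysis of uniform hypercubes
  removes the boundary effects that otherwise bias nearest-neighbor
  estimators upward.
- **Precomputed matrix**: row-wise two smallest off-diagonal entries of a
  validated (symmetric to 10⁻⁹, zero diagonal, nonnegative) matrix. This is
  how RMSD or other externally computed metrics enter; computing such
  metrics is out of scope here.

The estimate is exactly invariant under rescaling of the data or of the
distance matrix (μ is a ratio), and invariant under rigid motions and row
permutations up to floating-point noise.

## Scale-dependent dimension (decimation)

Nearest-neighbor estimators measure at the scale of the typical
second-neighbor distance, which shrinks as N^{−1/d}. `decimation_curve`
therefore shuffles the rows once per requested size *n* (seeded generator),
partitions them into ⌊N/n⌋ **disjoint** blocks of exactly *n* points
(remainder dropped; disjointness keeps block estimates independent),
estimates *d̂* on each block, and reports mean and population standard
deviation per size. The default size grid is geometric, ~10 sizes per
decade from 10 to N. A dataset on a *d*-soft-dimensional manifold blurred
by small noise in many directions shows *d̂(n)* ≈ d over a plateau of sizes
and rises when blocks are large enough to resolve the noise; the plateau
value counts the soft directions. `plateau_report` flags the longest run of
sizes whose means vary by less than a relative tolerance (default 10%,
ties resolved toward larger blocks); it is an advisory convenience — the
curve and its dispersion are the primary output, since no algorithmic
plateau definition is canonical.

## Synthetic generators

All benchmark families are generated in `twonn.datasets`, deterministically
from a seed:

- **hypercube**: uniform on [0,1]^d (unit box; pair with `box=[1]*d` for
  boundary-free analysis).
- **gaussian**: standard normal in d dimensions.
- **cauchy**: radius from the half-Cauchy density (2/π)/(1+x²), direction
  uniform on the unit sphere — the isotropic reading of "norms distributed
  as 1/(1+x²)". Note the radial law places a density spike at the origin
  and a heavy tail of isolated outliers; the *full* fit on such data is
  unstable by construction, which is exactly what the discard rule
  addresses. A dataset with i.i.d. Cauchy *coordinates* is a different
  object (its bulk looks effectively ~9-dimensional at N = 2500 in d = 20)
  and is not what this generator produces.
- **hypersphere**: uniform on the surface of the unit d-sphere in R^{d+1}
  (intrinsic dimension d), via normalized Gaussians.
- **swiss_roll**: (t cos t, y, t sin t) with t ∈ [1.5π, 4.5π], y ∈ [0, 21]
  (a conventional window; configurable). Uniform-area sampling draws t with
  density ∝ √(1+t²) (the arc-length element) by rejection; "uniform on the
  roll" means uniform in area, not in parameter.
- **swiss_gaussian**: bivariate normal in (t, y) centered mid-window, each
  std = half-window / 2.576 so ~99% of the mass lies inside the window,
  mapped onto the roll — a curved manifold with density variation.
- **add_orthogonal_noise**: appends k i.i.d. N(0, σ²) coordinates to every
  point, leaving the manifold coordinates untouched ("noise along k
  independent directions"). σ is the standard deviation per direction;
  σ = 0 appends exact zeros.

What the generators do *not* emulate: measurement noise within the manifold
coordinates, anisotropic or correlated noise, multi-component supports, and
non-synthetic feature correlations. Passing benchmarks on them shows the
estimator recovers dimension under curvature, density variation, heavy
tails and orthogonal noise — not that every real dataset satisfies local
homogeneity at its sampled density.

## Benchmark operating points and observed behavior

The acceptance experiments (`scripts/acceptance.py`, `tests/test_acceptance.py`)
run at the published sample sizes — N = 2500 for the slope benchmarks,
N = 25000 × 20 instances for convergence, N = 50000 for the decimation
datasets — chosen as the package's own reference conditions. Replicate-seed
means: hypercube d=14 full/discard ≈ 14.0/13.9; Swiss roll ≈ 1.99; Cauchy
d=20 discard ≈ 22.6 (the documented mild overestimate from outliers);
noisy-plane plateau ≈ 1.99 at n ≈ 1000; Gaussian-on-roll plateau ≈ 2.07.

Two published edge behaviors do not reproduce under the conventions above
and are asserted anyway (left failing) rather than tuned away:

- the *full* (no-discard) Cauchy fit here averages ≈ 21.7, not ≈ 6: under
  the isotropic generator the ratios μ have no extreme tail (max log μ
  ≈ 0.6 at N = 2500), so there are no dominant points for the full fit to
  collapse onto. An i.i.d.-Cauchy-coordinates dataset does collapse to ≈ 6,
  but its discard fit is then ≈ 9, not ≈ 22 — no single construction
  yields both reported values; this package keeps the isotropic definition
  and the stable discard estimate.
- the decimation curve of the σ = 10⁻⁴ noisy unit plane reaches ≈ 2.27 (not
  > 2.5) at n = 50000 and ≈ 2.4 (not < 1.5) at n = 5. Both edges depend on
  the unstated plane extent and cumulate convention; with the i/N cumulate
  and the infinite point dropped, tiny blocks are estimated near 2, and the
  dip toward 1 would require keeping the top-μ point under an i/(N+1)
  convention. The plateau itself — the scientifically load-bearing feature —
  is robust to all of these choices.

## Numerical notes

- −log(1−F) is computed as `-log1p(-F)`; the identity test domain avoids
  μ where 1 − F(μ) cancels catastrophically in double precision.
- Scale invariance is bit-exact for power-of-two rescaling (IEEE sqrt and
  division commute with ×2), which the tests exploit for exact assertions.
- Dispersion across blocks uses the population standard deviation (defined
  for a single block: 0).
- Goodness-of-fit assertions use Kolmogorov–Smirnov at fixed seeds with a
  lenient p > 10⁻³ threshold: μ values of nearby points share neighbors and
  are weakly dependent, so the KS null is only approximate.

## Limitations

No confidence intervals for d̂ are provided (the fit residuals are
correlated, so naive regression errors would mislead); the decimation
dispersion is the honest uncertainty surrogate. The estimator reports a
single global slope: multi-manifold mixtures yield an average, not a
decomposition. Exact duplicates must be dropped or fixed upstream. For
d ≳ 20 the estimate inherits the documented mild overestimation on
heavy-tailed or sharply bounded supports.
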