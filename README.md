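# twonn — intrinsic dimension from two nearest neighbors

High-dimensional datasets — molecular-dynamics snapshots, image collections,
feature tables — usually concentrate near a manifold of much lower dimension
than the ambient coordinate count. `twonn` estimates that **intrinsic
dimension (ID)** from a remarkably small amount of information: each point's
distances to its first and second nearest neighbors. Because the estimator
probes only the second-neighbor scale, it is insensitive to density
variations and curvature that confound larger-neighborhood methods, and it
extends naturally to a **scale-dependent** analysis that separates the
"soft" directions of a dataset from high-dimensional noise.

## The estimator

For point *i* let *r₁ ≤ r₂* be the distances to its two nearest neighbors
and *μ = r₂/r₁ ∈ [1, ∞)*. If the density is approximately constant out to
the second neighbor, the volumes of consecutive hyperspherical shells are
i.i.d. exponential, and μ follows a Pareto law that depends on the intrinsic
dimension *d* but **not** on the density ρ:

    f(μ) = d μ^(−d−1),      F(μ) = 1 − μ^(−d),      so   −log(1 − F(μ)) / log μ = d.

The algorithm: compute μ for every point, form the empirical cumulate
F(μ₍ᵢ₎) = i/N on the sorted ratios, and fit the set
{(log μ, −log(1 − F))} with a straight line through the origin. The slope is
the estimate *d̂*. By default the 10% of points with the highest μ are
discarded from the fit, which stabilizes it on heavy-tailed data.

For noisy data, `decimation_curve` runs the estimator on disjoint blocks of
decreasing size *n*: small blocks probe coarse scales where tiny noise
directions are invisible, so *d̂(n)* exhibits a plateau at the number of soft
directions even when the full-sample estimate is inflated by noise.

## Worked example

```python
import twonn

# a 2-D sheet rolled up in 3-D: curvature does not fool the estimator
roll = twonn.gen_swiss_roll(2500, seed=0)
print(twonn.estimate_id(roll).d_hat)            # 1.98

# a genuinely 14-dimensional uniform sample on a periodic box
cube = twonn.gen_hypercube(2500, 14, seed=0)
print(twonn.estimate_id(cube, box=[1.0]*14).d_hat)   # 14.04

# scale-dependent ID of a noisy plane (ambient dimension 22, soft dimension 2)
data = twonn.add_orthogonal_noise(twonn.gen_hypercube(20000, 2, seed=0),
                                  sigma=1e-4, k_dims=20, seed=1)
curve = twonn.decimation_curve(data, sizes=[100, 500, 2500], seed=1)
print(curve.d_mean)                              # [1.96 1.94 1.98]
```

The first two numbers are the fitted slopes *d̂*: ≈2 for the Swiss roll (the
dimension of its tangent plane) and ≈14 for the hypercube. The decimation
means stay at 2 across block sizes because at these scales the σ = 10⁻⁴
noise along the 20 extra directions is far below the neighbor distances —
the dataset has exactly two soft directions.

Non-Euclidean metrics (e.g. RMSD between molecular configurations) enter as
a precomputed distance matrix: `twonn.estimate_id(D, metric="precomputed")`.
See `examples/` for narrative scripts covering each capability.

## Command line

```bash
twonn simulate --family swiss_roll --n 2500 --seed 0 --output roll.txt
twonn estimate --input roll.txt --output report.json
twonn decimate --input roll.txt --sizes 100,500,2500 --seed 1 --output curve.tsv
```

`--metric matrix` reads a distance matrix, `--pbc L1,L2,...` enables
minimum-image periodic distances, `--discard` changes the tail-discard
fraction.

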