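# Methods

## Data model and conventions

Spike trains from repeated presentations of the same stimulus are binned
into an integer tensor `n_i(t, r)` (cell × time-bin × repetition). Bins are
half-open `[tΔ, (t+1)Δ)` with a left-closed edge convention and 0-based
indices; a trailing partial bin is discarded. The default bin width is
`Δ = 1000/60 ms ≈ 16.7 ms` (a 60 Hz bin rate), configurable everywhere.

All covariance estimators use the maximum-likelihood `1/T` and `1/R`
normalisations with **no Bessel correction**. This is deliberate: it makes
the decomposition

    Cov_total = Cov_stimulus + Cov_noise

an exact algebraic identity on every tensor (tested to machine precision),
and likewise makes `N × synchrony` exactly the sum of all pairwise noise
covariances. Noise correlations are normalised by the **total** variances
`V_i = Cov_total(n_i, n_i)`, not the noise variances; pairs with vanishing
variance propagate as missing values (never silent zeros), and prediction
metrics exclude them pairwise.

The trial-shuffling control permutes whole repetition traces independently
per cell. This preserves every per-bin marginal and all within-cell temporal
structure while destroying cross-cell noise correlations in expectation —
exactly the conditionally-independent surrogate the model comparisons need.

## Discrete copula stage

A copula is a joint c.d.f. on the unit square with uniform marginals. Five
families are implemented with their standard closed forms: independence
`uv`; Gumbel (`θ ∈ [1, ∞)`); Gaussian (`θ ∈ [−1, 1]`); Frank (`θ ∈ ℝ`);
Clayton (`θ ∈ [−1, ∞) \ {0}`). For integer counts, the probability of a
pair `(x, y)` is the rectangle inclusion–exclusion of the copula over the
marginal c.d.f. steps — the correct density with respect to counting
measure. Numerical choices:

- `u, v` are clipped to `[1e-12, 1 − 1e-12]` inside the family formulas;
  the boundary contract `C(u,0)=0, C(u,1)=u` is enforced exactly.
- Rectangle masses below `1e-15` (float cancellation) are clipped to zero
  and each per-bin table is renormalised.
- The Gaussian family evaluates the bivariate-normal c.d.f. with a 64-node
  Gauss–Legendre rule on the sine-substitution integral form — vectorised
  over whole grids of points, accurate to ~1e-14 away from `|θ| = 1`, and
  cross-checked in the tests against scipy's multivariate-normal c.d.f. and
  the arcsine closed form for Bernoulli margins (the dichotomized-Gaussian
  equivalence).
- Frank below `|θ| < 1e-6` returns the independence product (the formula
  cancels catastrophically there; the neglected term is O(θ)).

**Likelihood and fitting.** The pair log-likelihood sums `log P_t(n_i, n_j)`
over bins and repetitions with the per-bin (by default empirical) marginals
plugged in. Bins where either cell is constant across repetitions carry no
information about θ — the rectangle mass collapses to the other cell's
marginal — and contribute only a θ-independent constant. Observed pairs with
zero model mass give an explicit `-inf` (reported, and kept finite inside
the optimiser as a large penalty). θ is fitted by a derivative-free bounded
scalar search (tolerance 1e-6) on a transformed parameter that maps the
family domain to a box: `log(θ−1)` for Gumbel, `atanh θ` for Gaussian, raw θ
for Frank, `log θ` on Clayton's positive branch with the negative branch
searched separately and the better optimum kept. The independence point is
always evaluated and kept if it dominates (boundary optimum). Family
selection ranks families by the mean (over pairs) per-bin Kullback–Leibler
divergence between the empirical joint and the model joint, a plug-in
estimator restricted to the empirical support; per-bin averaging was chosen
because the per-bin joints are the model's native objects.

**Sampling.** Gaussian pairs are drawn through a latent bivariate normal;
Archimedean families use the conditional-distribution (inverse-Rosenblatt)
method with closed-form conditionals and a vectorised bisection inversion
(tolerance 1e-10). Copula samples map to counts through the generalized
inverse c.d.f. `F⁻¹(u) = min{k : F(k) ≥ u}`.

## The distance law

Across same-type pairs the fitted Gumbel parameter follows

    θ(d) = exp(exp(a + b d + c d²)),   θ = 1 (independence) beyond 1 mm.

The cutoff rule is implemented as independence because θ = 1 is the Gumbel
family's independence point (values below 1 are outside its domain). The
coefficients are fitted by **unweighted** ordinary least squares of
`log log θ_ij` on `[1, d, d²]`, which linearises the functional form
exactly; pairs beyond the cutoff or with θ̂ ≤ 1 are excluded. The OLS route
also supplies standard errors for the coefficients. Note the printed
reference coefficients make the quadratic turn up at `d = −b/2c ≈ 875 μm`,
so θ(d) is not strictly decreasing on the last ~125 μm before the cutoff;
the effect is numerically negligible (θ ≈ 1.005 either side).

Pair prediction composes θ(d) with the two cells' per-bin marginals to get
per-bin joint laws, per-bin covariances, and their time average. By
interface it consumes only marginals and a distance — it cannot receive a
joint recording — which is the property that makes cross-experiment
prediction possible. A batched path evaluates many pairs' joint tables at
once with θ as a broadcast axis (Gumbel/Frank/Clayton), which is what makes
the 400-cell mosaic (≈20 000 in-cutoff pairs) take seconds rather than
hours.

A caveat established while validating the estimator: plugging *empirical*
marginals (R ≈ 79 repetitions) into the discrete likelihood inflates θ̂ by
roughly 10% relative to fitting with the generating marginals, a plug-in
effect of marginal estimation noise. Parameter-recovery tests therefore
supply the generator's exact marginals, isolating the θ estimator itself;
end-to-end prediction tests keep the empirical route, since prediction
quality is what matters there.

## Time-dependent maximum-entropy stage

Per bin, counts follow a Boltzmann law with energy
`Σ_i h_i(t) n_i + Σ_{i≤j} J_ij n_i n_j − Σ_i ln n_i!` on `{0..n_max}^N`;
`J` (including its diagonal, which pins each cell's variance) is shared
across bins. With `J = 0` the model is exactly a set of independent
truncated-Poisson cells, which is also the fit's initialisation
(`h_i(t) = ln max(μ_i(t), 1e-4)`, the conditionally-independent solution).
`n_max` defaults to the largest observed count.

Fitting matches moments using the exponential-family gradient
`⟨O⟩_target − ⟨O⟩_model` for each parameter's conjugate statistic: per-bin
means for `h_i(t)`, time-summed second moments for `J_ii`, time-summed
cross moments for `J_ij`. Updates are sign-based with per-parameter
adaptive steps (×1.2 on a repeated gradient sign, ×0.5 on a flip, clipped
to `[1e-7, 0.5]`) — a resilient-propagation scheme chosen for robustness to
Monte-Carlo gradient noise. Iteration stops when the largest residual
(per-bin for means, per-bin-averaged for the time-summed statistics) falls
below `tol` (default 5e-4); unreachable targets surface as a flagged
non-convergence, never silently. Model moments come from exact enumeration
while `(n_max+1)^N ≤ 10⁶` and otherwise from single-site heat-bath Gibbs
sampling (all bins and chains updated in parallel, persistent chains across
iterations). Only the constrained statistics are matched: individual
per-bin second moments may differ from the targets at convergence because
only their time sum is a sufficient statistic.

Model-side predictions (triplet correlations, population-rate
distributions) use Gibbs samples in the role of repetitions. Log-likelihood
evaluation is supported only where the partition function is enumerable;
large-population likelihoods are out of scope.

## Synthetic data

The generators emulate the structure of repeated-trial retinal recordings:
smooth per-cell rate profiles (circularly smoothed, variance-normalised
log-normal noise; default mean 1/6 spikes/bin = 10 Hz at 60 Hz bins, log-sd
1, smoothing 5 bins — a plausible regime for OFF-alpha cells under
checkerboard stimulation), truncated-Poisson marginals capped at the
1 − 1e-6 Poisson quantile, and 79 repetitions as the default trial count.

Single pairs are drawn exactly from a chosen copula family. Whole
populations use a latent-Gaussian (generalised dichotomized-Gaussian)
construction with a distance-decaying latent correlation ρ(d): a correlated
normal vector per bin and repetition is pushed through Φ and each cell's
inverse count c.d.f. Marginals are exact by construction, any two cells
follow exactly a Gaussian copula with parameter ρ(d) (used as an oracle
equivalence in the tests), and the multicell law is globally consistent —
which an arbitrary collection of pairwise Gumbel margins cannot guarantee.
Latent correlation matrices that fail positive semi-definiteness are
repaired by eigenvalue clipping (with a warning when the repair moves an
eigenvalue by more than 0.05).

What the generators do **not** emulate: refractoriness and spike-history
structure, stimulus-locked higher-order dependence, cell-to-cell marginal
heterogeneity beyond the supplied rate profiles, and any departure of the
true pairwise dependence from the (Gumbel or Gaussian) copula shape.
Passing tests therefore certify the inference machinery under the model's
own assumptions, not the adequacy of those assumptions for any particular
real recording.

## Large-population synthesis and synchrony

The mosaic is a triangular lattice (side 194 μm) filled row-wise with
independent Gaussian jitter (sd 22 μm per coordinate); note the jitter pulls
the mean nearest-neighbour spacing well below the lattice side (to
~160 μm), as the minimum over ~6 jittered neighbour distances. Each site
receives the marginals of a cell drawn uniformly with replacement from a
library; pairwise covariances come from the copula distance law (exactly
zero beyond the cutoff), and the diagonal carries each site's noise
variance. Synchrony over a patch is then the covariance-matrix sum divided
by the patch size — analytically equivalent (and exactly equal, on matching
data) to the time-averaged variance of the sampled population rate, so the
scan never needs to sample the 400-cell model.

The saturation scan draws patch centres uniformly over the mosaic's
bounding box shrunk by the largest radius (to limit edge truncation; if
that inner region is empty the box centre is used), averages 20 centres per
radius over radii 0.1–2 mm in 0.1 mm steps, and defines saturation as the
smallest radius reaching 95% of the synchrony at the largest scanned
radius. Both the centre count and the 95% criterion are configuration
knobs. Stretching or compressing the correlation structure rescales
distance (cutoff included) inside θ(d) by the given factor. The
conditionally-independent control zeroes the off-diagonal covariances and
produces an exactly flat curve at the mean per-cell noise variance.

Problem sizes throughout (e.g. 120-bin / 79-repetition syntheses, a
25-cell mosaic for end-to-end recovery, 3-cell systems for enumeration
oracles, 400 cells for the synchrony scan) were chosen as the smallest
scales at which each statistical claim is cleanly resolvable.

## Known limitations

- θ is constant across time-bins and stimuli by design; stimulus-dependent
  or per-pair θ variants are out of scope.
- Only pairwise copulas are provided; higher-order dependence enters solely
  through the maximum-entropy stage.
- The Gaussian family has no batched-θ evaluation path (its c.d.f.
  quadrature is specific to scalar θ), so large mosaics should use the
  Archimedean families.
- Likelihood benchmarking of the max-ent model requires an enumerable state
  space (roughly N ≤ 10 at n_max ≤ 3).
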