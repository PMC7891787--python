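# seqpop

Infer the **simultaneous** activity of a population of same-type neurons from
**sequential** recordings.

Modern recordings can profile many neurons of a single functional type (for
example OFF-alpha retinal ganglion cells) across different experimental
sessions, but almost never all of them at once. Pooling sequentially recorded
responses as if they were simultaneous silently assumes the trial-to-trial
noise of different cells is independent — and in the retina it is not:
nearby ganglion cells share fast noise correlations. `seqpop` implements a
two-stage method that restores this shared noise:

1. **Discrete copula model of pairwise noise correlations.** For cells *i*,
   *j* with per-bin empirical count c.d.f.s `F_i^(t)`, `F_j^(t)`, the joint
   spike-count law in each time-bin is built with a Gumbel copula
   `C(u, v | θ)` whose parameter depends only on the inter-cell distance
   `d` (μm):

   `θ(d) = exp(exp(a + b·d + c·d²))`, with independence beyond a 1 mm
   cutoff. The per-pair θ is fitted by maximum likelihood on a few
   simultaneously recorded pairs; the three coefficients `(a, b, c)` are then
   fitted by least squares on the `log log θ` scale. For rat OFF-alpha cells
   the reference coefficients are `a = 0.73`, `b = −0.014 μm⁻¹`,
   `c = 8×10⁻⁶ μm⁻²`. After that, the noise covariance of **any** pair —
   including pairs never recorded together — is predicted from single-cell
   marginals plus distance alone.

2. **Time-dependent maximum-entropy population model.** Per time-bin,
   counts `n ∈ {0..n_max}^N` follow
   `P_t(n) ∝ exp( Σ_i h_i(t) n_i + Σ_{i≤j} J_ij n_i n_j − Σ_i ln n_i! )`,
   with bin-specific fields `h_i(t)` and one symmetric coupling matrix `J`
   shared across bins (diagonal included). It is fitted by moment matching
   (exponential-family gradients, adaptive per-parameter steps), with model
   moments from exact enumeration for small systems and Gibbs sampling
   otherwise. Its constraints are exactly the single-cell marginals plus the
   copula-predicted covariances, so the full population law again needs no
   joint recordings.

On top of these, the package synthesises large receptive-field mosaics
(jittered triangular lattice, side 194 μm, jitter sd 22 μm), assigns pooled
marginals to the sites, and studies **population synchrony**
`(1/N)·⟨Var K(t)⟩_t` (K(t) the summed population count, equal to the mean sum
of pairwise noise covariances) as a function of circular patch size — showing
that synchrony saturates only for patches of roughly 200 cells / 1.5 mm
radius, beyond current simultaneous-recording reach.

## Worked example

Simulate a cell pair 250 μm apart from the reference distance law, refit the
copula from the joint recording, and compare the noise correlation predicted
from marginals + distance with the empirical one:

```python
import numpy as np
from seqpop import fit_copula_parameter, ThetaDistanceLaw, predict_pair_statistics
from seqpop.synth import simulate_rate_profiles, simulate_pair
from seqpop.tensor import empirical_marginals
from seqpop.correlations import noise_correlation

law = ThetaDistanceLaw(a=0.73, b=-0.014, c=8e-6)
rates = simulate_rate_profiles(2, n_bins=600, seed=0, mean_rate=1/6)
pair = simulate_pair(rates[0], rates[1], "gumbel",
                     theta=law.theta(250.0), n_reps=79, seed=1)

fit = fit_copula_parameter("gumbel", pair.counts[0], pair.counts[1])
print(fit.summary())

marg = empirical_marginals(pair)
pred = predict_pair_statistics(marg.pmf[0], marg.pmf[1], 250.0, law)
print(f"theta(250 um)        = {law.theta(250.0):.3f}")
print(f"predicted noise corr = {pred.corr_noise:.3f}")
print(f"empirical noise corr = {noise_correlation(pair, 0, 1):.3f}")
```

Output:

```
Pair copula maximum-likelihood fit
==================================
family:            gumbel
theta:             1.1135548021226562
log-likelihood:    -33769.7
converged:         True
informative bins:  556 / 600
repetitions:       79

theta(250 um)        = 1.109
predicted noise corr = 0.063
empirical noise corr = 0.069
```

The refitted θ (1.114) sits on top of the generating value θ(250 μm) = 1.109,
and the correlation predicted *without ever touching the joint recording*
(0.063) matches the empirically measured one (0.069) to within trial noise.

A command-line pipeline mirrors the library
(`seqpop bin / corr / fit-copula / select-family / fit-distance / predict /
fit-maxent / sample / simulate / synchrony`); every command is a thin wrapper
over the functions above.

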