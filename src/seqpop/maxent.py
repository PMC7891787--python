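"""Time-dependent maximum-entropy population model on spike counts.

Per time-bin ``t`` the population count vector ``n = (n_1..n_N)``,
``n_i in {0..n_max}``, follows a Boltzmann distribution

    P_t(n) = exp( sum_i h_i(t) n_i + sum_{i<=j} J_ij n_i n_j
                  - sum_i ln(n_i!) ) / Z(t)

with bin-specific fields ``h_i(t)`` (setting each cell's time-varying
firing probability) and a single symmetric coupling matrix ``J`` shared by
all bins, including diagonal terms ``J_ii`` that pin each cell's variance.
The ``ln(n!)`` term makes the model a collection of independent (truncated)
Poisson cells when ``J = 0``.

The model is an exponential family, so the log-likelihood gradient for any
parameter is ``<O>_data - <O>_model`` with ``O`` the conjugate statistic:
per-bin means for ``h_i(t)``, time-summed second moments for ``J_ii`` and
time-summed cross moments for ``J_ij``.  Inference (`TimeDependentMaxEnt.fit`)
therefore needs only the single-cell marginals plus pairwise noise
covariances -- which in the two-stage pipeline come from the copula
distance-law prediction, never from joint recordings.  Model moments are
computed by exact enumeration when the state space is small and by Gibbs
sampling (single-site heat bath, persistent chains) otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .correlations import triplet_noise_correlation
from .tensor import MarginalSet, SpikeCountTensor

__all__ = [
    "MaxEntModel",
    "MomentTargets",
    "log_weight",
    "exact_moments",
    "gibbs_sample",
    "TimeDependentMaxEnt",
    "MaxEntResult",
    "fit_maxent",
    "population_rate_distribution",
    "predict_triplet_correlations",
]

#: exact enumeration is used while (n_max+1)**n_cells stays below this
ENUMERATION_LIMIT = 10**6


@dataclass
class MaxEntModel:
    """Parameters of the time-dependent maximum-entropy model."""

    h: np.ndarray          # (n_cells, n_bins) fields
    J: np.ndarray          # (n_cells, n_cells) symmetric couplings, incl. diag
    n_max: int

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.h.ndim != 2:
            raise ValueError("h must be (n_cells, n_bins)")
        if self.J.shape != (self.h.shape[0], self.h.shape[0]):
            raise ValueError("J must be square over cells")
        if not np.allclose(self.J, self.J.T, atol=1e-10):
            raise ValueError("J must be symmetric")
        self.J = 0.5 * (self.J + self.J.T)
        if self.n_max < 0:
            raise ValueError("n_max must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.h.shape[0]

    @property
    def n_bins(self) -> int:
        return self.h.shape[1]

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"h": self.h.tolist(), "J": self.J.tolist(),
                       "n_max": int(self.n_max)}, f)

    @classmethod
    def from_json(cls, path) -> "MaxEntModel":
        with open(path) as f:
            d = json.load(f)
        return cls(np.array(d["h"]), np.array(d["J"]), int(d["n_max"]))


def log_weight(model: MaxEntModel, state, t: int) -> float:
    """Unnormalised log probability of a count vector in bin ``t``.

    ``sum_i h_i(t) n_i + sum_{i<=j} J_ij n_i n_j - sum_i ln(n_i!)``.
    """
    n = np.asarray(state)
    if n.shape != (model.n_cells,):
        raise ValueError("state must have one count per cell")
    if np.any(n < 0) or np.any(n > model.n_max):
        raise ValueError(f"counts must lie in 0..{model.n_max}")
    nf = n.astype(float)
    quad = 0.5 * nf @ model.J @ nf + 0.5 * (np.diag(model.J) @ nf**2)
    return float(model.h[:, t] @ nf + quad - gammaln(nf + 1.0).sum())


@dataclass
class MomentTargets:
    """Sufficient statistics constraining the max-ent model.

    ``mean[i, t]`` and ``second[i, t]`` are per-bin first and second moments
    of each cell's count across repetitions; ``cross_sum[i, j]`` is the
    time-summed cross moment ``sum_t E[n_i(t) n_j(t)]`` for ``i != j``
    (the diagonal is ignored; ``J_ii`` is driven by ``second``).
    """

    mean: np.ndarray
    second: np.ndarray
    cross_sum: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.second = np.asarray(self.second, dtype=float)
        self.cross_sum = np.asarray(self.cross_sum, dtype=float)
        if self.mean.shape != self.second.shape or self.mean.ndim != 2:
            raise ValueError("mean and second must both be (n_cells, n_bins)")
        N = self.mean.shape[0]
        if self.cross_sum.shape != (N, N):
            raise ValueError("cross_sum must be (n_cells, n_cells)")
        if np.any(self.second + 1e-9 < self.mean**2):
            raise ValueError("second moments must dominate squared means")
        self.cross_sum = 0.5 * (self.cross_sum + self.cross_sum.T)

    @property
    def n_cells(self) -> int:
        return self.mean.shape[0]

    @property
    def n_bins(self) -> int:
        return self.mean.shape[1]

    @classmethod
    def from_marginals_and_covariances(cls, marginals: MarginalSet,
                                       noise_cov: np.ndarray) -> "MomentTargets":
        """Assemble targets from single-cell marginals + predicted covariances.

        ``noise_cov[i, j]`` is the (time-averaged) pairwise noise covariance,
        e.g. the copula prediction; only off-diagonal entries are used.
        The time-summed cross moment is
        ``sum_t mu_i(t) mu_j(t) + T * Cov_noise(i, j)``.
        """
        mu = marginals.means()
        second = marginals.second_moments()
        T = marginals.n_bins
        cross = mu @ mu.T + T * np.asarray(noise_cov, dtype=float)
        return cls(mu, second, cross)

    @classmethod
    def from_tensor(cls, tensor: SpikeCountTensor) -> "MomentTargets":
        """Empirical targets from a simultaneously recorded tensor."""
        counts = tensor.counts.astype(float)
        mean = counts.mean(axis=2)
        second = (counts**2).mean(axis=2)
        N, T, R = counts.shape
        cross = np.einsum("itr,jtr->ij", counts, counts) / R
        return cls(mean, second, cross)


def _enumerate_states(n_cells: int, n_max: int) -> np.ndarray:
    """All (n_max+1)**n_cells count vectors, shape (K, n_cells)."""
    grids = np.meshgrid(*([np.arange(n_max + 1)] * n_cells), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def exact_moments(model: MaxEntModel):
    """Exact model moments and per-bin log partition functions.

    Enumerates all states per bin; only valid while
    ``(n_max+1)**n_cells <= ENUMERATION_LIMIT``.  Returns
    ``(MomentTargets, log_Z)`` with ``log_Z`` of shape ``(n_bins,)``.
    """
    K = (model.n_max + 1) ** model.n_cells
    if K > ENUMERATION_LIMIT:
        raise ValueError(
            f"state space {K} exceeds enumeration limit {ENUMERATION_LIMIT}"
        )
    S = _enumerate_states(model.n_cells, model.n_max).astype(float)  # (K, N)
    quad = 0.5 * np.einsum("ki,ij,kj->k", S, model.J, S) \
        + 0.5 * (S**2) @ np.diag(model.J)
    base = quad - gammaln(S + 1.0).sum(axis=1)                       # (K,)
    logw = S @ model.h + base[:, None]                               # (K, T)
    log_Z = logsumexp(logw, axis=0)
    P = np.exp(logw - log_Z)                                         # (K, T)
    mean = S.T @ P                                                   # (N, T)
    second = (S.T**2) @ P
    cross = np.einsum("ki,kt,kj->ij", S, P, S)
    targets = MomentTargets(mean, second, cross)
    return targets, log_Z


def gibbs_sample(model: MaxEntModel, n_sweeps: int, n_chains: int,
                 burn_in: int, seed, thin: int = 1,
                 init_state: np.ndarray | None = None,
                 return_final: bool = False):
    """Single-site heat-bath Gibbs sampling of the max-ent model.

    Each sweep resamples every (cell, bin) site from its exact conditional
    over ``0..n_max`` given the other cells in the same bin; chains are
    independent and all bins are updated in parallel.  Returns a
    :class:`SpikeCountTensor` whose repetition axis concatenates the kept
    sweeps of all chains (``(n_sweeps - burn_in) // thin`` per chain).
    """
    if burn_in >= n_sweeps:
        raise ValueError("burn_in must be smaller than n_sweeps")
    rng = np.random.default_rng(seed)
    N, T, m = model.n_cells, model.n_bins, model.n_max
    k = np.arange(m + 1, dtype=float)
    k_pen = np.diag(model.J)[:, None] * k**2 - gammaln(k + 1.0)  # (N, m+1)
    if init_state is None:
        state = rng.integers(0, m + 1, size=(n_chains, T, N))
    else:
        state = np.array(init_state, dtype=np.int64)
        if state.shape != (n_chains, T, N):
            raise ValueError("init_state must be (n_chains, n_bins, n_cells)")
    kept = []
    for sweep in range(n_sweeps):
        for i in range(N):
            # local field from other cells: sum_{j != i} J_ij n_j
            b = state @ model.J[i] - model.J[i, i] * state[:, :, i]
            logits = (model.h[i][None, :] + b)[:, :, None] * k + k_pen[i]
            g = rng.gumbel(size=logits.shape)
            state[:, :, i] = np.argmax(logits + g, axis=2)
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            kept.append(state.copy())
    samples = np.concatenate(kept, axis=0)           # (reps, T, N)
    tensor = SpikeCountTensor(
        samples.transpose(2, 1, 0), bin_width=1.0,
        cell_ids=[f"cell{i}" for i in range(N)],
    )
    if return_final:
        return tensor, state
    return tensor


def _sampled_moments(tensor: SpikeCountTensor) -> MomentTargets:
    return MomentTargets.from_tensor(tensor)


@dataclass
class MaxEntResult:
    """Fitted max-ent model with its convergence diagnostics."""

    model: MaxEntModel
    converged: bool
    n_iter: int
    max_residual: float
    trace: np.ndarray = field(repr=False)
    method: str = "exact"

    def summary(self) -> str:
        lines = [
            "Time-dependent maximum-entropy fit",
            "==================================",
            f"cells x bins:   {self.model.n_cells} x {self.model.n_bins}",
            f"n_max:          {self.model.n_max}",
            f"moment method:  {self.method}",
            f"iterations:     {self.n_iter}",
            f"max residual:   {self.max_residual:.3g}",
            f"converged:      {self.converged}",
            f"mean |J| (off): "
            f"{np.abs(self.model.J[~np.eye(self.model.n_cells, dtype=bool)]).mean():.4g}",
        ]
        return "\n".join(lines)


class TimeDependentMaxEnt:
    """Moment-matching inference of the time-dependent max-ent model.

    Parameters
    ----------
    targets : MomentTargets
        Per-bin means and second moments plus time-summed cross moments.
    n_max : int
        Count cap (match the largest observed count of the data the
        targets came from).

    The fit ascends the log-likelihood with per-parameter adaptive steps on
    the exponential-family gradient (target minus model moment): the step is
    multiplied by 1.2 whenever a gradient component keeps its sign and by
    0.5 when it flips, with steps clipped to a safe range -- robust to
    Monte-Carlo gradient noise when moments are Gibbs-estimated.
    """

    def __init__(self, targets: MomentTargets, n_max: int):
        self.targets = targets
        self.n_max = int(n_max)

    def fit(self, tol: float = 5e-4, max_iter: int = 5000,
            gibbs_sweeps: int = 200, gibbs_chains: int = 20, seed=0,
            step_init: float = 0.05, step_grow: float = 1.2,
            step_shrink: float = 0.5, step_min: float = 1e-7,
            step_max: float = 0.5, verbose: bool = False) -> MaxEntResult:
        tg = self.targets
        N, T = tg.n_cells, tg.n_bins
        exact = (self.n_max + 1) ** N <= ENUMERATION_LIMIT

        # Poisson initialisation: conditionally-independent solution
        h = np.log(np.maximum(tg.mean, 1e-4))
        J = np.zeros((N, N))
        iu = np.triu_indices(N, k=1)

        step_h = np.full((N, T), step_init)
        step_Jd = np.full(N, step_init * 0.2)
        step_Jo = np.full(iu[0].size, step_init * 0.2)
        prev_sign_h = np.zeros((N, T))
        prev_sign_Jd = np.zeros(N)
        prev_sign_Jo = np.zeros(iu[0].size)

        rng_seed = np.random.default_rng(seed)
        chains = None
        trace = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            model = MaxEntModel(h, J, self.n_max)
            if exact:
                mom, _ = exact_moments(model)
            else:
                sub_seed = int(rng_seed.integers(0, 2**31 - 1))
                tensor, chains = gibbs_sample(
                    model, n_sweeps=gibbs_sweeps,
                    n_chains=gibbs_chains,
                    burn_in=gibbs_sweeps // 4 if chains is None else 0,
                    seed=sub_seed, init_state=chains, return_final=True,
                )
                mom = _sampled_moments(tensor)

            g_h = tg.mean - mom.mean                              # (N, T)
            g_Jd = (tg.second - mom.second).sum(axis=1)           # (N,)
            g_Jo = (tg.cross_sum - mom.cross_sum)[iu]             # (P,)
            resid = max(np.abs(g_h).max(),
                        np.abs(g_Jd).max() / T,
                        np.abs(g_Jo).max() / T if g_Jo.size else 0.0)
            trace.append(resid)
            if verbose and it % 50 == 0:
                print(f"iter {it:5d}  max residual {resid:.3e}")
            if resid < tol:
                converged = True
                break

            for g, step, prev in ((g_h, step_h, prev_sign_h),
                                  (g_Jd / T, step_Jd, prev_sign_Jd),
                                  (g_Jo / T, step_Jo, prev_sign_Jo)):
                sign = np.sign(g)
                same = sign * prev
                step *= np.where(same > 0, step_grow,
                                 np.where(same < 0, step_shrink, 1.0))
                np.clip(step, step_min, step_max, out=step)
                prev[...] = sign
            h += step_h * np.sign(g_h)
            np.fill_diagonal(J, np.diag(J) + step_Jd * np.sign(g_Jd))
            J[iu] += step_Jo * np.sign(g_Jo)
            J.T[iu] = J[iu]

        model = MaxEntModel(h, J, self.n_max)
        return MaxEntResult(model, converged, it, float(trace[-1]),
                            np.asarray(trace),
                            method="exact" if exact else "gibbs")


def fit_maxent(targets: MomentTargets, n_max: int, **config) -> MaxEntResult:
    """Functional wrapper around :class:`TimeDependentMaxEnt`."""
    return TimeDependentMaxEnt(targets, n_max).fit(**config)


def population_rate_distribution(source, top_fraction: float | None = None):
    """Distribution of the population rate K(t) = sum_i n_i(t).

    ``source`` is a :class:`SpikeCountTensor` (empirical or Gibbs-sampled).
    Counts are pooled over bins and repetitions.  With ``top_fraction=q``,
    only the fraction ``q`` of time-bins with the highest mean population
    rate is kept (e.g. 0.05 for the most active 5%).  Returns ``(support,
    pmf)``.
    """
    K = source.counts.sum(axis=0)                    # (T, R)
    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        n_keep = max(1, int(round(top_fraction * K.shape[0])))
        order = np.argsort(K.mean(axis=1))[::-1][:n_keep]
        K = K[order]
    values = K.ravel()
    pmf = np.bincount(values) / values.size
    return np.arange(pmf.size), pmf


def predict_triplet_correlations(model: MaxEntModel, triplets,
                                 n_samples: int = 200, seed=0,
                                 n_chains: int = 50) -> np.ndarray:
    """Monte-Carlo triplet noise correlations under the max-ent model.

    Gibbs samples play the role of repetitions; per-bin means are the model
    sample means.  ``n_samples`` is the number of kept sweeps per chain.
    """
    burn = max(20, n_samples // 4)
    tensor = gibbs_sample(model, n_sweeps=burn + n_samples,
                          n_chains=n_chains, burn_in=burn, seed=seed)
    return np.array([
        triplet_noise_correlation(tensor, i, j, k) for (i, j, k) in triplets
    ])
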