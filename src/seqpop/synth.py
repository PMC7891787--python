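"""Seeded generators of ground-truth synthetic recordings.

These emulate the statistical structure of repeated-trial retinal
recordings -- smooth time-varying firing rates binned at 60 Hz, ~79
repetitions, truncated-Poisson count marginals, and noise correlations
that decay with inter-cell distance -- so every stage of the inference
pipeline can be exercised against known ground truth without any
downloaded data.

Two dependence routes are provided.  ``simulate_pair`` draws a single cell
pair exactly from a chosen copula family (the same construction the model
assumes).  ``simulate_population`` draws a whole population through a
latent multivariate Gaussian with a distance-decaying correlation function
(a generalised dichotomized Gaussian): a latent normal vector is drawn per
bin and repetition, mapped through the standard-normal c.d.f. and then
each cell's inverse count c.d.f.  For any two cells this is exactly a
Gaussian copula with parameter rho(d), so marginals are exact while the
multicell joint law stays globally consistent -- which arbitrary pairwise
Gumbel margins cannot guarantee.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.special import ndtr

from .copulas import CopulaModel, sample_pair
from .tensor import CellGeometry, MarginalSet, SpikeCountTensor

__all__ = [
    "simulate_rate_profiles",
    "truncated_poisson_marginals",
    "simulate_pair",
    "simulate_population",
]

#: default mean rate, spikes per bin (10 Hz at the 60 Hz bin rate)
DEFAULT_MEAN_RATE = 1.0 / 6.0
#: truncation quantile for Poisson marginals
TRUNCATION_QUANTILE = 1.0 - 1e-6


def simulate_rate_profiles(n_cells: int, n_bins: int, seed=0,
                           smoothness: float = 5.0,
                           mean_rate: float = DEFAULT_MEAN_RATE,
                           log_sd: float = 1.0) -> np.ndarray:
    """Smooth non-negative rate traces (spikes/bin), one row per cell.

    Log-normal construction: circularly smoothed white noise (Gaussian
    kernel of sd ``smoothness`` bins, renormalised to unit variance) is
    exponentiated with a half-variance correction so the mean rate is
    ``mean_rate`` regardless of ``log_sd``.  Large ``smoothness`` gives
    near-constant rates.
    """
    if mean_rate < 0:
        raise ValueError("mean_rate must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_cells, n_bins))
    g = gaussian_filter1d(noise, sigma=smoothness, axis=1, mode="wrap")
    sd = g.std(axis=1, keepdims=True)
    # smoothness >> n_bins flattens the trace to float residue (the input
    # noise has unit variance, so sd is the attenuation); keep it constant
    g = np.where(sd > 1e-6, g / np.where(sd > 1e-6, sd, 1.0), 0.0)
    return mean_rate * np.exp(log_sd * g - 0.5 * log_sd**2)


def truncated_poisson_marginals(rates: np.ndarray,
                                n_max: int | None = None) -> MarginalSet:
    """Truncated-Poisson count marginals for given per-bin rates.

    The cap defaults to the ``1 - 1e-6`` quantile of the largest rate, so
    truncation is statistically invisible; the pmf is renormalised on
    ``0..n_max``.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if n_max is None:
        n_max = int(stats.poisson.ppf(TRUNCATION_QUANTILE, rates.max()))
        n_max = max(n_max, 1)
    k = np.arange(n_max + 1)
    pmf = stats.poisson.pmf(k[None, None, :], rates[:, :, None])
    pmf = pmf / pmf.sum(axis=2, keepdims=True)
    return MarginalSet(pmf)


def simulate_pair(rates_i, rates_j, family: str, theta, n_reps: int,
                  seed=0, n_max: int | None = None,
                  bin_width: float = 1000.0 / 60.0) -> SpikeCountTensor:
    """Two-cell tensor drawn exactly from a copula with Poisson marginals.

    Per bin, ``n_reps`` count pairs are drawn from the discrete copula
    joint law built on the two cells' truncated-Poisson marginals.
    """
    rates_i = np.asarray(rates_i, dtype=float)
    rates_j = np.asarray(rates_j, dtype=float)
    if rates_i.shape != rates_j.shape or rates_i.ndim != 1:
        raise ValueError("rates must be 1-d arrays of equal length")
    T = rates_i.size
    if n_max is None:
        n_max = int(stats.poisson.ppf(TRUNCATION_QUANTILE,
                                      max(rates_i.max(), rates_j.max())))
        n_max = max(n_max, 1)
    marg = truncated_poisson_marginals(np.stack([rates_i, rates_j]), n_max)
    cdf = marg.cdf
    model = CopulaModel(family, theta)
    rng = np.random.default_rng(seed)
    counts = np.zeros((2, T, n_reps), dtype=np.int64)
    for t in range(T):
        sub_seed = rng.integers(0, 2**31 - 1)
        x, y = sample_pair(model, cdf[0, t], cdf[1, t], n_reps, sub_seed)
        counts[0, t] = x
        counts[1, t] = y
    return SpikeCountTensor(counts, bin_width, ["cellA", "cellB"])


def _repair_psd(corr: np.ndarray, warn_threshold: float = 0.05):
    """Clip negative eigenvalues and restore the unit diagonal."""
    w, V = np.linalg.eigh(corr)
    if w.min() >= -1e-12:
        return corr
    w_clipped = np.clip(w, 0.0, None)
    if np.max(np.abs(w - w_clipped)) > warn_threshold:
        warnings.warn(
            "latent correlation repair moved an eigenvalue by more than "
            f"{warn_threshold}; the requested rho(d) is far from PSD",
            stacklevel=2,
        )
    repaired = (V * w_clipped) @ V.T
    d = np.sqrt(np.diag(repaired))
    return repaired / np.outer(d, d)


def simulate_population(geometry: CellGeometry, rates: np.ndarray, rho_fn,
                        n_reps: int, seed=0, n_max: int | None = None,
                        bin_width: float = 1000.0 / 60.0) -> SpikeCountTensor:
    """Population tensor with distance-decaying latent-Gaussian dependence.

    Parameters
    ----------
    geometry : CellGeometry
        Cell positions; pairwise distances feed ``rho_fn``.
    rates : (n_cells, n_bins) array
        Per-cell, per-bin mean rates (spikes/bin).
    rho_fn : callable
        Maps distance (um) to latent correlation in [-1, 1]; evaluated on
        the distance matrix.  Off-diagonal only; the diagonal is 1.
    n_reps : int
        Number of repetitions to draw.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    N, T = rates.shape
    if geometry.n_cells != N:
        raise ValueError("geometry and rates disagree on the number of cells")
    D = geometry.distance_matrix()
    corr = np.asarray(rho_fn(D), dtype=float)
    np.fill_diagonal(corr, 1.0)
    if np.any(np.abs(corr) > 1 + 1e-9):
        raise ValueError("rho(d) must map into [-1, 1]")
    corr = _repair_psd(corr)
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(N))

    marg = truncated_poisson_marginals(rates, n_max)
    cdf = marg.cdf                                       # (N, T, m+1)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((T * n_reps, N)) @ L.T
    u = ndtr(z).reshape(T, n_reps, N)
    counts = np.zeros((N, T, n_reps), dtype=np.int64)
    for i in range(N):
        # generalized inverse cdf per bin: min{k : F(k) >= u}
        counts[i] = (u[:, :, i, None] > cdf[i][:, None, :]).sum(axis=2)
    return SpikeCountTensor(counts, bin_width, list(geometry.cell_ids))
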