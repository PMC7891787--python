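"""Stimulus/noise covariance decomposition and correlation statistics.

For repeated presentations of the same stimulus, the total covariance of two
cells' spike counts splits exactly into a stimulus part (driven by the shared
time-varying mean rates) and a noise part (trial-to-trial co-fluctuations
around those means):

    Cov_total(n_i, n_j) = Cov_stimulus(n_i, n_j) + Cov_noise(n_i, n_j)

with all averages taken with the maximum-likelihood 1/T and 1/R
normalisations (no Bessel correction), which is what makes the decomposition
an exact algebraic identity.  Noise correlations are the noise covariance
normalised by the *total* variances V_i = Cov_total(n_i, n_i).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tensor import SpikeCountTensor

__all__ = [
    "covariance_decomposition",
    "noise_covariance_matrix",
    "noise_correlation",
    "noise_correlation_matrix",
    "total_variances",
    "triplet_noise_correlation",
    "cross_correlogram",
    "prediction_metrics",
    "pair_table",
]


def _moments(tensor: SpikeCountTensor):
    counts = tensor.counts.astype(float)
    mu_t = counts.mean(axis=2)           # (N, T) per-bin means across reps
    mu = mu_t.mean(axis=1)               # (N,) grand means
    return counts, mu_t, mu


def covariance_decomposition(tensor: SpikeCountTensor, i: int, j: int):
    """Return ``(total, stimulus, noise)`` covariance for cells ``i, j``."""
    if tensor.n_reps < 2:
        raise ValueError("covariance decomposition requires >= 2 repetitions")
    counts, mu_t, mu = _moments(tensor)
    di = counts[i] - mu_t[i][:, None]
    dj = counts[j] - mu_t[j][:, None]
    noise = (di * dj).mean()
    stimulus = ((mu_t[i] - mu[i]) * (mu_t[j] - mu[j])).mean()
    total = ((counts[i] - mu[i]) * (counts[j] - mu[j])).mean()
    return total, stimulus, noise


def noise_covariance_matrix(tensor: SpikeCountTensor) -> np.ndarray:
    """All pairwise noise covariances (diagonal = per-cell noise variance)."""
    counts, mu_t, _ = _moments(tensor)
    dev = counts - mu_t[:, :, None]            # (N, T, R)
    N, T, R = dev.shape
    flat = dev.reshape(N, T * R)
    return flat @ flat.T / (T * R)


def total_variances(tensor: SpikeCountTensor) -> np.ndarray:
    """Per-cell total variance V_i = Cov_total(n_i, n_i)."""
    counts, _, mu = _moments(tensor)
    dev = counts - mu[:, None, None]
    return (dev**2).mean(axis=(1, 2))


def noise_correlation(tensor: SpikeCountTensor, i: int, j: int) -> float:
    """Noise correlation Cov_noise / sqrt(V_i V_j); NaN if a V vanishes."""
    _, _, noise = covariance_decomposition(tensor, i, j)
    V = total_variances(tensor)
    if V[i] <= 0 or V[j] <= 0:
        return float("nan")
    return float(noise / np.sqrt(V[i] * V[j]))


def noise_correlation_matrix(tensor: SpikeCountTensor) -> np.ndarray:
    """Matrix of pairwise noise correlations (NaN where variances vanish)."""
    C = noise_covariance_matrix(tensor)
    V = total_variances(tensor)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = C / np.sqrt(np.outer(V, V))
    R[:, V <= 0] = np.nan
    R[V <= 0, :] = np.nan
    return R


def triplet_noise_correlation(tensor: SpikeCountTensor, i: int, j: int,
                              k: int) -> float:
    """Third-order noise correlation of cells ``(i, j, k)``.

    The third central noise moment, averaged 1/T and 1/R, normalised by
    sqrt(V_i V_j V_k) with the same total variances as the pairwise case.
    """
    counts, mu_t, _ = _moments(tensor)
    dev = counts - mu_t[:, :, None]
    m3 = (dev[i] * dev[j] * dev[k]).mean()
    V = total_variances(tensor)
    if min(V[i], V[j], V[k]) <= 0:
        return float("nan")
    return float(m3 / np.sqrt(V[i] * V[j] * V[k]))


def cross_correlogram(tensor: SpikeCountTensor, i: int, j: int,
                      max_lag_bins: int):
    """Lagged covariances of spike counts and of firing rates.

    Returns ``(lags, count_cov, rate_cov)`` where ``count_cov[l]`` is the
    covariance of ``n_i(t, r)`` with ``n_j(t + lag, r)`` (averaged over
    repetitions then time) and ``rate_cov`` is the same for the per-bin mean
    rates.  At zero lag, ``count_cov - rate_cov`` equals the noise
    covariance of the decomposition.
    """
    if not 0 <= max_lag_bins < tensor.n_bins:
        raise ValueError("max_lag_bins must satisfy 0 <= lag < n_bins")
    counts, mu_t, mu = _moments(tensor)
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    count_cov = np.empty(lags.size)
    rate_cov = np.empty(lags.size)
    T = tensor.n_bins
    for idx, lag in enumerate(lags):
        if lag >= 0:
            sl_i, sl_j = slice(0, T - lag), slice(lag, T)
        else:
            sl_i, sl_j = slice(-lag, T), slice(0, T + lag)
        ci = counts[i, sl_i] - mu[i]
        cj = counts[j, sl_j] - mu[j]
        count_cov[idx] = (ci * cj).mean()
        rate_cov[idx] = ((mu_t[i, sl_i] - mu[i]) * (mu_t[j, sl_j] - mu[j])).mean()
    return lags, count_cov, rate_cov


def prediction_metrics(empirical, predicted):
    """Pearson correlation and coefficient of determination of a prediction.

    Missing values (NaN) in either vector are excluded pairwise.  The c.o.d.
    is ``1 - SS_res / SS_tot`` around the empirical mean and may be negative;
    if the empirical values have no variance both metrics are NaN.
    """
    empirical = np.asarray(empirical, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if empirical.shape != predicted.shape:
        raise ValueError("empirical and predicted must have equal length")
    ok = ~(np.isnan(empirical) | np.isnan(predicted))
    e, p = empirical[ok], predicted[ok]
    if e.size < 2:
        return float("nan"), float("nan")
    ss_tot = ((e - e.mean()) ** 2).sum()
    if ss_tot == 0:
        return float("nan"), float("nan")
    pearson = float(np.corrcoef(e, p)[0, 1])
    cod = float(1.0 - ((e - p) ** 2).sum() / ss_tot)
    return pearson, cod


def pair_table(tensor: SpikeCountTensor, geometry=None,
               pairs=None) -> pd.DataFrame:
    """Per-pair covariance decomposition and noise correlation as a table.

    Columns: cell_i, cell_j, (distance_um if geometry), cov_total, cov_stim,
    cov_noise, corr_noise.
    """
    N = tensor.n_cells
    if pairs is None:
        pairs = [(i, j) for i in range(N) for j in range(i + 1, N)]
    C = noise_covariance_matrix(tensor)
    V = total_variances(tensor)
    counts, mu_t, mu = _moments(tensor)
    rows = []
    for i, j in pairs:
        total = ((counts[i] - mu[i]) * (counts[j] - mu[j])).mean()
        noise = C[i, j]
        stim = total - noise
        corr = noise / np.sqrt(V[i] * V[j]) if V[i] > 0 and V[j] > 0 else np.nan
        row = {
            "cell_i": tensor.cell_ids[i],
            "cell_j": tensor.cell_ids[j],
            "cov_total": total,
            "cov_stim": stim,
            "cov_noise": noise,
            "corr_noise": corr,
        }
        if geometry is not None:
            row["distance_um"] = geometry.distance(i, j)
        rows.append(row)
    return pd.DataFrame(rows)
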