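"""The three-parameter distance law for the Gumbel copula parameter.

Across pairs of same-type retinal ganglion cells, the fitted Gumbel
parameter depends on the inter-cell distance d (between receptive-field
centres, in micrometres) through a double exponential of a quadratic,

    theta(d) = exp(exp(a + b d + c d^2))        for d <= cutoff,

with independence (theta = 1) beyond the cutoff (default 1 mm).  Because
exp(exp(.)) > 1 everywhere, the law always stays inside the Gumbel domain.
Fitting is ordinary least squares of log(log theta_ij) on [1, d, d^2] over
pairs within the cutoff, which linearises the functional form exactly.

With the law in hand, the noise covariance and correlation of *any* pair of
cells can be predicted from sequential recordings alone: the per-bin joint
law is the Gumbel copula at theta(d) composed with the two cells' empirical
marginals, and the noise covariance is the time average of the per-bin
covariances.  By construction this prediction consumes only single-cell
marginals and a distance -- never a joint recording.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .copulas import FAMILIES, _rectangle_masses

__all__ = [
    "ThetaDistanceLaw",
    "theta_of_distance",
    "ThetaDistanceModel",
    "ThetaDistanceResult",
    "fit_theta_distance",
    "PairPrediction",
    "predict_pair_statistics",
    "predict_pairs_batch",
]

#: Printed coefficients of the distance law for rat OFF-alpha cells.
REFERENCE_COEFFICIENTS = (0.73, -0.014, 8e-6)


@dataclass
class ThetaDistanceLaw:
    """Coefficients (a, b, c) and cutoff of the theta-distance law.

    Units: ``a`` dimensionless, ``b`` um^-1, ``c`` um^-2, ``cutoff`` um.
    """

    a: float
    b: float
    c: float
    cutoff: float = 1000.0

    def theta(self, d, length_scale_factor: float = 1.0):
        """Gumbel theta at distance ``d`` (um); 1.0 beyond the cutoff.

        ``length_scale_factor`` rescales distance inside the law (and its
        cutoff): a factor of 2 stretches the correlation structure to twice
        the spatial scale, 0.5 compresses it.
        """
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("distance must be non-negative")
        x = d / float(length_scale_factor)
        inside = x <= self.cutoff
        expo = np.where(inside, self.a + self.b * x + self.c * x**2, 0.0)
        out = np.where(inside, np.exp(np.exp(expo)), 1.0)
        return out if out.shape else float(out)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"a": self.a, "b": self.b, "c": self.c,
                       "cutoff_um": self.cutoff}, f, indent=2)

    @classmethod
    def from_json(cls, path) -> "ThetaDistanceLaw":
        with open(path) as f:
            d = json.load(f)
        return cls(d["a"], d["b"], d["c"], d.get("cutoff_um", 1000.0))


def theta_of_distance(law: ThetaDistanceLaw, d):
    """Evaluate the law (functional wrapper)."""
    return law.theta(d)


@dataclass
class ThetaDistanceResult:
    """OLS fit of the distance law on the log(log theta) scale."""

    law: ThetaDistanceLaw
    ols_results: object
    n_pairs_used: int
    n_pairs_dropped: int

    @property
    def params(self) -> np.ndarray:
        return np.array([self.law.a, self.law.b, self.law.c])

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (a, b, c) from the OLS fit."""
        return np.asarray(self.ols_results.bse)

    def predict(self, d):
        return self.law.theta(d)

    def summary(self) -> str:
        lines = [
            "Theta-distance law  theta(d) = exp(exp(a + b d + c d^2))",
            "========================================================",
            f"a: {self.law.a:+.6g}  (se {self.bse[0]:.3g})",
            f"b: {self.law.b:+.6g} um^-1  (se {self.bse[1]:.3g})",
            f"c: {self.law.c:+.6g} um^-2  (se {self.bse[2]:.3g})",
            f"cutoff: {self.law.cutoff:g} um (independence beyond)",
            f"pairs used: {self.n_pairs_used} "
            f"(dropped {self.n_pairs_dropped}: beyond cutoff or theta <= 1)",
        ]
        return "\n".join(lines)


class ThetaDistanceModel:
    """Distance law fitted to per-pair copula parameters.

    Parameters
    ----------
    thetas : array
        Per-pair maximum-likelihood Gumbel parameters ``theta_ij``.
    distances : array
        Matching inter-cell distances ``d_ij`` in micrometres.
    cutoff : float
        Pairs beyond this distance are excluded from the fit and treated as
        independent by the fitted law.
    """

    def __init__(self, thetas, distances, cutoff: float = 1000.0):
        self.thetas = np.asarray(thetas, dtype=float)
        self.distances = np.asarray(distances, dtype=float)
        if self.thetas.shape != self.distances.shape:
            raise ValueError("thetas and distances must have equal length")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")
        self.cutoff = float(cutoff)

    def fit(self) -> ThetaDistanceResult:
        usable = (self.distances <= self.cutoff) & (self.thetas > 1.0)
        n_used = int(usable.sum())
        if n_used < 3:
            raise ValueError(
                f"need >= 3 usable pairs (d <= cutoff, theta > 1); got {n_used}"
            )
        d = self.distances[usable]
        y = np.log(np.log(self.thetas[usable]))
        X = np.column_stack([np.ones_like(d), d, d**2])
        res = sm.OLS(y, X).fit()
        a, b, c = res.params
        law = ThetaDistanceLaw(float(a), float(b), float(c), self.cutoff)
        return ThetaDistanceResult(law, res, n_used,
                                   int(usable.size - n_used))


def fit_theta_distance(thetas, distances,
                       cutoff: float = 1000.0) -> ThetaDistanceResult:
    """Functional wrapper around :class:`ThetaDistanceModel`."""
    return ThetaDistanceModel(thetas, distances, cutoff).fit()


@dataclass
class PairPrediction:
    """Copula-predicted pair statistics from marginals and distance only."""

    theta: float
    per_bin_cov: np.ndarray  # (T,) noise covariance in each time-bin
    cov_noise: float
    corr_noise: float

    @property
    def n_bins(self) -> int:
        return self.per_bin_cov.size


def _per_bin_covariances(family, theta, pmf_i, pmf_j):
    """Per-bin noise covariance of the copula joint, batched over bins."""
    Fx = np.cumsum(pmf_i, axis=1)
    Fy = np.cumsum(pmf_j, axis=1)
    P = _rectangle_masses(family, theta, Fx, Fy)      # (T, m+1, m+1)
    k = np.arange(pmf_i.shape[1], dtype=float)
    exy = np.einsum("tij,i,j->t", P, k, k)
    mu_i = pmf_i @ k
    mu_j = pmf_j @ k
    return exy - mu_i * mu_j


def predict_pair_statistics(marginals_i, marginals_j, d: float,
                            law: ThetaDistanceLaw,
                            family: str = "gumbel",
                            length_scale_factor: float = 1.0) -> PairPrediction:
    """Predict a pair's noise covariance/correlation from sequential data.

    Parameters
    ----------
    marginals_i, marginals_j : (T, m+1) arrays
        Per-bin marginal pmfs of the two cells (e.g. rows of a
        :class:`~seqpop.tensor.MarginalSet`).
    d : float
        Inter-cell distance in micrometres.
    law : ThetaDistanceLaw
        Fitted distance law supplying theta(d).

    The prediction consumes only the two cells' marginals and their
    distance; it never sees a joint recording.
    """
    pmf_i = np.asarray(marginals_i, dtype=float)
    pmf_j = np.asarray(marginals_j, dtype=float)
    if pmf_i.shape != pmf_j.shape:
        raise ValueError("the two marginal arrays must share (T, m+1) shape")
    theta = float(law.theta(d, length_scale_factor))
    fam = FAMILIES[family]
    if theta == fam.independence_theta or (family == "gumbel" and theta == 1.0):
        per_bin = np.zeros(pmf_i.shape[0])
    else:
        per_bin = _per_bin_covariances(fam, theta, pmf_i, pmf_j)
    cov_noise = float(per_bin.mean())
    k = np.arange(pmf_i.shape[1], dtype=float)
    for pmf in (pmf_i, pmf_j):
        if np.any(np.abs(pmf.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("marginal pmfs must sum to 1 per bin")
    V_i = _total_variance(pmf_i, k)
    V_j = _total_variance(pmf_j, k)
    if V_i <= 0 or V_j <= 0:
        corr = float("nan")
    else:
        corr = cov_noise / math.sqrt(V_i * V_j)
    return PairPrediction(theta, per_bin, cov_noise, corr)


def _total_variance(pmf, k):
    mu_t = pmf @ k
    var_t = pmf @ k**2 - mu_t**2
    return float(var_t.mean() + ((mu_t - mu_t.mean()) ** 2).mean())


def predict_pairs_batch(pmf_i, pmf_j, thetas,
                        family: str = "gumbel") -> np.ndarray:
    """Noise covariances for many pairs sharing the same two marginal sets.

    ``thetas`` is an array of copula parameters (one per pair); per time-bin,
    the joint tables of all pairs are evaluated in a single broadcast with
    theta as a batch axis, which makes the large-mosaic synthesis tractable.
    Returns the (n_pairs,) array of time-averaged noise covariances.
    Restricted to families whose c.d.f. broadcasts over theta (gumbel,
    frank, clayton, independent).
    """
    from .copulas import _clip_unit

    pmf_i = np.asarray(pmf_i, dtype=float)
    pmf_j = np.asarray(pmf_j, dtype=float)
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    fam = FAMILIES[family]
    if family == "gaussian":
        raise NotImplementedError(
            "batched theta evaluation is not available for the gaussian "
            "family; call predict_pair_statistics per pair instead"
        )
    T, m1 = pmf_i.shape
    k = np.arange(m1, dtype=float)
    Fx = np.concatenate([np.zeros((T, 1)), np.cumsum(pmf_i, axis=1)], axis=1)
    Fy = np.concatenate([np.zeros((T, 1)), np.cumsum(pmf_j, axis=1)], axis=1)
    mu_i = pmf_i @ k
    mu_j = pmf_j @ k
    cov = np.zeros(thetas.size)
    indep = 1.0 if family == "gumbel" else fam.independence_theta
    active = thetas != indep
    if not active.any():
        return cov
    th = thetas[active][:, None, None]                 # (P, 1, 1)
    exy = np.zeros((active.sum(), T))
    for t in range(T):
        u = _clip_unit(Fx[t])[None, :, None]           # (1, m+2, 1)
        v = _clip_unit(Fy[t])[None, None, :]           # (1, 1, m+2)
        C = fam._cdf(u, v, th)                         # (P, m+2, m+2)
        P = np.diff(np.diff(C, axis=-1), axis=-2)
        P = np.where(P < 1e-15, 0.0, P)
        total = P.sum(axis=(-2, -1), keepdims=True)
        P = P / np.where(total > 0, total, 1.0)
        exy[:, t] = np.einsum("pij,i,j->p", P, k, k)
    cov[active] = (exy - mu_i * mu_j).mean(axis=1)
    return cov
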