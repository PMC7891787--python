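"""Bivariate parametric copulas on discrete spike counts.

A copula ``C(u, v | theta)`` is a joint c.d.f. on the unit square with
uniform marginals; by Sklar's theorem, composing it with the marginal
c.d.f.s of two spike counts yields a joint law whose marginals are exactly
the inputs while ``theta`` alone encodes the dependence.  For integer
counts the joint probability mass of a pair ``(x, y)`` is the rectangle
inclusion-exclusion of the copula over the marginal c.d.f. steps:

    P(x, y) = C(F(x), G(y)) - C(F(x-1), G(y)) - C(F(x), G(y-1))
              + C(F(x-1), G(y-1)),      F(-1) = G(-1) = 0,

which is the correct density with respect to counting measure.  The
families implemented are Gumbel (theta >= 1), Gaussian (|theta| <= 1),
Frank (theta real), Clayton (theta >= -1, != 0) and the independence
copula ``C(u, v) = u v``.

Fitting (`PairCopulaModel.fit`) maximises the discrete log-likelihood of a
pair of simultaneously recorded cells over all time-bins and repetitions,
with the per-bin empirical marginals plugged in; bins where either cell is
deterministic across repetitions carry no information about ``theta`` and
contribute only a theta-independent constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .tensor import SpikeCountTensor, empirical_marginals

__all__ = [
    "CopulaFamily",
    "FAMILIES",
    "CopulaModel",
    "DiscreteJointLaw",
    "copula_cdf",
    "discrete_joint_pmf",
    "pair_log_likelihood",
    "PairCopulaModel",
    "PairCopulaResult",
    "fit_copula_parameter",
    "sample_pair",
    "kl_empirical_vs_model",
    "select_family",
]

_CLIP = 1e-12  # interior clipping of u, v inside family formulas


def _clip_unit(x):
    return np.clip(x, _CLIP, 1.0 - _CLIP)


class CopulaFamily:
    """A one-parameter bivariate copula family.

    Subclasses implement ``_cdf`` (and ``_cond_cdf`` where a conditional
    sampler is available) on interior points; the public :meth:`cdf`
    enforces the exact boundary contract C(u,0)=C(0,v)=0, C(u,1)=u,
    C(1,v)=v.
    """

    name: str = ""
    #: (low, high) closed bounds of the parameter domain (inf allowed).
    domain: tuple = (-np.inf, np.inf)
    #: theta value at (or towards) which the family is the independence copula
    independence_theta: float | None = None

    def validate_theta(self, theta: float) -> float:
        theta = float(theta)
        lo, hi = self.domain
        if not (lo <= theta <= hi) or not np.isfinite(theta):
            raise ValueError(
                f"theta={theta} outside the {self.name} domain [{lo}, {hi}]"
            )
        return theta

    def _cdf(self, u, v, theta):  # pragma: no cover - abstract
        raise NotImplementedError

    def _cond_cdf(self, u, v, theta):
        """P(V <= v | U = u); used by the conditional sampler."""
        raise NotImplementedError(f"no sampler for family '{self.name}'")

    def cdf(self, u, v, theta):
        theta = self.validate_theta(theta)
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if np.any((u < -1e-9) | (u > 1 + 1e-9) | (v < -1e-9) | (v > 1 + 1e-9)):
            raise ValueError("u and v must lie in [0, 1]")
        u = np.clip(u, 0.0, 1.0)
        v = np.clip(v, 0.0, 1.0)
        out = self._cdf(_clip_unit(u), _clip_unit(v), theta)
        out = np.asarray(out, dtype=float)
        # exact boundary contract
        out = np.where(u <= 0, 0.0, out)
        out = np.where(v <= 0, 0.0, out)
        out = np.where(u >= 1, np.minimum(v, 1.0) * (u >= 1), out)
        out = np.where(v >= 1, np.where(u >= 1, 1.0, u), out)
        return out if out.shape else float(out)

    # fitting transform: unbounded working parameter <-> theta
    def to_working(self, theta: float) -> float:
        return float(theta)

    def from_working(self, s: float) -> float:
        return float(s)

    #: bounds of the working parameter used by the bounded scalar search
    working_bounds: tuple = (-50.0, 50.0)

    def sample(self, theta, n_samples, rng):
        """Draw (u1, u2) pairs via the conditional-distribution method."""
        theta = self.validate_theta(theta)
        u1 = rng.random(n_samples)
        w = rng.random(n_samples)
        u2 = _invert_conditional(self, u1, w, theta)
        return u1, u2


def _invert_conditional(family, u1, w, theta, tol=1e-10):
    """Solve cond_cdf(u1, v) = w for v by vectorised bisection."""
    lo = np.full_like(u1, _CLIP)
    hi = np.full_like(u1, 1.0 - _CLIP)
    # cond_cdf is non-decreasing in v
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        c = family._cond_cdf(_clip_unit(u1), mid, theta)
        high = c >= w
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
        if np.max(hi - lo) < tol:
            break
    return 0.5 * (lo + hi)


class IndependentCopula(CopulaFamily):
    name = "independent"
    domain = (-np.inf, np.inf)  # parameter ignored
    independence_theta = 0.0

    def validate_theta(self, theta):
        return 0.0

    def _cdf(self, u, v, theta):
        return u * v

    def _cond_cdf(self, u, v, theta):
        return v

    def sample(self, theta, n_samples, rng):
        return rng.random(n_samples), rng.random(n_samples)


class GumbelCopula(CopulaFamily):
    name = "gumbel"
    domain = (1.0, np.inf)
    independence_theta = 1.0
    working_bounds = (-14.0, 5.0)  # theta = 1 + exp(s) in (1+8e-7, ~149)

    def _cdf(self, u, v, theta):
        # theta may be an array (broadcast against u, v) in batched paths
        if np.ndim(theta) == 0 and theta == 1.0:
            return u * v
        a = (-np.log(u)) ** theta
        b = (-np.log(v)) ** theta
        return np.exp(-((a + b) ** (1.0 / theta)))

    def _cond_cdf(self, u, v, theta):
        if theta == 1.0:
            return np.broadcast_to(v, np.broadcast(u, v).shape).copy()
        lu = -np.log(u)
        a = lu**theta
        b = (-np.log(v)) ** theta
        s = a + b
        C = np.exp(-(s ** (1.0 / theta)))
        return C * s ** ((1.0 - theta) / theta) * lu ** (theta - 1.0) / u

    def to_working(self, theta):
        return math.log(max(theta - 1.0, 1e-12))

    def from_working(self, s):
        return 1.0 + math.exp(s)


# 64-node Gauss-Legendre rule, used by the bivariate-normal c.d.f.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


def _bvn_cdf(x, y, rho):
    """Standard bivariate-normal c.d.f. with correlation ``rho``, vectorised.

    Uses the sine-substitution quadrature form

        Phi2(x, y, rho) = Phi(x) Phi(y)
            + (1/2pi) * int_0^{asin rho} exp(-(x^2 + y^2 - 2 x y sin t)
                                             / (2 cos^2 t)) dt,

    whose integrand is smooth and bounded, so a fixed Gauss-Legendre rule
    is accurate to ~1e-14 away from |rho| = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    upper = math.asin(rho)
    t = 0.5 * upper * (_GL_NODES + 1.0)              # nodes on [0, asin(rho)]
    w = 0.5 * upper * _GL_WEIGHTS
    sin_t = np.sin(t)
    cos2_t = np.cos(t) ** 2
    xx = x[..., None]
    yy = y[..., None]
    integrand = np.exp(-(xx**2 + yy**2 - 2.0 * xx * yy * sin_t) / (2.0 * cos2_t))
    corr = (integrand * w).sum(axis=-1) / (2.0 * math.pi)
    return special.ndtr(x) * special.ndtr(y) + corr


class GaussianCopula(CopulaFamily):
    name = "gaussian"
    domain = (-1.0, 1.0)
    independence_theta = 0.0
    working_bounds = (-6.0, 6.0)  # theta = tanh(s), |theta| <= 0.99999

    def _cdf(self, u, v, theta):
        if theta == 0.0:
            return u * v
        if theta == 1.0:
            return np.minimum(u, v)
        if theta == -1.0:
            return np.maximum(u + v - 1.0, 0.0)
        x = special.ndtri(u)
        y = special.ndtri(v)
        return _bvn_cdf(x, y, theta)

    def _cond_cdf(self, u, v, theta):
        x = special.ndtri(_clip_unit(u))
        y = special.ndtri(_clip_unit(v))
        return special.ndtr((y - theta * x) / math.sqrt(1.0 - theta**2))

    def to_working(self, theta):
        return math.atanh(np.clip(theta, -1 + 1e-9, 1 - 1e-9))

    def from_working(self, s):
        return math.tanh(s)

    def sample(self, theta, n_samples, rng):
        """Latent bivariate-normal sampler."""
        theta = self.validate_theta(theta)
        z = rng.standard_normal((n_samples, 2))
        z2 = theta * z[:, 0] + math.sqrt(max(1.0 - theta**2, 0.0)) * z[:, 1]
        return special.ndtr(z[:, 0]), special.ndtr(z2)


class FrankCopula(CopulaFamily):
    name = "frank"
    domain = (-np.inf, np.inf)
    independence_theta = 0.0
    working_bounds = (-50.0, 50.0)

    def _cdf(self, u, v, theta):
        if np.ndim(theta) == 0 and abs(theta) < 1e-6:
            return u * v
        num = np.expm1(-theta * u) * np.expm1(-theta * v)
        return -np.log1p(num / np.expm1(-theta)) / theta

    def _cond_cdf(self, u, v, theta):
        if abs(theta) < 1e-6:
            return np.broadcast_to(v, np.broadcast(u, v).shape).copy()
        eu = np.expm1(-theta * u)
        ev = np.expm1(-theta * v)
        return (eu + 1.0) * ev / (np.expm1(-theta) + eu * ev)


class ClaytonCopula(CopulaFamily):
    name = "clayton"
    domain = (-1.0, np.inf)  # theta = 0 excluded (independence limit)
    independence_theta = 0.0
    working_bounds = (-10.0, 5.0)  # positive branch: theta = exp(s)

    def validate_theta(self, theta):
        theta = float(theta)
        if theta == 0.0 or not (-1.0 <= theta) or not np.isfinite(theta):
            raise ValueError(f"theta={theta} outside the clayton domain [-1, inf)\\{{0}}")
        return theta

    def _cdf(self, u, v, theta):
        m = np.maximum(u ** (-theta) + v ** (-theta) - 1.0, 0.0)
        return np.where(m > 0, m ** (-1.0 / theta), 0.0)

    def _cond_cdf(self, u, v, theta):
        m = np.maximum(u ** (-theta) + v ** (-theta) - 1.0, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = u ** (-theta - 1.0) * m ** (-1.0 / theta - 1.0)
        return np.where(m > 0, out, np.where(theta > 0, 0.0, 1.0))

    def to_working(self, theta):
        return math.log(theta) if theta > 0 else theta

    def from_working(self, s):
        return math.exp(s)


FAMILIES: dict[str, CopulaFamily] = {
    f.name: f
    for f in (
        IndependentCopula(),
        GumbelCopula(),
        GaussianCopula(),
        FrankCopula(),
        ClaytonCopula(),
    )
}


@dataclass
class CopulaModel:
    """A copula family tag plus its parameter theta."""

    family: str
    theta: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown copula family '{self.family}'")
        fam = FAMILIES[self.family]
        if self.family == "independent":
            self.theta = None
        else:
            self.theta = fam.validate_theta(self.theta)

    @property
    def _family(self) -> CopulaFamily:
        return FAMILIES[self.family]

    def cdf(self, u, v):
        theta = 0.0 if self.theta is None else self.theta
        return self._family.cdf(u, v, theta)


def copula_cdf(model: CopulaModel, u, v):
    """Evaluate C(u, v | theta) for the model's family."""
    return model.cdf(u, v)


@dataclass
class DiscreteJointLaw:
    """Joint pmf of two integer counts on (0..nmax_x) x (0..nmax_y)."""

    pmf: np.ndarray

    def __post_init__(self):
        self.pmf = np.asarray(self.pmf, dtype=float)
        if self.pmf.ndim != 2:
            raise ValueError("joint pmf must be 2-d")

    def marginal_x(self) -> np.ndarray:
        return self.pmf.sum(axis=1)

    def marginal_y(self) -> np.ndarray:
        return self.pmf.sum(axis=0)

    def mean_product(self) -> float:
        """E[X Y] under the joint law."""
        x = np.arange(self.pmf.shape[0], dtype=float)
        y = np.arange(self.pmf.shape[1], dtype=float)
        return float(x @ self.pmf @ y)


def _rectangle_masses(family: CopulaFamily, theta, Fx, Fy):
    """Joint pmf tables by rectangle inclusion-exclusion, batched.

    Fx, Fy : arrays (..., m+1) of non-decreasing c.d.f.s ending at 1.
    Returns (..., m+1, m+1) tables, clipped and renormalised.
    """
    Fx0 = np.concatenate([np.zeros(Fx.shape[:-1] + (1,)), Fx], axis=-1)
    Fy0 = np.concatenate([np.zeros(Fy.shape[:-1] + (1,)), Fy], axis=-1)
    C = family.cdf(Fx0[..., :, None], Fy0[..., None, :], theta)
    P = np.diff(np.diff(C, axis=-1), axis=-2)
    P = np.where(P < 1e-15, 0.0, P)
    total = P.sum(axis=(-2, -1), keepdims=True)
    return P / np.where(total > 0, total, 1.0)


def discrete_joint_pmf(model: CopulaModel, cdf_x, cdf_y) -> DiscreteJointLaw:
    """Discrete joint law of two counts with marginal c.d.f.s ``cdf_x, cdf_y``."""
    cdf_x = np.asarray(cdf_x, dtype=float)
    cdf_y = np.asarray(cdf_y, dtype=float)
    for c in (cdf_x, cdf_y):
        if np.any(np.diff(c) < -1e-12):
            raise ValueError("marginal cdf must be non-decreasing")
        if abs(c[-1] - 1.0) > 1e-9:
            raise ValueError("marginal cdf must end at 1")
    theta = 0.0 if model.theta is None else model.theta
    P = _rectangle_masses(model._family, theta, cdf_x, cdf_y)
    return DiscreteJointLaw(P)


def _informative_bins(pmf_i, pmf_j):
    """Bins where both cells vary across repetitions (max pmf < 1)."""
    return (pmf_i.max(axis=1) < 1.0 - 1e-12) & (pmf_j.max(axis=1) < 1.0 - 1e-12)


def pair_log_likelihood(model: CopulaModel, counts_i, counts_j,
                        marginals: tuple) -> float:
    """Log-likelihood of a pair's counts under the discrete copula model.

    Parameters
    ----------
    counts_i, counts_j : int arrays (T, R)
        Simultaneously recorded counts of the two cells.
    marginals : (pmf_i, pmf_j)
        Per-bin marginal pmfs, shape (T, m+1) each, typically empirical.

    Returns ``sum_t sum_r log P_t(n_i(t,r), n_j(t,r))``; ``-inf`` if any
    observed pair has zero mass under the model.
    """
    pmf_i, pmf_j = (np.asarray(m, dtype=float) for m in marginals)
    counts_i = np.asarray(counts_i)
    counts_j = np.asarray(counts_j)
    Fx = np.cumsum(pmf_i, axis=1)
    Fy = np.cumsum(pmf_j, axis=1)
    theta = 0.0 if model.theta is None else model.theta
    P = _rectangle_masses(model._family, theta, Fx, Fy)  # (T, m+1, m+1)
    t_idx = np.arange(counts_i.shape[0])[:, None]
    probs = P[t_idx, counts_i, counts_j]
    with np.errstate(divide="ignore"):
        ll = np.log(probs)
    if np.any(np.isneginf(ll)):
        return float("-inf")
    return float(ll.sum())


@dataclass
class PairCopulaResult:
    """Maximum-likelihood fit of a copula family to one cell pair."""

    family: str
    theta: float | None
    llf: float
    converged: bool
    n_informative_bins: int
    n_bins: int
    n_reps: int
    model: CopulaModel = field(init=False)

    def __post_init__(self):
        self.model = CopulaModel(self.family, self.theta)

    def summary(self) -> str:
        lines = [
            "Pair copula maximum-likelihood fit",
            "==================================",
            f"family:            {self.family}",
            f"theta:             {self.theta if self.theta is not None else '-'}",
            f"log-likelihood:    {self.llf:.6g}",
            f"converged:         {self.converged}",
            f"informative bins:  {self.n_informative_bins} / {self.n_bins}",
            f"repetitions:       {self.n_reps}",
        ]
        return "\n".join(lines)


class PairCopulaModel:
    """Copula dependence model for one simultaneously recorded cell pair.

    Parameters
    ----------
    counts_i, counts_j : int arrays (T, R)
        The two cells' binned counts over time-bins and repetitions.
    family : str
        One of ``independent, gumbel, gaussian, frank, clayton``.
    marginals : (pmf_i, pmf_j), optional
        Per-bin marginal pmfs; estimated empirically from the counts when
        omitted.
    """

    def __init__(self, counts_i, counts_j, family="gumbel", marginals=None):
        self.counts_i = np.asarray(counts_i)
        self.counts_j = np.asarray(counts_j)
        if self.counts_i.shape != self.counts_j.shape:
            raise ValueError("the two count arrays must share (T, R) shape")
        self.family = family
        if family not in FAMILIES:
            raise ValueError(f"unknown copula family '{family}'")
        if marginals is None:
            n_max = int(max(self.counts_i.max(), self.counts_j.max()))
            marginals = (
                _empirical_pmf(self.counts_i, n_max),
                _empirical_pmf(self.counts_j, n_max),
            )
        self.marginals = tuple(np.asarray(m, dtype=float) for m in marginals)
        self._informative = _informative_bins(*self.marginals)

    def loglike(self, theta) -> float:
        return pair_log_likelihood(
            CopulaModel(self.family, theta), self.counts_i, self.counts_j,
            self.marginals,
        )

    def fit(self, xtol: float = 1e-6) -> PairCopulaResult:
        if not self._informative.any():
            raise ValueError(
                "no informative bins: both cells must vary across repetitions "
                "in at least one time-bin"
            )
        fam = FAMILIES[self.family]
        T, R = self.counts_i.shape

        if self.family == "independent":
            return PairCopulaResult(
                "independent", None, self.loglike(None), True,
                int(self._informative.sum()), T, R,
            )

        def neg(s):
            ll = self.loglike(fam.from_working(s))
            # zero-mass observations make ll = -inf; keep the search finite
            return -ll if np.isfinite(ll) else 1e30

        lo, hi = fam.working_bounds
        res = optimize.minimize_scalar(
            neg, bounds=(lo, hi), method="bounded",
            options={"xatol": xtol},
        )
        theta = fam.from_working(float(res.x))
        llf = -float(res.fun)
        converged = bool(res.success)

        if self.family == "clayton":
            # negative branch fitted separately; keep the better optimum
            res_neg = optimize.minimize_scalar(
                lambda t: -self.loglike(t),
                bounds=(-1.0 + 1e-6, -1e-6), method="bounded",
                options={"xatol": xtol},
            )
            if -float(res_neg.fun) > llf:
                theta, llf = float(res_neg.x), -float(res_neg.fun)
                converged = bool(res_neg.success)

        if fam.independence_theta is not None:
            indep = CopulaModel(self.family, fam.independence_theta) \
                if self.family != "clayton" else None
            ll_ind = (
                pair_log_likelihood(indep, self.counts_i, self.counts_j,
                                    self.marginals)
                if indep is not None
                else pair_log_likelihood(CopulaModel("independent"),
                                         self.counts_i, self.counts_j,
                                         self.marginals)
            )
            if ll_ind >= llf:  # boundary/independence optimum
                theta = (fam.independence_theta
                         if self.family != "clayton" else 1e-6)
                llf = ll_ind
                converged = True

        return PairCopulaResult(self.family, theta, llf, converged,
                                int(self._informative.sum()), T, R)


def _empirical_pmf(counts, n_max):
    T, R = counts.shape
    pmf = np.zeros((T, n_max + 1))
    for k in range(n_max + 1):
        pmf[:, k] = (counts == k).sum(axis=1) / R
    return pmf


def fit_copula_parameter(family: str, counts_i, counts_j,
                         marginals=None) -> PairCopulaResult:
    """Functional wrapper: maximum-likelihood theta for one pair."""
    return PairCopulaModel(counts_i, counts_j, family, marginals).fit()


def sample_pair(model: CopulaModel, cdf_x, cdf_y, n_samples: int, seed):
    """Sample integer count pairs from the discrete copula law.

    Copula samples ``(u1, u2)`` are mapped through the generalized inverse
    c.d.f.s ``F^{-1}(u) = min{k : F(k) >= u}``.
    """
    cdf_x = np.asarray(cdf_x, dtype=float)
    cdf_y = np.asarray(cdf_y, dtype=float)
    rng = np.random.default_rng(seed)
    theta = 0.0 if model.theta is None else model.theta
    u1, u2 = model._family.sample(theta, n_samples, rng)
    x = np.searchsorted(cdf_x, u1, side="left")
    y = np.searchsorted(cdf_y, u2, side="left")
    return np.clip(x, 0, cdf_x.size - 1), np.clip(y, 0, cdf_y.size - 1)


def kl_empirical_vs_model(counts_i, counts_j, model: CopulaModel,
                          marginals) -> float:
    """Mean per-bin KL divergence of the empirical joint from the model.

    Plug-in estimator restricted to the empirical support, averaged over
    time-bins; bins whose empirical joint is degenerate (a single observed
    pair matching degenerate marginals) contribute 0.
    """
    counts_i = np.asarray(counts_i)
    counts_j = np.asarray(counts_j)
    pmf_i, pmf_j = (np.asarray(m, dtype=float) for m in marginals)
    T, R = counts_i.shape
    m = pmf_i.shape[1] - 1
    Fx = np.cumsum(pmf_i, axis=1)
    Fy = np.cumsum(pmf_j, axis=1)
    theta = 0.0 if model.theta is None else model.theta
    Q = _rectangle_masses(model._family, theta, Fx, Fy)
    kl = 0.0
    for t in range(T):
        emp = np.zeros((m + 1, m + 1))
        np.add.at(emp, (counts_i[t], counts_j[t]), 1.0 / R)
        mask = emp > 0
        q = np.clip(Q[t][mask], 1e-300, None)
        kl += float((emp[mask] * np.log(emp[mask] / q)).sum())
    return kl / T


def select_family(tensor: SpikeCountTensor, pairs=None,
                  families=("independent", "gaussian", "gumbel", "frank",
                            "clayton")) -> pd.DataFrame:
    """Rank copula families by mean KL divergence over cell pairs.

    Each family is fitted per pair by maximum likelihood; the table reports
    the mean KL divergence (empirical vs model joint, per-bin average) and
    the mean log-likelihood across pairs, sorted by KL (winner first).
    Per-pair failures propagate as missing values.
    """
    N = tensor.n_cells
    if pairs is None:
        pairs = [(i, j) for i in range(N) for j in range(i + 1, N)]
    if not pairs:
        raise ValueError("at least one pair required")
    marg = empirical_marginals(tensor)
    rows = []
    for fam_name in families:
        kls, lls = [], []
        for i, j in sorted(pairs):
            ci, cj = tensor.counts[i], tensor.counts[j]
            pm = (marg.pmf[i], marg.pmf[j])
            try:
                fit = fit_copula_parameter(fam_name, ci, cj, pm)
                kls.append(kl_empirical_vs_model(ci, cj, fit.model, pm))
                lls.append(fit.llf)
            except ValueError:
                kls.append(np.nan)
                lls.append(np.nan)
        rows.append({
            "family": fam_name,
            "mean_kl": float(np.nanmean(kls)) if kls else np.nan,
            "mean_llf": float(np.nanmean(lls)) if lls else np.nan,
            "n_pairs": len(pairs),
        })
    table = pd.DataFrame(rows).sort_values("mean_kl").reset_index(drop=True)
    return table
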