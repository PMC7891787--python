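"""Large-population synthesis and synchrony scaling on a synthetic mosaic.

Receptive fields of same-type retinal ganglion cells tile the retina as a
near-regular mosaic; :func:`generate_lattice` reproduces its inter-cell
distance statistics with a jittered triangular lattice (side 194 um,
Gaussian jitter sd 22 um).  Each lattice site receives the recorded
marginal response of a (randomly chosen) real or synthetic cell, and all
pairwise noise covariances are predicted from the copula distance law --
so a population far larger than any simultaneous recording can be
assembled from sequential data alone.

Population synchrony is the time-averaged across-trial variance of the
population rate ``K(t) = sum_i n_i(t)`` divided by the population size,
which equals the mean sum of all pairwise noise covariances (diagonal
included).  Scanning synchrony over circular patches of growing radius
shows it saturating once patches exceed the correlation length of the
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import ThetaDistanceLaw, predict_pairs_batch
from .tensor import CellGeometry, MarginalSet, SpikeCountTensor

__all__ = [
    "generate_lattice",
    "assemble_population",
    "PopulationCovariance",
    "circular_subsample",
    "synchrony",
    "SynchronyCurve",
    "synchrony_scan",
]


def generate_lattice(n_cells: int, side: float = 194.0,
                     jitter_sd: float = 22.0, seed=0) -> CellGeometry:
    """Jittered triangular lattice of receptive-field centres (um).

    Rows are spaced ``side * sqrt(3)/2`` apart with alternate rows offset by
    ``side / 2``; the lattice is filled row-wise to ``n_cells`` and
    independent Gaussian jitter of sd ``jitter_sd`` is added to each
    coordinate.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    n_cols = int(np.ceil(np.sqrt(n_cells)))
    n_rows = int(np.ceil(n_cells / n_cols))
    xs, ys = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            xs.append(c * side + (side / 2.0 if r % 2 else 0.0))
            ys.append(r * side * np.sqrt(3.0) / 2.0)
    pos = np.column_stack([xs, ys])[:n_cells]
    pos = pos + rng.normal(0.0, jitter_sd, size=pos.shape) if jitter_sd > 0 else pos
    return CellGeometry([f"site{i}" for i in range(n_cells)], pos)


@dataclass
class PopulationCovariance:
    """A synthetic population: geometry, per-site marginals, noise covariances.

    ``cov[i, j]`` holds the copula-predicted noise covariance for ``i != j``
    (exactly 0 beyond the distance cutoff) and the per-site noise variance
    on the diagonal, i.e. exactly the matrix whose subset sums give the
    population synchrony.
    """

    geometry: CellGeometry
    cov: np.ndarray
    assignment: np.ndarray = field(default=None)
    marginals: MarginalSet = field(default=None, repr=False)

    def independent(self) -> "PopulationCovariance":
        """Conditionally-independent control: off-diagonals zeroed."""
        return PopulationCovariance(self.geometry, np.diag(np.diag(self.cov)),
                                    self.assignment, self.marginals)


def assemble_population(geometry: CellGeometry, marginal_library: MarginalSet,
                        law: ThetaDistanceLaw, seed=0,
                        length_scale_factor: float = 1.0,
                        family: str = "gumbel") -> PopulationCovariance:
    """Assign library marginals to lattice sites and predict all covariances.

    Each site receives the per-bin marginals of a cell drawn uniformly with
    replacement from ``marginal_library``; pairwise noise covariances are
    computed through the copula distance law for every pair within the
    cutoff and are exactly zero beyond it.
    """
    if marginal_library.n_cells < 1:
        raise ValueError("marginal library must contain at least one cell")
    rng = np.random.default_rng(seed)
    N = geometry.n_cells
    assignment = rng.integers(0, marginal_library.n_cells, size=N)
    D = geometry.distance_matrix()
    thetas = np.asarray(law.theta(D, length_scale_factor))

    noise_var = marginal_library.noise_variances()
    cov = np.diag(noise_var[assignment].astype(float))

    iu, ju = np.triu_indices(N, k=1)
    active = thetas[iu, ju] > 1.0
    # group pairs by their (library_i, library_j) marginal sources
    keys = np.stack([
        np.minimum(assignment[iu], assignment[ju]),
        np.maximum(assignment[iu], assignment[ju]),
    ], axis=1)
    vals = np.zeros(iu.size)
    for key in np.unique(keys[active], axis=0):
        sel = active & (keys[:, 0] == key[0]) & (keys[:, 1] == key[1])
        vals[sel] = predict_pairs_batch(
            marginal_library.pmf[key[0]], marginal_library.pmf[key[1]],
            thetas[iu[sel], ju[sel]], family=family,
        )
    cov[iu, ju] = vals
    cov[ju, iu] = vals
    return PopulationCovariance(geometry, cov, assignment, marginal_library)


def circular_subsample(geometry: CellGeometry, center, radius: float):
    """Indices of all cells within ``radius`` (inclusive) of ``center``."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    center = np.asarray(center, dtype=float)
    d = np.linalg.norm(geometry.positions - center, axis=1)
    return np.flatnonzero(d <= radius)


def synchrony(source, subset=None) -> float:
    """Population synchrony: time-averaged Var(K(t)) per cell.

    ``source`` is either a :class:`SpikeCountTensor` (variance of the
    population rate across repetitions, averaged over bins, divided by N)
    or a pairwise noise-covariance matrix (sum of all entries over the
    subset, divided by the subset size).  The two routes agree exactly on
    matching data because Var(sum) = sum of covariances.
    """
    if isinstance(source, SpikeCountTensor):
        if subset is not None and np.asarray(subset).size == 0:
            raise ValueError("empty cell subset")
        counts = source.counts if subset is None \
            else source.counts[np.asarray(subset, dtype=np.intp)]
        K = counts.sum(axis=0).astype(float)         # (T, R)
        var_t = K.var(axis=1)                        # 1/R normalisation
        return float(var_t.mean() / counts.shape[0])
    cov = np.asarray(source, dtype=float)
    idx = np.arange(cov.shape[0]) if subset is None \
        else np.asarray(subset, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("empty cell subset")
    sub = cov[np.ix_(idx, idx)]
    return float(sub.sum() / idx.size)


@dataclass
class SynchronyCurve:
    """Synchrony versus patch size, averaged over patch centres."""

    radii: np.ndarray                 # (n_radii,) um
    mean_synchrony: np.ndarray        # (n_radii,)
    mean_n_cells: np.ndarray          # (n_radii,)
    synchrony_per_center: np.ndarray = field(repr=False)  # (n_centers, n_radii)
    n_cells_per_center: np.ndarray = field(repr=False)
    centers: np.ndarray = field(repr=False)

    def saturation(self, fraction: float = 0.95):
        """Smallest radius reaching ``fraction`` of the large-radius asymptote.

        The asymptote is the mean synchrony at the largest scanned radius.
        Returns ``(radius_um, n_cells)`` at the saturation point.
        """
        target = fraction * self.mean_synchrony[-1]
        reached = np.flatnonzero(self.mean_synchrony >= target)
        idx = int(reached[0]) if reached.size else len(self.radii) - 1
        return float(self.radii[idx]), float(self.mean_n_cells[idx])

    def plot(self, ax=None, against: str = "radius", **kwargs):
        """Plot synchrony against patch radius (mm) or cell count."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.radii / 1000.0 if against == "radius" else self.mean_n_cells
        ax.plot(x, self.mean_synchrony, marker="o", **kwargs)
        ax.set_xlabel("patch radius (mm)" if against == "radius"
                      else "number of neurons")
        ax.set_ylabel("synchrony (counts$^2$ / cell / bin)")
        return ax


def synchrony_scan(population: PopulationCovariance, radii, n_centers: int = 20,
                   seed=0) -> SynchronyCurve:
    """Synchrony over circular patches of increasing radius.

    Patch centres are drawn uniformly over the mosaic's inner region (the
    bounding box shrunk by the largest radius, to limit edge truncation;
    if that region is empty the bounding-box centre is used).  For each
    centre the same nested patches are evaluated at every radius via the
    covariance-matrix route.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) < 0):
        raise ValueError("radii must be sorted ascending")
    rng = np.random.default_rng(seed)
    pos = population.geometry.positions
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    margin = radii.max()
    in_lo, in_hi = lo + margin, hi - margin
    mid = 0.5 * (lo + hi)
    in_lo = np.where(in_lo <= in_hi, in_lo, mid)
    in_hi = np.where(in_lo <= in_hi, in_hi, mid)
    centers = in_lo + rng.random((n_centers, 2)) * (in_hi - in_lo)

    sync = np.full((n_centers, radii.size), np.nan)
    ncells = np.zeros((n_centers, radii.size))
    for ci, center in enumerate(centers):
        for ri, r in enumerate(radii):
            idx = circular_subsample(population.geometry, center, r)
            ncells[ci, ri] = idx.size
            if idx.size:
                sync[ci, ri] = synchrony(population.cov, idx)
    # a radius can leave every patch empty (NaN synchrony); keep it NaN
    valid = ~np.isnan(sync)
    n_valid = valid.sum(axis=0)
    mean_sync = np.where(
        n_valid > 0,
        np.where(valid, sync, 0.0).sum(axis=0) / np.maximum(n_valid, 1),
        np.nan,
    )
    return SynchronyCurve(radii, mean_sync, ncells.mean(axis=0),
                          sync, ncells, centers)
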