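"""Spike-count tensors, cell geometry, empirical marginals, and file I/O.

The central container is :class:`SpikeCountTensor`: integer spike counts
``n_i(t, r)`` indexed by cell x time-bin x repetition, obtained by binning
repeated-trial spike trains at a fixed bin width (default 1000/60 ms, i.e. a
60 Hz bin rate).  :class:`MarginalSet` holds the per-cell, per-bin empirical
distribution of counts across repetitions -- the single-cell statistics that
sequential recordings give access to.  :func:`shuffle_repetitions` implements
the trial-shuffling control that destroys noise correlations while preserving
every single-cell marginal (the conditionally-independent surrogate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BIN_MS",
    "SpikeCountTensor",
    "CellGeometry",
    "MarginalSet",
    "bin_spike_trains",
    "empirical_marginals",
    "shuffle_repetitions",
    "read_spikes",
    "write_spikes",
    "read_positions",
    "write_positions",
    "read_tensor",
    "write_tensor",
]

#: Default bin width in milliseconds (60 Hz bin rate).
DEFAULT_BIN_MS = 1000.0 / 60.0


@dataclass
class SpikeCountTensor:
    """Integer spike counts indexed by cell x time-bin x repetition.

    Parameters
    ----------
    counts : ndarray of int, shape (n_cells, n_bins, n_reps)
        ``counts[i, t, r]`` is the number of spikes of cell ``i`` in time-bin
        ``t`` during repetition ``r``.
    bin_width : float
        Bin width in milliseconds.
    cell_ids : list of str
        One identifier per cell, in row order.
    """

    counts: np.ndarray
    bin_width: float
    cell_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3-d array (cell x bin x rep)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if min(self.counts.shape) < 1:
            raise ValueError("all tensor dimensions must be >= 1")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(self.counts.shape[0])]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.cell_ids) != self.counts.shape[0]:
            raise ValueError("cell_ids length must match the cell dimension")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def n_reps(self) -> int:
        return self.counts.shape[2]

    @property
    def n_max(self) -> int:
        """Largest observed count anywhere in the tensor."""
        return int(self.counts.max())

    def rates(self) -> np.ndarray:
        """Per-cell, per-bin mean count across repetitions (the PSTH)."""
        return self.counts.mean(axis=2)

    def select_cells(self, indices) -> "SpikeCountTensor":
        indices = np.asarray(indices)
        return SpikeCountTensor(
            self.counts[indices],
            self.bin_width,
            [self.cell_ids[i] for i in indices],
        )


@dataclass
class CellGeometry:
    """(x, y) positions of receptive-field centres, in micrometres."""

    cell_ids: list
    positions: np.ndarray  # (n_cells, 2), um

    def __post_init__(self):
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n_cells, 2) array")
        if len(self.cell_ids) != self.positions.shape[0]:
            raise ValueError("one position per cell id required")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def distance_matrix(self) -> np.ndarray:
        """Symmetric matrix of pairwise Euclidean distances (um)."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.positions[i] - self.positions[j]))

    def align_to(self, cell_ids) -> "CellGeometry":
        """Reorder to match ``cell_ids``; error names any missing cell."""
        index = {c: k for k, c in enumerate(self.cell_ids)}
        missing = [str(c) for c in cell_ids if str(c) not in index]
        if missing:
            raise KeyError(f"positions missing for cells: {', '.join(missing)}")
        order = [index[str(c)] for c in cell_ids]
        return CellGeometry([str(c) for c in cell_ids], self.positions[order])


@dataclass
class MarginalSet:
    """Per-cell, per-bin empirical count distributions.

    ``pmf[i, t, k]`` is the probability that cell ``i`` emits ``k`` spikes in
    bin ``t`` (estimated across repetitions, or supplied by a model).  The
    support is the common grid ``0..n_max``.
    """

    pmf: np.ndarray  # (n_cells, n_bins, n_max + 1)

    def __post_init__(self):
        self.pmf = np.asarray(self.pmf, dtype=float)
        if self.pmf.ndim != 3:
            raise ValueError("pmf must be (n_cells, n_bins, n_max + 1)")
        if np.any(self.pmf < -1e-12):
            raise ValueError("pmf entries must be non-negative")
        sums = self.pmf.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each pmf must sum to 1")

    @property
    def n_cells(self) -> int:
        return self.pmf.shape[0]

    @property
    def n_bins(self) -> int:
        return self.pmf.shape[1]

    @property
    def n_max(self) -> int:
        return self.pmf.shape[2] - 1

    @property
    def cdf(self) -> np.ndarray:
        """Cumulative distributions F_i^(t)(k), same shape as ``pmf``."""
        return np.cumsum(self.pmf, axis=2)

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.n_max + 1)

    def means(self) -> np.ndarray:
        """Per-cell, per-bin mean count mu_i(t)."""
        return self.pmf @ self.support

    def second_moments(self) -> np.ndarray:
        """Per-cell, per-bin second moment E[n_i(t)^2]."""
        return self.pmf @ self.support.astype(float) ** 2

    def bin_variances(self) -> np.ndarray:
        """Per-cell, per-bin across-repetition variance."""
        return self.second_moments() - self.means() ** 2

    def noise_variances(self) -> np.ndarray:
        """Per-cell time-averaged noise variance (diagonal of Eq-15 sum)."""
        return self.bin_variances().mean(axis=1)

    def total_variances(self) -> np.ndarray:
        """Per-cell total count variance V_i (noise + stimulus parts)."""
        mu = self.means()
        mu_bar = mu.mean(axis=1, keepdims=True)
        return self.noise_variances() + ((mu - mu_bar) ** 2).mean(axis=1)

    def select_cells(self, indices) -> "MarginalSet":
        return MarginalSet(self.pmf[np.asarray(indices, dtype=np.intp)])


def bin_spike_trains(spikes, bin_width: float, duration: float,
                     cell_ids=None, n_reps: int | None = None) -> SpikeCountTensor:
    """Bin repeated-trial spike trains into a :class:`SpikeCountTensor`.

    Parameters
    ----------
    spikes : DataFrame or iterable of (cell_id, repetition, time_s)
        Spike events.  Times are in seconds; repetitions are integers
        numbered contiguously from 0.
    bin_width : float
        Bin width in milliseconds.  Bins are half-open ``[t*D, (t+1)*D)``,
        0-based; a trailing partial bin is discarded.
    duration : float
        Trial duration in seconds.  All spike times must lie in
        ``[0, duration)``.
    cell_ids : sequence, optional
        Full roster of cells (so silent cells still get a row).  Defaults to
        the sorted set of ids present in ``spikes``.
    n_reps : int, optional
        Total number of repetitions; defaults to ``max(repetition) + 1``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isinstance(spikes, pd.DataFrame):
        df = spikes.rename(columns=str)
        cells = df["cell_id"].to_numpy()
        reps = df["repetition"].to_numpy()
        times = df["time_s"].to_numpy(dtype=float)
    else:
        rows = list(spikes)
        if rows:
            cells = np.array([r[0] for r in rows])
            reps = np.array([int(r[1]) for r in rows])
            times = np.array([float(r[2]) for r in rows])
        else:
            cells = np.array([], dtype=object)
            reps = np.array([], dtype=int)
            times = np.array([], dtype=float)

    if times.size and (times.min() < 0 or times.max() >= duration):
        bad = np.flatnonzero((times < 0) | (times >= duration))[:5]
        raise ValueError(f"spike times outside [0, duration) at rows {bad.tolist()}")
    if reps.size and reps.min() < 0:
        raise ValueError("repetition indices must be non-negative")

    if cell_ids is None:
        cell_ids = sorted({str(c) for c in cells})
        if not cell_ids:
            raise ValueError("no spikes and no cell_ids roster given")
    cell_ids = [str(c) for c in cell_ids]
    cell_index = {c: k for k, c in enumerate(cell_ids)}
    unknown = sorted({str(c) for c in cells} - set(cell_ids))
    if unknown:
        raise KeyError(f"spikes reference unknown cells: {', '.join(unknown)}")

    n_bins = int(np.floor(duration * 1000.0 / bin_width))
    if n_bins < 1:
        raise ValueError("duration shorter than one bin")
    R = int(reps.max()) + 1 if reps.size else 1
    if n_reps is not None:
        if reps.size and reps.max() >= n_reps:
            raise ValueError("repetition index exceeds declared n_reps")
        R = int(n_reps)

    counts = np.zeros((len(cell_ids), n_bins, R), dtype=np.int64)
    if times.size:
        bins = np.floor(times * 1000.0 / bin_width).astype(int)
        keep = bins < n_bins  # trailing partial bin dropped
        ci = np.array([cell_index[str(c)] for c in cells])
        np.add.at(counts, (ci[keep], bins[keep], reps[keep]), 1)
    return SpikeCountTensor(counts, bin_width, cell_ids)


def empirical_marginals(tensor: SpikeCountTensor,
                        n_max: int | None = None) -> MarginalSet:
    """Empirical count histograms across repetitions, per cell and bin."""
    if n_max is None:
        n_max = tensor.n_max
    if n_max < tensor.n_max:
        raise ValueError("n_max smaller than the largest observed count")
    N, T, R = tensor.counts.shape
    pmf = np.zeros((N, T, n_max + 1))
    for k in range(n_max + 1):
        pmf[:, :, k] = (tensor.counts == k).sum(axis=2) / R
    return MarginalSet(pmf)


def shuffle_repetitions(tensor: SpikeCountTensor, seed) -> SpikeCountTensor:
    """Permute repetitions independently per cell (trial-shuffling control).

    Whole repetition traces are kept intact, so within-cell temporal
    structure and every per-bin marginal are preserved while cross-cell
    noise correlations are destroyed in expectation -- the surrogate for a
    conditionally-independent population.
    """
    if tensor.n_reps < 2:
        raise ValueError("shuffling requires at least 2 repetitions")
    rng = np.random.default_rng(seed)
    out = np.empty_like(tensor.counts)
    for i in range(tensor.n_cells):
        out[i] = tensor.counts[i][:, rng.permutation(tensor.n_reps)]
    return SpikeCountTensor(out, tensor.bin_width, list(tensor.cell_ids))


# ---------------------------------------------------------------------------
# File I/O: delimited text for spikes and positions, HDF5 for tensors.
# ---------------------------------------------------------------------------

def read_spikes(path) -> pd.DataFrame:
    """Read a spikes table (TSV/CSV with columns cell_id, repetition, time_s)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"cell_id", "repetition", "time_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spikes file missing columns: {sorted(missing)}")
    if df["time_s"].isna().any() or df["repetition"].isna().any():
        bad = df.index[df[["repetition", "time_s"]].isna().any(axis=1)][:5]
        raise ValueError(f"malformed spike rows at {bad.tolist()}")
    df["repetition"] = df["repetition"].astype(int)
    df["cell_id"] = df["cell_id"].astype(str)
    return df


def write_spikes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_positions(path) -> CellGeometry:
    """Read a positions table (columns cell_id, x_um, y_um)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"cell_id", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"positions file missing columns: {sorted(missing)}")
    ids = df["cell_id"].astype(str).tolist()
    dup = {c for c in ids if ids.count(c) > 1}
    if dup:
        raise ValueError(f"duplicate cell ids in positions file: {sorted(dup)}")
    return CellGeometry(ids, df[["x_um", "y_um"]].to_numpy(dtype=float))


def write_positions(geometry: CellGeometry, path) -> None:
    pd.DataFrame({
        "cell_id": geometry.cell_ids,
        "x_um": geometry.positions[:, 0],
        "y_um": geometry.positions[:, 1],
    }).to_csv(path, sep="\t", index=False)


def write_tensor(tensor: SpikeCountTensor, path) -> None:
    """Write a tensor to an HDF5 container (datasets counts, bin_width_ms, cell_ids)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=tensor.counts, compression="gzip")
        f.create_dataset("bin_width_ms", data=float(tensor.bin_width))
        f.create_dataset(
            "cell_ids", data=np.array(tensor.cell_ids, dtype=h5py.string_dtype())
        )


def read_tensor(path) -> SpikeCountTensor:
    with h5py.File(path, "r") as f:
        for name in ("counts", "bin_width_ms", "cell_ids"):
            if name not in f:
                raise ValueError(f"tensor file missing dataset '{name}'")
        counts = f["counts"][...]
        bin_width = float(f["bin_width_ms"][()])
        cell_ids = [c.decode() if isinstance(c, bytes) else str(c)
                    for c in f["cell_ids"][...]]
    return SpikeCountTensor(counts, bin_width, cell_ids)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2)


def read_json(path) -> dict:
    with open(path) as f:
        return json.load(f)
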