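"""Free-energy surface reconstruction and block-analysis uncertainties.

Two estimators are provided.  From a HILLS record, the well-tempered
relation F(s) = -(γ/(γ-1)) V(s, t_end) converts the accumulated bias into a
free energy (γ = inf gives the standard -V).  From a COLVAR record carrying
per-frame bias values, last-bias reweighting assigns each frame the weight
exp(+V/k_B T) after discarding an equilibration fraction and histograms the
target CVs; F = -k_B T ln ρ on the grid, min-shifted to zero, with rarely
visited bins masked rather than extrapolated.  Uncertainties come from block
analysis: the frame sequence is cut into contiguous blocks, a per-block FES
is computed, and the per-bin standard error of the block means is reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import kt


@dataclass
class FESAxis:
    """One CV axis of a free-energy grid."""

    name: str
    edges: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if len(self.edges) < 2 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("axis edges must be strictly increasing, >= 2 values")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


@dataclass
class FESGrid:
    """1D/2D free-energy grid with per-bin uncertainty.

    ``F`` is min-shifted so the lowest unmasked bin is 0; ``mask`` flags bins
    never (or too rarely) visited; ``error`` holds per-bin standard errors
    where available; ``counts`` the raw visit counts where applicable.
    """

    axes: list[FESAxis]
    F: np.ndarray
    error: np.ndarray | None = None
    mask: np.ndarray | None = None
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        expected = tuple(ax.n_bins for ax in self.axes)
        if self.F.shape != expected:
            raise ValueError(f"F shape {self.F.shape} != grid shape {expected}")
        if self.mask is None:
            self.mask = ~np.isfinite(self.F)
        if self.error is not None and np.any(
            np.asarray(self.error)[~self.mask] < 0
        ):
            raise ValueError("errors must be non-negative")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def min_shift(self) -> None:
        """Shift F so the lowest unmasked bin is exactly 0."""
        valid = ~self.mask & np.isfinite(self.F)
        if not np.any(valid):
            raise ValueError("all bins are masked")
        self.F = self.F - self.F[valid].min()
        self.F[~valid] = np.nan


def uniform_axis(name: str, lo: float, hi: float, n_bins: int, units: str = "") -> FESAxis:
    return FESAxis(name, np.linspace(lo, hi, n_bins + 1), units)


def discrete_axis(name: str, values: np.ndarray, units: str = "") -> FESAxis:
    """Bin edges at midpoints so each discrete CV value owns one bin."""
    v = np.asarray(values, dtype=float)
    mids = 0.5 * (v[:-1] + v[1:])
    step_lo = v[1] - v[0]
    step_hi = v[-1] - v[-2]
    edges = np.concatenate([[v[0] - step_lo / 2], mids, [v[-1] + step_hi / 2]])
    return FESAxis(name, edges, units)


def _bias_on_grid(
    hills: pd.DataFrame, axes: list[FESAxis]
) -> np.ndarray:
    names = [ax.name for ax in axes]
    for n in names:
        if n not in hills.columns or f"sigma_{n}" not in hills.columns:
            raise ValueError(f"hills record lacks CV column {n!r}")
    grids = np.meshgrid(*[ax.centers for ax in axes], indexing="ij")
    v = np.zeros(grids[0].shape)
    centers = hills[names].to_numpy()
    sigmas = hills[[f"sigma_{n}" for n in names]].to_numpy()
    heights = hills["height"].to_numpy()
    for c, s, h in zip(centers, sigmas, heights):
        z2 = sum(((g - ci) / si) ** 2 for g, ci, si in zip(grids, c, s))
        v += h * np.exp(-0.5 * z2)
    return v


def fes_from_hills(
    hills: pd.DataFrame,
    axes: list[FESAxis],
    gamma: float | None = None,
    temperature: float = 310.0,
) -> FESGrid:
    """Free energy from the accumulated hills: F = -(γ/(γ-1)) V(s, end).

    For γ = inf (standard metadynamics) F = -V.  ``gamma`` defaults to the
    ``biasf`` column of the record.  The result is min-shifted to 0.
    """
    if len(hills) == 0:
        raise ValueError("hills record is empty")
    if gamma is None:
        gamma = float(hills["biasf"].iloc[0])
    if not gamma > 1:
        raise ValueError("bias factor gamma must be > 1 (or inf)")
    factor = 1.0 if math.isinf(gamma) else gamma / (gamma - 1.0)
    v = _bias_on_grid(hills, axes)
    grid = FESGrid(axes=axes, F=-factor * v, mask=np.zeros(v.shape, dtype=bool))
    grid.min_shift()
    return grid


def _frame_weights(colvar: pd.DataFrame, temperature: float) -> np.ndarray:
    if "bias" not in colvar.columns:
        raise ValueError("colvar record lacks a 'bias' column")
    v = colvar["bias"].to_numpy(dtype=float)
    return np.exp((v - v.max()) / kt(temperature))


def _histogram(
    colvar: pd.DataFrame,
    axes: list[FESAxis],
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    sample = []
    for ax in axes:
        if ax.name not in colvar.columns:
            raise ValueError(f"requested axis {ax.name!r} absent from colvar")
        sample.append(colvar[ax.name].to_numpy(dtype=float))
    sample = np.stack(sample, axis=1)
    edges = [ax.edges for ax in axes]
    hist, _ = np.histogramdd(sample, bins=edges, weights=weights)
    counts, _ = np.histogramdd(sample, bins=edges)
    return hist, counts


def fes_reweight(
    colvar: pd.DataFrame,
    axes: list[FESAxis],
    temperature: float = 310.0,
    equilibration_fraction: float = 0.2,
    min_count: int = 5,
) -> FESGrid:
    """Last-bias reweighted free energy over the target CV axes.

    Frames after the equilibration discard get weights proportional to
    exp(+V_bias/k_B T); the weighted histogram ρ gives F = -k_B T ln ρ,
    min-shifted; bins visited fewer than ``min_count`` times are masked.
    """
    if not 0.0 <= equilibration_fraction < 1.0:
        raise ValueError("equilibration_fraction must be in [0, 1)")
    start = int(len(colvar) * equilibration_fraction)
    sub = colvar.iloc[start:]
    if len(sub) == 0:
        raise ValueError("no frames left after equilibration discard")
    w = _frame_weights(sub, temperature)
    hist, counts = _histogram(sub, axes, w)
    mask = counts < min_count
    with np.errstate(divide="ignore"):
        f = -kt(temperature) * np.log(hist, where=hist > 0,
                                      out=np.full(hist.shape, np.inf))
    f[mask] = np.nan
    grid = FESGrid(axes=axes, F=f, mask=mask | ~np.isfinite(f), counts=counts)
    grid.min_shift()
    return grid


@dataclass
class BlockErrorConfig:
    """Block-analysis settings: contiguous blocks of ``block_size`` samples."""

    block_size: int = 100

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")


def block_error_series(
    values: np.ndarray,
    config: BlockErrorConfig | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Standard error of the (weighted) mean of a series by block analysis.

    The series is cut into contiguous full blocks; the SE is the standard
    deviation of block means over sqrt(number of blocks).  For i.i.d. data
    this approaches σ/sqrt(n); for correlated data blocks longer than the
    correlation time recover the inflated, autocorrelation-corrected SE.
    """
    if config is None:
        config = BlockErrorConfig()
    x = np.asarray(values, dtype=float)
    b = config.block_size
    n_blocks = len(x) // b
    if n_blocks < 2:
        raise ValueError("need at least 2 full blocks")
    x = x[: n_blocks * b].reshape(n_blocks, b)
    if weights is None:
        means = x.mean(axis=1)
    else:
        w = np.asarray(weights, dtype=float)[: n_blocks * b].reshape(n_blocks, b)
        means = (x * w).sum(axis=1) / w.sum(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_blocks))


def block_error(
    colvar: pd.DataFrame,
    axes: list[FESAxis],
    temperature: float = 310.0,
    config: BlockErrorConfig | None = None,
    equilibration_fraction: float = 0.0,
) -> np.ndarray:
    """Per-bin standard error of the reweighted FES by block analysis.

    Contiguous blocks of ``block_size`` frames each yield a block FES
    (normalized weighted histogram → -k_B T ln ρ); the per-bin standard
    error of the block means is returned, NaN where fewer than two blocks
    visited the bin.  Identical blocks give zero error everywhere visited.
    """
    if config is None:
        config = BlockErrorConfig()
    start = int(len(colvar) * equilibration_fraction)
    sub = colvar.iloc[start:]
    b = config.block_size
    n_blocks = len(sub) // b
    if n_blocks < 2:
        raise ValueError("need at least 2 full blocks")
    kbt = kt(temperature)
    block_f = []
    for i in range(n_blocks):
        blk = sub.iloc[i * b : (i + 1) * b]
        w = _frame_weights(blk, temperature)
        hist, counts = _histogram(blk, axes, w)
        rho = hist / hist.sum()
        with np.errstate(divide="ignore"):
            f = np.where(counts > 0, -kbt * np.log(np.where(rho > 0, rho, 1.0)),
                         np.nan)
        block_f.append(f)
    stack = np.stack(block_f)
    visited = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # dof<=0 on rare bins
        se = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(visited)
    se[visited < 2] = np.nan
    return se


@dataclass
class Basin:
    """A local free-energy minimum of a 1D/2D surface."""

    indices: tuple[int, ...]
    cv_values: tuple[float, ...]
    F: float
    delta_F: float  # relative to the global minimum
    barrier: float | None  # max F on the 1D grid path to the global minimum
    activation: float | None  # barrier - F (1D only)


def _prominence_1d(f: np.ndarray, valid: np.ndarray, i: int) -> float:
    """Depth of minimum ``i`` below the lowest saddle separating it from any
    strictly deeper bin (classic topographic prominence; inf-free)."""
    barriers = []
    for step in (-1, 1):
        running_max = f[i]
        j = i + step
        found = None
        while 0 <= j < len(f):
            if valid[j]:
                running_max = max(running_max, f[j])
                if f[j] < f[i]:
                    found = running_max
                    break
            j += step
        barriers.append(running_max if found is None else found)
    return min(barriers) - f[i]


def locate_minima(fes: FESGrid, min_depth: float = 0.0) -> list[Basin]:
    """Labelled basins of a free-energy grid, sorted by F.

    1D: local minima of the unmasked profile (plateaus collapse to their
    lowest-CV bin; equal minima tie-break deterministically the same way);
    each basin reports ΔF to the global minimum and the lowest connecting
    barrier (max F on the grid path towards the global minimum).  Basins
    whose topographic prominence — depth below the lowest saddle separating
    them from deeper territory — is under ``min_depth`` are dropped, which
    suppresses sampling wiggles.  2D: local minima over the 4-neighbourhood;
    barriers are not computed and ``min_depth`` is ignored.
    """
    f = fes.F
    valid = ~fes.mask & np.isfinite(f)
    if not np.any(valid):
        raise ValueError("all bins are masked")
    centers = [ax.centers for ax in fes.axes]
    minima: list[tuple[int, ...]] = []
    if fes.ndim == 1:
        n = len(f)
        for i in range(n):
            if not valid[i]:
                continue
            left = f[i - 1] if i > 0 and valid[i - 1] else np.inf
            right = f[i + 1] if i < n - 1 and valid[i + 1] else np.inf
            if f[i] < left and f[i] <= right:
                minima.append((i,))
    else:
        ni, nj = f.shape
        for i in range(ni):
            for j in range(nj):
                if not valid[i, j]:
                    continue
                nb = []
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    a, bj = i + di, j + dj
                    if 0 <= a < ni and 0 <= bj < nj and valid[a, bj]:
                        nb.append(f[a, bj])
                # plateaus: strict inequality against the earlier neighbours
                before = (
                    f[i, j - 1] if j > 0 and valid[i, j - 1] else np.inf,
                    f[i - 1, j] if i > 0 and valid[i - 1, j] else np.inf,
                )
                if all(f[i, j] <= x for x in nb) and all(
                    f[i, j] < x or np.isinf(x) for x in before
                ):
                    minima.append((i, j))
    if not minima:  # monotone profile: the lowest valid bin is the one basin
        flat = np.where(valid.ravel())[0]
        best = flat[np.argmin(f.ravel()[flat])]
        minima = [tuple(np.unravel_index(best, f.shape))]
    minima.sort(key=lambda idx: (f[idx], idx))
    global_idx = minima[0]
    basins: list[Basin] = []
    for idx in minima:
        if fes.ndim == 1:
            i0, i1 = sorted((idx[0], global_idx[0]))
            path = f[i0 : i1 + 1]
            barrier = float(np.nanmax(path)) if i0 != i1 else float(f[idx])
            activation = barrier - float(f[idx])
        else:
            barrier = None
            activation = None
        basin = Basin(
            indices=idx,
            cv_values=tuple(float(centers[d][idx[d]]) for d in range(fes.ndim)),
            F=float(f[idx]),
            delta_F=float(f[idx] - f[global_idx]),
            barrier=barrier,
            activation=activation,
        )
        keep = (
            idx == global_idx
            or fes.ndim != 1
            or _prominence_1d(f, valid, idx[0]) >= min_depth
        )
        if keep:
            basins.append(basin)
    return basins


def basins_frame(basins: list[Basin]) -> pd.DataFrame:
    """Basin list as a tidy table."""
    return pd.DataFrame(
        {
            "cv": [b.cv_values if len(b.cv_values) > 1 else b.cv_values[0]
                   for b in basins],
            "F": [b.F for b in basins],
            "delta_F": [b.delta_F for b in basins],
            "barrier": [b.barrier for b in basins],
            "activation": [b.activation for b in basins],
        }
    )
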