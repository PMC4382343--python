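"""Histogram partitions of projected stimuli and the plug-in density machinery.

A :class:`BinPartition` is a product of per-axis partitions of the real line
into half-open cells ``[b_{i-1}, b_i)``, with unbounded outer cells so every
point maps to exactly one bin.  From an assignment of projected stimuli to
bins we form the plug-in (maximum-likelihood) estimates

* ``p̂_i``  — fraction of all stimuli in bin i,
* ``q̂_i``  — fraction of spikes whose stimulus fell in bin i (a stimulus
  eliciting r spikes contributes r times),
* ``q̂_i^(j)`` — fraction of j-spike stimuli in bin i, for each count j,

and from these the piecewise-constant nonlinearities: the density ratio
``ĝ = q̂/p̂``, the rate ``f̂ = (n_sp / NΔ) ĝ`` in spikes/s, and the per-count
probabilities ``f̂^(j) = n_i^(j)/n_i``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BinPartition",
    "HistogramDensities",
    "PiecewiseNonlinearity",
    "build_bins",
    "estimate_densities",
    "ratio_nonlinearity",
    "ml_rate",
    "ml_count_probs",
]


@dataclass(frozen=True)
class BinPartition:
    """Cartesian product of per-axis half-open partitions of the real line.

    ``interior_edges[a]`` holds the finite, strictly increasing interior edges
    of axis ``a``; the outer cells extend to ±∞.  Multi-axis bins are flattened
    row-major, so the total bin count is the product of per-axis counts.
    Values exactly at an interior edge go to the right cell.
    """

    interior_edges: tuple  # tuple of 1-D float arrays, one per axis

    @property
    def n_axes(self) -> int:
        return len(self.interior_edges)

    @property
    def bins_per_axis(self) -> tuple:
        return tuple(len(e) + 1 for e in self.interior_edges)

    @property
    def n_bins(self) -> int:
        return int(np.prod(self.bins_per_axis))

    def assign(self, x: np.ndarray) -> np.ndarray:
        """Map projected points (N, p) or (N,) to flat bin indices (N,)."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.shape[1] != self.n_axes:
            raise ValueError(
                f"projected points have {x.shape[1]} axes, partition has {self.n_axes}"
            )
        idx = np.zeros(x.shape[0], dtype=np.intp)
        for a, edges in enumerate(self.interior_edges):
            # side='right' puts values equal to an edge into the right cell
            axis_idx = np.searchsorted(edges, x[:, a], side="right")
            idx = idx * (len(edges) + 1) + axis_idx
        return idx

    def edges_table(self) -> pd.DataFrame:
        """Per-axis edge table (axis, left, right) for inspection/serialization."""
        rows = []
        for a, edges in enumerate(self.interior_edges):
            full = np.concatenate([[-np.inf], edges, [np.inf]])
            for i in range(len(full) - 1):
                rows.append((a, i, full[i], full[i + 1]))
        return pd.DataFrame(rows, columns=["axis", "bin", "left", "right"])


@dataclass(frozen=True)
class HistogramDensities:
    """Plug-in densities and occupancy tallies over a bin partition."""

    partition: BinPartition
    p_hat: np.ndarray          # (m,) Σ=1
    q_hat: np.ndarray          # (m,) spike-weighted, Σ=1 when n_sp>0
    q_hat_by_count: np.ndarray  # (r_max+1, m), row j sums to 1 when N^(j)>0
    n_i: np.ndarray            # (m,) stimuli per bin
    n_i_by_count: np.ndarray   # (r_max+1, m) stimuli per (count, bin) cell
    counts_by_j: np.ndarray    # (r_max+1,) N^(j)
    n_samples: int
    n_spikes: int

    @property
    def r_max(self) -> int:
        return self.q_hat_by_count.shape[0] - 1

    def to_frame(self, bin_width: float | None = None) -> pd.DataFrame:
        """1-D summary table (bin, left, right, n_i, p̂, q̂ and optionally f̂)."""
        if self.partition.n_axes != 1:
            raise ValueError("summary table is defined for 1-D partitions")
        edges = np.concatenate(
            [[-np.inf], self.partition.interior_edges[0], [np.inf]]
        )
        df = pd.DataFrame(
            {
                "bin": np.arange(self.partition.n_bins),
                "left": edges[:-1],
                "right": edges[1:],
                "n_i": self.n_i,
                "p_hat": self.p_hat,
                "q_hat": self.q_hat,
            }
        )
        if bin_width is not None:
            rate = ml_rate(self, bin_width)
            df["f_hat"] = rate.values
        return df


@dataclass(frozen=True)
class PiecewiseNonlinearity:
    """A per-bin-constant function over a partition.

    ``kind`` is one of ``"ratio"`` (ĝ, dimensionless), ``"rate"`` (f̂ in
    spikes/s) or ``"count-prob"`` (rows of per-count probabilities).
    ``occupied`` flags bins with at least one training stimulus.
    """

    partition: BinPartition
    values: np.ndarray
    kind: str
    occupied: np.ndarray

    def __call__(self, x: np.ndarray) -> np.ndarray:
        idx = self.partition.assign(x)
        if self.values.ndim == 1:
            return self.values[idx]
        return self.values[:, idx]


def build_bins(x, n_bins: int, scheme: str = "equal-occupancy") -> BinPartition:
    """Partition each projected axis into ``n_bins`` cells.

    ``equal-occupancy`` places interior edges at empirical quantiles (the
    default elsewhere in the package: it stabilizes p̂ in the tails, where the
    log density ratio is most noise-sensitive); ``equal-width`` spaces them
    evenly over the data range.  Falls back to equal-width with a warning when
    there are too few distinct values for the required quantiles.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if scheme not in ("equal-occupancy", "equal-width"):
        raise ValueError(f"unknown binning scheme: {scheme!r}")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot build bins from empty data")
    if x.ndim == 1:
        x = x[:, None]
    per_axis = []
    for a in range(x.shape[1]):
        col = x[:, a]
        if n_bins == 1:
            per_axis.append(np.empty(0))
            continue
        if scheme == "equal-occupancy":
            edges = np.quantile(col, np.arange(1, n_bins) / n_bins)
            if len(np.unique(edges)) < n_bins - 1:
                warnings.warn(
                    f"axis {a}: too few distinct values for {n_bins} "
                    "equal-occupancy bins; falling back to equal-width",
                    stacklevel=2,
                )
                edges = np.linspace(col.min(), col.max(), n_bins + 1)[1:-1]
        else:
            edges = np.linspace(col.min(), col.max(), n_bins + 1)[1:-1]
        per_axis.append(np.asarray(edges, dtype=float))
    return BinPartition(tuple(per_axis))


def estimate_densities(x, counts, partition: BinPartition) -> HistogramDensities:
    """Tally plug-in densities of projected stimuli over a partition.

    The spike-triggered estimate q̂ weights each stimulus by its spike count
    (a two-spike stimulus counts twice); the per-count rows q̂^(j) condition on
    the exact count j.  With no spikes, q̂ is returned as all-zero and flagged
    by ``n_spikes == 0``; downstream information estimators apply the
    spikes-absent convention.
    """
    counts = np.asarray(counts)
    idx = partition.assign(x)
    m = partition.n_bins
    N = len(counts)
    n_sp = int(counts.sum())
    r_max = int(counts.max(initial=0))

    n_i = np.bincount(idx, minlength=m).astype(np.int64)
    p_hat = n_i / N

    spike_mass = np.bincount(idx, weights=counts.astype(float), minlength=m)
    q_hat = spike_mass / n_sp if n_sp > 0 else np.zeros(m)

    n_i_by_count = np.zeros((r_max + 1, m), dtype=np.int64)
    # counts are small non-negative integers; one bincount per observed value
    for j in range(r_max + 1):
        sel = counts == j
        if sel.any():
            n_i_by_count[j] = np.bincount(idx[sel], minlength=m)
    counts_by_j = n_i_by_count.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        q_hat_by_count = np.where(
            counts_by_j[:, None] > 0, n_i_by_count / counts_by_j[:, None], 0.0
        )
    return HistogramDensities(
        partition=partition,
        p_hat=p_hat,
        q_hat=q_hat,
        q_hat_by_count=q_hat_by_count,
        n_i=n_i,
        n_i_by_count=n_i_by_count,
        counts_by_j=counts_by_j,
        n_samples=N,
        n_spikes=n_sp,
    )


def ratio_nonlinearity(dens: HistogramDensities) -> PiecewiseNonlinearity:
    """Density-ratio nonlinearity ĝ_i = q̂_i / p̂_i (0 on empty bins)."""
    occupied = dens.n_i > 0
    g = np.zeros_like(dens.p_hat)
    g[occupied] = dens.q_hat[occupied] / dens.p_hat[occupied]
    return PiecewiseNonlinearity(dens.partition, g, "ratio", occupied)


def ml_rate(dens: HistogramDensities, bin_width: float) -> PiecewiseNonlinearity:
    """Maximum-likelihood piecewise-constant rate, f̂_i in spikes/s.

    Equal to spikes-in-bin / (stimuli-in-bin * Δ), i.e. (n_sp/(NΔ)) ĝ; the
    fitted rates reproduce the total spike count: Σ_t f̂(x_t) Δ = n_sp.
    Empty bins get rate 0 and are flagged unoccupied.
    """
    g = ratio_nonlinearity(dens)
    scale = dens.n_spikes / (dens.n_samples * bin_width)
    return PiecewiseNonlinearity(dens.partition, scale * g.values, "rate", g.occupied)


def ml_count_probs(dens: HistogramDensities) -> PiecewiseNonlinearity:
    """Per-count probabilities f̂_i^(j) = n_i^(j) / n_i per occupied bin.

    Rows over j sum to 1 within each occupied bin; unoccupied bins are flagged
    and their columns left at 0.
    """
    occupied = dens.n_i > 0
    vals = np.zeros_like(dens.q_hat_by_count)
    vals[:, occupied] = dens.n_i_by_count[:, occupied] / dens.n_i[occupied]
    return PiecewiseNonlinearity(dens.partition, vals, "count-prob", occupied)
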