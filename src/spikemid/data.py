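"""Core data containers: stimulus/response datasets, filter matrices, repeat rasters.

The universal input is a set of stimulus-response pairs ``(s_t, r_t)`` binned
at width ``Δ``: an ``(N, D)`` real stimulus matrix and a length-``N`` vector of
non-negative integer spike counts.  Filters are the columns of a ``(D, p)``
matrix ``K``; only the column space of ``K`` is identifiable, so recovery is
always scored with principal angles, never elementwise filter error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import subspace_angles

__all__ = [
    "Dataset",
    "RepeatRaster",
    "make_dataset",
    "project",
    "orthonormalize",
    "fix_column_signs",
    "subspace_angle_deg",
    "read_dataset_csv",
    "write_dataset_csv",
    "read_filters_csv",
    "write_filters_csv",
]


@dataclass(frozen=True)
class Dataset:
    """Paired stimuli and binned spike counts.

    Attributes
    ----------
    stimuli : ndarray, shape (N, D)
        One stimulus row per time bin.
    counts : ndarray of int, shape (N,)
        Spikes observed in each bin; non-negative.
    bin_width : float
        Bin width Δ in seconds, strictly positive.
    """

    stimuli: np.ndarray
    counts: np.ndarray
    bin_width: float
    ground_truth: dict | None = field(default=None, compare=False)

    @property
    def n_samples(self) -> int:
        return self.stimuli.shape[0]

    @property
    def n_dim(self) -> int:
        return self.stimuli.shape[1]

    @property
    def n_spikes(self) -> int:
        return int(self.counts.sum())

    @property
    def mean_count(self) -> float:
        """Mean spike count per bin, r̄ = n_sp / N."""
        return self.n_spikes / self.n_samples

    @property
    def is_binary(self) -> bool:
        return self.counts.max(initial=0) <= 1


@dataclass(frozen=True)
class RepeatRaster:
    """Spike counts from a frozen-noise experiment: repeats x time bins."""

    counts: np.ndarray  # (n_rpt, n_t) non-negative integers
    bin_width: float

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts: raster must be 2-D (repeats x time bins)")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts: raster entries must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts: raster entries must be non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin_width: must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def n_repeats(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def n_spikes(self) -> int:
        return int(self.counts.sum())

    @property
    def duration(self) -> float:
        """Stimulus duration T = n_t * Δ in seconds."""
        return self.n_bins * self.bin_width

    def psth(self) -> np.ndarray:
        """Trial-averaged rate λ̂(t) in spikes/s for each time bin."""
        return self.counts.mean(axis=0) / self.bin_width


def make_dataset(stimuli, counts, bin_width, ground_truth=None) -> Dataset:
    """Validate and assemble a :class:`Dataset`.

    Raises ``ValueError`` naming the offending field for dimension mismatches,
    negative or non-integral counts, or a non-positive bin width.
    """
    stimuli = np.atleast_2d(np.asarray(stimuli, dtype=float))
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("counts: expected a 1-D vector of spike counts")
    if stimuli.shape[0] != counts.shape[0]:
        raise ValueError(
            f"stimuli/counts: {stimuli.shape[0]} stimulus rows but "
            f"{counts.shape[0]} counts"
        )
    if stimuli.shape[0] < 1:
        raise ValueError("stimuli: need at least one sample")
    if not np.issubdtype(counts.dtype, np.integer):
        rounded = np.round(counts)
        if not np.allclose(counts, rounded):
            raise ValueError("counts: spike counts must be integers")
        counts = rounded
    counts = counts.astype(np.int64)
    if (counts < 0).any():
        raise ValueError("counts: spike counts must be non-negative")
    bin_width = float(bin_width)
    if not bin_width > 0:
        raise ValueError("bin_width: must be positive")
    return Dataset(stimuli, counts, bin_width, ground_truth)


def project(dataset: Dataset, filters: np.ndarray) -> np.ndarray:
    """Project stimuli onto the filter columns: ``x_t = K^T s_t``.

    Returns an ``(N, p)`` array of projected values.
    """
    K = np.atleast_2d(np.asarray(filters, dtype=float))
    if K.shape[0] != dataset.n_dim:
        raise ValueError(
            f"filters: K has {K.shape[0]} rows but stimuli have "
            f"{dataset.n_dim} dimensions"
        )
    return dataset.stimuli @ K


def fix_column_signs(K: np.ndarray) -> np.ndarray:
    """Flip column signs so each column's largest-magnitude entry is positive."""
    K = np.array(K, dtype=float, copy=True)
    idx = np.argmax(np.abs(K), axis=0)
    signs = np.sign(K[idx, np.arange(K.shape[1])])
    signs[signs == 0] = 1.0
    return K * signs


def orthonormalize(K: np.ndarray) -> np.ndarray:
    """Orthonormalize filter columns (thin QR) and apply the sign convention."""
    K = np.atleast_2d(np.asarray(K, dtype=float))
    if K.shape[1] > K.shape[0]:
        raise ValueError("filters: more columns than stimulus dimensions")
    Q, _ = np.linalg.qr(K)
    return fix_column_signs(Q)


def subspace_angle_deg(K_a: np.ndarray, K_b: np.ndarray) -> float:
    """Largest principal angle between two filter column spaces, in degrees.

    Invariant to column sign flips and to rotations within each subspace; this
    is the canonical recovery-error metric because only the subspace spanned
    by the filters is identifiable.
    """
    K_a = np.atleast_2d(np.asarray(K_a, dtype=float))
    K_b = np.atleast_2d(np.asarray(K_b, dtype=float))
    if K_a.ndim == 2 and K_a.shape[0] == 1:
        K_a = K_a.T
    if K_b.ndim == 2 and K_b.shape[0] == 1:
        K_b = K_b.T
    if K_a.shape != K_b.shape:
        raise ValueError("filter matrices must have identical shapes")
    angles = subspace_angles(K_a, K_b)
    return float(np.degrees(np.max(angles))) if angles.size else 0.0


# ---------------------------------------------------------------------------
# CSV I/O (header-less numeric tables; '.' decimal, LF endings)


def write_dataset_csv(dataset: Dataset, stimuli_path, counts_path) -> None:
    pd.DataFrame(dataset.stimuli).to_csv(
        stimuli_path, header=False, index=False, float_format="%.17g"
    )
    pd.DataFrame(dataset.counts).to_csv(counts_path, header=False, index=False)


def read_dataset_csv(stimuli_path, counts_path, bin_width) -> Dataset:
    stimuli = pd.read_csv(
        stimuli_path, header=None, float_precision="round_trip"
    ).to_numpy(dtype=float)
    counts = pd.read_csv(counts_path, header=None).to_numpy().ravel()
    return make_dataset(stimuli, counts, bin_width)


def write_filters_csv(K: np.ndarray, path) -> None:
    pd.DataFrame(np.atleast_2d(K)).to_csv(
        path, header=False, index=False, float_format="%.17g"
    )


def read_filters_csv(path) -> np.ndarray:
    return pd.read_csv(
        path, header=None, float_precision="round_trip"
    ).to_numpy(dtype=float)
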