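"""Seeded generative models for linear-nonlinear spiking neurons.

Every estimator in the package is exercised against data drawn from one of
these generators, each of which attaches its ground truth (true filters and
nonlinearity) to the returned :class:`~spikemid.data.Dataset` so recovery can
be scored with principal angles.

Families
--------
* ``lnp``  — Poisson counts, rate λ = f(K^T s) in spikes/s;
* ``lnb``  — Bernoulli (binary) responses, spike probability f(K^T s) ∈ [0,1];
* ``lnc``  — categorical counts with per-count probability functions f^(j).

Named toys
----------
* :func:`halfcircle_bernoulli` — stimuli uniform on the right unit half-circle,
  spike probability rising linearly with angle; the canonical example where
  the spikes-only objective is asymptotically biased while the Bernoulli
  objective is not.
* :func:`sigmoid_bernoulli_2d` — 2-D Gaussian stimuli, one true filter,
  logistic nonlinearity; used for bin-count sensitivity studies.
* :func:`excit_suppress_gaussian` — 2-D Gaussian stimuli, spike probability
  rising along s1 and falling along s2.  The exact published form of this
  nonlinearity is not available; this is a synthetic stand-in,
  λ(s) = σ(g_e·s1)·σ(−g_s·s2), that reproduces the qualitative phenomenon
  (both axes informative, silences favoring the suppressive axis).
* :func:`count_toys` — uniform unit-disk stimuli with 0/1/2-spike responses,
  either deterministic in the horizontal projection or variance-coded
  (stimulus modulates count variance, never the mean).
* :func:`two_stimulus_worked_example` — the deterministic two-sequence
  experiment (A always elicits 3 spikes, B always 1, Δ = 1 s).
* :func:`frozen_noise_repeats` — Poisson draws around a fixed rate profile.

All randomness flows from a single integer seed through
``numpy.random.default_rng``.
"""

from __future__ import annotations

import numpy as np

from .data import Dataset, RepeatRaster, make_dataset

__all__ = [
    "simulate",
    "halfcircle_bernoulli",
    "sigmoid_bernoulli_2d",
    "excit_suppress_gaussian",
    "count_toys",
    "two_stimulus_worked_example",
    "frozen_noise_repeats",
    "draw_stimuli",
]


def _sigmoid(u):
    return 1.0 / (1.0 + np.exp(-u))


def draw_stimuli(law: str, n: int, rng, n_dim: int = 2) -> np.ndarray:
    """Draw stimuli from one of the named stimulus laws."""
    if law == "gaussian":
        return rng.standard_normal((n, n_dim))
    if law == "unit-disk":
        # polar with sqrt-radius for uniform area density
        r = np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, size=n)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])
    if law == "half-circle":
        th = rng.uniform(-np.pi / 2, np.pi / 2, size=n)
        return np.column_stack([np.cos(th), np.sin(th)])
    raise ValueError(f"unknown stimulus law: {law!r}")


def simulate(
    family: str,
    nonlinearity,
    filters: np.ndarray,
    n_samples: int,
    bin_width: float,
    seed: int,
    stimulus_law: str = "gaussian",
) -> Dataset:
    """Draw a seeded dataset from an LN model.

    Parameters
    ----------
    family : {'lnp', 'lnb', 'lnc'}
        Spiking model.  For 'lnp' the nonlinearity returns a rate in
        spikes/s; for 'lnb' a probability in [0, 1]; for 'lnc' it returns an
        (r_max+1, N) array of per-count probabilities summing to 1 per sample.
    nonlinearity : callable
        Maps projected stimuli (N, p) (or (N,) when p = 1) to the quantity
        above.
    filters : ndarray (D, p)
        True filters K*; attached to the output as ground truth.
    """
    rng = np.random.default_rng(seed)
    K = np.atleast_2d(np.asarray(filters, dtype=float))
    if K.ndim == 2 and K.shape[0] == 1:
        K = K.T
    S = draw_stimuli(stimulus_law, n_samples, rng, n_dim=K.shape[0])
    x = S @ K
    if K.shape[1] == 1:
        x = x.ravel()
    if family == "lnp":
        lam = np.asarray(nonlinearity(x), dtype=float)
        if (lam < 0).any():
            raise ValueError("lnp nonlinearity must return non-negative rates")
        counts = rng.poisson(lam * bin_width)
    elif family == "lnb":
        lam = np.asarray(nonlinearity(x), dtype=float)
        if (lam < 0).any() or (lam > 1).any():
            raise ValueError("lnb nonlinearity must return probabilities in [0,1]")
        counts = rng.binomial(1, lam)
    elif family == "lnc":
        probs = np.asarray(nonlinearity(x), dtype=float)
        if probs.ndim != 2 or probs.shape[1] != n_samples:
            raise ValueError("lnc nonlinearity must return (r_max+1, N) probabilities")
        if (probs < 0).any() or not np.allclose(probs.sum(axis=0), 1.0):
            raise ValueError("lnc probabilities must be a simplex per sample")
        u = rng.uniform(size=n_samples)
        counts = (u[None, :] > np.cumsum(probs, axis=0)).sum(axis=0)
    else:
        raise ValueError(f"unknown family: {family!r}")
    return make_dataset(
        S,
        counts,
        bin_width,
        ground_truth={"family": family, "filters": K, "nonlinearity": nonlinearity},
    )


def halfcircle_bernoulli(n_samples: int, seed: int) -> Dataset:
    """Bernoulli neuron on the unit half-circle.

    Stimuli are (cos θ, sin θ) with θ ~ Unif(−π/2, π/2); the spike probability
    rises linearly with angle, p(spike|θ) = θ/π + 1/2.  The marginal spike
    fraction is 1/2.  The most informative single direction is the vertical
    axis; the spikes-only (single-spike) objective is biased clockwise from it.
    """
    rng = np.random.default_rng(seed)
    th = rng.uniform(-np.pi / 2, np.pi / 2, size=n_samples)
    S = np.column_stack([np.cos(th), np.sin(th)])
    lam = th / np.pi + 0.5
    counts = rng.binomial(1, lam)
    return make_dataset(
        S,
        counts,
        1.0,
        ground_truth={
            "family": "lnb",
            "filters": np.array([[0.0], [1.0]]),
            "theta": th,
            "spike_prob": lam,
        },
    )


def sigmoid_bernoulli_2d(
    n_samples: int,
    seed: int,
    angle_deg: float = 45.0,
    slope: float = 4.0,
    offset: float = -2.0,
) -> Dataset:
    """2-D Gaussian stimuli driving a Bernoulli neuron with a logistic ramp.

    The single true filter points at ``angle_deg``; spike probability is
    σ(slope·(k^T s) + offset).  The default offset keeps spiking sparse
    (roughly 20% of bins), in the regime where histogram bin count visibly
    trades off over- against under-fitting.
    """
    rng = np.random.default_rng(seed)
    S = rng.standard_normal((n_samples, 2))
    k = np.array([np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))])
    lam = _sigmoid(slope * (S @ k) + offset)
    counts = rng.binomial(1, lam)
    return make_dataset(
        S,
        counts,
        1.0,
        ground_truth={
            "family": "lnb",
            "filters": k[:, None],
            "slope": slope,
            "offset": offset,
        },
    )


def excit_suppress_gaussian(
    n_samples: int,
    seed: int,
    excitatory_gain: float = 2.0,
    suppressive_gain: float = 1.0,
) -> Dataset:
    """Synthetic excitatory/suppressive Bernoulli neuron (stand-in form).

    2-D standard-Gaussian stimuli; spike probability
    λ(s) = σ(g_e·s1) · exp(−g_s·s2²) is monotone increasing along s1
    (excitatory) and falls off with the magnitude of the projection onto s2
    (suppressive).  With either gain set to 0 the corresponding axis carries
    no information; with both active each cardinal axis is a local maximum of
    the Bernoulli information.  The exact published nonlinearity for this
    scenario is not available; this stand-in reproduces the qualitative
    structure only.
    """
    rng = np.random.default_rng(seed)
    S = rng.standard_normal((n_samples, 2))
    lam = _sigmoid(excitatory_gain * S[:, 0]) * np.exp(
        -suppressive_gain * S[:, 1] ** 2
    )
    counts = rng.binomial(1, lam)
    return make_dataset(
        S,
        counts,
        1.0,
        ground_truth={
            "family": "lnb",
            "excitatory_gain": excitatory_gain,
            "suppressive_gain": suppressive_gain,
        },
    )


def count_toys(
    variant: str,
    n_samples: int,
    seed: int,
    breakpoints: tuple | None = None,
    slope: float = 4.0,
) -> Dataset:
    """0/1/2-spike neurons on the unit disk, sensitive to the horizontal axis.

    ``variant='deterministic'``: the count is a piecewise-constant function of
    the horizontal projection with two breakpoints (defaults at the terciles
    of the projection's marginal distribution over the disk), so the response
    is a deterministic, dramatically non-Poisson function of the stimulus.

    ``variant='variance-coded'``: with probability σ(slope·x) the neuron
    flips a fair coin between 0 and 2 spikes, otherwise it emits exactly 1.
    The conditional mean count is 1 for every stimulus — only the variance is
    stimulus-dependent — so the spike-triggered distribution equals the raw
    one and the spikes-only objective is blind to the filter.
    """
    rng = np.random.default_rng(seed)
    r = np.sqrt(rng.uniform(size=n_samples))
    th = rng.uniform(0, 2 * np.pi, size=n_samples)
    S = np.column_stack([r * np.cos(th), r * np.sin(th)])
    x = S[:, 0]
    if variant == "deterministic":
        if breakpoints is None:
            # terciles of the horizontal-projection marginal on the unit disk
            breakpoints = tuple(np.quantile(x, [1 / 3, 2 / 3]))
        b1, b2 = breakpoints
        counts = np.where(x < b1, 0, np.where(x < b2, 1, 2))
    elif variant == "variance-coded":
        p_flip = _sigmoid(slope * x)
        flip = rng.uniform(size=n_samples) < p_flip
        coin = rng.integers(0, 2, size=n_samples) * 2  # 0 or 2
        counts = np.where(flip, coin, 1)
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    return make_dataset(
        S,
        counts,
        1.0,
        ground_truth={
            "family": "lnc",
            "filters": np.array([[1.0], [0.0]]),
            "variant": variant,
        },
    )


def two_stimulus_worked_example():
    """The deterministic two-sequence experiment.

    Two equiprobable stimulus sequences, s1 = AB and s2 = BA, each lasting two
    1-second bins; stimulus A always elicits 3 spikes and B always 1.  Returns
    ``(raster, labels, experiment_raster)``: a 2x2 raster with one row per
    sequence and its labels, plus the concatenated single-trial raster
    (3,1,1,3) representing the whole experiment for the PSTH-based estimate.
    """
    raster = RepeatRaster(np.array([[3, 1], [1, 3]]), 1.0)
    labels = np.array([0, 1])
    experiment = RepeatRaster(np.array([[3, 1, 1, 3]]), 1.0)
    return raster, labels, experiment


def frozen_noise_repeats(
    rate_profile, n_repeats: int, bin_width: float, seed: int
) -> RepeatRaster:
    """Poisson spike counts around a fixed rate profile, repeated n times.

    The PSTH of the draws converges to ``rate_profile`` (spikes/s) as the
    number of repeats grows.
    """
    lam = np.asarray(rate_profile, dtype=float)
    if (lam < 0).any():
        raise ValueError("rate profile must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam * bin_width, size=(n_repeats, len(lam)))
    return RepeatRaster(counts, bin_width)
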