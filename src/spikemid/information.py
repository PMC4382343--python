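"""Plug-in information estimators for spike trains.

All estimators are spike-normalized (bits/spike) plug-in Kullback-Leibler
divergences between conditioned and raw projected-stimulus histograms:

* single-spike information  Î_ss = Σ_i q̂_i log2(q̂_i/p̂_i)  — spikes only;
* silence information       Î_0  = ((N−n_sp)/n_sp) KL(q̂^(0) ‖ p̂) — binary data;
* Bernoulli information     Î_Ber = Î_0 + Î_ss  — spikes and silences;
* count information         Î_count = Σ_j (N^(j)/(r̄N)) KL(q̂^(j) ‖ p̂) — all counts,
  reducing exactly to Î_Ber when the maximum count is 1.

Each of these equals a model log-likelihood per spike plus a constant (see
:mod:`spikemid.likelihoods`), so maximizing the information over filters is
maximum-likelihood subspace estimation.  Internal sums use natural logs; all
public values are reported in bits.  A dataset with no spikes yields 0 with a
warning (a convention so sparse pipelines do not crash, not a claim).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import RepeatRaster
from .histograms import HistogramDensities

__all__ = [
    "InfoReport",
    "single_spike_info",
    "silence_info",
    "bernoulli_info",
    "count_info",
    "lnx_info_from_loglik",
    "psth_single_spike_info",
    "xval_single_spike_info",
    "stimulus_entropy_decomposition",
]

_LN2 = np.log(2.0)


def _kl_nats(q: np.ndarray, p: np.ndarray) -> float:
    """KL(q‖p) in nats with the 0·log 0 = 0 convention.

    Requires support(q) ⊆ support(p); for plug-in histograms this holds by
    construction (a spike-triggered stimulus is a stimulus).
    """
    q = np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    mask = q > 0
    if (p[mask] <= 0).any():
        raise ValueError("support of q is not contained in support of p")
    return float(np.sum(q[mask] * np.log(q[mask] / p[mask])))


@dataclass
class InfoReport:
    """Spike-normalized information estimates with unit bookkeeping.

    All stored values are in the unit given by ``unit`` (default bits).  The
    additive identities ``i_ber = i_0 + i_ss`` (binary data) and
    ``i_count = Σ_j i_by_count[j]`` hold exactly.
    """

    i_ss: float | None = None
    i_0: float | None = None
    i_ber: float | None = None
    i_count: float | None = None
    i_by_count: np.ndarray | None = None
    unit: str = "bits"
    provenance: dict = field(default_factory=dict)

    def in_unit(self, unit: str) -> "InfoReport":
        """Return a copy converted to ``unit`` ('bits' or 'nats'); no-op if same."""
        if unit not in ("bits", "nats"):
            raise ValueError("unit must be 'bits' or 'nats'")
        if unit == self.unit:
            return self
        factor = _LN2 if unit == "nats" else 1.0 / _LN2
        conv = lambda v: None if v is None else v * factor  # noqa: E731
        return InfoReport(
            i_ss=conv(self.i_ss),
            i_0=conv(self.i_0),
            i_ber=conv(self.i_ber),
            i_count=conv(self.i_count),
            i_by_count=None if self.i_by_count is None else self.i_by_count * factor,
            unit=unit,
            provenance=dict(self.provenance),
        )

    def to_json(self, **kwargs) -> str:
        d = {
            k: v
            for k, v in {
                "i_ss": self.i_ss,
                "i_0": self.i_0,
                "i_ber": self.i_ber,
                "i_count": self.i_count,
                "i_by_count": None
                if self.i_by_count is None
                else list(map(float, self.i_by_count)),
                "unit": self.unit,
                "provenance": self.provenance,
            }.items()
            if v is not None
        }
        return json.dumps(d, **kwargs)


def single_spike_info(dens: HistogramDensities) -> float:
    """Single-spike information Î_ss in bits/spike.

    KL divergence between the spike-weighted and raw projected-stimulus
    histograms.  Returns 0 with a warning when the dataset has no spikes.
    """
    if dens.n_spikes == 0:
        warnings.warn("no spikes: single-spike information defined as 0", stacklevel=2)
        return 0.0
    return _kl_nats(dens.q_hat, dens.p_hat) / _LN2


def silence_info(dens: HistogramDensities, n_samples=None, n_spikes=None) -> float:
    """Information per spike carried by silences, Î_0, for binary counts.

    The KL divergence between the silence-conditioned and raw histograms,
    weighted by the silence-to-spike ratio (N − n_sp)/n_sp.
    """
    N = dens.n_samples if n_samples is None else n_samples
    n_sp = dens.n_spikes if n_spikes is None else n_spikes
    if dens.r_max > 1:
        raise ValueError(
            "counts exceed 1: silence information is defined for binary data; "
            "use count_info for general counts"
        )
    if n_sp == 0 or n_sp == N:
        raise ValueError(
            "silence information requires both spikes and silences "
            "(0 < n_sp < N)"
        )
    q0 = dens.q_hat_by_count[0]
    return (N - n_sp) / n_sp * _kl_nats(q0, dens.p_hat) / _LN2


def bernoulli_info(dens: HistogramDensities) -> InfoReport:
    """Bernoulli information Î_Ber = Î_0 + Î_ss for binary spike trains.

    The mutual information between projected stimulus and binary response,
    normalized by spike probability; strictly greater than Î_ss whenever the
    response is neither all zeros nor all ones.
    """
    i_ss = single_spike_info(dens)
    i_0 = silence_info(dens)
    return InfoReport(
        i_ss=i_ss,
        i_0=i_0,
        i_ber=i_0 + i_ss,
        provenance={
            "objective": "bernoulli",
            "n_samples": dens.n_samples,
            "n_spikes": dens.n_spikes,
            "n_bins": dens.partition.n_bins,
        },
    )


def count_info(dens: HistogramDensities) -> InfoReport:
    """Count information Î_count = Σ_j (N^(j)/(r̄N)) KL(q̂^(j) ‖ p̂) in bits/spike.

    Mutual information between projected stimulus and integer spike count,
    normalized by the mean count r̄.  The per-count terms I_j are reported
    separately; they use the exact-count conditionals q̂^(j), not the
    spike-weighted q̂ (I_1 is not the single-spike information).  Reduces to
    :func:`bernoulli_info` exactly when the maximum count is 1.
    """
    if dens.n_spikes == 0:
        warnings.warn("no spikes: count information defined as 0", stacklevel=2)
        return InfoReport(i_count=0.0, i_by_count=np.zeros(1))
    rbar_n = dens.n_spikes  # r̄ * N = n_sp
    i_j = np.array(
        [
            dens.counts_by_j[j] / rbar_n * _kl_nats(dens.q_hat_by_count[j], dens.p_hat)
            for j in range(dens.r_max + 1)
        ]
    ) / _LN2
    return InfoReport(
        i_0=i_j[0] if dens.r_max >= 0 else None,
        i_count=float(i_j.sum()),
        i_by_count=i_j,
        provenance={
            "objective": "count",
            "n_samples": dens.n_samples,
            "n_spikes": dens.n_spikes,
            "n_bins": dens.partition.n_bins,
            "r_max": dens.r_max,
        },
    )


def lnx_info_from_loglik(loglik_model: float, loglik_null: float, n: int) -> float:
    """Generic model-based information in bits per sample.

    ``(ℒ_model − ℒ_null)/n`` with both log-likelihoods in nats on the same
    data, converted to bits.  For histogram-ML fits this recovers the plug-in
    information estimators times the spikes-per-sample factor.
    """
    return (loglik_model - loglik_null) / n / _LN2


def psth_single_spike_info(raster: RepeatRaster) -> float:
    """Single-spike information of a frozen-noise repeat raster, bits/spike.

    Uses the PSTH (trial-averaged rate) λ̂(t) as the plug-in rate estimate:
    ``Î_ss = (1/n_t) Σ_t (λ̂(t)/λ̄) log2(λ̂(t)/λ̄)``, with λ̄ the mean rate.
    Equals the inhomogeneous-vs-homogeneous Poisson log-likelihood ratio per
    spike.
    """
    if raster.n_spikes == 0:
        raise ValueError("all-zero raster: PSTH information undefined")
    lam = raster.psth()
    lbar = lam.mean()
    ratio = lam / lbar
    mask = ratio > 0
    return float(np.mean(np.where(mask, ratio * np.log(np.where(mask, ratio, 1.0)), 0.0))) / _LN2


def xval_single_spike_info(
    rate_train: np.ndarray,
    raster_test: RepeatRaster,
    floor: float = 0.5,
) -> float:
    """Cross-validated single-spike information, bits/spike (can be negative).

    ``(ℒ(λ̂_train; r_test) − ℒ(λ̄_test; r_test)) / n_sp_test`` under the Poisson
    model.  A training rate of exactly 0 where test spikes occur would give
    −∞; those bins are floored at ``floor`` pseudo-spikes spread over the
    training observations of that bin (a held-out-evaluation guard only; raw
    plug-ins are never smoothed), with a warning.
    """
    lam = np.asarray(rate_train, dtype=float).copy()
    r = raster_test.counts
    if lam.shape[0] != raster_test.n_bins:
        raise ValueError("training rate must be defined on the test time grid")
    n_sp = raster_test.n_spikes
    if n_sp == 0:
        raise ValueError("test raster has no spikes")
    spikes_per_bin = r.sum(axis=0)
    bad = (lam <= 0) & (spikes_per_bin > 0)
    if bad.any():
        warnings.warn(
            f"{bad.sum()} time bins have zero training rate but test spikes; "
            "applying pseudocount floor",
            stacklevel=2,
        )
        lam[bad] = floor / (raster_test.n_repeats * raster_test.bin_width)
    delta = raster_test.bin_width
    nrpt = raster_test.n_repeats
    lbar = n_sp / (r.size * delta)
    # Poisson log-likelihood difference; log r! terms cancel
    with np.errstate(divide="ignore"):
        log_lam = np.where(spikes_per_bin > 0, np.log(np.maximum(lam, 1e-300)), 0.0)
    ll_model = float(np.sum(spikes_per_bin * log_lam) - nrpt * delta * lam.sum())
    ll_null = float(n_sp * np.log(lbar) - nrpt * delta * lbar * len(lam))
    return (ll_model - ll_null) / n_sp / _LN2


def stimulus_entropy_decomposition(
    raster: RepeatRaster, labels: np.ndarray
) -> tuple[float, float]:
    """Prior and posterior entropy (bits) of stimulus identity given one spike.

    For an experiment with a discrete set of stimulus sequences (``labels``
    assigns each raster row to a sequence), computes the entropy H(s) of the
    sequence identity and the conditional entropy H(s|τ) given the time bin of
    one spike drawn uniformly at random.  Their difference is the single-spike
    information in bits/spike (for equiprobable sequences with equal spike
    totals).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != raster.n_repeats:
        raise ValueError("labels must assign one stimulus identity per raster row")
    uniq = np.unique(labels)
    # p(s): fraction of presentations
    p_s = np.array([(labels == u).mean() for u in uniq])
    prior = float(-np.sum(p_s * np.log2(p_s)))
    # joint p(s, τ): probability that a random spike falls in bin t of sequence s
    per_label = np.array(
        [raster.counts[labels == u].sum(axis=0) for u in uniq], dtype=float
    )
    joint = per_label / per_label.sum()
    p_tau = joint.sum(axis=0)
    posterior = 0.0
    for t in range(raster.n_bins):
        if p_tau[t] <= 0:
            continue
        cond = joint[:, t] / p_tau[t]
        mask = cond > 0
        posterior -= p_tau[t] * float(np.sum(cond[mask] * np.log2(cond[mask])))
    return prior, posterior
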