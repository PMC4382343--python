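"""Log-likelihoods for the LNP/LNB/LNC spiking models and their null models.

The central identities (exact for any dataset and any binning, in nats):

* Poisson:   n_sp · Î_ss·ln2   = ℒ_lnp(θ̂) − ℒ_lnp(θ₀), with θ̂ the histogram-ML
  piecewise-constant rate and θ₀ the constant rate n_sp/(NΔ);
* Bernoulli: n_sp · Î_Ber·ln2  = ℒ_lnb(θ̂) + N·Ĥ[r] = ℒ_lnb(θ̂) − ℒ_null;
* Count:     n_sp · Î_count·ln2 = ℒ_lnc(θ̂) + N·Ĥ[r] = ℒ_lnc(θ̂) − ℒ_null,

where Ĥ[r] is the plug-in marginal response entropy, and the null model's
log-likelihood is −N·Ĥ[r].  Because the null term does not depend on the
filters, information-maximizing and likelihood-maximizing subspaces coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "LogLik",
    "lnp_loglik",
    "lnp_null_loglik",
    "lnb_loglik",
    "lnb_null_loglik",
    "lnc_loglik",
    "lnc_null_loglik",
    "response_entropy",
]


@dataclass(frozen=True)
class LogLik:
    """A log-likelihood value in nats with provenance."""

    value: float
    n: int
    n_spikes: int
    model: str

    def __float__(self) -> float:
        return self.value


def _log_factorial(counts: np.ndarray) -> float:
    """Σ log r_t! via log-gamma for overflow safety."""
    return float(gammaln(np.asarray(counts, dtype=float) + 1.0).sum())


def lnp_loglik(rates, counts, bin_width) -> LogLik:
    """Exact Poisson log-likelihood, nats, including the log r_t! terms.

    ``rates`` are per-sample intensities λ_t in spikes/s.  A zero rate at a
    bin with spikes makes the data impossible: the value is −inf.
    """
    lam = np.asarray(rates, dtype=float)
    r = np.asarray(counts)
    if lam.shape != r.shape:
        raise ValueError("rates and counts must have the same length")
    if (lam < 0).any():
        raise ValueError("rates must be non-negative")
    mu = lam * bin_width
    n_sp = int(r.sum())
    spiking = r > 0
    if (mu[spiking] == 0).any():
        value = -np.inf
    else:
        with np.errstate(divide="ignore"):
            log_mu = np.where(spiking, np.log(np.where(spiking, mu, 1.0)), 0.0)
        value = float(np.sum(r * log_mu) - mu.sum() - _log_factorial(r))
    return LogLik(value, len(r), n_sp, "lnp")


def lnp_null_loglik(counts, bin_width) -> LogLik:
    """Poisson log-likelihood at the constant ML rate λ₀ = n_sp/(NΔ).

    Closed form n_sp·ln(n_sp/N) − n_sp − Σ ln r_t!; with no spikes the rate
    terms vanish by the 0·ln 0 convention.
    """
    r = np.asarray(counts)
    N = len(r)
    n_sp = int(r.sum())
    rate_terms = n_sp * np.log(n_sp / N) - n_sp if n_sp > 0 else 0.0
    value = float(rate_terms - _log_factorial(r))
    return LogLik(value, N, n_sp, "null-poisson")


def lnb_loglik(probs, counts) -> LogLik:
    """Bernoulli log-likelihood Σ r ln λ + (1−r) ln(1−λ), nats.

    ``probs`` are per-sample spike probabilities λ_t ∈ [0, 1]; counts must be
    binary.  A probability of exactly 0 (resp. 1) at an observed spike
    (resp. silence) yields −inf.
    """
    lam = np.asarray(probs, dtype=float)
    r = np.asarray(counts)
    if lam.shape != r.shape:
        raise ValueError("probs and counts must have the same length")
    if r.max(initial=0) > 1 or r.min(initial=0) < 0:
        raise ValueError("counts must be binary for the Bernoulli model")
    if (lam < 0).any() or (lam > 1).any():
        raise ValueError("probs must lie in [0, 1]")
    spikes = r == 1
    if (lam[spikes] == 0).any() or (lam[~spikes] == 1).any():
        value = -np.inf
    else:
        with np.errstate(divide="ignore"):
            t1 = np.where(spikes, np.log(np.where(spikes, lam, 1.0)), 0.0)
            t0 = np.where(~spikes, np.log(np.where(~spikes, 1.0 - lam, 1.0)), 0.0)
        value = float(t1.sum() + t0.sum())
    return LogLik(value, len(r), int(r.sum()), "lnb")


def lnb_null_loglik(counts) -> LogLik:
    """Bernoulli log-likelihood at the constant ML probability n_sp/N.

    Equals −N·Ĥ[r] with Ĥ[r] the plug-in binary response entropy.
    """
    r = np.asarray(counts)
    N = len(r)
    return LogLik(
        -N * response_entropy(r, model="bernoulli"), N, int(r.sum()), "null-bernoulli"
    )


def lnc_loglik(count_probs, counts) -> LogLik:
    """Categorical (count-model) log-likelihood Σ_t ln f^(r_t)(x_t), nats.

    ``count_probs`` is an (r_max+1, N) array of per-sample probability vectors
    over counts j = 0..r_max (each column sums to 1).  Zero probability at an
    observed count yields −inf.
    """
    f = np.asarray(count_probs, dtype=float)
    r = np.asarray(counts)
    if f.ndim != 2 or f.shape[1] != len(r):
        raise ValueError("count_probs must be (r_max+1, N)")
    if r.max(initial=0) > f.shape[0] - 1:
        raise ValueError("observed count exceeds the model's maximum count")
    if not np.allclose(f.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("per-sample count probabilities must sum to 1")
    probs = f[r, np.arange(len(r))]
    if (probs == 0).any():
        value = -np.inf
    else:
        value = float(np.log(probs).sum())
    return LogLik(value, len(r), int(r.sum()), "lnc")


def lnc_null_loglik(counts) -> LogLik:
    """Categorical log-likelihood at the marginal count frequencies.

    Equals Σ_j N^(j) ln(N^(j)/N) = −N·Ĥ[r].
    """
    r = np.asarray(counts)
    N = len(r)
    return LogLik(
        -N * response_entropy(r, model="count"), N, int(r.sum()), "null-count"
    )


def response_entropy(counts, model: str = "count") -> float:
    """Plug-in marginal entropy Ĥ[r] of the count distribution, nats.

    ``model='bernoulli'`` uses the two-outcome form (requires binary counts);
    ``model='count'`` uses the full empirical count distribution.  The two
    agree on binary data.
    """
    r = np.asarray(counts)
    N = len(r)
    if model == "bernoulli":
        if r.max(initial=0) > 1:
            raise ValueError("bernoulli entropy requires binary counts")
        rho = r.sum() / N
        h = 0.0
        for p in (rho, 1.0 - rho):
            if p > 0:
                h -= p * np.log(p)
        return float(h)
    if model == "count":
        freqs = np.bincount(r) / N
        mask = freqs > 0
        return float(-np.sum(freqs[mask] * np.log(freqs[mask])))
    raise ValueError("model must be 'bernoulli' or 'count'")
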