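"""The silence-information lower bound for Bernoulli neurons.

For a binary response with marginal spike probability ρ, the mutual
information between stimulus and response decomposes exactly as

    I(s, r) = ρ·KL(Q1 ‖ P) + (1−ρ)·KL(Q0 ‖ P),

with Q1 = p(s|spike), Q0 = p(s|silence), P = p(s) = ρQ1 + (1−ρ)Q0 — a
generalized Jensen-Shannon divergence.  A spikes-only objective discards the
second (silence) term.  In the rare-spiking limit the neglected fraction is
bounded below by ρ/2:

    silence term / I  =  ½ρ²V(Q1,Q0) / (ρ·KL(Q1‖Q0) − ½ρ²V + O(ρ³))  ≥  ρ/2,

where V(Q1,Q0) = Σ Q1(Q1/Q0 − 1) ≥ KL(Q1‖Q0) (since z−1 ≥ log z).  The bound
is conjectured to hold at every ρ; :func:`min_silence_fraction_binary`
measures the actual minimum over binary-stimulus channels and
:func:`js_conjecture_probe` searches randomized distribution pairs at ρ = ½
for counterexamples (reporting, never asserting).

Channels here are finite/discrete; continuous stimuli are handled upstream
by discretization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiscreteChannel",
    "exact_info_decomposition",
    "loss_lower_bound",
    "v_divergence",
    "taylor_terms",
    "taylor_remainder_sweep",
    "min_silence_fraction_binary",
    "silence_fraction_curve",
    "js_conjecture_probe",
]

_LN2 = np.log(2.0)
# channels with less total information than this are treated as uninformative
ZERO_INFO_GUARD_BITS = 1e-12


def _kl_bits(q, p):
    q = np.asarray(q, float)
    p = np.asarray(p, float)
    mask = q > 0
    if (p[mask] <= 0).any():
        return np.inf
    return float(np.sum(q[mask] * np.log(q[mask] / p[mask]))) / _LN2


@dataclass(frozen=True)
class DiscreteChannel:
    """A finite stimulus alphabet with per-stimulus Bernoulli spike probability."""

    p_stimulus: np.ndarray  # P_s, sums to 1
    spike_prob: np.ndarray  # λ(s) in [0, 1]

    def __post_init__(self):
        ps = np.asarray(self.p_stimulus, float)
        lam = np.asarray(self.spike_prob, float)
        if ps.shape != lam.shape:
            raise ValueError("p_stimulus and spike_prob must have equal length")
        if not np.isclose(ps.sum(), 1.0):
            raise ValueError("p_stimulus must sum to 1")
        if (ps < 0).any() or (lam < 0).any() or (lam > 1).any():
            raise ValueError("probabilities out of range")
        object.__setattr__(self, "p_stimulus", ps)
        object.__setattr__(self, "spike_prob", lam)

    @property
    def rho(self) -> float:
        """Marginal spike probability p(r = 1)."""
        return float(self.p_stimulus @ self.spike_prob)

    @property
    def q1(self) -> np.ndarray:
        """Spike-conditioned stimulus distribution p(s|r = 1)."""
        return self.p_stimulus * self.spike_prob / self.rho

    @property
    def q0(self) -> np.ndarray:
        """Silence-conditioned stimulus distribution p(s|r = 0)."""
        return self.p_stimulus * (1 - self.spike_prob) / (1 - self.rho)


def exact_info_decomposition(ch: DiscreteChannel) -> dict:
    """Exact I(s,r) and its spike/silence KL terms, in bits.

    Returns ``i_total``, ``spike_term``, ``silence_term`` and
    ``silence_fraction`` (None for a zero-information channel).
    """
    rho = ch.rho
    ps = ch.p_stimulus
    if rho <= 0 or rho >= 1:
        spike = silence = 0.0
    else:
        spike = rho * _kl_bits(ch.q1, ps)
        silence = (1 - rho) * _kl_bits(ch.q0, ps)
    total = spike + silence
    frac = silence / total if total > ZERO_INFO_GUARD_BITS else None
    return {
        "i_total": total,
        "spike_term": spike,
        "silence_term": silence,
        "silence_fraction": frac,
    }


def loss_lower_bound(rho: float) -> float:
    """Rare-spiking lower bound ρ/2 on the neglected information fraction."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    return rho / 2.0


def v_divergence(q1, q0) -> float:
    """V(Q1, Q0) = Σ Q1(Q1/Q0 − 1); an upper bound on KL(Q1‖Q0) (nats).

    Infinite (tagged by +inf) when Q1 has mass where Q0 has none.
    """
    q1 = np.asarray(q1, float)
    q0 = np.asarray(q0, float)
    mask = q1 > 0
    if (q0[mask] <= 0).any():
        return np.inf
    return float(np.sum(q1[mask] * (q1[mask] / q0[mask] - 1.0)))


def taylor_terms(ch: DiscreteChannel) -> dict:
    """Leading small-ρ Taylor terms of the information decomposition (nats).

    ``silence_quadratic`` = ½ρ²V(Q1,Q0) approximates the silence term;
    ``spike_linear`` = ρ·KL(Q1‖Q0) is the leading term of the total.
    """
    rho = ch.rho
    V = v_divergence(ch.q1, ch.q0)
    kl10 = _kl_bits(ch.q1, ch.q0) * _LN2
    return {"silence_quadratic": 0.5 * rho**2 * V, "spike_linear": rho * kl10}


def taylor_remainder_sweep(q1, q0, rhos=None) -> pd.DataFrame:
    """Empirical Taylor remainders of the decomposition over a ρ sweep (nats).

    For fixed conditional distributions Q1 ≠ Q0 and each ρ, builds the channel
    with P = ρQ1 + (1−ρ)Q0 and tabulates

    * ``remainder_silence`` = |(1−ρ)KL(Q0‖P) − ½ρ²V|,
    * ``remainder_total``   = |I − ρKL(Q1‖Q0) + ½ρ²V|.

    Both scale as O(ρ³); the log-log slope of each column against ρ estimates
    the order of the first neglected term.
    """
    q1 = np.asarray(q1, float)
    q0 = np.asarray(q0, float)
    if rhos is None:
        rhos = np.logspace(-4, -1, 16)
    V = v_divergence(q1, q0)
    kl10 = float(np.sum(q1[q1 > 0] * np.log(q1[q1 > 0] / q0[q1 > 0])))
    rows = []
    for rho in np.asarray(rhos, float):
        ps = rho * q1 + (1 - rho) * q0
        silence = (1 - rho) * float(np.sum(q0 * np.log(q0 / ps)))
        total = silence + rho * float(
            np.sum(q1[q1 > 0] * np.log(q1[q1 > 0] / ps[q1 > 0]))
        )
        rows.append(
            {
                "rho": rho,
                "silence_term": silence,
                "i_total": total,
                "remainder_silence": abs(silence - 0.5 * rho**2 * V),
                "remainder_total": abs(total - rho * kl10 + 0.5 * rho**2 * V),
            }
        )
    return pd.DataFrame(rows)


def min_silence_fraction_binary(rho: float, n_grid: int = 400) -> float:
    """Minimum silence fraction over binary-stimulus channels at marginal ρ.

    Searches stimulus priors q = p(s=1) and conditional spike probabilities
    (λ(0), λ(1)) consistent with the marginal ρ, over an n_grid × n_grid
    lattice, excluding channels with negligible total information.  The
    conjecture is that the result is at least ρ/2 for every ρ.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie strictly between 0 and 1")
    qs = np.linspace(1e-3, 1 - 1e-3, n_grid)
    lam1s = np.linspace(0.0, 1.0, n_grid)
    best = 1.0
    for q in qs:
        lam0 = (rho - q * lam1s) / (1 - q)
        ok = (lam0 >= 0.0) & (lam0 <= 1.0)
        if not ok.any():
            continue
        l1, l0 = lam1s[ok], lam0[ok]
        # vectorized two-point channels: columns are (s=0, s=1)
        ps = np.array([1 - q, q])
        lam = np.stack([l0, l1], axis=1)  # (n_ok, 2)
        q1 = ps * lam / rho
        q0 = ps * (1 - lam) / (1 - rho)

        def _kl_rows(a, b):
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(a > 0, a * np.log(np.where(a > 0, a, 1.0) / b), 0.0)
            return t.sum(axis=1) / _LN2

        spike = rho * _kl_rows(q1, ps[None, :])
        silence = (1 - rho) * _kl_rows(q0, ps[None, :])
        total = spike + silence
        informative = total > ZERO_INFO_GUARD_BITS
        if informative.any():
            best = min(best, float((silence[informative] / total[informative]).min()))
    return best


def silence_fraction_curve(rhos, n_grid: int = 200) -> pd.DataFrame:
    """Bound ρ/2 and the numerical binary-stimulus minimum over a ρ sweep."""
    rows = [
        {
            "rho": float(r),
            "bound": loss_lower_bound(float(r)),
            "numerical_min": min_silence_fraction_binary(float(r), n_grid),
        }
        for r in np.asarray(rhos, float)
    ]
    return pd.DataFrame(rows)


def js_conjecture_probe(
    n_trials: int = 10000, alphabet_size: int = 4, seed: int = 0
) -> dict:
    """Randomized search for counterexamples to the ρ = ½ bound (fraction ≥ ¼).

    Draws Dirichlet pairs (Q0, Q1), builds the ρ = ½ mixture channel, and
    records the minimum observed silence fraction and the minimizing pair.
    Degenerate pairs (zero total information) are skipped.  This reports the
    search outcome; it never asserts the conjecture.
    """
    rng = np.random.default_rng(seed)
    worst = {"min_fraction": 1.0, "q1": None, "q0": None}
    for _ in range(n_trials):
        q1 = rng.dirichlet(np.ones(alphabet_size))
        q0 = rng.dirichlet(np.ones(alphabet_size))
        ps = 0.5 * (q1 + q0)
        spike = 0.5 * _kl_bits(q1, ps)
        silence = 0.5 * _kl_bits(q0, ps)
        total = spike + silence
        if total <= ZERO_INFO_GUARD_BITS:
            continue
        frac = silence / total
        if frac < worst["min_fraction"]:
            worst = {"min_fraction": frac, "q1": q1, "q0": q0}
    worst["n_trials"] = n_trials
    worst["conjectured_bound"] = 0.25
    return worst
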