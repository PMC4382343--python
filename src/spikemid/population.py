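"""Population-level (infinite-data) information curves by numerical quadrature.

For an analytic toy neuron — known stimulus law p(s) and conditional response
distribution p(r|s) — the plug-in objectives can be evaluated without
sampling: quadrature nodes replace data, exact conditional probabilities
replace observed counts, and the histogram tallies become weighted sums.
This isolates *estimator* bias (which direction an objective prefers in the
limit of infinite data) from sampling noise.

The histogram partition is part of the objective being analyzed, not a
nuisance: a histogram-based estimator run with m bins converges, as the
amount of data grows, to the maximizer of the *binned* information at that
resolution — which is precisely why a mis-matched objective can stay biased
"even with infinite data".  The package's canonical resolution for these
curves is 20 equal-width bins along the projection; the bin count is exposed
because the displacement of the spikes-only argmax depends on it (it
vanishes in the infinitely-fine-bin limit, where the binned curves approach
the continuous-KL curves).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "population_info",
    "halfcircle_nodes",
    "unit_disk_nodes",
    "gaussian_2d_nodes",
    "halfcircle_population_curves",
    "halfcircle_argmax_bias",
    "variance_coded_population_curves",
    "excit_suppress_population_curves",
]

_LN2 = np.log(2.0)


def _sigmoid(u):
    return 1.0 / (1.0 + np.exp(-u))


def _kl_bits(q, p):
    mask = q > 0
    return float(np.sum(q[mask] * np.log(q[mask] / p[mask]))) / _LN2


def population_info(
    x: np.ndarray,
    weights: np.ndarray,
    count_probs: np.ndarray,
    n_bins: int = 20,
    scheme: str = "equal-width",
) -> dict:
    """Binned information quantities of a projection under exact conditionals.

    Parameters
    ----------
    x : (n_nodes,) projected quadrature nodes.
    weights : (n_nodes,) stimulus-law quadrature weights, summing to 1.
    count_probs : (r_max+1, n_nodes) conditional count probabilities p(r=j|s).
    n_bins, scheme : histogram resolution along the projection.

    Returns a dict with ``i_ss``, ``i_0`` (when counts include 0), ``i_ber``
    (binary case), ``i_count`` and ``i_by_count``, all in bits/spike.
    """
    probs = np.asarray(count_probs, dtype=float)
    j_vals = np.arange(probs.shape[0])
    mean_count = probs.T @ j_vals  # E[r|s] per node
    rbar = float(weights @ mean_count)
    if rbar <= 0:
        raise ValueError("the model never spikes; information undefined")
    if scheme == "equal-width":
        edges = np.linspace(x.min(), x.max(), n_bins + 1)[1:-1]
    elif scheme == "equal-occupancy":
        # place edges only between distinct atoms of the projected quadrature
        # distribution: splitting a tied group would let numerically-leaked
        # orthogonal components order the tie, creating spurious information
        order = np.argsort(x, kind="stable")
        xs, ws = x[order], weights[order]
        tol = 1e-9 * max(np.ptp(xs), 1.0)
        new_atom = np.concatenate([[True], np.diff(xs) > tol])
        atom_id = np.cumsum(new_atom) - 1
        atom_val = np.bincount(atom_id, weights=xs * ws) / np.bincount(
            atom_id, weights=ws
        )
        cum = np.cumsum(np.bincount(atom_id, weights=ws))
        targets = np.arange(1, n_bins) / n_bins
        picks = np.searchsorted(cum, targets, side="left")
        picks = picks[picks < len(atom_val) - 1]
        edges = np.unique((atom_val[picks] + atom_val[picks + 1]) / 2.0)
    else:
        raise ValueError(f"unknown binning scheme: {scheme!r}")
    idx = np.searchsorted(edges, x, side="right")
    p_hat = np.bincount(idx, weights=weights, minlength=n_bins)
    # spike-weighted (each expected spike counts once)
    q_hat = np.bincount(idx, weights=weights * mean_count, minlength=n_bins) / rbar
    out = {"i_ss": _kl_bits(q_hat, p_hat)}
    marg = probs @ weights  # p(r=j)
    i_j = np.zeros(probs.shape[0])
    for j in j_vals:
        if marg[j] <= 0:
            continue
        q_j = np.bincount(idx, weights=weights * probs[j], minlength=n_bins) / marg[j]
        i_j[j] = marg[j] / rbar * _kl_bits(q_j, p_hat)
    out["i_by_count"] = i_j
    out["i_count"] = float(i_j.sum())
    if probs.shape[0] == 2:  # binary response: Bernoulli decomposition
        out["i_0"] = i_j[0]
        out["i_ber"] = out["i_0"] + out["i_ss"]
    return out


# -- quadrature node factories ----------------------------------------------


def halfcircle_nodes(n_quad: int = 20001):
    """Midpoint nodes for θ ~ Unif(−π/2, π/2) on the unit half-circle."""
    th = (np.arange(n_quad) + 0.5) / n_quad * np.pi - np.pi / 2
    S = np.column_stack([np.cos(th), np.sin(th)])
    w = np.full(n_quad, 1.0 / n_quad)
    return S, w, th


def unit_disk_nodes(n_radial: int = 80, n_angular: int = 360):
    """Equal-area polar grid over the uniform unit disk."""
    r = np.sqrt((np.arange(n_radial) + 0.5) / n_radial)
    th = (np.arange(n_angular) + 0.5) / n_angular * 2 * np.pi
    R, T = np.meshgrid(r, th, indexing="ij")
    S = np.column_stack([(R * np.cos(T)).ravel(), (R * np.sin(T)).ravel()])
    w = np.full(S.shape[0], 1.0 / S.shape[0])
    return S, w


def gaussian_2d_nodes(n_per_axis: int = 101):
    """Tensor Gauss-Hermite nodes for a 2-D standard Gaussian."""
    z, wz = np.polynomial.hermite_e.hermegauss(n_per_axis)
    wz = wz / wz.sum()
    Z1, Z2 = np.meshgrid(z, z, indexing="ij")
    W = np.outer(wz, wz).ravel()
    S = np.column_stack([Z1.ravel(), Z2.ravel()])
    return S, W


def _project(S, angle_deg):
    a = np.deg2rad(angle_deg)
    return S @ np.array([np.cos(a), np.sin(a)])


# -- named toy curves --------------------------------------------------------


def halfcircle_population_curves(
    angles_deg=None,
    n_bins: int = 20,
    scheme: str = "equal-width",
    n_quad: int = 20001,
) -> pd.DataFrame:
    """Asymptotic information-versus-angle curves for the half-circle neuron.

    Spike probability θ/π + 1/2 on θ ~ Unif(−π/2, π/2).  Returns a table with
    columns angle_deg, i_ss, i_0, i_ber.  The Bernoulli curve peaks at the
    vertical axis (90°); the spikes-only curve peaks clockwise of it by an
    amount that depends on the histogram resolution.
    """
    if angles_deg is None:
        angles_deg = np.arange(0.0, 180.0, 0.25)
    S, w, th = halfcircle_nodes(n_quad)
    lam = th / np.pi + 0.5
    probs = np.vstack([1 - lam, lam])
    rows = []
    for a in np.asarray(angles_deg, dtype=float):
        info = population_info(_project(S, a), w, probs, n_bins, scheme)
        rows.append(
            {"angle_deg": a, "i_ss": info["i_ss"], "i_0": info["i_0"], "i_ber": info["i_ber"]}
        )
    return pd.DataFrame(rows)


def halfcircle_argmax_bias(
    grid_step_deg: float = 0.25,
    n_bins: int = 20,
    scheme: str = "equal-width",
    n_quad: int = 20001,
) -> dict:
    """Arg-max angles of the asymptotic curves and the spikes-only bias.

    Returns ``argmax_bernoulli_deg``, ``argmax_single_spike_deg`` and
    ``clockwise_bias_deg`` (= 90° − spikes-only argmax).
    """
    curves = halfcircle_population_curves(
        np.arange(0.0, 180.0, grid_step_deg), n_bins, scheme, n_quad
    )
    a_ber = float(curves.angle_deg[curves.i_ber.idxmax()])
    a_ss = float(curves.angle_deg[curves.i_ss.idxmax()])
    return {
        "argmax_bernoulli_deg": a_ber,
        "argmax_single_spike_deg": a_ss,
        "clockwise_bias_deg": 90.0 - a_ss,
    }


def variance_coded_population_curves(
    angles_deg=None,
    slope: float = 4.0,
    n_bins: int = 20,
    scheme: str = "equal-width",
    n_radial: int = 80,
    n_angular: int = 360,
) -> pd.DataFrame:
    """Asymptotic curves for the variance-coded count neuron on the unit disk.

    With probability σ(slope·s1) the response is 0 or 2 spikes (fair coin),
    otherwise exactly 1: the conditional mean count is 1 everywhere, so the
    single-spike curve is identically zero while the count curve peaks at the
    horizontal axis (0°).
    """
    if angles_deg is None:
        angles_deg = np.arange(0.0, 180.0, 1.0)
    S, w = unit_disk_nodes(n_radial, n_angular)
    p_flip = _sigmoid(slope * S[:, 0])
    probs = np.vstack([p_flip / 2, 1 - p_flip, p_flip / 2])
    rows = []
    for a in np.asarray(angles_deg, dtype=float):
        info = population_info(_project(S, a), w, probs, n_bins, scheme)
        rows.append(
            {"angle_deg": a, "i_ss": info["i_ss"], "i_count": info["i_count"]}
        )
    return pd.DataFrame(rows)


def excit_suppress_population_curves(
    angles_deg=None,
    excitatory_gain: float = 2.0,
    suppressive_gain: float = 1.0,
    n_bins: int = 20,
    scheme: str = "equal-occupancy",
    n_per_axis: int = 101,
) -> pd.DataFrame:
    """Asymptotic Bernoulli curves for the excitatory/suppressive stand-in.

    λ(s) = σ(g_e·s1)·exp(−g_s·s2²) on 2-D Gaussian stimuli (synthetic
    stand-in nonlinearity; see
    :func:`spikemid.simulate.excit_suppress_gaussian`).  Both cardinal axes
    are informative: the total Bernoulli information has local maxima at 0°
    and 90°, and the spikes-only and Bernoulli objectives can disagree about
    which is global.  Bins default to equal-occupancy here because the
    Gaussian projections are unbounded.
    """
    if angles_deg is None:
        angles_deg = np.arange(0.0, 180.0, 1.0)
    S, w = gaussian_2d_nodes(n_per_axis)
    lam = _sigmoid(excitatory_gain * S[:, 0]) * np.exp(
        -suppressive_gain * S[:, 1] ** 2
    )
    probs = np.vstack([1 - lam, lam])
    rows = []
    for a in np.asarray(angles_deg, dtype=float):
        info = population_info(_project(S, a), w, probs, n_bins, scheme)
        rows.append(
            {"angle_deg": a, "i_ss": info["i_ss"], "i_0": info["i_0"], "i_ber": info["i_ber"]}
        )
    return pd.DataFrame(rows)
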