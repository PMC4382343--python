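"""Maximum-likelihood / maximally-informative subspace estimation.

:class:`MaximallyInformativeDimensions` finds the filter matrix K maximizing
a plug-in information objective over projected-stimulus histograms:

* ``objective='poisson'``   — single-spike information (classic MID; exactly
  the ML filter estimate of an LNP model with piecewise-constant rate);
* ``objective='bernoulli'`` — Bernoulli information (spikes and silences;
  ML for a binary-response LN model);
* ``objective='count'``     — count information (arbitrary count
  distributions; ML for the categorical LN model).

The histogram objectives are piecewise-constant in K, so the default search
is derivative-free: an exhaustive angle grid for one filter in a 2-D stimulus
space (how the toy analyses are framed, and reproducible), and multi-restart
Nelder-Mead over unconstrained filter coordinates with per-evaluation
orthonormalization otherwise.  The histogram is rebuilt at every candidate K
(the bin partition depends on the projection).

The number of histogram bins per filter axis, ``n_bins``, is the estimator's
key capacity parameter: too many bins overfit the nonlinearity and inflate
the information estimate at small N; too few underfit.  Choose it by
cross-validation (:func:`cross_validate_bins`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .data import Dataset, make_dataset, orthonormalize
from .histograms import build_bins, estimate_densities, ml_rate
from .information import bernoulli_info, count_info, single_spike_info
from .likelihoods import lnp_loglik, lnp_null_loglik

__all__ = [
    "MaximallyInformativeDimensions",
    "FitTrace",
    "plug_in_objective",
    "info_curve",
    "fit_subspace",
    "held_out_single_spike_info",
    "cross_validate_bins",
]

_LN2 = np.log(2.0)


@dataclass
class FitTrace:
    """Per-restart optimization record; the reported optimum is the max."""

    restarts: list = field(default_factory=list)  # (K, value, converged)
    seed: int | None = None
    flags: list = field(default_factory=list)

    @property
    def best_value(self) -> float:
        return max(v for _, v, _ in self.restarts)


def plug_in_objective(
    x: np.ndarray,
    counts: np.ndarray,
    objective: str,
    n_bins: int,
    scheme: str = "equal-occupancy",
) -> tuple[float, dict]:
    """Evaluate a plug-in information objective on projected data.

    Returns ``(value_bits_per_spike, components)`` where components holds the
    decomposition (i_ss/i_0 for 'bernoulli', per-count terms for 'count').
    """
    bins = build_bins(x, n_bins, scheme)
    dens = estimate_densities(x, counts, bins)
    if objective == "poisson":
        v = single_spike_info(dens)
        return v, {"i_ss": v}
    if objective == "bernoulli":
        rep = bernoulli_info(dens)
        return rep.i_ber, {"i_ss": rep.i_ss, "i_0": rep.i_0, "i_ber": rep.i_ber}
    if objective == "count":
        rep = count_info(dens)
        return rep.i_count, {"i_count": rep.i_count, "i_by_count": rep.i_by_count}
    raise ValueError(f"unknown objective: {objective!r}")


class MaximallyInformativeDimensions(TransformerMixin, BaseEstimator):
    """Subspace estimator maximizing plug-in information (bits/spike).

    Parameters
    ----------
    n_filters : int, default=1
        Number of filters p (histogram objectives are practical for p <= 3:
        the bin count grows as ``n_bins ** p``).
    objective : {'poisson', 'bernoulli', 'count'}, default='poisson'
        Information objective; 'bernoulli' requires binary responses.
    n_bins : int, default=15
        Histogram bins per filter axis — the capacity of the implied
        piecewise-constant nonlinearity.  Data-dependent; sweep it with
        :func:`cross_validate_bins`.
    binning : {'equal-occupancy', 'equal-width'}, default='equal-occupancy'
        Bin-edge placement (quantile edges stabilize the density ratio's
        denominator in sparsely sampled tails).
    method : {'auto', 'grid', 'nelder-mead'}, default='auto'
        'grid' (exhaustive angles; only for D=2, p=1) or multi-restart
        Nelder-Mead.  'auto' picks 'grid' when applicable.
    grid_step_deg : float, default=1.0
        Angle spacing for the exhaustive grid.
    n_restarts : int, default=10
        Nelder-Mead restarts (the first starts at the STA/STC subspace).
    bin_width : float, default=1.0
        Time-bin width Δ in seconds for rate bookkeeping.
    tol : float, default=1e-10
        Plateau tolerance in bits for tie-breaking and the flat-objective
        diagnostic.
    random_state : int or None
        Seed for restart initialization.

    Attributes
    ----------
    filters_ : ndarray (D, p)
        Orthonormal, sign-normalized filter estimate.
    info_ : float
        Objective value at the optimum, bits/spike.
    components_ : dict
        Decomposition of the objective at the optimum.
    trace_ : FitTrace
        Per-restart values, convergence flags and diagnostics.
    """

    def __init__(
        self,
        n_filters: int = 1,
        objective: str = "poisson",
        n_bins: int = 15,
        binning: str = "equal-occupancy",
        method: str = "auto",
        grid_step_deg: float = 1.0,
        n_restarts: int = 10,
        max_iter: int = 2000,
        bin_width: float = 1.0,
        tol: float = 1e-10,
        random_state: int | None = None,
    ):
        self.n_filters = n_filters
        self.objective = objective
        self.n_bins = n_bins
        self.binning = binning
        self.method = method
        self.grid_step_deg = grid_step_deg
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.bin_width = bin_width
        self.tol = tol
        self.random_state = random_state

    # -- objective plumbing -------------------------------------------------

    def _value(self, S, r, K):
        x = S @ K
        if K.shape[1] == 1:
            x = x.ravel()
        return plug_in_objective(x, r, self.objective, self.n_bins, self.binning)

    def _sta_stc_init(self, S, r):
        """Spike-triggered average plus leading spike-triggered-covariance axes."""
        w = r.astype(float)
        if w.sum() == 0:
            return np.eye(S.shape[1])[:, : self.n_filters]
        mu = S.mean(axis=0)
        sta = (S * w[:, None]).sum(axis=0) / w.sum() - mu
        cols = [sta] if np.linalg.norm(sta) > 1e-12 else []
        if len(cols) < self.n_filters:
            Sc = S - mu
            cov_all = Sc.T @ Sc / len(S)
            Ss = Sc * np.sqrt(w)[:, None]
            cov_spk = Ss.T @ Ss / w.sum()
            dcov = cov_spk - cov_all
            eigval, eigvec = np.linalg.eigh(dcov)
            order = np.argsort(-np.abs(eigval))
            for i in order:
                cols.append(eigvec[:, i])
                if len(cols) >= self.n_filters:
                    break
        K0 = np.column_stack(cols[: self.n_filters])
        return orthonormalize(K0)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        S, r = validate_data(self, X, y, dtype=float)
        r = np.asarray(r)
        if not np.issubdtype(r.dtype, np.integer):
            if not np.allclose(r, np.round(r)):
                raise ValueError("responses must be integer spike counts")
            r = np.round(r).astype(np.int64)
        if (r < 0).any():
            raise ValueError("responses must be non-negative")
        if self.objective == "bernoulli" and r.max(initial=0) > 1:
            raise ValueError(
                "objective='bernoulli' requires binary responses; "
                "use objective='count' for general counts"
            )
        D, p = S.shape[1], self.n_filters
        if p > D:
            raise ValueError("n_filters cannot exceed the stimulus dimension")
        method = self.method
        if method == "auto":
            method = "grid" if (D == 2 and p == 1) else "nelder-mead"
        if method == "grid" and (D != 2 or p != 1):
            raise ValueError("grid search requires a 2-D stimulus space and one filter")
        trace = FitTrace(seed=self.random_state)
        if method == "grid":
            angles = np.arange(0.0, 180.0, self.grid_step_deg)
            values = np.empty_like(angles)
            for i, a in enumerate(angles):
                K = np.array([[np.cos(np.deg2rad(a))], [np.sin(np.deg2rad(a))]])
                values[i], _ = self._value(S, r, K)
            # ties within tol resolve to the smallest angle (argmax is first-hit)
            best = int(np.argmax(values))
            a = angles[best]
            K_best = np.array([[np.cos(np.deg2rad(a))], [np.sin(np.deg2rad(a))]])
            trace.restarts.append((K_best, float(values[best]), True))
            if values.max() - values.min() < self.tol:
                trace.flags.append("no informative direction")
            self.angle_grid_ = angles
            self.angle_values_ = values
        else:
            rng = np.random.default_rng(self.random_state)
            inits = [self._sta_stc_init(S, r)]
            for _ in range(self.n_restarts - 1):
                inits.append(orthonormalize(rng.standard_normal((D, p))))

            def neg(theta):
                K = orthonormalize(theta.reshape(D, p))
                v, _ = self._value(S, r, K)
                return -v

            for K0 in inits:
                res = minimize(
                    neg,
                    K0.ravel(),
                    method="Nelder-Mead",
                    options={"maxiter": self.max_iter, "xatol": 1e-6, "fatol": 1e-12},
                )
                K_end = orthonormalize(res.x.reshape(D, p))
                trace.restarts.append((K_end, float(-res.fun), bool(res.success)))
            values = np.array([v for _, v, _ in trace.restarts])
            K_best = trace.restarts[int(np.argmax(values))][0]
            if not any(c for _, _, c in trace.restarts):
                trace.flags.append("non-convergence: best-so-far returned")
            if values.max() - values.min() < self.tol and len(values) > 1:
                trace.flags.append("no informative direction")
        self.filters_ = orthonormalize(K_best)
        self.info_, self.components_ = self._value(S, r, self.filters_)
        self.trace_ = trace
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        return X @ self.filters_

    def score(self, X, y):
        """Plug-in objective (bits/spike) of the fitted filters on (X, y)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        v, _ = self._value(X, np.asarray(y), self.filters_)
        return v

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


def fit_subspace(dataset: Dataset, objective="poisson", n_filters=1, **kwargs):
    """Functional wrapper: fit a subspace on a :class:`Dataset`.

    Returns ``(filters, trace)`` from a fitted
    :class:`MaximallyInformativeDimensions`.
    """
    est = MaximallyInformativeDimensions(
        n_filters=n_filters, objective=objective, bin_width=dataset.bin_width, **kwargs
    )
    est.fit(dataset.stimuli, dataset.counts)
    return est.filters_, est.trace_


def info_curve(
    dataset: Dataset,
    objective: str = "poisson",
    angles_deg=None,
    n_bins: int = 15,
    scheme: str = "equal-occupancy",
) -> pd.DataFrame:
    """Objective value versus projection angle for a 2-D stimulus space.

    Projects onto (cos ψ, sin ψ) for each angle ψ and evaluates the plug-in
    objective with its decomposition (spike/silence or per-count components).
    """
    if dataset.n_dim != 2:
        raise ValueError("info_curve requires a 2-D stimulus space")
    if angles_deg is None:
        angles_deg = np.arange(0.0, 180.0, 1.0)
    rows = []
    for a in np.asarray(angles_deg, dtype=float):
        k = np.array([[np.cos(np.deg2rad(a))], [np.sin(np.deg2rad(a))]])
        v, comp = plug_in_objective(
            (dataset.stimuli @ k).ravel(), dataset.counts, objective, n_bins, scheme
        )
        row = {"angle_deg": a, "value": v}
        for key, val in comp.items():
            if np.ndim(val) == 0:
                row[key] = val
        rows.append(row)
    return pd.DataFrame(rows)


def held_out_single_spike_info(
    filters: np.ndarray,
    train: Dataset,
    test: Dataset,
    n_bins: int = 15,
    scheme: str = "equal-occupancy",
    floor: float = 0.5,
) -> float:
    """Cross-validated single-spike information of a filter estimate, bits/spike.

    Fits the piecewise-constant rate on the training set, evaluates the
    Poisson log-likelihood of the test responses under it, and subtracts the
    test-set homogeneous-rate log-likelihood, per test spike.  Bins that are
    empty in training but visited by spiking test stimuli get a pseudocount
    floor of ``floor`` spikes (held-out evaluation only; training plug-ins are
    never smoothed).  Can be negative for a poor model.
    """
    K = np.atleast_2d(filters)
    x_tr = train.stimuli @ K
    x_te = test.stimuli @ K
    if K.shape[1] == 1:
        x_tr, x_te = x_tr.ravel(), x_te.ravel()
    bins = build_bins(x_tr, n_bins, scheme)
    dens = estimate_densities(x_tr, train.counts, bins)
    rate = ml_rate(dens, train.bin_width)
    lam_te = rate(x_te)
    idx = bins.assign(x_te)
    occupancy = np.maximum(dens.n_i[idx], 1)
    bad = (lam_te <= 0) & (test.counts > 0)
    lam_te = np.where(bad, floor / (occupancy * train.bin_width), lam_te)
    ll_model = lnp_loglik(lam_te, test.counts, test.bin_width).value
    ll_null = lnp_null_loglik(test.counts, test.bin_width).value
    return (ll_model - ll_null) / test.n_spikes / _LN2


def cross_validate_bins(
    dataset: Dataset,
    n_bins_grid,
    objective: str = "poisson",
    n_filters: int = 1,
    train_fraction: float = 0.8,
    random_state: int | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Sweep the histogram bin count and report held-out information.

    Splits the data (default 80/20), fits the subspace at each bin count on
    the training part, and scores held-out single-spike information of the
    fitted filters.  Returns a table (n_bins, train_info, test_info).
    """
    rng = np.random.default_rng(random_state)
    N = dataset.n_samples
    perm = rng.permutation(N)
    n_tr = int(round(train_fraction * N))
    tr, te = perm[:n_tr], perm[n_tr:]
    d_tr = make_dataset(dataset.stimuli[tr], dataset.counts[tr], dataset.bin_width)
    d_te = make_dataset(dataset.stimuli[te], dataset.counts[te], dataset.bin_width)
    rows = []
    for m in n_bins_grid:
        est = MaximallyInformativeDimensions(
            n_filters=n_filters,
            objective=objective,
            n_bins=int(m),
            bin_width=dataset.bin_width,
            random_state=random_state,
            **fit_kwargs,
        )
        est.fit(d_tr.stimuli, d_tr.counts)
        rows.append(
            {
                "n_bins": int(m),
                "train_info": est.info_,
                "test_info": held_out_single_spike_info(
                    est.filters_, d_tr, d_te, n_bins=int(m)
                ),
            }
        )
    return pd.DataFrame(rows)
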