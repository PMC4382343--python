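"""Cylindrical basis functions (CBFs) and analytic likelihood derivatives.

The many-filter LNP nonlinearity is parametrized as

    λ = f(x) = g( Σ_i α_i φ_i(x) ),    x = K^T s,

where each first-order atom φ(x) = exp(−(x_a − μ)²/(2σ²)) is a Gaussian bump
along one projected axis (constant along the others), a second-order atom is
a Gaussian bump in a pair of axes, and the output nonlinearity g (softplus by
default, optionally exp) keeps the rate positive.  With d atoms per axis a
first-order basis needs p·d weights — linear, not exponential, in the number
of filters — which is what makes joint ML estimation of many filters
tractable.  A full d-per-axis RBF grid over all p axes (``order=2`` covers
the pairwise case) needs d^p weights; for p = 1 the two parametrizations
coincide.

The log-likelihood used for fitting is the Poisson form without the
parameter-free Σ log r_t! constant:

    ℒ(θ) = r^T log λ − Δ·1^T λ.

This module supplies ℒ together with its exact gradient and Hessian over
{K, α}, assembled from the chain rule through u = Φα and λ = g(u):

    ∂ℒ/∂θ  = J_u^T [ g′(u) ∘ (r/λ − Δ) ],
    ∂²ℒ/∂θ² = J_u^T diag(w₂) J_u + Σ_t w₁_t ∂²u_t/∂θ²,
    w₁ = g′(u) ∘ (r/λ − Δ),   w₂ = g″(u) ∘ (r/λ − Δ) − g′(u)² ∘ (r/λ²),

with J_u the Jacobian of u in (vec K, α).  Correctness is pinned by
finite-difference tests rather than by typography.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihoods import LogLik

__all__ = [
    "BasisAtom",
    "BasisSpec",
    "default_basis",
    "eval_basis",
    "output_nonlinearity",
    "cbf_lnp_rate",
    "cbf_lnp_loglik_grad_hess",
]


@dataclass(frozen=True)
class BasisAtom:
    """One Gaussian bump: ``dims`` it acts on (1 or 2), centers, shared width."""

    dims: tuple
    centers: tuple
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if len(self.dims) not in (1, 2) or len(self.dims) != len(self.centers):
            raise ValueError("an atom acts on 1 or 2 dimensions with matching centers")


@dataclass(frozen=True)
class BasisSpec:
    """An ordered collection of basis atoms plus the output nonlinearity g."""

    atoms: tuple
    output: str = "softplus"  # or "exponential"

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_dims(self) -> int:
        return 1 + max(d for a in self.atoms for d in a.dims)


def default_basis(
    n_filters: int,
    n_per_axis: int,
    x: np.ndarray,
    order: int = 1,
    output: str = "softplus",
) -> BasisSpec:
    """Quantile-placed basis over the projected training values.

    First-order: ``n_filters * n_per_axis`` atoms with centers at the
    per-axis quantiles of ``x`` and width equal to the spacing between
    adjacent centers.  Second-order: an ``n_per_axis²`` grid per axis pair.
    Quantile placement makes the basis invariant to the scale of the
    projections (which is arbitrary up to the filter normalization).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] != n_filters:
        raise ValueError("projected values must have one column per filter")
    if n_per_axis < 1:
        raise ValueError("need at least one basis atom per axis")
    qs = (np.arange(n_per_axis) + 0.5) / n_per_axis
    centers, sigmas = [], []
    for a in range(n_filters):
        col = x[:, a]
        if np.ptp(col) == 0:
            raise ValueError(f"projected axis {a} has zero variance")
        c = np.quantile(col, qs)
        spacing = np.diff(c).mean() if n_per_axis > 1 else np.std(col)
        if spacing <= 0:
            spacing = max(np.std(col), 1e-6)
        centers.append(c)
        sigmas.append(spacing)
    atoms = []
    if order == 1:
        for a in range(n_filters):
            for mu in centers[a]:
                atoms.append(BasisAtom((a,), (float(mu),), float(sigmas[a])))
    elif order == 2:
        for a in range(n_filters):
            for b in range(a + 1, n_filters):
                sig = float(np.sqrt(sigmas[a] * sigmas[b]))
                for mu_a in centers[a]:
                    for mu_b in centers[b]:
                        atoms.append(
                            BasisAtom((a, b), (float(mu_a), float(mu_b)), sig)
                        )
        if n_filters == 1:
            for mu in centers[0]:
                atoms.append(BasisAtom((0,), (float(mu),), float(sigmas[0])))
    else:
        raise ValueError("order must be 1 or 2")
    return BasisSpec(tuple(atoms), output)


def eval_basis(basis: BasisSpec, x: np.ndarray, derivatives: bool = True):
    """Evaluate Φ and its input-derivatives at projected points.

    Returns ``(Phi, dPhi, d2Phi)`` where ``Phi`` is (N, n_φ); ``dPhi`` is a
    (p, N, n_φ) array of ∂Φ/∂x_i; ``d2Phi`` maps the pair (i, j) with i ≤ j
    to the (N, n_φ) array of second derivatives.  With ``derivatives=False``
    the latter two are None.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    N, p = x.shape
    n_phi = basis.n_atoms
    Phi = np.empty((N, n_phi))
    dPhi = np.zeros((p, N, n_phi)) if derivatives else None
    d2Phi = {} if derivatives else None
    for k, atom in enumerate(basis.atoms):
        s2 = atom.sigma**2
        z = sum(
            (x[:, d] - mu) ** 2 for d, mu in zip(atom.dims, atom.centers)
        )
        phi = np.exp(-z / (2 * s2))
        Phi[:, k] = phi
        if not derivatives:
            continue
        for d, mu in zip(atom.dims, atom.centers):
            dPhi[d, :, k] = phi * (-(x[:, d] - mu) / s2)
        for ai, (di, mi) in enumerate(zip(atom.dims, atom.centers)):
            for dj, mj in list(zip(atom.dims, atom.centers))[ai:]:
                lo, hi = min(di, dj), max(di, dj)
                arr = d2Phi.setdefault((lo, hi), np.zeros((N, n_phi)))
                if di == dj:
                    arr[:, k] = phi * ((x[:, di] - mi) ** 2 / s2**2 - 1.0 / s2)
                else:
                    arr[:, k] = (
                        phi * ((x[:, di] - mi) / s2) * ((x[:, dj] - mj) / s2)
                    )
    return Phi, dPhi, d2Phi


def output_nonlinearity(name: str):
    """Return (g, g', g'') callables for a named output nonlinearity."""
    if name == "softplus":

        def g(u):
            return np.logaddexp(0.0, u)

        def g1(u):
            return 1.0 / (1.0 + np.exp(-u))

        def g2(u):
            s = g1(u)
            return s * (1.0 - s)

        return g, g1, g2
    if name == "exponential":
        return np.exp, np.exp, np.exp
    raise ValueError(f"unknown output nonlinearity: {name!r}")


def cbf_lnp_rate(K, alpha, basis: BasisSpec, S) -> np.ndarray:
    """Spike rate λ_t = g(Σ α_i φ_i(K^T s_t)) at each stimulus, spikes/s."""
    x = S @ np.atleast_2d(K)
    Phi, _, _ = eval_basis(basis, x, derivatives=False)
    g, _, _ = output_nonlinearity(basis.output)
    return g(Phi @ np.asarray(alpha, float))


def cbf_lnp_loglik_grad_hess(
    K,
    alpha,
    basis: BasisSpec,
    S,
    counts,
    bin_width: float,
    hessian: bool = True,
):
    """ℒ(θ) = r^T log λ − Δ 1^T λ with exact gradient and Hessian over {K, α}.

    Parameter order is (vec K column-major: k_1 then k_2 ..., then α).
    Returns ``(LogLik, grad, hess)``; ``hess`` is None unless requested.
    The Σ log r_t! constant is omitted (parameter-free).  A non-finite rate
    raises with the offending sample index.
    """
    K = np.atleast_2d(np.asarray(K, float))
    alpha = np.asarray(alpha, float)
    S = np.asarray(S, float)
    r = np.asarray(counts, float)
    D, p = K.shape
    N = S.shape[0]
    x = S @ K
    Phi, dPhi, d2Phi = eval_basis(basis, x)
    u = Phi @ alpha
    g, g1, g2 = output_nonlinearity(basis.output)
    lam, lam1, lam2 = g(u), g1(u), g2(u)
    if not np.all(np.isfinite(lam)):
        bad = int(np.argmin(np.isfinite(lam)))
        raise FloatingPointError(f"non-finite rate at sample {bad}")
    spiking = r > 0
    if (lam[spiking] <= 0).any():
        value = -np.inf
    else:
        with np.errstate(divide="ignore"):
            log_lam = np.where(spiking, np.log(np.where(spiking, lam, 1.0)), 0.0)
        value = float(r @ log_lam - bin_width * lam.sum())
    ll = LogLik(value, N, int(r.sum()), "cbf-lnp")

    # residual-like weights; guard 0/0 where lam=0 and r=0
    lam_safe = np.where(lam > 0, lam, 1.0)
    resid = r / lam_safe - bin_width  # r/λ − Δ
    w1 = lam1 * resid
    # Jacobian of u in (vec K | α): filter block columns are (Φ^(i)α) ∘ s_d
    proj_deriv = np.stack([dPhi[i] @ alpha for i in range(p)])  # (p, N)
    n_par = D * p + len(alpha)
    grad = np.empty(n_par)
    for i in range(p):
        grad[i * D : (i + 1) * D] = S.T @ (w1 * proj_deriv[i])
    grad[D * p :] = Phi.T @ w1

    H = None
    if hessian:
        w2 = lam2 * resid - lam1**2 * (r / lam_safe**2)
        J = np.empty((N, n_par))
        for i in range(p):
            J[:, i * D : (i + 1) * D] = S * proj_deriv[i][:, None]
        J[:, D * p :] = Phi
        H = (J * w2[:, None]).T @ J
        # curvature of u itself: zero in α-α, S^T diag(w1·Φ^{(i,j)}α) S in k-k,
        # and S^T diag(w1) Φ^{(i)} in k-α
        for i in range(p):
            for j in range(i, p):
                lo, hi = (i, j)
                block = d2Phi.get((lo, hi))
                if block is not None:
                    cross = S.T @ (S * (w1 * (block @ alpha))[:, None])
                    H[i * D : (i + 1) * D, j * D : (j + 1) * D] += cross
                    if i != j:
                        H[j * D : (j + 1) * D, i * D : (i + 1) * D] += cross.T
            mixed = S.T @ ((w1[:, None] * dPhi[i]))
            H[i * D : (i + 1) * D, D * p :] += mixed
            H[D * p :, i * D : (i + 1) * D] += mixed.T
    return ll, grad, H
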