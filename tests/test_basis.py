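import numpy as np
import pytest

from spikemid.basis import (
    BasisAtom,
    cbf_lnp_loglik_grad_hess,
    cbf_lnp_rate,
    default_basis,
    eval_basis,
    output_nonlinearity,
)
from spikemid.data import orthonormalize


def _random_problem(seed, D=3, p=2, N=60, output="softplus"):
    rng = np.random.default_rng(seed)
    S = rng.standard_normal((N, D))
    K = orthonormalize(rng.standard_normal((D, p)))
    basis = default_basis(p, 3, S @ K, order=1, output=output)
    alpha = rng.normal(scale=0.6, size=basis.n_atoms)
    r = rng.poisson(1.0, size=N)
    return S, K, alpha, basis, r


class TestDefaultBasis:
    def test_first_order_atom_count_is_linear_in_filters(self, rng):
        x = rng.standard_normal((500, 8))
        basis = default_basis(8, 3, x, order=1)
        assert basis.n_atoms == 24  # p*d parameters, not d**p

    def test_second_order_pair_grid(self, rng):
        x = rng.standard_normal((500, 2))
        basis = default_basis(2, 3, x, order=2)
        assert basis.n_atoms == 9  # d^2 for the single pair

    def test_one_filter_orders_coincide(self, rng):
        x = rng.standard_normal(500)
        b1 = default_basis(1, 3, x, order=1)
        b2 = default_basis(1, 3, x, order=2)
        assert b1.atoms == b2.atoms

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            default_basis(1, 3, np.zeros(100))

    def test_invalid_atom(self):
        with pytest.raises(ValueError):
            BasisAtom((0,), (0.0,), -1.0)


class TestEvalBasis:
    def test_gaussian_bump_values(self, rng):
        x = rng.standard_normal(200)
        basis = default_basis(1, 3, x, order=1)
        atom = basis.atoms[1]
        at_center = np.array([atom.centers[0]])
        Phi, dPhi, _ = eval_basis(basis, at_center)
        assert Phi[0, 1] == pytest.approx(1.0)
        assert dPhi[0][0, 1] == pytest.approx(0.0, abs=1e-12)
        one_sigma = np.array([atom.centers[0] + atom.sigma])
        Phi2, _, _ = eval_basis(basis, one_sigma)
        assert Phi2[0, 1] == pytest.approx(np.exp(-0.5))

    @pytest.mark.parametrize("order", [1, 2])
    def test_derivatives_match_finite_differences(self, rng, order):
        x = rng.standard_normal((30, 2))
        basis = default_basis(2, 3, x, order=order)
        pts = rng.standard_normal((5, 2))
        Phi, dPhi, d2Phi = eval_basis(basis, pts)
        eps = 1e-6
        for d in range(2):
            e = np.zeros(2)
            e[d] = eps
            fd = (
                eval_basis(basis, pts + e, derivatives=False)[0]
                - eval_basis(basis, pts - e, derivatives=False)[0]
            ) / (2 * eps)
            assert np.allclose(dPhi[d], fd, rtol=1e-6, atol=1e-8)
        eps = 1e-4  # larger step: 4-point stencils lose ~eps^-2 in roundoff
        for (i, j), block in d2Phi.items():
            ei = np.zeros(2); ei[i] = eps
            ej = np.zeros(2); ej[j] = eps
            fd2 = (
                eval_basis(basis, pts + ei + ej, derivatives=False)[0]
                - eval_basis(basis, pts + ei - ej, derivatives=False)[0]
                - eval_basis(basis, pts - ei + ej, derivatives=False)[0]
                + eval_basis(basis, pts - ei - ej, derivatives=False)[0]
            ) / (4 * eps**2)
            assert np.allclose(block, fd2, rtol=1e-4, atol=1e-6)


class TestLoglikDerivatives:
    @pytest.mark.parametrize("output", ["softplus", "exponential"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_and_hessian_match_finite_differences(self, seed, output):
        S, K, alpha, basis, r = _random_problem(seed, output=output)
        D, p = K.shape
        theta = np.concatenate([K.ravel(order="F"), alpha])

        def value(t):
            Kt = t[: D * p].reshape(D, p, order="F")
            return cbf_lnp_loglik_grad_hess(
                Kt, t[D * p :], basis, S, r, 0.1, hessian=False
            )[0].value

        def grad(t):
            Kt = t[: D * p].reshape(D, p, order="F")
            return cbf_lnp_loglik_grad_hess(
                Kt, t[D * p :], basis, S, r, 0.1, hessian=False
            )[1]

        _, g, H = cbf_lnp_loglik_grad_hess(K, alpha, basis, S, r, 0.1)
        eps = 1e-6
        eye = np.eye(len(theta))
        g_fd = np.array(
            [(value(theta + eps * e) - value(theta - eps * e)) / (2 * eps) for e in eye]
        )
        scale = max(np.abs(g_fd).max(), 1.0)
        assert np.abs(g - g_fd).max() / scale < 1e-5
        H_fd = np.array(
            [(grad(theta + eps * e) - grad(theta - eps * e)) / (2 * eps) for e in eye]
        )
        hscale = max(np.abs(H_fd).max(), 1.0)
        assert np.abs(H - H_fd).max() / hscale < 1e-4
        assert np.allclose(H, H.T, atol=1e-10)

    def test_zero_weights_give_zero_filter_gradient_softplus(self, rng):
        S, K, _, basis, r = _random_problem(3)
        alpha = np.zeros(basis.n_atoms)
        _, g, _ = cbf_lnp_loglik_grad_hess(K, alpha, basis, S, r, 0.1)
        D, p = K.shape
        assert np.allclose(g[: D * p], 0.0, atol=1e-12)
        lam = cbf_lnp_rate(K, alpha, basis, S)
        assert np.allclose(lam, np.log(2.0))  # softplus(0)

    def test_alpha_block_concave_at_optimum(self, rng):
        # with K fixed and g convex log-concave, the alpha subproblem is concave
        S, K, alpha, basis, r = _random_problem(4)
        D, p = K.shape
        n_a = basis.n_atoms
        _, _, H = cbf_lnp_loglik_grad_hess(K, alpha, basis, S, r, 0.1)
        Ha = H[D * p :, D * p :]
        eig = np.linalg.eigvalsh(Ha)
        assert eig.max() <= 1e-8

    def test_exponential_output_is_multiplicatively_separable(self, rng):
        # first-order basis with g=exp factorizes across axes
        x = rng.standard_normal((100, 2))
        basis = default_basis(2, 3, x, order=1, output="exponential")
        alpha = rng.normal(scale=0.5, size=basis.n_atoms)
        g = output_nonlinearity("exponential")[0]

        def f(pt):
            Phi, _, _ = eval_basis(basis, pt[None, :], derivatives=False)
            return g(Phi @ alpha)[0]

        a, b = rng.standard_normal(2), rng.standard_normal(2)
        lhs = f(np.array([a[0], a[1]])) * f(np.array([b[0], b[1]]))
        rhs = f(np.array([a[0], b[1]])) * f(np.array([b[0], a[1]]))
        assert lhs == pytest.approx(rhs, rel=1e-10)
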