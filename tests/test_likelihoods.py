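import numpy as np
import pytest
from scipy import stats

import spikemid as sm
from spikemid.histograms import build_bins, estimate_densities, ml_count_probs, ml_rate
from spikemid.likelihoods import (
    lnb_loglik,
    lnb_null_loglik,
    lnc_loglik,
    lnc_null_loglik,
    lnp_loglik,
    lnp_null_loglik,
    response_entropy,
)

from conftest import random_count_dataset

LN2 = np.log(2.0)


class TestPoissonLoglik:
    def test_single_bin_values(self):
        assert lnp_loglik([100.0], [0], 0.01).value == pytest.approx(-1.0)
        assert lnp_loglik([100.0], [2], 0.01).value == pytest.approx(-1.0 - np.log(2))

    def test_matches_scipy_pmf_sum(self, rng):
        lam = rng.uniform(0.5, 5.0, 30)
        r = rng.poisson(lam * 0.1)
        ll = lnp_loglik(lam, r, 0.1).value
        assert ll == pytest.approx(stats.poisson.logpmf(r, lam * 0.1).sum())

    def test_zero_rate_with_spike_is_impossible(self):
        assert lnp_loglik([0.0, 1.0], [1, 0], 1.0).value == -np.inf

    def test_null_closed_form(self):
        assert lnp_null_loglik([1, 1], 1.0).value == pytest.approx(-2.0)
        assert lnp_null_loglik([0, 0], 1.0).value == pytest.approx(0.0)

    def test_null_equals_loglik_at_mean_rate(self, rng):
        r = rng.poisson(1.3, 40)
        lbar = r.sum() / (40 * 0.2)
        assert lnp_null_loglik(r, 0.2).value == pytest.approx(
            lnp_loglik(np.full(40, lbar), r, 0.2).value
        )


class TestBernoulliLoglik:
    def test_fair_coin(self):
        r = np.array([0, 1, 1, 0, 1])
        assert lnb_loglik(np.full(5, 0.5), r).value == pytest.approx(-5 * np.log(2))

    def test_perfect_prediction_is_certain(self):
        r = np.array([0, 1, 1, 0])
        assert lnb_loglik(r.astype(float), r).value == 0.0

    def test_matches_scipy_pmf_sum(self, rng):
        p = rng.uniform(0.05, 0.95, 25)
        r = (rng.uniform(size=25) < p).astype(int)
        assert lnb_loglik(p, r).value == pytest.approx(
            stats.bernoulli.logpmf(r, p).sum()
        )

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            lnb_loglik([0.5, 0.5], [0, 2])


class TestCountLoglik:
    def test_certain_prediction(self):
        probs = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 0.0]])
        assert lnc_loglik(probs, [1, 0]).value == 0.0

    def test_uniform_over_three_counts(self):
        probs = np.full((3, 7), 1 / 3)
        assert lnc_loglik(probs, [0, 1, 2, 0, 1, 2, 0]).value == pytest.approx(
            -7 * np.log(3)
        )

    def test_plug_in_fit_matches_cell_tally(self):
        x, r, _ = random_count_dataset(11, family="lnc")
        dens = estimate_densities(x, r, build_bins(x, 5))
        probs = ml_count_probs(dens)(x)
        ll = lnc_loglik(probs, r).value
        expected = sum(
            dens.n_i_by_count[j, i] * np.log(dens.n_i_by_count[j, i] / dens.n_i[i])
            for j in range(dens.r_max + 1)
            for i in range(dens.partition.n_bins)
            if dens.n_i_by_count[j, i] > 0
        )
        assert ll == pytest.approx(expected)


class TestResponseEntropy:
    def test_balanced_binary_is_ln2(self):
        assert response_entropy([0, 1, 0, 1], "bernoulli") == pytest.approx(np.log(2))

    def test_constant_counts_have_zero_entropy(self):
        assert response_entropy([2, 2, 2], "count") == 0.0

    def test_three_outcome_oracle(self):
        counts = [0] * 2 + [1] * 1 + [2] * 1
        assert response_entropy(counts, "count") == pytest.approx(1.5 * np.log(2))


class TestEquivalenceIdentities:
    """The exact information-loglik identities on random data, all regimes."""

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("m", [3, 10])
    def test_poisson_identity(self, seed, m):
        x, r, _ = random_count_dataset(seed, family="lnp")
        dens = estimate_densities(x, r, build_bins(x, m))
        rate = ml_rate(dens, 0.02)
        lhs = sm.single_spike_info(dens) * LN2 * r.sum()
        rhs = lnp_loglik(rate(x), r, 0.02).value - lnp_null_loglik(r, 0.02).value
        assert lhs == pytest.approx(rhs, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_bernoulli_identity(self, seed):
        x, r, _ = random_count_dataset(seed, family="lnb")
        dens = estimate_densities(x, r, build_bins(x, 8))
        probs = ml_count_probs(dens)(x)
        lhs = sm.bernoulli_info(dens).i_ber * LN2 * r.sum()
        rhs = lnb_loglik(probs[1], r).value - lnb_null_loglik(r).value
        assert lhs == pytest.approx(rhs, abs=1e-9)
        # the null term is exactly -N * H[r]
        assert lnb_null_loglik(r).value == pytest.approx(
            -len(r) * response_entropy(r, "bernoulli")
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_count_identity(self, seed):
        x, r, _ = random_count_dataset(seed, family="lnc")
        dens = estimate_densities(x, r, build_bins(x, 8))
        probs = ml_count_probs(dens)(x)
        lhs = sm.count_info(dens).i_count * LN2 * r.sum()
        rhs = lnc_loglik(probs, r).value - lnc_null_loglik(r).value
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_identity_invariant_to_bin_width_and_size(self):
        # the Poisson identity holds for any bin width and sample count
        x, r, _ = random_count_dataset(20, family="lnp")
        for dt in (1e-3, 1.0, 10.0):
            dens = estimate_densities(x, r, build_bins(x, 6))
            rate = ml_rate(dens, dt)
            lhs = sm.single_spike_info(dens) * LN2 * r.sum()
            rhs = lnp_loglik(rate(x), r, dt).value - lnp_null_loglik(r, dt).value
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_information_and_likelihood_rank_angles_identically(self):
        # same argmax and identical ordering up to an additive constant
        ds = sm.simulate.sigmoid_bernoulli_2d(1500, seed=6)
        angles = np.arange(0, 180, 5.0)
        infos, logliks = [], []
        for a in angles:
            k = np.array([np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))])
            x = ds.stimuli @ k
            dens = estimate_densities(x, ds.counts, build_bins(x, 8))
            infos.append(sm.single_spike_info(dens))
            rate = ml_rate(dens, ds.bin_width)
            logliks.append(lnp_loglik(rate(x), ds.counts, ds.bin_width).value)
        infos, logliks = np.array(infos), np.array(logliks)
        assert np.array_equal(np.argsort(infos), np.argsort(logliks))
        shifted = infos * LN2 * ds.n_spikes
        assert np.allclose(shifted - shifted[0], logliks - logliks[0], atol=1e-8)
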