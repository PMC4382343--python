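import numpy as np
import pytest

import spikemid as sm
from spikemid.data import RepeatRaster
from spikemid.histograms import build_bins, estimate_densities, ml_count_probs
from spikemid.likelihoods import (
    lnb_loglik,
    lnb_null_loglik,
    lnp_loglik,
    lnp_null_loglik,
)

from conftest import random_count_dataset

LN2 = np.log(2.0)


def _densities(x, r, m=6):
    return estimate_densities(x, r, build_bins(x, m))


class TestSingleSpikeInfo:
    def test_zero_for_identical_distributions(self):
        x = np.array([0.1, 0.9, 0.2, 0.8])
        dens = _densities(x, np.array([1, 1, 1, 1]), m=2)
        assert sm.single_spike_info(dens) == pytest.approx(0.0, abs=1e-12)

    def test_direct_kl_oracle(self):
        # p = (1/2, 1/2), q = (3/4, 1/4): build 4 stimuli with 3 spikes left, 1 right
        x = np.array([0.1, 0.2, 0.8, 0.9])
        r = np.array([2, 1, 1, 0])
        dens = _densities(x, r, m=2)
        expected = 0.75 * np.log2(1.5) + 0.25 * np.log2(0.5)
        assert sm.single_spike_info(dens) == pytest.approx(expected)
        assert expected == pytest.approx(0.18872, abs=1e-4)

    def test_no_spikes_convention(self):
        dens = _densities(np.arange(4.0), np.zeros(4, int), m=2)
        with pytest.warns(UserWarning, match="no spikes"):
            assert sm.single_spike_info(dens) == 0.0


class TestSilenceAndBernoulli:
    def test_silences_like_raw_distribution_give_zero(self):
        x = np.array([0.1, 0.9, 0.2, 0.8])
        dens = _densities(x, np.array([1, 0, 0, 1]), m=1)
        assert sm.silence_info(dens) == pytest.approx(0.0, abs=1e-12)

    def test_kl_oracle_one_bit(self):
        # silences all left, spikes all right, half spiking
        x = np.array([0.1, 0.2, 0.8, 0.9])
        dens = _densities(x, np.array([0, 0, 1, 1]), m=2)
        assert sm.silence_info(dens) == pytest.approx(1.0)

    def test_rejects_non_binary(self):
        dens = _densities(np.arange(4.0), np.array([0, 2, 0, 1]), m=2)
        with pytest.raises(ValueError, match="count_info"):
            sm.silence_info(dens)

    @pytest.mark.parametrize("counts", [[1, 1, 1, 1], [0, 0, 0, 0]])
    def test_rejects_all_spikes_or_all_silences(self, counts):
        dens = _densities(np.arange(4.0), np.array(counts), m=2)
        with pytest.raises(ValueError):
            sm.silence_info(dens)

    def test_stimulus_independent_spiking_gives_zero(self):
        x = np.array([0.1, 0.9, 0.2, 0.8])
        dens = _densities(x, np.array([1, 1, 0, 0]), m=1)
        rep = sm.bernoulli_info(dens)
        assert rep.i_ber == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_binary_stimulus_two_bits(self):
        # spike iff right half; rho = 1/2 -> 2 bits/spike (1 bit MI / 0.5)
        x = np.tile([0.1, 0.9], 50)
        r = np.tile([0, 1], 50)
        rep = sm.bernoulli_info(_densities(x, r, m=2))
        assert rep.i_ber == pytest.approx(2.0)

    def test_additivity_exact(self, lnb_dataset):
        x = lnb_dataset.stimuli[:, 0]
        dens = _densities(x, lnb_dataset.counts, m=10)
        rep = sm.bernoulli_info(dens)
        assert rep.i_ber == rep.i_0 + rep.i_ss
        assert rep.i_0 > 0 and rep.i_ber > rep.i_ss

    def test_bernoulli_converges_to_single_spike_in_sparse_limit(self):
        # as spike fraction -> 0 the silence share of the total vanishes
        rng = np.random.default_rng(0)
        x = rng.standard_normal(60000)
        fractions = []
        for scale in (0.5, 0.1, 0.02):
            lam = scale / (1 + np.exp(-1.5 * x))
            r = (rng.uniform(size=len(x)) < lam).astype(int)
            rep = sm.bernoulli_info(_densities(x, r, m=10))
            fractions.append(rep.i_0 / rep.i_ber)
        assert fractions[0] > fractions[1] > fractions[2]
        assert fractions[2] < 0.02


class TestCountInfo:
    def test_stimulus_independent_counts_give_zero(self):
        x = np.tile([0.1, 0.9], 30)
        r = np.tile([0, 2, 1, 0, 2, 1], 10)
        rep = sm.count_info(_densities(x, r, m=1))
        assert rep.i_count == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_half_bit(self):
        # stimulus A -> 3 spikes, B -> 1 spike, equiprobable: MI 1 bit, rbar 2
        x = np.array([0.0, 1.0, 1.0, 0.0])
        r = np.array([3, 1, 1, 3])
        rep = sm.count_info(_densities(x, r, m=2))
        assert rep.i_count == pytest.approx(0.5)

    def test_reduces_to_bernoulli_on_binary(self, lnb_dataset):
        x = lnb_dataset.stimuli[:, 0]
        dens = _densities(x, lnb_dataset.counts, m=9)
        rep_b = sm.bernoulli_info(dens)
        rep_c = sm.count_info(dens)
        assert rep_c.i_count == pytest.approx(rep_b.i_ber, abs=1e-14)
        assert rep_c.i_count == pytest.approx(rep_c.i_by_count.sum())

    def test_brute_force_cell_sum_oracle(self):
        x, r, _ = random_count_dataset(5, family="lnc")
        dens = _densities(x, r, m=5)
        # direct evaluation of the defining sum over all (bin, count) cells
        N, n_sp = dens.n_samples, dens.n_spikes
        total = 0.0
        for j in range(dens.r_max + 1):
            for i in range(dens.partition.n_bins):
                nij = dens.n_i_by_count[j, i]
                if nij == 0:
                    continue
                qij = nij / dens.counts_by_j[j]
                total += (
                    dens.counts_by_j[j] / n_sp * qij * np.log2(qij / dens.p_hat[i])
                )
        assert sm.count_info(dens).i_count == pytest.approx(total)


class TestLnxInfo:
    def test_model_equals_null_gives_zero(self):
        assert sm.lnx_info_from_loglik(-10.0, -10.0, 5) == 0.0

    def test_histogram_ml_fit_recovers_scaled_information(self):
        x, r, _ = random_count_dataset(8, family="lnp")
        dens = _densities(x, r, m=6)
        from spikemid.histograms import ml_rate

        rate = ml_rate(dens, 0.05)
        ll = lnp_loglik(rate(x), r, 0.05).value
        ll0 = lnp_null_loglik(r, 0.05).value
        per_sample = sm.lnx_info_from_loglik(ll, ll0, len(r))
        expected = r.sum() / len(r) * sm.single_spike_info(dens)
        assert per_sample == pytest.approx(expected, abs=1e-12)

    def test_bernoulli_ml_fit_recovers_scaled_information(self):
        x, r, _ = random_count_dataset(4, family="lnb")
        dens = _densities(x, r, m=6)
        probs = ml_count_probs(dens)(x)
        ll = lnb_loglik(probs[1], r).value
        ll0 = lnb_null_loglik(r).value
        per_sample = sm.lnx_info_from_loglik(ll, ll0, len(r))
        expected = r.sum() / len(r) * sm.bernoulli_info(dens).i_ber
        assert per_sample == pytest.approx(expected, abs=1e-12)


class TestPsthInfo:
    def test_worked_example(self, worked_example):
        _, _, experiment = worked_example
        info = sm.psth_single_spike_info(experiment)
        assert info == pytest.approx(0.18872, abs=1e-4)
        assert round(info, 2) == 0.19

    def test_constant_psth_gives_zero(self):
        raster = RepeatRaster(np.full((5, 8), 2), 0.5)
        assert sm.psth_single_spike_info(raster) == pytest.approx(0.0, abs=1e-12)

    def test_identity_with_poisson_loglik_difference(self):
        raster = sm.simulate.frozen_noise_repeats([3.0, 1.0, 5.0, 2.0], 40, 0.5, seed=2)
        info = sm.psth_single_spike_info(raster)
        lam = np.repeat(raster.psth()[None, :], raster.n_repeats, axis=0).ravel()
        r = raster.counts.ravel()
        ll = lnp_loglik(lam, r, raster.bin_width).value
        ll0 = lnp_null_loglik(r, raster.bin_width).value
        assert info == pytest.approx((ll - ll0) / raster.n_spikes / LN2, abs=1e-10)


class TestXvalInfo:
    def test_training_psth_rate_reproduces_plug_in(self):
        raster = sm.simulate.frozen_noise_repeats([4.0, 1.0, 2.0], 30, 0.2, seed=9)
        xv = sm.xval_single_spike_info(raster.psth(), raster)
        assert xv == pytest.approx(sm.psth_single_spike_info(raster), abs=1e-12)

    def test_homogeneous_rate_gives_zero(self):
        raster = sm.simulate.frozen_noise_repeats([2.0, 2.0, 2.0], 20, 0.5, seed=1)
        lbar = raster.n_spikes / (raster.counts.size * raster.bin_width)
        assert sm.xval_single_spike_info(np.full(3, lbar), raster) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_anticorrelated_training_rate_is_negative(self):
        raster = sm.simulate.frozen_noise_repeats([5.0, 1.0], 50, 1.0, seed=4)
        swapped = raster.psth()[::-1]
        assert sm.xval_single_spike_info(swapped, raster) < 0


class TestEntropyDecomposition:
    def test_worked_example(self, worked_example):
        raster, labels, _ = worked_example
        prior, posterior = sm.stimulus_entropy_decomposition(raster, labels)
        assert prior == pytest.approx(1.0)
        assert posterior == pytest.approx(0.8113, abs=1e-4)
        assert prior - posterior == pytest.approx(0.18872, abs=1e-4)

    def test_identical_responses_leave_prior_uncertainty(self):
        raster = RepeatRaster(np.array([[2, 2], [2, 2]]), 1.0)
        prior, posterior = sm.stimulus_entropy_decomposition(raster, np.array([0, 1]))
        assert posterior == pytest.approx(prior)

    def test_fully_separating_responses_resolve_stimulus(self):
        raster = RepeatRaster(np.array([[4, 0], [0, 4]]), 1.0)
        prior, posterior = sm.stimulus_entropy_decomposition(raster, np.array([0, 1]))
        assert posterior == pytest.approx(0.0, abs=1e-12)


def test_unit_conversion_round_trip():
    rep = sm.InfoReport(i_ss=0.5, i_0=0.25, i_ber=0.75, unit="bits")
    nats = rep.in_unit("nats")
    assert nats.i_ss == pytest.approx(0.5 * LN2)
    back = nats.in_unit("bits")
    assert back.i_ss == pytest.approx(0.5)
    assert rep.in_unit("bits") is rep
    assert "bits" in rep.to_json()
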