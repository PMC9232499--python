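"""Circular-distribution fits, Akaike-weight comparison and pattern labels."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oncostream import (
    DistributionModel,
    HeadingSample,
    akaike_weights,
    angle_histogram,
    circular_kde,
    classify_pattern,
    fit_bimodal,
    fit_unimodal,
    loglik_uniform,
)
from oncostream.motion_classifier import KAPPA_MAX, bimodal_logpdf, vonmises_logpdf

from tests._oracles import grid_max_loglik, random_heading_sample

LOG_2PI = np.log(2 * np.pi)


def vm_sample(rng, mu, kappa, n):
    return HeadingSample(np.mod(rng.vonmises(mu, kappa, n), 2 * np.pi))


def stream_sample(rng, axis, kappa, n):
    lane = rng.integers(0, 2, n)
    return HeadingSample(
        np.mod(axis + np.pi * lane + rng.vonmises(0.0, kappa, n), 2 * np.pi)
    )


class TestUniform:
    @pytest.mark.parametrize("n", [1, 10])
    def test_closed_form(self, n, rng):
        s = HeadingSample(rng.uniform(0, 2 * np.pi, n))
        assert loglik_uniform(s).log_likelihood == pytest.approx(-n * LOG_2PI, abs=1e-12)

    def test_independent_of_angle_values(self, rng):
        a = HeadingSample(rng.uniform(0, 2 * np.pi, 50))
        b = HeadingSample(np.full(50, 1.234))
        assert loglik_uniform(a).log_likelihood == loglik_uniform(b).log_likelihood


class TestUnimodalFit:
    def test_antipodal_sample_collapses_to_uniform(self):
        s = HeadingSample([0.0, np.pi, 0.0, np.pi])
        fit = fit_unimodal(s)
        assert fit.kappa == 0.0
        assert fit.log_likelihood == pytest.approx(-4 * LOG_2PI, abs=1e-12)

    def test_identical_headings_clip_to_kappa_max(self):
        fit = fit_unimodal(HeadingSample(np.full(20, 1.0)))
        assert fit.kappa == KAPPA_MAX
        assert fit.kappa_clipped
        assert fit.mu == pytest.approx(1.0, abs=1e-9)

    def test_parameter_recovery_large_sample(self, rng):
        fit = fit_unimodal(vm_sample(rng, np.pi / 4, 4.0, 2000))
        dmu = np.angle(np.exp(1j * (fit.mu - np.pi / 4)))
        assert abs(dmu) < 0.05
        assert fit.kappa == pytest.approx(4.0, rel=0.10)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(6):
            th = random_heading_sample(rng, int(rng.integers(10, 51)))
            fit = fit_unimodal(HeadingSample(th))
            oracle = grid_max_loglik(th, "flock")
            assert fit.log_likelihood == pytest.approx(oracle, abs=1e-3)

    def test_requires_two_headings(self):
        with pytest.raises(ValueError):
            fit_unimodal(HeadingSample([0.5]))


class TestBimodalFit:
    def test_two_antipodal_points_clip_to_kappa_max(self):
        fit = fit_bimodal(HeadingSample([0.0, np.pi]))
        assert fit.kappa == pytest.approx(KAPPA_MAX)
        assert fit.kappa_clipped
        assert fit.mu == pytest.approx(0.0, abs=1e-6) or fit.mu == pytest.approx(
            np.pi, abs=1e-6
        )

    def test_uniform_sample_approaches_uniform_loglik(self, rng):
        th = rng.uniform(0, 2 * np.pi, 400)
        fit = fit_bimodal(HeadingSample(th))
        uni = -400 * LOG_2PI
        assert fit.log_likelihood >= uni - 1e-9  # nested model can't do worse
        assert fit.log_likelihood - uni < 5.0  # and overfits only mildly
        assert fit.kappa < 1.0

    def test_axis_recovery_large_sample(self, rng):
        fit = fit_bimodal(stream_sample(rng, np.pi / 3, 3.0, 2000))
        daxis = np.angle(np.exp(2j * (fit.mu - np.pi / 3))) / 2
        assert abs(daxis) < 0.05
        assert fit.kappa == pytest.approx(3.0, rel=0.10)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(6):
            th = random_heading_sample(rng, int(rng.integers(10, 51)))
            fit = fit_bimodal(HeadingSample(th))
            oracle = grid_max_loglik(th, "stream")
            assert fit.log_likelihood == pytest.approx(oracle, abs=1e-3)


class TestModelNesting:
    @given(seed=st.integers(0, 10_000))
    def test_kappa_zero_likelihoods_equal_uniform_exactly(self, seed):
        th = np.random.default_rng(seed).uniform(0, 2 * np.pi, 37)
        uni = -37 * LOG_2PI
        assert vonmises_logpdf(th, 1.0, 0.0).sum() == pytest.approx(uni, abs=1e-10)
        assert bimodal_logpdf(th, 1.0, 0.0).sum() == pytest.approx(uni, abs=1e-10)


class TestAkaikeWeights:
    @staticmethod
    def fits_with_aic(aics):
        # AIC = 2k - 2 logL; swarm has k=0, the others k=2
        ks = {"swarm": 0, "stream": 2, "flock": 2}
        return {
            fam: DistributionModel(fam, (2 * ks[fam] - a) / 2.0, ks[fam])
            for fam, a in zip(("swarm", "stream", "flock"), aics)
        }

    def test_equal_aic_gives_equal_thirds(self):
        pf = akaike_weights(self.fits_with_aic([100.0, 100.0, 100.0]))
        for w in pf.akaike_weights.values():
            assert w == pytest.approx(1 / 3, abs=1e-12)
        assert pf.label == "swarm"  # parsimony tie-break

    def test_closed_form_example(self):
        pf = akaike_weights(self.fits_with_aic([100.0, 110.0, 110.0]))
        assert pf.akaike_weights["swarm"] == pytest.approx(0.9867, abs=5e-5)
        assert pf.akaike_weights["stream"] == pytest.approx(0.0066, abs=5e-5)
        assert pf.akaike_weights["flock"] == pytest.approx(0.0066, abs=5e-5)

    @given(
        lls=st.lists(
            st.floats(-1e4, 0, allow_nan=False, allow_infinity=False),
            min_size=3,
            max_size=3,
        )
    )
    def test_weights_normalize_and_deltas_nonnegative(self, lls):
        fits = {
            fam: DistributionModel(fam, ll, k)
            for fam, ll, k in zip(("swarm", "stream", "flock"), lls, (0, 2, 2))
        }
        pf = akaike_weights(fits)
        assert sum(pf.akaike_weights.values()) == pytest.approx(1.0, abs=1e-12)
        assert min(pf.delta_aic.values()) == 0.0
        assert all(d >= 0 for d in pf.delta_aic.values())
        assert pf.label == max(pf.akaike_weights, key=pf.akaike_weights.get)

    def test_nonfinite_loglik_rejected(self):
        fits = self.fits_with_aic([100.0, 110.0, 110.0])
        fits["flock"].log_likelihood = np.nan
        with pytest.raises(ValueError):
            akaike_weights(fits)


class TestClassifyPattern:
    def test_stream_flock_swarm_generators_recovered(self, rng):
        stream = classify_pattern(stream_sample(rng, np.pi / 4, 4.0, 500))
        assert stream.label == "stream"
        assert stream.akaike_weights["stream"] > 0.99
        flock = classify_pattern(vm_sample(rng, np.pi, 4.0, 500))
        assert flock.label == "flock"
        assert flock.akaike_weights["flock"] > 0.99
        swarm_rng = np.random.default_rng(1)
        swarm = classify_pattern(HeadingSample(swarm_rng.uniform(0, 2 * np.pi, 500)))
        assert swarm.label == "swarm"

    def test_insufficient_sample_gives_null_label(self, rng):
        out = classify_pattern(HeadingSample(rng.uniform(0, 2 * np.pi, 10)), min_n=30)
        assert out.insufficient_sample
        assert out.label is None
        assert out.n == 10

    def test_rotation_equivariance_of_fit_and_weights(self, rng):
        th = np.mod(rng.vonmises(1.0, 2.5, 300), 2 * np.pi)
        phi = 1.2345
        a = classify_pattern(HeadingSample(th))
        b = classify_pattern(HeadingSample(np.mod(th + phi, 2 * np.pi)))
        for fam in a.fits:
            assert b.fits[fam].log_likelihood == pytest.approx(
                a.fits[fam].log_likelihood, abs=1e-6
            )
            assert b.akaike_weights[fam] == pytest.approx(
                a.akaike_weights[fam], abs=1e-6
            )
        assert np.angle(
            np.exp(1j * (b.fits["flock"].mu - a.fits["flock"].mu - phi))
        ) == pytest.approx(0.0, abs=1e-6)


class TestKDEAndHistogram:
    def test_kde_integrates_to_one(self, rng):
        kde = circular_kde(HeadingSample(rng.uniform(0, 2 * np.pi, 100)))
        integral = kde.density.mean() * 2 * np.pi  # uniform grid over the circle
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_single_observation_is_the_kernel(self):
        kde = circular_kde(HeadingSample([0.0]), bandwidth_kappa=5.0)
        expected = np.exp(vonmises_logpdf(kde.grid, 0.0, 5.0))
        np.testing.assert_allclose(kde.density, expected, atol=1e-12)

    def test_vanishing_bandwidth_flattens_to_uniform(self, rng):
        kde = circular_kde(
            HeadingSample(rng.uniform(0, 2 * np.pi, 30)), bandwidth_kappa=1e-8
        )
        np.testing.assert_allclose(kde.density, 1 / (2 * np.pi), atol=1e-7)

    def test_histogram_counts_and_boundaries(self):
        counts, _ = angle_histogram(HeadingSample([0.0, np.pi]), n_bins=4)
        assert counts.tolist() == [1, 0, 1, 0]
        eps = 1e-9
        counts, _ = angle_histogram(HeadingSample([2 * np.pi - eps]), n_bins=8)
        assert counts[-1] == 1

    @given(seed=st.integers(0, 1000), n_bins=st.integers(2, 36))
    def test_histogram_total_is_sample_size(self, seed, n_bins):
        th = np.random.default_rng(seed).uniform(0, 2 * np.pi, 57)
        counts, _ = angle_histogram(HeadingSample(th), n_bins=n_bins)
        assert counts.sum() == 57
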