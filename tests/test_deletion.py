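"""Noise model, Y statistic, chi / noncentral-chi likelihoods, deletion calls."""
import numpy as np
import pytest
from scipy import integrate, stats

import abscna
from abscna.datamodel import NoiseModel, Segment
from abscna.deletion import deletion_likelihoods, y_statistic
from abscna.errors import InsufficientDataError, NotADeletionError


def _segment_track(cn, alpha=0.4, L=100, seed=0):
    cfg = abscna.SimConfig(
        segments=[abscna.SegmentSpec(L, cn[0], cn[1])],
        alpha=alpha, rho=-0.042, noise_sd=0.25, seed=seed,
    )
    track, _ = abscna.simulate_sample(cfg)
    seg = Segment("chr1", 0, L, mean_total=float(track.totals.mean()))
    return track, seg


class TestNoiseModel:
    def test_recovery_on_balanced_track(self):
        cfg = abscna.SimConfig(
            segments=[abscna.SegmentSpec(10000, 1, 1)], alpha=0.4,
            rho=-0.042, noise_sd=0.25, seed=4,
        )
        track, _ = abscna.simulate_sample(cfg)
        segs = abscna.segment_track(track, track.totals)
        abscna.annotate_segments(segs, track, None)
        noise = abscna.estimate_noise_model(track, None, segs)
        assert noise.rho == pytest.approx(-0.042, abs=0.02)
        assert np.sqrt(noise.sigma2) == pytest.approx(0.25, abs=0.01)
        assert noise.sigma_d2 == pytest.approx(
            2 * noise.sigma2 * (1 - noise.rho)
        )

    def test_no_qualifying_loci_errors(self):
        track, seg = _segment_track((0, 0), L=500)
        seg.mean_total = 0.8  # outside the [1.8, 2.2] window
        with pytest.raises(InsufficientDataError):
            abscna.estimate_noise_model(track, None, [seg])


class TestYStatistic:
    def test_zero_differences_give_zero(self, true_noise):
        a = np.ones(20)
        Y, L = y_statistic(a, a, true_noise)
        assert Y == 0.0 and L == 20

    def test_unit_differences_closed_form(self, true_noise):
        sd = true_noise.sigma_d
        a = np.full(4, 1.0 + sd)
        b = np.ones(4)
        Y, L = y_statistic(a, b, true_noise, min_loci=4)
        assert Y == pytest.approx(2.0)  # sqrt(4 * sd^2 / sd^2)

    def test_too_few_loci_rejected(self, true_noise):
        with pytest.raises(InsufficientDataError):
            y_statistic(np.ones(5), np.ones(5), true_noise)

    def test_null_mean_is_degrees_of_freedom(self, true_noise):
        # pure-noise differences: E[Y^2] = L; signal level high enough that
        # the zero floor never censors
        L, nseg = 100, 1000
        cfg = abscna.SimConfig(
            segments=[abscna.SegmentSpec(L * nseg, 0, 0)], alpha=0.8,
            rho=-0.042, noise_sd=0.25, seed=17,
        )
        track, _ = abscna.simulate_sample(cfg)
        d = (track.a_signal - track.b_signal).reshape(nseg, L)
        y2 = (d**2).sum(axis=1) / true_noise.sigma_d2
        assert y2.mean() == pytest.approx(100, abs=5)


class TestLikelihoods:
    def test_zero_noncentrality_reduces_to_central(self):
        for y in (0.5, 3.0, 11.0):
            f_homo, f_hemi = deletion_likelihoods(y, 10, 0.0)
            assert f_hemi == pytest.approx(f_homo, rel=1e-9)

    @pytest.mark.parametrize("L,lam", [(1, 0.0), (10, 0.0), (10, 4.0),
                                       (100, 15.0)])
    def test_densities_integrate_to_one(self, L, lam):
        for which in (0, 1):
            total, _ = integrate.quad(
                lambda y: deletion_likelihoods(y, L, lam)[which],
                0, np.inf, limit=200,
            )
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_chi1_is_folded_normal(self):
        f_homo, _ = deletion_likelihoods(0.5, 1, 0.0)
        assert f_homo == pytest.approx(2 * stats.norm.pdf(0.5), rel=1e-9)


class TestClassification:
    def test_homo_segments_called_homo(self, true_noise):
        correct = 0
        for rep in range(100):
            track, seg = _segment_track((0, 0), seed=1000 + rep)
            call = abscna.classify_deletion(track, seg, true_noise)
            correct += call.type == "homo" and call.posterior_homo > 0.99
        assert correct >= 99

    def test_hemi_segments_called_hemi(self, true_noise):
        correct = 0
        for rep in range(100):
            track, seg = _segment_track((1, 0), seed=2000 + rep)
            call = abscna.classify_deletion(track, seg, true_noise)
            correct += call.type == "hemi" and call.posterior_homo < 0.01
        assert correct >= 99

    def test_zero_y_with_large_lambda_is_homo(self, true_noise):
        track, seg = _segment_track((0, 0), seed=5)
        track = track.with_signals(np.full(100, 0.4), np.full(100, 0.4))
        call = abscna.classify_deletion(track, seg, true_noise)
        assert call.Y == 0.0 and call.posterior_homo > 1 - 1e-9

    def test_non_deletion_segment_rejected(self, true_noise):
        track, seg = _segment_track((1, 1))
        with pytest.raises(NotADeletionError):
            abscna.classify_deletion(track, seg, true_noise)

    def test_posterior_monotone_in_lambda(self):
        # for fixed Y with Y^2 > L, raising the noncentrality toward the
        # best-fitting value sqrt(Y^2 - L) monotonically favors hemi
        # (beyond it the noncentral model overshoots and homo recovers)
        Y, L = 12.0, 64
        lam_star = np.sqrt(Y**2 - L)
        posts = []
        for lam in np.linspace(0.0, lam_star, 15):
            f_homo, f_hemi = deletion_likelihoods(Y, L, lam)
            posts.append(f_homo / (f_homo + f_hemi))
        assert np.all(np.diff(posts) <= 1e-12)
        far = deletion_likelihoods(Y, L, 3 * lam_star)
        assert far[0] / (far[0] + far[1]) > posts[-1]

    def test_corrupted_noise_model_flips_hemi_to_homo(self, true_noise):
        """Estimating the noise over unmasked, imbalance-contaminated loci
        inflates sigma_d (strongly negative rho AND inflated sigma) and
        flips hemi calls to homo; substituting the corrupted rho alone,
        with the true sigma, is not sufficient to flip."""
        cfg = abscna.default_validation_config(seed=3)
        track, _ = abscna.simulate_sample(cfg)
        segs = abscna.segment_track(track, track.totals)
        abscna.annotate_segments(segs, track, None)
        corrupted = abscna.estimate_noise_model(
            track, None, segs, cn_window=(-np.inf, np.inf)
        )
        assert corrupted.rho < -0.3
        assert corrupted.sigma_d > 2 * true_noise.sigma_d
        rho_only = NoiseModel(sigma2=true_noise.sigma2, rho=corrupted.rho)
        flipped = kept_with_rho_only = 0
        for rep in range(20):
            htrack, hseg = _segment_track((1, 0), seed=3000 + rep)
            assert abscna.classify_deletion(htrack, hseg, true_noise).type == "hemi"
            flipped += abscna.classify_deletion(htrack, hseg, corrupted).type == "homo"
            kept_with_rho_only += (
                abscna.classify_deletion(htrack, hseg, rho_only).type == "hemi"
            )
        assert flipped == 20
        assert kept_with_rho_only == 20

    def test_null_calibration_against_central_chi(self, true_noise):
        # 2000 homo segments of L=100: Y ~ chi(100) (KS, p > 0.01)
        L, nseg = 100, 2000
        cfg = abscna.SimConfig(
            segments=[abscna.SegmentSpec(L * nseg, 0, 0)], alpha=0.8,
            rho=-0.042, noise_sd=0.25, seed=11,
        )
        track, _ = abscna.simulate_sample(cfg)
        d = (track.a_signal - track.b_signal).reshape(nseg, L)
        Y = np.sqrt((d**2).sum(axis=1) / true_noise.sigma_d2)
        ks = stats.kstest(Y, "chi", args=(L,))
        assert ks.pvalue > 0.01
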