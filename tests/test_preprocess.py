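"""Smoothing, windowed inter-allele correlation, balance masking, and
crosstalk/saturation inversion."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import abscna
from abscna.errors import InsufficientDataError, ParameterError
from conftest import make_track


class TestMovingAverage:
    def test_constant_signal_unchanged(self):
        track = make_track([0.7] * 30, [0.7] * 30)
        out = abscna.moving_average_total(track, window=7)
        np.testing.assert_allclose(out, 1.4, atol=1e-12)

    def test_impulse_spread_over_window(self):
        a = [0.0] * 5 + [3.0] + [0.0] * 5
        track = make_track(a, [0.0] * 11)
        out = abscna.moving_average_total(track, window=3)
        np.testing.assert_allclose(out[4:7], 1.0, atol=1e-12)

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 2, 50)
        track = make_track(a, a)
        np.testing.assert_allclose(
            abscna.moving_average_total(track, window=1), track.totals
        )

    def test_even_window_rejected(self):
        track = make_track([1.0] * 10, [1.0] * 10)
        with pytest.raises(ParameterError):
            abscna.moving_average_total(track, window=4)

    def test_smoothing_respects_chromosome_borders(self):
        n = 40
        chrom = np.array(["chr1"] * 20 + ["chr2"] * 20, dtype=object)
        track = abscna.AllelicTrack.from_arrays(
            chrom, np.tile(np.arange(1, 21), 2),
            np.array([1.0] * 20 + [3.0] * 20),
            np.zeros(n),
        )
        out = abscna.moving_average_total(track, window=5)
        assert np.all(out[:20] == 1.0) and np.all(out[20:] == 3.0)


class TestSlidingCorrelation:
    def test_identical_series_give_one(self):
        rng = np.random.default_rng(1)
        a = 1.0 + 0.3 * rng.standard_normal(60)
        track = make_track(a, a)
        prof = abscna.sliding_allelic_correlation(track, window=20)
        defined = np.isfinite(prof.r)
        assert defined.any()
        np.testing.assert_allclose(prof.r[defined], 1.0, atol=1e-9)

    def test_mirrored_series_give_minus_one(self):
        rng = np.random.default_rng(2)
        a = 1.0 + 0.3 * rng.standard_normal(60)
        track = make_track(a, np.clip(2.0 - a, 0, None))
        prof = abscna.sliding_allelic_correlation(track, window=20)
        defined = np.isfinite(prof.r)
        np.testing.assert_allclose(prof.r[defined], -1.0, atol=1e-9)

    def test_null_r_concentrates_near_zero(self):
        # iid noise around balanced (1,1), rho=0: |r| < 0.15 for >=95% of loci
        cfg = abscna.SimConfig(
            segments=[abscna.SegmentSpec(5000, 1, 1)], alpha=0.0, rho=0.0,
            noise_sd=0.25, seed=3,
        )
        track, _ = abscna.simulate_sample(cfg)
        prof = abscna.sliding_allelic_correlation(track, window=200)
        r = prof.r[np.isfinite(prof.r)]
        assert np.mean(np.abs(r) < 0.15) >= 0.95

    def test_short_chromosome_flagged_undefined(self):
        track = make_track([1.0] * 30, [1.0] * 30)
        prof = abscna.sliding_allelic_correlation(track, window=200)
        assert not np.isfinite(prof.r).any()


class TestAutoThreshold:
    def test_bimodal_threshold_separates_clusters(self, rng):
        r = np.concatenate([
            rng.normal(-0.9, 0.03, 500), rng.normal(0.0, 0.05, 500),
        ])
        thr = abscna.auto_balance_threshold(r)
        assert -0.8 < thr < -0.15
        mask = abscna.balanced_mask(r, thr)
        assert mask[500:].mean() > 0.95 and mask[:500].mean() < 0.05

    def test_unimodal_returns_floor(self, rng):
        r = rng.normal(0.0, 0.05, 500)
        assert abscna.auto_balance_threshold(r) == pytest.approx(-0.5)

    def test_too_few_values_falls_back_to_floor(self, rng):
        r = np.concatenate([rng.normal(-0.9, 0.03, 20),
                            rng.normal(0.0, 0.05, 20)])
        assert abscna.auto_balance_threshold(r) == pytest.approx(-0.5)

    def test_empty_input_errors(self):
        with pytest.raises(InsufficientDataError):
            abscna.auto_balance_threshold(np.array([]))


class TestBalancedMask:
    def test_threshold_semantics(self):
        r = np.array([-0.9, 0.0, np.nan])
        np.testing.assert_array_equal(
            abscna.balanced_mask(r, -0.45), [False, True, False]
        )
        assert abscna.balanced_mask(r, -1.0).sum() == 2  # all defined kept
        assert abscna.balanced_mask(r, 1.1).sum() == 0


@pytest.fixture(scope="module")
def loh_track():
    # (1,1) background with an embedded (2,0) copy-neutral LOH segment
    cfg = abscna.SimConfig(
        segments=[
            abscna.SegmentSpec(5000, 1, 1),
            abscna.SegmentSpec(5000, 2, 0),
            abscna.SegmentSpec(5000, 1, 1),
        ],
        alpha=0.4, rho=-0.042, noise_sd=0.25, seed=11,
    )
    return abscna.simulate_sample(cfg)[0]


class TestImbalanceDetection:
    """Copy-neutral LOH masking and the protection of the rho estimate."""

    def test_loh_loci_masked_balanced_retained(self, loh_track):
        prof = abscna.sliding_allelic_correlation(loh_track, window=200)
        thr = abscna.auto_balance_threshold(prof.r)
        mask = abscna.balanced_mask(prof.r, thr)
        inside = slice(5000, 10000)
        r_inside = prof.r[inside][np.isfinite(prof.r[inside])]
        assert r_inside.mean() < -0.5
        assert r_inside.mean() < thr
        assert mask[inside].mean() < 0.10           # >=90% of LOH masked out
        defined_bal = np.isfinite(prof.r) & np.ones(len(mask), bool)
        defined_bal[inside] = False
        assert mask[defined_bal].mean() > 0.90      # >=90% balanced retained

    def test_masking_protects_rho_estimate(self):
        # 30% copy-neutral LOH: unmasked estimate biased negative by >0.1,
        # masked estimate within 0.05 of the configured rho
        cfg = abscna.SimConfig(
            segments=[
                abscna.SegmentSpec(7000, 1, 1),
                abscna.SegmentSpec(6000, 2, 0),
                abscna.SegmentSpec(7000, 1, 1),
            ],
            alpha=0.4, rho=-0.042, noise_sd=0.25, seed=13,
        )
        track, _ = abscna.simulate_sample(cfg)
        raw_rho = np.corrcoef(track.a_signal, track.b_signal)[0, 1]
        assert raw_rho < -0.042 - 0.1
        prof = abscna.sliding_allelic_correlation(track, window=200)
        thr = abscna.auto_balance_threshold(prof.r)
        mask = abscna.balanced_mask(prof.r, thr)
        masked_rho = np.corrcoef(track.a_signal[mask], track.b_signal[mask])[0, 1]
        assert masked_rho == pytest.approx(-0.042, abs=0.05)


class TestCrosstalkCorrection:
    @given(c=st.floats(0.01, 0.5), a=st.floats(0.0, 4.0), b=st.floats(0.0, 4.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linear_crosstalk_exactly_inverted(self, c, a, b):
        track = make_track([a], [b])
        distorted = abscna.apply_distortions(track, crosstalk=c)
        restored = abscna.correct_crosstalk(distorted, c)
        assert restored.a_signal[0] == pytest.approx(a, abs=1e-9)
        assert restored.b_signal[0] == pytest.approx(b, abs=1e-9)

    def test_saturation_inverted_below_ninety_percent(self):
        M = 4.0
        vals = np.linspace(0.0, 0.9 * M, 50)
        track = make_track(vals, vals[::-1])
        distorted = abscna.apply_distortions(track, 0.0, M)
        restored = abscna.correct_crosstalk(distorted, 0.0, M)
        np.testing.assert_allclose(restored.a_signal, vals, atol=1e-6)

    def test_noop_parameters_are_identity(self):
        track = make_track([1.0, 2.0], [0.5, 0.7])
        out = abscna.correct_crosstalk(track, 0.0, None)
        np.testing.assert_array_equal(out.a_signal, track.a_signal)

    def test_crosstalk_coefficient_validated(self):
        track = make_track([1.0], [1.0])
        with pytest.raises(ParameterError):
            abscna.correct_crosstalk(track, 1.0)
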