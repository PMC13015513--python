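import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refnorm import (NormalizationParams, classify_bins, estimate_alignment,
                     estimate_noise_cutoff, estimate_scaling_factors,
                     normalize_bins, spikein_ratio_factor)
from refnorm.errors import DataError, EstimationError

SIG = np.arange(8, 12)        # central columns of a 20-bin profile
BG = np.r_[0:4, 16:20]


def _profile(bg, peak):
    p = np.full(20, float(bg))
    p[SIG] += peak
    return p


class TestScalingFactors:
    def test_identical_profiles_give_unity(self):
        p = _profile(1.0, 5.0)
        assert estimate_scaling_factors(p, p, SIG, BG) == pytest.approx((1.0, 1.0))

    def test_uniform_background_shift_only_moves_sfbg(self):
        # target = control + b everywhere except the peak height is unchanged:
        # sfbg = bg/(bg+b) < 1 and the background-subtracted sfsig stays 1
        bg, peak, b = 1.0, 6.0, 0.5
        ctrl = _profile(bg, peak)
        tgt = _profile(bg + b, peak)
        sfbg, sfsig = estimate_scaling_factors(ctrl, tgt, SIG, BG)
        assert sfbg == pytest.approx(bg / (bg + b))
        assert sfsig == pytest.approx(1.0)

    def test_pure_depth_factor_scales_both(self):
        ctrl = _profile(1.0, 5.0)
        sfbg, sfsig = estimate_scaling_factors(ctrl, 3.0 * ctrl, SIG, BG)
        assert (sfbg, sfsig) == pytest.approx((1 / 3, 1 / 3))

    def test_no_enrichment_is_an_error(self):
        flat = np.full(20, 2.0)
        with pytest.raises(EstimationError, match="no enrichment"):
            estimate_scaling_factors(flat, flat, SIG, BG)

    def test_raw_mode_skips_background_subtraction(self):
        ctrl = _profile(1.0, 5.0)
        tgt = _profile(2.0, 4.0)
        _, sfsig = estimate_scaling_factors(ctrl, tgt, SIG, BG, background_subtract=False)
        assert sfsig == pytest.approx(ctrl[SIG].mean() / tgt[SIG].mean())


class TestAlignment:
    def test_identity(self):
        x = np.array([1.0, 2.0, 3.5, 4.0])
        assert estimate_alignment(x, x) == pytest.approx((1.0, 0.0))

    def test_recovers_constructed_affine_map(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 1.2, 100)
        a_true, b_true = 1.7, -0.8
        y = (x - b_true) / a_true
        a, b = estimate_alignment(x, y)
        assert a == pytest.approx(a_true, abs=1e-12)
        assert b == pytest.approx(b_true, abs=1e-12)

    def test_known_moments(self):
        # x: mean 3, sd 1; y: mean 5, sd 2 -> alpha 0.5, beta 0.5
        x = np.array([2.0, 3.0, 4.0])
        y = np.array([3.0, 5.0, 7.0])
        assert estimate_alignment(x, y) == pytest.approx((0.5, 0.5))

    def test_moment_matching_is_exact(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2, 57)
        y = rng.normal(4, 0.3, 57)
        a, b = estimate_alignment(x, y)
        yhat = a * y + b
        assert yhat.mean() == pytest.approx(x.mean(), abs=1e-12)
        assert yhat.std(ddof=1) == pytest.approx(x.std(ddof=1), abs=1e-12)

    def test_constant_target_is_an_error(self):
        with pytest.raises(EstimationError, match="constant"):
            estimate_alignment(np.array([1.0, 2.0, 3.0]), np.full(3, 2.0))


class TestNoiseCutoff:
    def test_equal_variance_gaussians_cross_at_midpoint(self):
        rng = np.random.default_rng(2)
        bg = rng.normal(1.0, 0.5, 5000)
        sig = rng.normal(5.0, 0.5, 5000)
        noise, info = estimate_noise_cutoff(bg, sig, pseudocount=1.0)
        bw = max(info["bandwidth_bg"], info["bandwidth_sig"])
        assert not info["fallback"]
        assert abs(info["log2_cutoff"] - 3.0) < bw
        assert noise == pytest.approx(2 ** info["log2_cutoff"] - 1.0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        bg = rng.normal(0.5, 0.4, 3000)
        sig = rng.normal(4.0, 0.6, 3000)
        d = 1.25
        _, i1 = estimate_noise_cutoff(bg, sig)
        _, i2 = estimate_noise_cutoff(bg + d, sig + d)
        assert i2["log2_cutoff"] - i1["log2_cutoff"] == pytest.approx(d, abs=0.02)

    def test_signal_below_background_takes_fallback(self, caplog):
        rng = np.random.default_rng(4)
        bg = rng.normal(5.0, 0.5, 2000)
        sig = rng.normal(1.0, 0.5, 2000)
        with caplog.at_level("WARNING"):
            _, info = estimate_noise_cutoff(bg, sig)
        assert info["fallback"]
        assert info["log2_cutoff"] == pytest.approx(3.0, abs=0.05)

    def test_identical_distributions_error(self):
        v = np.array([1.0, 2.0, 3.0])
        with pytest.raises(EstimationError, match="override"):
            estimate_noise_cutoff(v, v)


IDENTITY = NormalizationParams(sfbg=1.0, sfsig=1.0, alpha=1.0, beta=0.0, noise=1.0)


class TestClassifyAndNormalize:
    def test_all_zero_bins_are_background(self):
        cls = classify_bins(np.zeros(100), IDENTITY)
        assert cls.n_signal == 0

    def test_zero_noise_makes_positive_bins_signal(self):
        params = NormalizationParams(1, 1, 1, 0, noise=0.0)
        cls = classify_bins(np.array([0.0, 0.5, 2.0]), params)
        assert cls.is_signal[""].tolist() == [False, True, True]

    def test_tie_at_cutoff_is_background(self):
        params = NormalizationParams(1, 2.0, 1, 0, noise=4.0)
        cls = classify_bins(np.array([2.0, 2.0001]), params)  # scaled: 4.0, 4.0002
        assert cls.is_signal[""].tolist() == [False, True]

    def test_identity_parameters_return_input_on_both_branches(self):
        v = np.array([0.0, 0.4, 1.0, 3.0, 50.0])
        mask = np.array([False, False, False, True, True])
        out = normalize_bins(v, mask, IDENTITY, pseudocount=1.0)
        assert np.allclose(out, v, atol=1e-12)

    def test_alpha_one_closed_form(self):
        # with alpha = 1 the signal branch is v*sfsig*2^beta + c*(2^beta - 1)
        params = NormalizationParams(sfbg=1, sfsig=1.3, alpha=1.0, beta=0.7, noise=0)
        v = np.array([2.0, 9.0])
        c = 0.5
        out = normalize_bins(v, np.array([True, True]), params, pseudocount=c)
        expected = v * 1.3 * 2 ** 0.7 + c * (2 ** 0.7 - 1)
        assert np.allclose(out, expected, atol=1e-12)

    def test_background_branch_scales_linearly(self):
        params = NormalizationParams(sfbg=0.5, sfsig=1, alpha=1, beta=0, noise=100)
        out = normalize_bins(np.array([4.0]), np.array([False]), params)
        assert out[0] == pytest.approx(2.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.2, 5), st.floats(0.2, 5), st.floats(0.2, 3),
           st.floats(-2, 2), st.floats(0.1, 5))
    def test_both_branches_strictly_increasing_and_nonnegative(
            self, sfbg, sfsig, alpha, beta, c):
        params = NormalizationParams(sfbg=sfbg, sfsig=sfsig, alpha=alpha,
                                     beta=beta, noise=1.0)
        v = np.linspace(0, 100, 200)
        for mask_value in (False, True):
            mask = np.full(v.shape, mask_value)
            out = normalize_bins(v, mask, params, pseudocount=c)
            assert np.all(out >= 0)
            raw = np.diff(out)
            # monotone non-decreasing overall, strictly increasing once
            # above the zero floor
            assert np.all(raw >= -1e-12)
            assert np.all(raw[out[1:] > 0] > 0)

    def test_nonpositive_alpha_is_rejected(self):
        with pytest.raises(EstimationError, match="alpha"):
            NormalizationParams(1, 1, alpha=-0.5, beta=0, noise=0)


class TestSpikeinRatio:
    def test_equal_counts(self):
        assert spikein_ratio_factor(5e6, 5e6) == 1.0

    def test_ratio(self):
        assert spikein_ratio_factor(2e6, 4e6) == pytest.approx(0.5)

    def test_nonpositive_count_error(self):
        with pytest.raises(DataError):
            spikein_ratio_factor(0, 100)
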