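"""Redox-ratio statistics and PSD power-law estimation."""

import warnings

import numpy as np
import pytest

from wunet.metabolic import (MetricProfile, fit_beta, fluctuation_image,
                             psd2d, radial_psd, redox_map, section_rr_stats,
                             stack_metrics)
from wunet.stack_io import TissueStack


class TestRedoxMap:
    def test_equal_channels_give_half(self):
        m = redox_map(np.ones((8, 8)), np.ones((8, 8)))
        np.testing.assert_allclose(m.values, 0.5)

    def test_zero_fad_gives_zero(self):
        m = redox_map(np.ones((8, 8)), np.zeros((8, 8)))
        np.testing.assert_allclose(m.values, 0.0)

    def test_three_to_one_ratio(self):
        m = redox_map(np.ones((4, 4)), 3 * np.ones((4, 4)))
        np.testing.assert_allclose(m.values, 0.75)

    def test_scale_invariance_and_bounds(self, rng):
        a = rng.random((16, 16)) + 0.1
        b = rng.random((16, 16)) + 0.1
        m1 = redox_map(a, b)
        m2 = redox_map(7.3 * a, 7.3 * b)
        np.testing.assert_allclose(m1.values, m2.values, rtol=1e-12)
        assert (m1.values >= 0).all() and (m1.values <= 1).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            redox_map(np.ones((4, 4)), np.ones((4, 5)))

    def test_mask_and_zero_sum_excluded(self):
        nadph = np.zeros((16, 16))
        nadph[:8] = 1.0
        mask = np.zeros((16, 16), bool)
        mask[:4] = True
        m = redox_map(nadph, nadph, mask)
        assert m.valid_mask.sum() == 4 * 16


class TestSectionRrStats:
    def test_constant_field(self):
        m = redox_map(np.ones((32, 32)), np.ones((32, 32)))
        mean, iqr = section_rr_stats(m)
        assert mean == 0.5 and iqr == 0.0

    def test_uniform_iqr(self, rng):
        # order statistics of U(0,1): IQR -> 0.5
        vals = rng.random(1_000_000)
        m = redox_map(1 - vals.reshape(1000, 1000),
                      vals.reshape(1000, 1000))
        mean, iqr = section_rr_stats(m)
        assert abs(iqr - 0.5) < 0.01

    def test_bimodal_half_fields(self):
        # halves at RR 0.2 / 0.8 -> mean 0.5, IQR 0.6 (brute-force
        # percentiles of the bimodal set)
        nadph = np.ones((32, 32))
        fad = np.where(np.arange(32)[:, None] < 16, 0.25, 4.0) * nadph
        mean, iqr = section_rr_stats(redox_map(nadph, fad))
        np.testing.assert_allclose(mean, 0.5, atol=1e-12)
        np.testing.assert_allclose(iqr, 0.6, atol=1e-12)

    def test_too_few_pixels_warns_nan(self):
        m = redox_map(np.ones((5, 5)), np.ones((5, 5)))
        with pytest.warns(RuntimeWarning):
            mean, iqr = section_rr_stats(m)
        assert np.isnan(mean) and np.isnan(iqr)


class TestFluctuationImage:
    def test_constant_in_mask_gives_ones(self):
        img = np.full((16, 16), 4.0)
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        np.testing.assert_allclose(fluctuation_image(img, mask), 1.0)

    def test_scale_invariance(self, rng):
        img = rng.random((16, 16)) + 0.5
        mask = img > 0.8
        np.testing.assert_allclose(fluctuation_image(img, mask),
                                   fluctuation_image(3 * img, mask),
                                   rtol=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            fluctuation_image(np.zeros((8, 8)), np.ones((8, 8), bool))


class TestRadialPsd:
    def test_white_noise_flat(self, rng):
        k, psd = radial_psd(rng.standard_normal((128, 128)))
        assert abs(fit_beta(k, psd).beta) < 0.1

    def test_cosine_peak_lands_in_right_bin(self):
        n = 64
        x = np.cos(2 * np.pi * 8 * np.arange(n) / n)
        img = np.tile(x, (n, 1))
        k, psd = radial_psd(img)
        assert np.nanargmax(psd) == np.argmin(np.abs(k - 8 / n))

    def test_parseval(self, rng):
        img = rng.standard_normal((64, 64))
        img -= img.mean()
        total = psd2d(img).sum()
        np.testing.assert_allclose(total, img.size * img.var(), rtol=1e-6)

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError):
            radial_psd(rng.random((64, 32)))


class TestFitBeta:
    def test_exact_power_law(self):
        k = np.arange(1, 65) / 128
        psd = 3.7 * k ** -2.0
        fit = fit_beta(k, psd, (k[0], k[-1]))
        assert abs(fit.beta - 2.0) < 1e-9
        assert abs(fit.A - 3.7) < 1e-9
        assert abs(fit.r_squared_fit - 1.0) < 1e-9

    def test_flat_psd_gives_zero(self):
        k = np.arange(1, 33) / 64
        fit = fit_beta(k, np.full(32, 5.0), (k[0], k[-1]))
        assert abs(fit.beta) < 1e-12

    def test_too_few_bins_rejected(self):
        k = np.arange(1, 6) / 64
        with pytest.raises(ValueError):
            fit_beta(k, np.ones(5), (k[0], k[-1]))

    def test_nonpositive_bins_excluded(self):
        k = np.arange(1, 33) / 64
        psd = k ** -1.5
        psd[5] = 0.0
        fit = fit_beta(k, psd, (k[0], k[-1]))
        assert abs(fit.beta - 1.5) < 1e-9


class TestStackMetrics:
    @staticmethod
    def _stack_from_sections(sections, channel):
        return TissueStack(channel=channel,
                           voxels=np.asarray(sections)[:, None],
                           provenance="clean")

    def test_depth_constant_profiles_have_zero_variance(self, rng):
        sec = rng.random((64, 64)) + 0.5
        nadph = self._stack_from_sections([sec] * 4, "NADPH")
        fad = self._stack_from_sections([0.8 * sec] * 4, "FAD")
        mp = stack_metrics(nadph, fad)
        for key in ("var_mean_rr", "var_rr_iqr", "var_beta"):
            assert mp.summaries[key] < 1e-12

    def test_depth_permutation_invariance(self, midsize_paired):
        ps = midsize_paired
        mp = stack_metrics(ps.clean["NADPH"], ps.clean["FAD"],
                           masks=ps.masks)
        perm = np.array([3, 0, 6, 1, 7, 2, 5, 4])
        from dataclasses import replace
        nadph_p = replace(ps.clean["NADPH"],
                          voxels=ps.clean["NADPH"].voxels[perm])
        fad_p = replace(ps.clean["FAD"],
                        voxels=ps.clean["FAD"].voxels[perm])
        mp_p = stack_metrics(nadph_p, fad_p, masks=ps.masks[perm])
        for key, val in mp.summaries.items():
            np.testing.assert_allclose(mp_p.summaries[key], val, rtol=1e-9)

    def test_clean_stack_recovers_configured_profiles(self, midsize_paired):
        ps = midsize_paired
        cfg = ps.config
        mp = stack_metrics(ps.clean["NADPH"], ps.clean["FAD"],
                           masks=ps.masks)
        assert np.all(np.abs(mp.mean_rr - cfg.rr_profile) < 0.02)
        assert np.all(np.abs(mp.beta - cfg.beta_profile) < 0.2)

    def test_depth_mismatch_rejected(self, rng):
        a = self._stack_from_sections(rng.random((3, 64, 64)), "NADPH")
        b = self._stack_from_sections(rng.random((2, 64, 64)), "FAD")
        with pytest.raises(ValueError):
            stack_metrics(a, b)

    def test_failed_depths_recorded_as_nan(self, rng):
        # second depth is all zeros -> no valid pixels, metrics NaN
        good = rng.random((64, 64)) + 0.5
        nadph = self._stack_from_sections([good, np.zeros((64, 64))],
                                          "NADPH")
        fad = self._stack_from_sections([good, np.zeros((64, 64))], "FAD")
        mp = stack_metrics(nadph, fad)
        assert mp.n_failed_depths == 1
        assert np.isfinite(mp.summaries["mean_rr"])
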