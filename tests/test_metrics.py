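"""Resolution metrology, R-L deconvolution and MS-SSIM."""

import numpy as np
import pytest

from hgiscan.objects import frame_coords
from hgiscan.optics import OpticsConfig, jinc, widefield_image
from hgiscan.objects import make_line_pair
from hgiscan.metrics import (
    airy_rayleigh_criterion,
    dip_ratio,
    estimate_psf_sigma,
    ism_airy_resolution_gain,
    line_profile,
    ms_ssim,
    ms_ssim_sampled,
    rayleigh_resolution,
    richardson_lucy,
    two_point_separation,
)


def _two_gaussian_line_image(d: float, sigma: float, n: int = 210) -> np.ndarray:
    x = frame_coords(n)
    prof = (np.exp(-(x - d / 2) ** 2 / (2 * sigma**2))
            + np.exp(-(x + d / 2) ** 2 / (2 * sigma**2)))
    return np.tile(prof, (n, 1))


class TestProfilesAndDips:
    def test_profile_of_symmetric_pair_is_symmetric(self):
        img = widefield_image(make_line_pair(60), OpticsConfig())
        x, prof = line_profile(img)
        assert np.allclose(prof, prof[::-1], rtol=1e-9)

    def test_zero_separation_profile_is_single_peaked(self):
        img = widefield_image(make_line_pair(0), OpticsConfig())
        x, prof = line_profile(img)
        # monotone rise then fall: exactly one +to- transition of the slope
        slope = np.sign(np.diff(prof))
        slope = slope[slope != 0]
        assert (np.diff(slope) != 0).sum() == 1

    def test_two_gaussian_dip_matches_closed_form(self):
        sigma, d = 20.0, 55.0
        img = _two_gaussian_line_image(d, sigma)
        x, prof = line_profile(img)
        saddle = 2 * np.exp(-(d**2) / (8 * sigma**2))
        xf = np.linspace(-105, 105, 100001)
        two = (np.exp(-(xf - d / 2) ** 2 / (2 * sigma**2))
               + np.exp(-(xf + d / 2) ** 2 / (2 * sigma**2)))
        expected = saddle / two.max()
        assert dip_ratio(x, prof) == pytest.approx(expected, rel=1e-3)


class TestRayleighResolution:
    def test_criterion_constant_matches_classic_airy_value(self):
        assert airy_rayleigh_criterion() == pytest.approx(0.735, abs=0.001)

    def test_exact_hit_returns_that_separation(self):
        sigma = 20.0
        images = {d: _two_gaussian_line_image(d, sigma) for d in
                  (30, 40, 50, 60, 70)}
        x, prof = line_profile(images[50])
        crit = dip_ratio(x, prof)
        est = rayleigh_resolution(images, criterion_ratio=crit)
        assert est.resolution_px == pytest.approx(50.0, abs=1e-6)
        assert est.status == "ok"

    def test_out_of_range_series_is_flagged(self):
        sigma = 5.0  # resolves everything in the series
        images = {d: _two_gaussian_line_image(d, sigma) for d in (60, 80)}
        est = rayleigh_resolution(images)
        assert est.status == "below_range"
        assert est.resolution_px == 60.0

    def test_resolution_is_monotone_in_psf_width(self):
        series = {}
        for sigma in (20.0, 25.0, 30.0):
            series[sigma] = rayleigh_resolution(
                {d: _two_gaussian_line_image(d, sigma)
                 for d in range(30, 131, 10)})
        values = [series[s].resolution_px for s in (20.0, 25.0, 30.0)]
        assert values == sorted(values)

    def test_jinc_product_psf_ratio_is_139_not_153(self):
        # pointwise jinc^4 understates the scanning gain: the reassignment
        # PSF is a convolution of half-scaled PSFs, giving ~1.53
        d2 = two_point_separation(lambda v: jinc(v) ** 2)
        d4 = two_point_separation(lambda v: jinc(v) ** 4)
        assert d2 / d4 == pytest.approx(1.39, abs=0.01)
        assert ism_airy_resolution_gain() == pytest.approx(1.53, abs=0.03)


class TestPsfEstimation:
    def test_recovers_known_sigma_within_two_percent(self):
        img = widefield_image(make_line_pair(0), OpticsConfig())
        est = estimate_psf_sigma(img, line_width_px=10, coherent=True)
        assert est == pytest.approx(30.0, rel=0.02)

    def test_estimates_agree_across_separations(self):
        sigmas = []
        for sep in (0, 120):
            img = widefield_image(make_line_pair(sep), OpticsConfig())
            sigmas.append(estimate_psf_sigma(img, line_width_px=10,
                                             separation_px=sep))
        assert abs(sigmas[0] - sigmas[1]) / sigmas[0] < 0.05

    def test_incoherent_model(self):
        cfg = OpticsConfig(coherent=False, sigma_det_px=25.0)
        img = widefield_image(make_line_pair(0), cfg)
        est = estimate_psf_sigma(img, line_width_px=10, coherent=False)
        assert est == pytest.approx(25.0, rel=0.02)


class TestRichardsonLucy:
    def test_delta_psf_is_a_fixed_point(self):
        img = widefield_image(make_line_pair(60), OpticsConfig()).values
        delta = np.zeros((11, 11))
        delta[5, 5] = 1.0
        out = richardson_lucy(img, delta, iterations=25)
        assert np.abs(out - img).max() < 1e-9 * img.max()

    def test_dip_deepens_with_iterations(self):
        cfg = OpticsConfig(coherent=False, sigma_det_px=20.0)
        img = widefield_image(make_line_pair(50), cfg).values
        x = frame_coords(33)
        g = np.exp(-(x**2) / (2 * 20.0**2))
        psf = np.outer(g, g)
        dips = []
        for iters in (5, 30, 120):
            dec = richardson_lucy(img, psf, iterations=iters)
            xs, prof = line_profile(dec)
            dips.append(dip_ratio(xs, prof))
        assert dips[0] > dips[1] > dips[2]

    def test_rejects_invalid_psf(self):
        with pytest.raises(ValueError):
            richardson_lucy(np.ones((10, 10)), np.zeros((3, 3)))


class TestMsSsim:
    def test_identical_images_score_one(self, rng):
        img = rng.random((50, 50))
        assert ms_ssim(img, img) == pytest.approx(1.0, abs=1e-9)

    def test_noise_scores_low_against_structure(self, rng):
        ref = np.zeros((50, 50))
        ref[10:40, 20:30] = 1.0
        noise = rng.random((50, 50))
        assert ms_ssim(noise, ref) < 0.1

    def test_single_scale_agrees_with_skimage(self, rng):
        from skimage.metrics import structural_similarity

        a = rng.random((64, 64))
        b = np.clip(a + 0.1 * rng.standard_normal((64, 64)), 0, 1)
        ours = ms_ssim(a, b, scales=1, radius=5)
        ref = structural_similarity(a, b, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False, data_range=1.0)
        assert ours == pytest.approx(ref, abs=0.02)

    def test_sampled_report_statistics(self, rng):
        ref = rng.random((200, 400))
        report = ms_ssim_sampled(ref, ref, n_samples=10, crop_px=50, seed=1)
        assert report.mean == pytest.approx(1.0, abs=1e-9)
        assert report.stderr == pytest.approx(0.0, abs=1e-12)
        assert report.n_samples == 10 and report.crop_px == 50

    def test_crop_larger_than_region_rejected(self, rng):
        img = rng.random((100, 100))
        with pytest.raises(ValueError, match="crop"):
            ms_ssim_sampled(img, img, n_samples=5, crop_px=50,
                            region=(30, 30, 40, 40))
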