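"""Forward model: APSF construction, image formation, scan series."""

import numpy as np
import pytest
from scipy.optimize import brentq

from hgiscan.objects import ObjectPattern, frame_coords, make_line_pair
from hgiscan.optics import (
    OpticsConfig,
    gaussian_apsf_1d,
    jinc,
    make_apsf,
    scan_offsets,
    scan_series,
    scan_snapshot,
    sigma_ism,
    widefield_image,
)


class TestSigmaIsm:
    def test_narrow_illumination_ratio(self):
        # sigma_il = sigma_det / 2 composes to 0.89 sigma_il
        assert round(sigma_ism(0.5, 1.0) / 0.5, 2) == 0.89

    def test_equal_widths_give_sqrt2_reduction(self):
        assert sigma_ism(3.0, 3.0) == pytest.approx(3.0 / np.sqrt(2))

    def test_widefield_limit(self):
        assert sigma_ism(np.inf, 30.0) == 30.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sigma_ism(-1.0, 30.0)


class TestApsf:
    def test_gaussian_energy_and_second_moment(self, optics):
        k = make_apsf(optics)
        psf = np.abs(k.values) ** 2
        assert psf.sum() == pytest.approx(1.0, abs=1e-9)
        y, x = k.coords()
        var = (psf * x[None, :] ** 2).sum()
        assert np.sqrt(var) == pytest.approx(optics.sigma_det_px, rel=1e-3)

    def test_kernel_is_real_and_radially_symmetric(self, optics):
        for model in ("gaussian", "jinc"):
            k = make_apsf(OpticsConfig(apsf_model=model)).values
            assert np.isrealobj(k)
            assert np.allclose(k, k[::-1, :]) and np.allclose(k, k.T)

    def test_jinc_first_zero_at_061_lambda_over_na(self):
        cfg = OpticsConfig(apsf_model="jinc")
        k = make_apsf(cfg)
        centre = k.values.shape[0] // 2
        radial = k.values[centre, centre:]
        sign_change = np.where(np.diff(np.sign(radial)))[0][0]
        expected = 0.61 * cfg.lambda_over_na_px
        assert abs(sign_change + 0.5 - expected) <= 1.0  # within grid sampling


class TestWidefieldImaging:
    def test_coherent_impulse_response_is_apsf_squared(self, optics):
        obj = np.zeros((210, 210), np.uint8)
        obj[105, 105] = 1
        img = widefield_image(obj, optics).values
        x = frame_coords(210)
        g = gaussian_apsf_1d(x - x[105], optics.sigma_det_px)
        expected = np.outer(g, g) ** 2
        # the kernel is normalised over its own (wider) support, so allow a
        # small uniform scale tolerance from the truncated tails
        assert np.allclose(img, expected, rtol=5e-3)

    def test_all_off_object_gives_zero_image(self, optics):
        img = widefield_image(np.zeros((210, 210), np.uint8), optics)
        assert img.values.max() == 0.0

    def test_incoherent_imaging_conserves_energy(self):
        # object kept > 6 sigma from the frame edge so no flux leaves it
        cfg = OpticsConfig(coherent=False, sigma_det_px=8.0)
        obj = make_line_pair(40, length_px=101, line_width_px=10)
        img = widefield_image(obj, cfg)
        assert img.total() == pytest.approx(float(obj.pixels.sum()), rel=1e-6)

    def test_two_point_midpoint_ratio_matches_quadrature_oracle(self, optics):
        # two in-phase points 120 px apart; separable Gaussian APSF makes
        # the midpoint-to-peak ratio a 1D quantity
        d = 120
        obj = np.zeros((210, 210), np.uint8)
        obj[105, 105 - d // 2] = 1
        obj[105, 105 + d // 2] = 1
        row = widefield_image(obj, optics).values[105]
        ratio = row[105] / row.max()
        xf = np.linspace(-210, 210, 30001)
        amp = (gaussian_apsf_1d(xf + d / 2, optics.sigma_det_px)
               + gaussian_apsf_1d(xf - d / 2, optics.sigma_det_px))
        oracle = amp[len(xf) // 2] ** 2 / (amp**2).max()
        assert ratio == pytest.approx(oracle, rel=1e-2)

    def test_product_of_matched_apsfs_has_ism_width(self, optics):
        # |APSF_il . APSF_det|^2 second moment equals sigma_ism to 1%
        x = frame_coords(1001)
        g = gaussian_apsf_1d(x, optics.sigma_det_px)
        prod = (g * g) ** 2
        sigma = np.sqrt((prod * x**2).sum() / prod.sum())
        assert sigma == pytest.approx(
            sigma_ism(optics.sigma_det_px, optics.sigma_det_px), rel=1e-2)

    def test_coherent_jinc_two_point_resolution_near_084_lambda_over_na(self):
        from hgiscan.metrics import airy_rayleigh_criterion

        crit = airy_rayleigh_criterion()
        xs = np.linspace(-40, 40, 40001)

        def dip(d):
            prof = (jinc(xs - d / 2) + jinc(xs + d / 2)) ** 2
            return prof[len(xs) // 2] / prof.max()

        d = brentq(lambda s: dip(s) - crit, 3.0, 8.0)  # in jinc-argument units
        lam_over_na = 2 * np.pi  # jinc argument for x = lambda/NA
        assert d / lam_over_na == pytest.approx(0.84, rel=0.03)


class TestScanning:
    def test_widefield_limit_reduces_to_displaced_widefield_image(self, optics):
        obj = make_line_pair(40)
        snap = scan_snapshot(obj, optics, (20.0, -40.0))
        displayed = obj.shifted((-20, 40))
        expected = widefield_image(displayed, optics)
        assert np.allclose(snap.intensity.values, expected.values)

    def test_uniform_object_snapshot_is_shift_invariant(self):
        # narrow PSFs keep the display-clipping boundary invisible at centre
        cfg = OpticsConfig(coherent=False, sigma_det_px=10.0,
                           sigma_il_px=10.0)
        flat = ObjectPattern(np.ones((210, 210), np.uint8))
        a = scan_snapshot(flat, cfg, (0.0, 0.0)).intensity.values
        b = scan_snapshot(flat, cfg, (20.0, -20.0)).intensity.values
        centre = slice(75, 135)
        assert np.allclose(a[centre, centre], b[centre, centre], rtol=1e-9)

    def test_far_shift_gives_near_zero_snapshot(self):
        cfg = OpticsConfig().focused()
        obj = make_line_pair(20, length_px=21, line_width_px=4)
        near = scan_snapshot(obj, cfg, (0.0, 0.0)).intensity.values
        far = scan_snapshot(obj, cfg, (0.0, 200.0)).intensity.values
        assert far.max() < 1e-4 * near.max()

    def test_raster_counts(self):
        assert len(scan_offsets(20.0, 20.0)) == 1
        cfg = OpticsConfig().focused()
        obj = make_line_pair(40)
        series = scan_series(obj, cfg, step_px=70.0)
        assert len(series) == int(np.ceil(210 / 70)) ** 2
        assert len(scan_offsets(210.0, 20.0)) ** 2 == 121

    def test_snapshot_tiff_roundtrip_preserves_shift_metadata(self, tmp_path):
        from hgiscan.optics import load_snapshots, save_snapshots

        cfg = OpticsConfig().focused()
        series = scan_series(make_line_pair(40), cfg, step_px=105.0)
        path = str(tmp_path / "snaps.tiff")
        save_snapshots(path, series)
        back = load_snapshots(path)
        assert [s.shift_S for s in back] == [s.shift_S for s in series]
        for a, b in zip(back, series):
            assert np.allclose(a.intensity.values, b.intensity.values,
                               rtol=1e-6)

    def test_snapshots_carry_their_shifts(self):
        cfg = OpticsConfig().focused()
        series = scan_series(make_line_pair(40), cfg, step_px=105.0)
        shifts = {s.shift_S for s in series}
        assert shifts == {(-52.5, -52.5), (-52.5, 52.5),
                          (52.5, -52.5), (52.5, 52.5)}
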