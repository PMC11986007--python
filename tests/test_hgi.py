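"""Hermite-Gaussian basis, mode measurement and pseudoinverse reconstruction."""

import numpy as np
import pytest

from hgiscan.objects import ObjectPattern, frame_coords, make_line_pair
from hgiscan.optics import FieldMap, OpticsConfig, widefield_field
from hgiscan.hgi import (
    ModeAmplitudes,
    build_forward_operator,
    hg_basis,
    hgi_label,
    measure_amplitudes,
    measure_object,
    reconstruct_object,
)


class TestBasis:
    def test_mode_count_is_441_for_orders_up_to_20(self, basis):
        assert basis.n_max == 20
        assert basis.n_modes == 441

    def test_grid_orthonormality(self, basis):
        assert basis.gram_error() < 1e-3

    def test_ground_mode_is_unit_norm_gaussian_of_width_sigma(self, basis):
        phi00 = basis.mode(0, 0)
        p = np.abs(phi00) ** 2
        assert p.sum() * basis.pitch**2 == pytest.approx(1.0, abs=1e-6)
        var = (p * basis.x[None, :] ** 2).sum() * basis.pitch**2
        assert np.sqrt(var) == pytest.approx(basis.sigma, rel=1e-6)

    def test_specific_mode_overlaps(self, basis):
        p = basis.pitch**2
        phi23, phi32 = basis.mode(2, 3), basis.mode(3, 2)
        assert (phi23 * phi23).sum() * p == pytest.approx(1.0, abs=1e-6)
        assert abs((phi23 * phi32).sum() * p) < 1e-9

    def test_rejects_grid_too_small(self):
        with pytest.raises(ValueError, match="px"):
            hg_basis(20, 30.0, x=frame_coords(210))


class TestMeasurement:
    def test_basis_element_maps_to_unit_coefficient(self, small_basis):
        field = FieldMap(small_basis.mode(0, 4).astype(complex))
        amps = measure_amplitudes(field, small_basis)
        expected = np.zeros((5, 5), complex)
        expected[0, 4] = 1.0
        assert np.allclose(amps.c, expected, atol=1e-6)

    def test_linearity_with_complex_superposition(self, small_basis):
        field = FieldMap((small_basis.mode(1, 0) + 1j * small_basis.mode(0, 1))
                         / np.sqrt(2))
        amps = measure_amplitudes(field, small_basis)
        assert amps.c[1, 0] == pytest.approx(1 / np.sqrt(2), abs=1e-6)
        assert amps.c[0, 1] == pytest.approx(1j / np.sqrt(2), abs=1e-6)

    def test_point_source_amplitudes_match_explicit_2d_quadrature(self, small_basis):
        from hgiscan.optics import gaussian_apsf_1d

        x0 = 7.0
        cfg = OpticsConfig(sigma_det_px=12.0)
        g = gaussian_apsf_1d(small_basis.x - x0, cfg.sigma_det_px)
        gy = gaussian_apsf_1d(small_basis.x, cfg.sigma_det_px)
        field = FieldMap(np.outer(gy, g).astype(complex))
        amps = measure_amplitudes(field, small_basis)
        # independent oracle: explicit 2D mode rasters and brute-force sums
        for m in range(3):
            for n in range(3):
                phi = small_basis.mode(m, n)
                oracle = (phi * field.values).sum() * small_basis.pitch**2
                assert amps.c[m, n] == pytest.approx(oracle, abs=1e-12)

    def test_measurement_vector_interleaves_re_im(self, small_basis):
        c = np.arange(25, dtype=float).reshape(5, 5) + 1j
        amps = ModeAmplitudes(c, small_basis.sigma)
        vec = amps.measurement_vector()
        assert len(vec) == 2 * 25
        assert vec[0] == c[0, 0].real and vec[1] == c[0, 0].imag
        back = ModeAmplitudes.from_measurement_vector(vec, small_basis.sigma)
        assert np.allclose(back.c, c)

    def test_grid_mismatch_is_rejected(self, small_basis):
        with pytest.raises(ValueError, match="grid"):
            measure_amplitudes(FieldMap(np.zeros((10, 10))), small_basis)

    def test_noise_is_seeded_and_reproducible(self, small_basis):
        field = FieldMap(small_basis.mode(0, 0).astype(complex))
        a = measure_amplitudes(field, small_basis, noise_sd=0.1, seed=5)
        b = measure_amplitudes(field, small_basis, noise_sd=0.1, seed=5)
        c = measure_amplitudes(field, small_basis, noise_sd=0.1, seed=6)
        assert np.array_equal(a.c, b.c)
        assert not np.array_equal(a.c, c.c)

    def test_separable_fast_path_matches_explicit_image_route(self, basis, optics):
        obj = make_line_pair(40)
        fast = measure_object(obj, optics, basis)
        pad = (len(basis.x) - obj.frame_px) // 2
        field = widefield_field(obj, optics, pad_px=pad)
        explicit = measure_amplitudes(field, basis)
        err = np.linalg.norm(fast.c - explicit.c) / np.linalg.norm(explicit.c)
        assert err < 1e-6

    def test_parseval_on_truncated_subspace(self, basis, optics):
        # general field: mode energy bounded by field norm
        obj = make_line_pair(40)
        pad = (len(basis.x) - obj.frame_px) // 2
        field = widefield_field(obj, optics, pad_px=pad)
        energy = (np.abs(field.values) ** 2).sum() * basis.pitch**2
        mode_energy = float((np.abs(measure_amplitudes(field, basis).c) ** 2).sum())
        assert mode_energy <= energy * (1 + 1e-9)
        # in-span field: equality
        span = FieldMap(0.6 * basis.mode(2, 5) - 0.8j * basis.mode(7, 1))
        amps = measure_amplitudes(span, basis)
        assert (np.abs(amps.c) ** 2).sum() == pytest.approx(1.0, abs=1e-3)


class TestForwardOperator:
    def test_operator_matches_measurement_on_aligned_grid(self, basis, optics):
        # frame 200 px, 50 sites -> 4-px boxes aligned with the DMD grid
        op = build_forward_operator(basis, optics, 50, frame_px=200)
        obj = np.zeros((200, 200), np.uint8)
        obj[80:120, 60:100] = 1
        amps = measure_object(ObjectPattern(obj), optics, basis)
        pred = op.apply(obj[::4, ::4].astype(float))
        err = np.linalg.norm(pred.c - amps.c) / np.linalg.norm(amps.c)
        assert err < 1e-6

    def test_focused_columns_decay_away_from_axis(self, basis):
        # illumination amplitude exp(-r^2/4 sigma_il^2): 6 sigma -> ~1e-4
        cfg = OpticsConfig(sigma_il_px=15.0)
        op = build_forward_operator(basis, cfg, 50, frame_px=210)
        norms = np.linalg.norm(op.matrix, axis=0).reshape(50, 50)
        yy, xx = np.meshgrid(op.grid_y, op.grid_x, indexing="ij")
        far = np.hypot(yy, xx) > 6 * cfg.sigma_il_px
        assert far.any()
        assert norms[far].max() < 1e-3 * norms.max()


class TestReconstruction:
    def test_all_off_object_reconstructs_to_zero(self, basis, optics,
                                                 widefield_operator):
        amps = measure_object(ObjectPattern(np.zeros((210, 210), np.uint8)),
                              optics, basis)
        intensity, _ = reconstruct_object(amps, widefield_operator)
        assert intensity.values.max() == 0.0

    def test_point_source_localises_to_subpixel(self, basis, optics,
                                                widefield_operator):
        obj = np.zeros((210, 210), np.uint8)
        obj[105, 105] = 1  # at physical coordinates (0.5, 0.5)
        amps = measure_object(ObjectPattern(obj), optics, basis)
        intensity, _ = reconstruct_object(amps, widefield_operator)
        v = intensity.values
        yy, xx = np.meshgrid(widefield_operator.grid_y,
                             widefield_operator.grid_x, indexing="ij")
        cy = (v * yy).sum() / v.sum()
        cx = (v * xx).sum() / v.sum()
        assert abs(cy - 0.5) < 1.0 and abs(cx - 0.5) < 1.0

    def test_forward_then_reconstruct_is_a_projection(self, basis, optics,
                                                      widefield_operator):
        amps = measure_object(make_line_pair(40), optics, basis)
        _, f1 = reconstruct_object(amps, widefield_operator, 1e-3)
        amps2 = widefield_operator.apply(f1.values)
        _, f2 = reconstruct_object(amps2, widefield_operator, 1e-3)
        err = np.linalg.norm(f2.values - f1.values) / np.linalg.norm(f1.values)
        assert err < 1e-6

    def test_hgi_resolves_below_the_direct_imaging_limit(self, basis, optics,
                                                         widefield_operator):
        # at 50 px (far below the ~108 px DI limit) HGI shows a midpoint dip
        from hgiscan.metrics import dip_ratio, line_profile
        from hgiscan.optics import widefield_image

        obj = make_line_pair(50)
        amps = measure_object(obj, optics, basis)
        intensity, _ = reconstruct_object(amps, widefield_operator)
        x, prof = line_profile(intensity)
        hgi_dip = dip_ratio(x, prof)
        xd, profd = line_profile(widefield_image(obj, optics))
        di_dip = dip_ratio(xd, profd)
        assert hgi_dip < 0.735 < di_dip

    def test_noise_monotonically_degrades_reconstruction(self, basis, optics,
                                                         widefield_operator):
        obj = make_line_pair(60)
        clean = reconstruct_object(measure_object(obj, optics, basis),
                                   widefield_operator, 1e-2)[0].values
        mses = []
        scale = float(np.abs(measure_object(obj, optics, basis).c).max())
        for noise in (0.0, 1e-3, 1e-2, 1e-1):
            errs = []
            for seed in range(20):
                amps = measure_object(obj, optics, basis,
                                      noise_sd=noise * scale, seed=seed)
                rec = reconstruct_object(amps, widefield_operator, 1e-2)[0].values
                errs.append(((rec - clean) ** 2).mean())
            mses.append(np.mean(errs))
        assert all(a <= b + 1e-15 for a, b in zip(mses, mses[1:]))


class TestLabels:
    def test_all_off_object_has_zero_label(self, basis, optics,
                                           widefield_operator):
        label = hgi_label(ObjectPattern(np.zeros((210, 210), np.uint8)),
                          optics, basis, widefield_operator)
        assert label.shape == (50, 50)
        assert label.max() == 0.0

    def test_scanning_label_fades_outside_illumination(self, basis,
                                                       widefield_operator):
        # object far from the illumination axis
        obj = np.zeros((210, 210), np.uint8)
        obj[10:40, 10:40] = 1
        pattern = ObjectPattern(obj)
        cfg = OpticsConfig(sigma_il_px=15.0)
        wide = hgi_label(pattern, cfg, basis, widefield_operator,
                         illuminated=False)
        faded = hgi_label(pattern, cfg, basis, widefield_operator,
                          illuminated=True)
        assert faded.max() < 1e-2 * wide.max()

    def test_label_approaches_object_as_mode_count_grows(self, optics):
        obj = make_line_pair(60, length_px=101, line_width_px=20)
        target = _box_average_to_label_grid(obj.pixels.astype(float))
        errs = []
        for n_max in (4, 8, 20):
            b = hg_basis(n_max, 30.0)
            op = build_forward_operator(b, optics, 50, frame_px=210)
            label = hgi_label(obj, optics, b, op, smear_sigma=0.0,
                              sv_floor_rel=1e-6)
            errs.append(np.linalg.norm(label - target) / np.linalg.norm(target))
        assert errs[0] > errs[1] > errs[2]


def _box_average_to_label_grid(pix: np.ndarray, grid: int = 50) -> np.ndarray:
    """Exact box-average of a frame raster onto the reconstruction grid."""
    from scipy.interpolate import RegularGridInterpolator

    n = pix.shape[0]
    edges = np.linspace(0, n, grid + 1)
    cum = np.zeros((n + 1, n + 1))
    cum[1:, 1:] = np.cumsum(np.cumsum(pix, 0), 1)
    interp = RegularGridInterpolator((np.arange(n + 1), np.arange(n + 1)), cum)
    pts = np.array(np.meshgrid(edges, edges, indexing="ij")).reshape(2, -1).T
    c = interp(pts).reshape(grid + 1, grid + 1)
    box = (n / grid) ** 2
    return (c[1:, 1:] - c[:-1, 1:] - c[1:, :-1] + c[:-1, :-1]) / box
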