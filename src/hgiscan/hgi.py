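"""Hermite-Gaussian imaging: basis, mode measurement, reconstruction.

Spatial-mode demultiplexing measures the image-plane field in the
Hermite-Gaussian (HG) basis

    phi_mn(x, y) = N_mn H_n(x / (sqrt(2) sigma)) H_m(y / (sqrt(2) sigma))
                   exp(-(x^2 + y^2) / (4 sigma^2)),

orthonormal on the plane; the complex overlaps c_mn = <phi_mn, E> carry the
geometrical moments of the object field, from which the object is
reconstructed.  With mode orders m, n <= 20 there are 441 modes and the
real/imaginary-interleaved measurement vector has length 882.

Reconstruction here is the "perfect HGI" route: the measurement is a linear
map from a pixelised object amplitude to mode amplitudes, discretised into a
matrix (the forward operator) and inverted by a Tikhonov-damped
pseudoinverse.  Mode amplitudes decay exponentially with order, so the
inversion needs a singular-value floor, especially under the per-mode
complex Gaussian noise that stands in for local-oscillator shot noise in a
heterodyne readout.

For the default Gaussian APSF the measurement of a frame object never forms
the image explicitly: because both the APSF and the modes factorise along x
and y, the overlap of mode (m, n) with ``(obj . A_il) (*) APSF_det`` equals
a two-sided contraction of the illuminated object with 1D tables
``w_n = u_n (*) g`` (the adjoint of the convolution), which is exact and
fast.  The explicit image-plane route is kept for the Jinc model and as an
independent consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .objects import ObjectPattern, frame_coords
from .optics import (
    FieldMap,
    IntensityMap,
    OpticsConfig,
    gaussian_apsf_1d,
    illumination_amplitude,
    make_apsf,
)

__all__ = [
    "HGBasis",
    "ModeAmplitudes",
    "ForwardOperator",
    "hg_modes_1d",
    "hg_basis",
    "required_half_extent",
    "measure_amplitudes",
    "measure_object",
    "build_forward_operator",
    "reconstruct_object",
    "hgi_label",
    "LABEL_GRID",
]

LABEL_GRID = 50  # reconstruction raster: 50 x 50 sites over the frame


def hg_modes_1d(n_max: int, x: np.ndarray, sigma: float) -> np.ndarray:
    """Orthonormal 1D Hermite-Gaussian functions u_0..u_N sampled on ``x``.

    Uses the stable three-term recurrence of harmonic-oscillator
    eigenfunctions with length scale ``a = sqrt(2) sigma`` (so that
    ``|u_0|^2`` has standard deviation ``sigma``).
    """
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    a = np.sqrt(2.0) * sigma
    xi = x / a
    u = np.empty((n_max + 1, len(x)))
    u[0] = np.pi**-0.25 * a**-0.5 * np.exp(-(xi**2) / 2.0)
    if n_max >= 1:
        u[1] = np.sqrt(2.0) * xi * u[0]
    for n in range(1, n_max):
        u[n + 1] = (np.sqrt(2.0 / (n + 1)) * xi * u[n]
                    - np.sqrt(n / (n + 1)) * u[n - 1])
    return u


def required_half_extent(n_max: int, sigma: float, tol: float = 1e-6) -> float:
    """Half-extent containing all but ``tol`` of mode (N, N)'s energy.

    Computed from the 1D tail of u_N (each axis is allotted ``tol/2``).
    """
    a = np.sqrt(2.0) * sigma
    # generous probe grid: classical turning point plus evanescent tail
    probe = np.arange(0.0, (np.sqrt(2 * n_max + 1) + 6.0) * a, min(1.0, a / 8))
    u = hg_modes_1d(n_max, probe, sigma)[n_max]
    energy = 2.0 * np.cumsum(u**2) * (probe[1] - probe[0])
    total = energy[-1]
    idx = np.searchsorted(energy, total * (1.0 - tol / 2.0))
    return float(probe[min(idx, len(probe) - 1)])


@dataclass
class HGBasis:
    """Sampled Hermite-Gaussian basis of orders 0..N on a square grid."""

    n_max: int = 20
    sigma: float = 30.0
    x: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    modes_1d: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.x is None:
            # even-sized grid (half-integer coordinates) so that even DMD
            # frames embed in it without any sub-pixel offset
            half = int(np.ceil(required_half_extent(self.n_max, self.sigma)))
            self.x = frame_coords(2 * (half + 1))
        self.x = np.asarray(self.x, dtype=float)
        half_extent = float(np.max(np.abs(self.x)))
        needed = required_half_extent(self.n_max, self.sigma)
        if half_extent < needed:
            raise ValueError(
                f"basis grid half-extent {half_extent:.0f} px too small for "
                f"mode ({self.n_max}, {self.n_max}); at least {needed:.0f} px "
                "is required to contain its energy to 1e-6"
            )
        if self.modes_1d is None:
            self.modes_1d = hg_modes_1d(self.n_max, self.x, self.sigma)

    @property
    def pitch(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def n_modes(self) -> int:
        return (self.n_max + 1) ** 2

    def mode(self, m: int, n: int) -> np.ndarray:
        """Sampled 2D mode phi_mn (m indexes y, n indexes x)."""
        return np.outer(self.modes_1d[m], self.modes_1d[n])

    def gram_error(self) -> float:
        """Worst deviation of the sampled 1D Gram matrix from identity."""
        g = self.modes_1d @ self.modes_1d.T * self.pitch
        return float(np.max(np.abs(g - np.eye(self.n_max + 1))))


@dataclass
class ModeAmplitudes:
    """Complex HG mode coefficients c_mn (m indexes y, n indexes x)."""

    c: np.ndarray
    sigma: float
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=complex)
        if self.c.ndim != 2 or self.c.shape[0] != self.c.shape[1]:
            raise ValueError("mode coefficients must form a square (N+1, N+1) array")

    @property
    def n_max(self) -> int:
        return self.c.shape[0] - 1

    @property
    def n_modes(self) -> int:
        return self.c.size

    def vector(self) -> np.ndarray:
        """Flat complex vector in row-major (m, n) order."""
        return self.c.ravel()

    def measurement_vector(self) -> np.ndarray:
        """Real measurement vector, Re/Im interleaved; length 2 (N+1)^2."""
        flat = self.vector()
        out = np.empty(2 * flat.size)
        out[0::2] = flat.real
        out[1::2] = flat.imag
        return out

    @classmethod
    def from_measurement_vector(cls, vec: np.ndarray, sigma: float) -> "ModeAmplitudes":
        vec = np.asarray(vec, dtype=float)
        n = int(round(np.sqrt(vec.size / 2)))
        if 2 * n * n != vec.size:
            raise ValueError("measurement vector length must be 2 (N+1)^2")
        flat = vec[0::2] + 1j * vec[1::2]
        return cls(flat.reshape(n, n), sigma)

    def to_csv(self, path: str) -> None:
        n = self.n_max + 1
        m_idx, n_idx = np.divmod(np.arange(n * n), n)
        flat = self.vector()
        np.savetxt(path, np.column_stack([m_idx, n_idx, flat.real, flat.imag]),
                   delimiter=",", header="m,n,re,im", comments="")


def hg_basis(n_max: int = 20, sigma: float = 30.0,
             x: np.ndarray | None = None) -> HGBasis:
    """Construct the orthonormal sampled basis (see :class:`HGBasis`)."""
    return HGBasis(n_max=n_max, sigma=sigma, x=x)


def measure_amplitudes(fieldmap: FieldMap, basis: HGBasis,
                       noise_sd: float = 0.0,
                       seed: int | None = None) -> ModeAmplitudes:
    """Project an image-plane field onto the basis: c_mn = <phi_mn, E>.

    The field and basis must share the grid.  With ``noise_sd > 0`` an
    independent complex Gaussian of that standard deviation (per quadrature)
    is added to every coefficient -- a surrogate for local-oscillator shot
    noise in sequential heterodyne mode readout.
    """
    ny, nx = fieldmap.values.shape
    if ny != len(basis.x) or nx != len(basis.x):
        raise ValueError(
            f"field grid {fieldmap.values.shape} does not match the basis "
            f"grid ({len(basis.x)}, {len(basis.x)})"
        )
    if abs(fieldmap.pitch_px - basis.pitch) > 1e-9:
        raise ValueError("field and basis grid pitches differ")
    u = basis.modes_1d
    c = (u @ fieldmap.values @ u.T) * basis.pitch**2
    return _with_noise(c, basis.sigma, noise_sd, seed)


def _with_noise(c: np.ndarray, sigma: float, noise_sd: float,
                seed: int | None) -> ModeAmplitudes:
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        c = c + noise_sd * (rng.standard_normal(c.shape)
                            + 1j * rng.standard_normal(c.shape))
    return ModeAmplitudes(np.asarray(c, dtype=complex), sigma, noise_sd, seed)


def _adjoint_tables(basis: HGBasis, config: OpticsConfig,
                    x_obj: np.ndarray) -> np.ndarray:
    """1D tables w_n(x) = (u_n (*) g)(x) on object-plane columns ``x_obj``.

    These are the convolution adjoints: for a separable APSF g(x)g(y),
    <u_m x u_n, APSF (*) f> = <w_m x w_n, f> for any object raster f.  The
    kernel (truncation, normalisation) and the quadrature grid are exactly
    those of the image-plane convolution route, so the two paths agree to
    rounding error.
    """
    if config.apsf_model != "gaussian":
        raise NotImplementedError(
            "the separable fast path requires the Gaussian APSF model"
        )
    s = config.sigma_det_px
    half_k = int(np.ceil(7 * s))
    taps = frame_coords(2 * half_k + 1)
    norm = np.sqrt((gaussian_apsf_1d(taps, s) ** 2).sum())
    x_obj = np.asarray(x_obj, dtype=float)
    d = basis.x[None, :] - x_obj[:, None]
    g = np.where(np.abs(d) <= half_k + 1e-9,
                 gaussian_apsf_1d(d, s) / norm, 0.0)
    return basis.modes_1d @ g.T * basis.pitch


class _TableCache(dict):
    def key(self, basis: HGBasis, config: OpticsConfig, n: int) -> tuple:
        return (basis.n_max, basis.sigma, config.sigma_det_px, n)


_tables: _TableCache = _TableCache()


def _frame_tables(basis: HGBasis, config: OpticsConfig, frame_px: int) -> np.ndarray:
    key = _tables.key(basis, config, frame_px)
    if key not in _tables:
        _tables[key] = _adjoint_tables(basis, config, frame_coords(frame_px))
    return _tables[key]


def measure_object(obj: ObjectPattern | np.ndarray, config: OpticsConfig,
                   basis: HGBasis, shift_S: tuple[float, float] = (0.0, 0.0),
                   noise_sd: float = 0.0,
                   seed: int | None = None) -> ModeAmplitudes:
    """Mode amplitudes of the image of a (possibly displaced) frame object.

    Equivalent to forming the coherent image field and calling
    :func:`measure_amplitudes`, but computed by the exact separable
    contraction for the Gaussian APSF.  ``shift_S`` follows the scan
    convention: the displayed pattern is the object displaced by ``-S``.
    Focused illumination (finite ``sigma_il_px``) multiplies the displayed
    object by the centred illumination amplitude before detection.
    """
    if isinstance(obj, ObjectPattern):
        pattern = obj
    else:
        pattern = ObjectPattern(np.asarray(obj, dtype=np.uint8))
    raster = pattern.shifted((-shift_S[0], -shift_S[1])).pixels.astype(float) \
        if shift_S != (0.0, 0.0) else pattern.pixels.astype(float)
    il = illumination_amplitude(config, raster.shape)
    w = _frame_tables(basis, config, raster.shape[0])
    c = w @ (raster * il) @ w.T
    return _with_noise(c, basis.sigma, noise_sd, seed)


# ---------------------------------------------------------------------------
# forward operator and reconstruction


@dataclass
class ForwardOperator:
    """Linear map from a pixelised object amplitude to mode amplitudes.

    Column ``j`` holds the amplitudes measured from the image of a unit
    object pixel (a square of side ``pixel_px``) at reconstruction-grid site
    ``j`` (row-major over (y, x)).  ``illumination`` records the amplitude
    envelope the operator was built with (1 for widefield).
    """

    matrix: np.ndarray
    basis: HGBasis
    config: OpticsConfig
    grid_x: np.ndarray
    grid_y: np.ndarray
    pixel_px: float
    _svd: tuple | None = field(default=None, repr=False)

    @property
    def n_sites(self) -> tuple[int, int]:
        return (len(self.grid_y), len(self.grid_x))

    def apply(self, obj_on_grid: np.ndarray) -> ModeAmplitudes:
        """Amplitudes predicted for an object discretised on the recon grid."""
        c = self.matrix @ np.asarray(obj_on_grid, dtype=complex).ravel()
        n = self.basis.n_max + 1
        return ModeAmplitudes(c.reshape(n, n), self.basis.sigma)

    def svd(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._svd is None:
            self._svd = np.linalg.svd(self.matrix, full_matrices=False)
        return self._svd


def build_forward_operator(
    basis: HGBasis,
    config: OpticsConfig,
    recon_grid: int | tuple[np.ndarray, np.ndarray] = LABEL_GRID,
    frame_px: int = 210,
) -> ForwardOperator:
    """Discretise the measurement model over a reconstruction grid.

    ``recon_grid`` is either the number of sites per axis spanning the frame
    (box pixels of side ``frame_px / n``) or explicit (y, x) site coordinate
    arrays.  Focused illumination is taken from ``config.sigma_il_px`` and is
    centred at the grid origin.
    """
    if isinstance(recon_grid, int):
        pixel = frame_px / recon_grid
        xs = frame_coords(recon_grid, pixel)
        ys = xs.copy()
    else:
        ys, xs = recon_grid
        pixel = float(xs[1] - xs[0])

    if config.apsf_model == "gaussian":
        # B[n, j] = <u_n (*) g, box_j . a_il> -- exact separable build; the
        # box quadrature uses ~1 px sub-samples so that DMD-pixel-aligned
        # reconstruction grids reproduce the frame quadrature exactly
        n_sub = max(1, int(round(pixel)))
        fine = pixel / n_sub
        offsets = (np.arange(n_sub) - (n_sub - 1) / 2.0) * fine
        b = np.empty((basis.n_max + 1, len(xs)))
        w_cols = []
        for j, xc in enumerate(xs):
            w_cols.append(xc + offsets)
        cols = np.concatenate(w_cols)
        w = _adjoint_tables(basis, config, cols)
        if config.widefield:
            a_il = np.ones_like(cols)
        else:
            a_il = np.exp(-(cols**2) / (4 * config.sigma_il_px**2))
        wa = w * a_il
        for j in range(len(xs)):
            sl = slice(j * len(offsets), (j + 1) * len(offsets))
            b[:, j] = wa[:, sl].sum(axis=1) * fine
        by = b if np.array_equal(xs, ys) else None
        if by is None:
            raise ValueError("recon grid must be square")
        n1 = basis.n_max + 1
        mat = np.einsum("mj,nk->mnjk", b, b).reshape(n1 * n1, len(ys) * len(xs))
        matrix = mat.astype(complex)
    else:
        matrix = _build_operator_generic(basis, config, ys, xs, pixel)

    return ForwardOperator(matrix, basis, config, xs, ys, pixel)


def _build_operator_generic(basis: HGBasis, config: OpticsConfig,
                            ys: np.ndarray, xs: np.ndarray,
                            pixel: float) -> np.ndarray:
    """Column-by-column operator build via explicit image formation.

    Used for non-separable APSF models (Jinc): the image of a point at a
    reconstruction site is the shifted APSF sampled on the basis grid, and
    the column is its mode overlap, scaled by the box-pixel area.
    """
    from .optics import jinc

    gx = basis.x
    u = basis.modes_1d
    n1 = basis.n_max + 1
    norm = np.sqrt(np.sum(np.abs(make_apsf(config).values) ** 2))
    scale = 2 * np.pi * config.na * config.pitch_um * 1e-6 / (
        config.wavelength_nm * 1e-9)
    cols = np.empty((n1 * n1, len(ys) * len(xs)), dtype=complex)
    for jy, yc in enumerate(ys):
        for jx, xc in enumerate(xs):
            rr = np.hypot(gx[:, None] - yc, gx[None, :] - xc)
            img = jinc(scale * rr) / norm
            if not config.widefield:
                img = img * np.exp(-(yc**2 + xc**2) / (4 * config.sigma_il_px**2))
            c = (u @ img @ u.T) * basis.pitch**2 * pixel**2
            cols[:, jy * len(xs) + jx] = c.ravel()
    return cols


def reconstruct_object(
    amplitudes: ModeAmplitudes,
    operator: ForwardOperator,
    sv_floor_rel: float = 1e-3,
) -> tuple[IntensityMap, FieldMap]:
    """Tikhonov-damped pseudoinverse reconstruction from mode amplitudes.

    Singular values below ``sv_floor_rel`` times the largest are discarded
    (mode amplitudes decay exponentially with order, so the inversion must
    be damped; use ~1e-1 under measurement noise).  Returns the intensity
    ``|a|^2`` on the reconstruction grid together with the complex field
    estimate.
    """
    if amplitudes.n_max != operator.basis.n_max:
        raise ValueError("amplitudes and operator use different mode counts")
    u_svd, s, vh = operator.svd()
    if sv_floor_rel <= 0:
        import warnings

        warnings.warn("zero regularisation on an ill-conditioned operator; "
                      "flooring singular values at 1e-12 of the largest")
        sv_floor_rel = 1e-12
    keep = s >= sv_floor_rel * s[0]
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    a = (vh.conj().T * s_inv) @ (u_svd.conj().T @ amplitudes.vector())
    ny, nx = operator.n_sites
    fieldmap = FieldMap(a.reshape(ny, nx), pitch_px=operator.pixel_px)
    return fieldmap.intensity(), fieldmap


def hgi_label(
    obj: ObjectPattern,
    config: OpticsConfig,
    basis: HGBasis,
    operator: ForwardOperator,
    smear_sigma: float = 1.0,
    illuminated: bool = False,
    sv_floor_rel: float = 1e-3,
) -> np.ndarray:
    """Training label: noiseless perfect-HGI reconstruction on the 50x50 grid.

    The object is forward-simulated and reconstructed without noise, then
    (for the scanning variant, ``illuminated=True``) multiplied by the
    focused-illumination intensity envelope so the label fades to black
    outside the illuminated region, and finally smeared by a Gaussian of
    ``smear_sigma`` label pixels.  Values are clipped to [0, 1].
    """
    from dataclasses import replace

    from scipy.ndimage import gaussian_filter

    widefield_cfg = config if config.widefield else replace(
        config, sigma_il_px=np.inf)
    amps = measure_object(obj, widefield_cfg, basis)
    intensity, _ = reconstruct_object(amps, operator, sv_floor_rel)
    label = intensity.values
    if illuminated:
        il = illumination_amplitude(config, label.shape,
                                    pitch_px=operator.pixel_px)
        label = label * il**2
    if smear_sigma > 0:
        label = gaussian_filter(label, smear_sigma, mode="constant")
    return np.clip(label, 0.0, 1.0)
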