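"""Binary DMD-style test objects.

Everything the workbench images is a binary amplitude bitmap displayed on a
simulated digital micromirror device (DMD): a square frame of 210 x 210
physical pixels (7.56 um pitch), usually composed of 10 x 10-pixel binary
"logical" pixels.  This module generates the standard object families --
parallel line pairs for resolution metrology, random bitmaps / ellipses /
lines for training sets, and a synthetic emblem standing in for a large
printed logo -- plus tiling of oversized bitmaps into overlapping frames.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_FRAME_PX = 210
DEFAULT_LOGICAL_PX = 10
DEFAULT_PITCH_UM = 7.56

__all__ = [
    "ObjectPattern",
    "TrainingSet",
    "frame_coords",
    "make_line_pair",
    "standard_line_pair_series",
    "make_random_bitmap",
    "make_random_ellipse",
    "make_random_line",
    "make_training_set",
    "make_synthetic_emblem",
    "tile_large_object",
    "reassemble_tiles",
]


def frame_coords(n: int, pitch: float = 1.0) -> np.ndarray:
    """Centred pixel-centre coordinates of an ``n``-sample axis.

    The frame origin sits at the geometric centre, so for even ``n`` the
    coordinates are half-integers.  ``x`` increases with column index.
    """
    return (np.arange(n) - (n - 1) / 2.0) * pitch


@dataclass
class ObjectPattern:
    """A binary amplitude bitmap on the DMD grid.

    Parameters
    ----------
    pixels : ndarray of {0, 1}, shape (rows, cols)
        Mirror state; 1 means "on" (reflecting into the imaging path).
    pitch_um : float
        Physical pixel pitch in micrometres.
    logical_pixel : int
        Side of a logical pixel in physical pixels (metadata only; not all
        patterns are logical-pixel aligned).
    """

    pixels: np.ndarray
    pitch_um: float = DEFAULT_PITCH_UM
    logical_pixel: int = DEFAULT_LOGICAL_PX

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("ObjectPattern pixels must be binary (0/1)")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def frame_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def amplitude(self) -> np.ndarray:
        """Flat-phase complex amplitude reflection of the pattern."""
        return self.pixels.astype(float)

    def on_fraction(self) -> float:
        return float(self.pixels.mean())

    def shifted(self, shift: tuple[float, float]) -> "ObjectPattern":
        """Pattern displaced by ``(dy, dx)`` physical pixels inside the frame.

        Pixels shifted beyond the frame boundary are lost, which is what a
        physical DMD does when a pattern is scanned by re-displaying it
        displaced.  Non-integer shifts are rounded to the pixel grid.
        """
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        out = np.zeros_like(self.pixels)
        ny, nx = self.pixels.shape
        ys = slice(max(dy, 0), min(ny + dy, ny))
        xs = slice(max(dx, 0), min(nx + dx, nx))
        ys_src = slice(max(-dy, 0), min(ny - dy, ny))
        xs_src = slice(max(-dx, 0), min(nx - dx, nx))
        out[ys, xs] = self.pixels[ys_src, xs_src]
        return ObjectPattern(out, self.pitch_um, self.logical_pixel)

    # -- raster I/O --------------------------------------------------------

    def to_image(self, path: str) -> None:
        """Write as an 8-bit grayscale PNG/TIFF (on = 255)."""
        from PIL import Image

        Image.fromarray(self.pixels * np.uint8(255), mode="L").save(path)

    @classmethod
    def from_image(cls, path: str, threshold: float = 0.5, **kwargs) -> "ObjectPattern":
        """Load an 8-bit grayscale raster, binarising at ``threshold``."""
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
        return cls((arr >= threshold).astype(np.uint8), **kwargs)


@dataclass
class TrainingSet:
    """An ordered, shuffled collection of patterns with a 9:1 split.

    ``labels`` stays ``None`` until a reconstruction module attaches label
    rasters (one per pattern, in the same order).
    """

    patterns: list[ObjectPattern]
    kinds: list[str]
    split_index: int
    seed: int
    composition: tuple[int, int, int]
    labels: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.patterns)

    @property
    def train(self) -> list[ObjectPattern]:
        return self.patterns[: self.split_index]

    @property
    def validation(self) -> list[ObjectPattern]:
        return self.patterns[self.split_index:]


# ---------------------------------------------------------------------------
# generators


def _empty_frame(frame_px: int) -> np.ndarray:
    return np.zeros((frame_px, frame_px), dtype=np.uint8)


def make_line_pair(
    separation_px: int,
    length_px: int = 175,
    line_width_px: int = DEFAULT_LOGICAL_PX,
    frame_px: int = DEFAULT_FRAME_PX,
    orientation: str = "vertical",
) -> ObjectPattern:
    """Two parallel lines, centred in the frame.

    ``separation_px`` is the centre-to-centre distance measured across the
    lines; ``separation_px = 0`` degenerates to a single line.  Lines are
    vertical by default (separation along x), matching the resolution-target
    layout used throughout the workbench.
    """
    if separation_px < 0:
        raise ValueError("separation_px must be >= 0")
    if length_px < 1 or line_width_px < 1:
        raise ValueError("length_px and line_width_px must be >= 1")
    if length_px > frame_px:
        raise ValueError(
            f"length_px = {length_px} exceeds the frame side {frame_px}"
        )
    if separation_px + line_width_px > frame_px:
        raise ValueError(
            f"separation_px + line_width_px = {separation_px + line_width_px} "
            f"exceeds the frame side {frame_px}"
        )
    x = frame_coords(frame_px)
    # half-open [c - L/2, c + L/2) intervals give exact pixel counts on the
    # even frame grid (odd lengths end up half a pixel off centre)
    along = (x >= -length_px / 2.0 - 1e-9) & (x < length_px / 2.0 - 1e-9)
    across = np.zeros(frame_px, dtype=bool)
    for centre in (-separation_px / 2.0, separation_px / 2.0):
        across |= (x >= centre - line_width_px / 2.0 - 1e-9) & \
                  (x < centre + line_width_px / 2.0 - 1e-9)
    img = np.outer(along, across).astype(np.uint8)
    if orientation == "horizontal":
        img = img.T
    elif orientation != "vertical":
        raise ValueError("orientation must be 'vertical' or 'horizontal'")
    return ObjectPattern(img)


def standard_line_pair_series(
    separations: Sequence[int] = tuple(range(20, 131, 10)), **kwargs
) -> dict[int, ObjectPattern]:
    """The standard resolution series: separations 20..130 px in steps of 10."""
    return {int(s): make_line_pair(int(s), **kwargs) for s in separations}


def make_random_bitmap(
    fill_factor: float,
    seed: int,
    frame_px: int = DEFAULT_FRAME_PX,
    logical_pixel: int = DEFAULT_LOGICAL_PX,
) -> ObjectPattern:
    """Random logical-pixel bitmap: each logical pixel on with ``fill_factor``."""
    if not 0.0 < fill_factor < 1.0:
        raise ValueError("fill_factor must lie strictly between 0 and 1")
    n_logical = frame_px // logical_pixel
    rng = np.random.default_rng(seed)
    logical = (rng.random((n_logical, n_logical)) < fill_factor).astype(np.uint8)
    img = np.kron(logical, np.ones((logical_pixel, logical_pixel), dtype=np.uint8))
    full = _empty_frame(frame_px)
    full[: img.shape[0], : img.shape[1]] = img
    return ObjectPattern(full, logical_pixel=logical_pixel)


def make_random_ellipse(
    seed: int,
    frame_px: int = DEFAULT_FRAME_PX,
    logical_pixel: int = DEFAULT_LOGICAL_PX,
) -> ObjectPattern:
    """Filled ellipse with random centre, semi-axes and orientation.

    Semi-axes are drawn uniformly from [1, 10] logical pixels, the centre
    uniformly inside the frame and the orientation uniformly over [0, pi).
    """
    rng = np.random.default_rng(seed)
    cy, cx = rng.uniform(0, frame_px, size=2)
    a, b = rng.uniform(1, 10, size=2) * logical_pixel
    theta = rng.uniform(0, np.pi)
    y, x = np.mgrid[0:frame_px, 0:frame_px]
    yr = (y + 0.5) - cy
    xr = (x + 0.5) - cx
    u = np.cos(theta) * xr + np.sin(theta) * yr
    v = -np.sin(theta) * xr + np.cos(theta) * yr
    img = ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)
    return ObjectPattern(img, logical_pixel=logical_pixel)


def make_random_line(
    seed: int,
    frame_px: int = DEFAULT_FRAME_PX,
    logical_pixel: int = DEFAULT_LOGICAL_PX,
) -> ObjectPattern:
    """Straight line of variable width between two random frame points."""
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0, frame_px, size=2)
    p1 = rng.uniform(0, frame_px, size=2)
    width = rng.uniform(1, 3) * logical_pixel
    y, x = np.mgrid[0:frame_px, 0:frame_px]
    pts = np.stack([(y + 0.5).ravel(), (x + 0.5).ravel()], axis=1)
    d = p1 - p0
    denom = float(d @ d)
    if denom < 1e-12:
        t = np.zeros(len(pts))
    else:
        t = np.clip((pts - p0) @ d / denom, 0.0, 1.0)
    closest = p0 + t[:, None] * d
    dist = np.linalg.norm(pts - closest, axis=1).reshape(frame_px, frame_px)
    return ObjectPattern((dist <= width / 2.0).astype(np.uint8),
                         logical_pixel=logical_pixel)


def make_training_set(
    n_bitmaps: int = 10_000,
    n_ellipses: int = 5_000,
    n_lines: int = 5_000,
    seed: int = 0,
    fill_range: tuple[float, float] = (0.2, 0.8),
    frame_px: int = DEFAULT_FRAME_PX,
    logical_pixel: int = DEFAULT_LOGICAL_PX,
) -> TrainingSet:
    """Training collection: bitmaps (20-80% fill), ellipses and lines, 9:1 split.

    Per-pattern seeds are derived from the master seed by a counter-based
    spawn, so the collection is reproducible and order-independent of how
    individual patterns are materialised.
    """
    if min(n_bitmaps, n_ellipses, n_lines) < 0:
        raise ValueError("pattern counts must be >= 0")
    master = np.random.SeedSequence(seed)
    fill_rng = np.random.default_rng(master.spawn(1)[0])
    patterns: list[ObjectPattern] = []
    kinds: list[str] = []
    counter = 0

    def child_seed() -> int:
        nonlocal counter
        counter += 1
        # counter-based derivation keeps every pattern's stream independent
        return int(np.random.SeedSequence([seed, counter]).generate_state(1)[0])

    for _ in range(n_bitmaps):
        fill = float(fill_rng.uniform(*fill_range))
        patterns.append(make_random_bitmap(fill, child_seed(), frame_px, logical_pixel))
        kinds.append("bitmap")
    for _ in range(n_ellipses):
        patterns.append(make_random_ellipse(child_seed(), frame_px, logical_pixel))
        kinds.append("ellipse")
    for _ in range(n_lines):
        patterns.append(make_random_line(child_seed(), frame_px, logical_pixel))
        kinds.append("line")

    order = np.random.default_rng(master.spawn(2)[1]).permutation(len(patterns))
    patterns = [patterns[i] for i in order]
    kinds = [kinds[i] for i in order]
    split_index = int(round(0.9 * len(patterns)))
    return TrainingSet(patterns, kinds, split_index, seed,
                       (n_bitmaps, n_ellipses, n_lines))


def make_synthetic_emblem(
    width_px: int = 1680,
    height_px: int = 630,
    seed: int = 7,
    logical_pixel: int = DEFAULT_LOGICAL_PX,
) -> np.ndarray:
    """Synthetic logo-like bitmap (glyph strokes, rings and bars).

    A stand-in for a large printed emblem: a band of glyph-like strokes on a
    bordered field, rich in edges at the logical-pixel scale.  Deterministic
    under ``seed``.  Returned as a raw binary raster (it is larger than one
    frame and is meant to be tiled with :func:`tile_large_object`).
    """
    rng = np.random.default_rng(seed)
    img = np.zeros((height_px, width_px), dtype=np.uint8)
    lp = logical_pixel
    # border
    img[: 2 * lp, :] = 1
    img[-2 * lp:, :] = 1
    img[:, : 2 * lp] = 1
    img[:, -2 * lp:] = 1
    y, x = np.mgrid[0:height_px, 0:width_px]
    # rings
    n_rings = max(2, width_px // 400)
    for _ in range(n_rings):
        cy = rng.uniform(0.25, 0.75) * height_px
        cx = rng.uniform(0.1, 0.9) * width_px
        r = rng.uniform(4, 10) * lp
        rr = np.hypot(y - cy, x - cx)
        img[(rr <= r) & (rr >= r - 1.5 * lp)] = 1
    # glyph-like vertical/diagonal strokes in a central band
    band = (y > 0.3 * height_px) & (y < 0.7 * height_px)
    n_strokes = max(6, width_px // 120)
    for _ in range(n_strokes):
        cx = rng.uniform(0.08, 0.92) * width_px
        slant = rng.uniform(-0.4, 0.4)
        w = rng.uniform(0.8, 1.6) * lp
        stroke = np.abs((x - cx) - slant * (y - height_px / 2)) <= w / 2
        img[stroke & band] = 1
    # horizontal bars
    for _ in range(3):
        cy = rng.uniform(0.32, 0.68) * height_px
        x0, x1 = np.sort(rng.uniform(0.1, 0.9, 2)) * width_px
        bar = (np.abs(y - cy) <= 0.6 * lp) & (x >= x0) & (x <= x1)
        img[bar] = 1
    return img


def tile_large_object(
    bitmap: np.ndarray,
    frame_px: int = DEFAULT_FRAME_PX,
    overlap_px: int = 70,
) -> list[tuple[ObjectPattern, tuple[int, int]]]:
    """Cut an oversized bitmap into overlapping frame-sized tiles.

    Returns ``(pattern, (row_offset, col_offset))`` pairs; offsets refer to
    the tile's top-left corner in the input bitmap, so stitching can invert
    the operation.  A bitmap smaller than one frame yields a single
    zero-padded tile at offset (0, 0).
    """
    if overlap_px >= frame_px:
        raise ValueError("overlap_px must be smaller than frame_px")
    bitmap = np.asarray(bitmap, dtype=np.uint8)
    h, w = bitmap.shape
    if h <= frame_px and w <= frame_px:
        tile = _empty_frame(frame_px)
        tile[:h, :w] = bitmap
        return [(ObjectPattern(tile), (0, 0))]

    def offsets(size: int) -> list[int]:
        if size <= frame_px:
            return [0]
        stride = frame_px - overlap_px
        offs = list(range(0, size - frame_px, stride))
        offs.append(size - frame_px)
        return offs

    tiles = []
    for oy in offsets(h):
        for ox in offsets(w):
            patch = np.zeros((frame_px, frame_px), dtype=np.uint8)
            sub = bitmap[oy: oy + frame_px, ox: ox + frame_px]
            patch[: sub.shape[0], : sub.shape[1]] = sub
            tiles.append((ObjectPattern(patch), (oy, ox)))
    return tiles


def reassemble_tiles(
    tiles: list[tuple[ObjectPattern, tuple[int, int]]],
    shape: tuple[int, int],
) -> np.ndarray:
    """Overlap-aware reassembly of raw tiles; inverts :func:`tile_large_object`."""
    out = np.zeros(shape, dtype=np.uint8)
    for pattern, (oy, ox) in tiles:
        h = min(pattern.frame_px, shape[0] - oy)
        w = min(pattern.frame_px, shape[1] - ox)
        out[oy: oy + h, ox: ox + w] = pattern.pixels[:h, :w]
    return out
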