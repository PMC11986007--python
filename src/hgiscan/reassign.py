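"""Pixel reassignment and frame stitching.

A scan snapshot taken with the object displaced by ``S`` sees the object
convolved with the narrow composed PSF of width sigma_ISM, magnified by
``sigma_det^2 / sigma_ISM^2`` about the illumination axis and apodised by
the detection envelope.  Pixel reassignment inverts the magnification
(contracting each snapshot about the origin by ``sigma_ISM^2 /
sigma_det^2``) and sums the snapshots displaced by their own scan shifts:

    I_ISM(y) = sum_i I'(y - S_i | S_i)

which equals the object convolved with the sigma_ISM-wide PSF, times the
summed illumination envelope.  Dividing by that envelope (the response of
the same pipeline to a uniform all-on object) flattens raster-induced
shading; the division is the default in the workbench pipelines.

The derivation is one-dimensional and Gaussian; in 2D the contraction is
applied isotropically about the illumination centre, and for HGI snapshots
the effective detection width entering the contraction factor is fitted
from the pipeline's own line response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .optics import IntensityMap, Snapshot

__all__ = [
    "ReassignConfig",
    "rescale_snapshot",
    "pixel_reassign",
    "stitch_frames",
]

_ORDERS = {"bilinear": 1, "bicubic": 3}


@dataclass
class ReassignConfig:
    """Geometry of the reassignment step.

    ``sigma_det_eff`` is the effective detection width seen by the
    snapshots (sigma_det for direct imaging; a fitted effective width for
    HGI snapshots); ``sigma_ism`` the composed width.  The rescale factor
    ``sigma_det_eff^2 / sigma_ism^2`` is >= 1 (2 for matched widths).
    """

    sigma_det_eff: float
    sigma_ism: float
    interpolation: str = "bilinear"
    normalise: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.sigma_ism <= self.sigma_det_eff:
            raise ValueError("require 0 < sigma_ism <= sigma_det_eff")
        if self.interpolation not in _ORDERS:
            raise ValueError("interpolation must be 'bilinear' or 'bicubic'")

    @property
    def rescale_factor(self) -> float:
        return float(self.sigma_det_eff**2 / self.sigma_ism**2)


def rescale_snapshot(snapshot: Snapshot, config: ReassignConfig) -> Snapshot:
    """Contract a snapshot about the grid origin by sigma_ism^2/sigma_det^2.

    Implements the coordinate change ``I'(y|S) = I((sigma_det^2 /
    sigma_ism^2) y | S)``: the output at position y samples the input at the
    magnified position.  The grid (and its pitch) is unchanged.
    """
    factor = config.rescale_factor
    if abs(factor - 1.0) < 1e-12:
        return Snapshot(IntensityMap(snapshot.intensity.values.copy(),
                                     snapshot.intensity.pitch_px),
                        snapshot.shift_S)
    vals = snapshot.intensity.values
    ny, nx = vals.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    coords = np.stack([(yy - cy) * factor + cy, (xx - cx) * factor + cx])
    out = ndimage.map_coordinates(vals, coords, order=_ORDERS[config.interpolation],
                                  mode="constant", cval=0.0)
    out = np.clip(out, 0.0, None)  # bicubic can ring slightly negative
    return Snapshot(IntensityMap(out, snapshot.intensity.pitch_px), snapshot.shift_S)


def _shift_image(vals: np.ndarray, shift_rows: float, shift_cols: float,
                 order: int) -> np.ndarray:
    if abs(shift_rows - round(shift_rows)) < 1e-9 and \
       abs(shift_cols - round(shift_cols)) < 1e-9:
        dr, dc = int(round(shift_rows)), int(round(shift_cols))
        out = np.zeros_like(vals)
        ny, nx = vals.shape
        rs = slice(max(dr, 0), min(ny + dr, ny))
        cs = slice(max(dc, 0), min(nx + dc, nx))
        rs_src = slice(max(-dr, 0), min(ny - dr, ny))
        cs_src = slice(max(-dc, 0), min(nx - dc, nx))
        out[rs, cs] = vals[rs_src, cs_src]
        return out
    return np.clip(ndimage.shift(vals, (shift_rows, shift_cols), order=order,
                                 mode="constant", cval=0.0), 0.0, None)


def pixel_reassign(snapshots: list[Snapshot], config: ReassignConfig,
                   weight: np.ndarray | None = None) -> IntensityMap:
    """Combine scan snapshots: rescale each, displace by its shift, and sum.

    With ``weight`` given (the same pipeline's response to a uniform all-on
    object) the sum is divided by it wherever it exceeds 1e-3 of its peak,
    flattening the raster-induced illumination shading.  Without a weight
    the raw sum is returned, whose total intensity equals the sum of the
    rescaled snapshots' totals exactly.
    """
    if not snapshots:
        raise ValueError("no snapshots to reassign")
    pitch = snapshots[0].intensity.pitch_px
    order = _ORDERS[config.interpolation]
    acc = np.zeros_like(snapshots[0].intensity.values)
    # fixed summation order makes the result independent of scan ordering
    for snap in sorted(snapshots, key=lambda s: tuple(s.shift_S)):
        rescaled = rescale_snapshot(snap, config)
        sy, sx = snap.shift_S
        acc += _shift_image(rescaled.intensity.values, sy / pitch, sx / pitch,
                            order)
    if weight is not None:
        w = np.asarray(weight, dtype=float)
        mask = w > 1e-3 * w.max()
        acc = np.where(mask, acc / np.where(mask, w, 1.0), 0.0)
    return IntensityMap(acc, pitch)


def stitch_frames(frame_images: list[np.ndarray | IntensityMap],
                  tile_offsets: list[tuple[int, int]],
                  shape: tuple[int, int],
                  crop_margin: int = 35) -> np.ndarray:
    """Place central crops of overlapping tiles on a large canvas.

    Each tile keeps its central region (``crop_margin`` trimmed per side,
    except along canvas borders, which stay uncropped so the canvas remains
    covered); residual overlaps are feathered by averaging.
    """
    if len(frame_images) != len(tile_offsets):
        raise ValueError("one offset per tile is required")
    acc = np.zeros(shape, dtype=float)
    cnt = np.zeros(shape, dtype=float)
    for img, (oy, ox) in zip(frame_images, tile_offsets):
        vals = img.values if isinstance(img, IntensityMap) else np.asarray(img)
        fy, fx = vals.shape
        m_top = 0 if oy == 0 else crop_margin
        m_left = 0 if ox == 0 else crop_margin
        m_bot = 0 if oy + fy >= shape[0] else crop_margin
        m_right = 0 if ox + fx >= shape[1] else crop_margin
        ys = slice(oy + m_top, min(oy + fy - m_bot, shape[0]))
        xs = slice(ox + m_left, min(ox + fx - m_right, shape[1]))
        sub = vals[m_top: m_top + (ys.stop - ys.start),
                   m_left: m_left + (xs.stop - xs.start)]
        acc[ys, xs] += sub
        cnt[ys, xs] += 1.0
    covered = cnt > 0
    acc[covered] /= cnt[covered]
    return acc
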