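"""Background-offset and velocity-aliasing correction.

Eddy currents leave a small, spatially smooth, temporally static velocity
offset in phase-contrast images.  It is estimated from static tissue
surrounding the vessels — pixels with decent signal magnitude but almost no
velocity fluctuation over the cycle — and its mean velocity is subtracted
everywhere, making static tissue the zero-velocity reference.

Velocities between Venc and 2*Venc wrap and reappear with opposite sign.
Within a vessel ROI whose dominant flow direction is known, such wrapped
samples are restored by shifting them 2*Venc toward the dominant direction.
Double-wrapped velocities (> 2*Venc) are out of contract: the acquisition
must be repeated with a higher Venc.

Order contract: unaliasing must run before offset estimation, since the
offset estimate assumes an unwrapped velocity field near the vessels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .segmentation import VesselROI
from .series_io import CineSeries, VelocitySeries

__all__ = [
    "StaticMask",
    "InsufficientStaticTissueError",
    "detect_static_tissue",
    "background_correct",
    "unalias",
]

_BOX = np.ones((3, 3), dtype=bool)  # Chebyshev unit ball


class InsufficientStaticTissueError(ValueError):
    """Raised when too few pixels qualify as static reference tissue."""


@dataclasses.dataclass(frozen=True, eq=False)
class StaticMask:
    """Static-tissue reference region and its mean velocity offset (cm/s)."""

    mask: np.ndarray  # (H, W) bool
    mean_offset: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


def _bbox_mask(shape: tuple[int, int], rois: list[VesselROI]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for roi in rois:
        rows, cols = np.nonzero(roi.mask)
        out[rows.min():rows.max() + 1, cols.min():cols.max() + 1] = True
    return out


def detect_static_tissue(series: CineSeries, vel: VelocitySeries,
                         rois: list[VesselROI], *,
                         annulus: tuple[int, int] = (3, 10),
                         exclude_rois: list[VesselROI] | None = None,
                         mag_frac: float = 0.3,
                         sd_frac: float = 0.05,
                         min_pixels: int = 20) -> StaticMask:
    """Find static reference tissue around vessel ROIs.

    Candidate pixels lie in an annulus ``annulus[0]..annulus[1]`` pixels
    (Chebyshev distance) around the union of the ROI bounding boxes, have a
    temporal-mean magnitude of at least ``mag_frac`` times the median
    in-ROI magnitude (excludes air), and a temporal velocity SD of at most
    ``sd_frac * Venc`` (excludes flowing blood).  Pixels of any ROI in
    ``exclude_rois`` (default: ``rois``), dilated by 2 to cover the
    partial-volume halo, are removed.

    The returned ``mean_offset`` is the mean over the mask of the
    temporal-mean velocity.
    """
    if not rois:
        raise ValueError("at least one ROI is required")
    inner, outer = annulus
    if not 0 < inner <= outer:
        raise ValueError(f"invalid annulus {annulus}")
    if exclude_rois is None:
        exclude_rois = rois

    shape = vel.velocity.shape[1:]
    base = _bbox_mask(shape, rois)
    ring = ndimage.binary_dilation(base, structure=_BOX, iterations=outer)
    if inner > 1:
        ring &= ~ndimage.binary_dilation(base, structure=_BOX,
                                         iterations=inner - 1)
    else:
        ring &= ~base

    excluded = np.zeros(shape, dtype=bool)
    for roi in exclude_rois:
        excluded |= roi.mask
    excluded = ndimage.binary_dilation(excluded, structure=_BOX, iterations=2)

    mag_mean = series.magnitude.mean(axis=0)
    roi_union = np.zeros(shape, dtype=bool)
    for roi in rois:
        roi_union |= roi.mask
    mag_ref = float(np.median(mag_mean[roi_union]))
    vel_sd = vel.velocity.std(axis=0)

    static = (ring & ~excluded
              & (mag_mean >= mag_frac * mag_ref)
              & (vel_sd <= sd_frac * vel.venc))
    n = int(static.sum())
    if n < min_pixels:
        raise InsufficientStaticTissueError(
            f"insufficient static tissue: {n} qualifying pixels < {min_pixels}"
        )
    mean_offset = float(vel.velocity.mean(axis=0)[static].mean())
    return StaticMask(mask=static, mean_offset=mean_offset)


def background_correct(vel: VelocitySeries, static: StaticMask) -> VelocitySeries:
    """Subtract the static-tissue mean velocity from every pixel and frame.

    After correction the mean velocity over the static mask is exactly zero
    (to float round-off); re-estimating the offset on the corrected series
    therefore returns ~0.
    """
    return VelocitySeries(velocity=vel.velocity - static.mean_offset,
                          venc=vel.venc, pixel_area=vel.pixel_area)


def unalias(vel: VelocitySeries, roi: VesselROI, *,
            min_opposing_frac: float = 0.0) -> VelocitySeries:
    """Restore singly-wrapped velocities inside a vessel ROI.

    In-ROI samples whose sign opposes ``roi.direction_sign`` are shifted by
    ``2 * Venc`` toward the dominant direction when the candidate magnitude
    lies in ``(Venc, 2*Venc]``.  All other samples are left untouched; no
    sample ever leaves ``(-2*Venc, 2*Venc]``.

    ``min_opposing_frac`` guards against noise: opposing samples with
    ``|v| <= min_opposing_frac * Venc`` are treated as genuine near-zero
    flow rather than wrap-around (a truly wrapped peak below 2*Venc *
    (1 - min_opposing_frac) always clears the guard).  The default 0.0
    applies the plain sign rule.
    """
    if not roi.mask.any():
        raise ValueError("ROI must be non-empty")
    venc = vel.venc
    d = roi.direction_sign
    v = vel.velocity.copy()
    sub = v[:, roi.mask]
    opposing = (np.sign(sub) == -d) & (np.abs(sub) > min_opposing_frac * venc)
    candidate = sub + d * 2.0 * venc
    ok = opposing & (np.abs(candidate) > venc) & (np.abs(candidate) <= 2.0 * venc)
    sub[ok] = candidate[ok]
    v[:, roi.mask] = sub
    return VelocitySeries(velocity=v, venc=venc, pixel_area=vel.pixel_area)
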