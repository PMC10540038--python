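"""Construction of the PVS analysis region from tissue labels.

The analysis region is the supratentorial white matter plus basal ganglia.
The label union is smoothed with an edge-preserving 1 mm binary median
filter, enclosed holes (PVS mislabelled as CSF) are filled, and a rim of
voxels within 1 mm of the ventricles is removed. White matter
hyperintensities are returned as a separate mask so the segmentation stage
can exclude them from PVS foreground while (by default) keeping them in the
volume-fraction denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateRoiError, ParameterError
from .volume import LabelVolume, RoiMask


@dataclass
class RoiBuildParams:
    """Parameters of the ROI construction.

    smoothing_radius_mm : radius of the binary median filter ball (default 1).
    ventricle_dilation_mm : rim width removed around the ventricles (default 1).
    include_labels : tissue classes forming the analysis region.
    """

    smoothing_radius_mm: float = 1.0
    ventricle_dilation_mm: float = 1.0
    include_labels: tuple[str, ...] = ("white_matter", "basal_ganglia")

    def __post_init__(self) -> None:
        if self.smoothing_radius_mm < 0 or self.ventricle_dilation_mm < 0:
            raise ParameterError("ROI radii must be >= 0")


def _ball_footprint(radius_mm: float,
                    spacing: tuple[float, float, float]) -> np.ndarray:
    """Voxel offsets whose center-to-center world distance is <= radius."""
    half = [int(np.floor(radius_mm / s + 1e-9)) for s in spacing]
    grids = np.meshgrid(*[np.arange(-h, h + 1) * s
                          for h, s in zip(half, spacing)], indexing="ij")
    dist2 = sum(g ** 2 for g in grids)
    return dist2 <= radius_mm ** 2 + 1e-9


def dilate_mask(mask: RoiMask, radius_mm: float) -> RoiMask:
    """Euclidean dilation: grow to voxels within radius_mm (world distance).

    Radius 0 is the identity.
    """
    if radius_mm < 0:
        raise ParameterError("dilation radius must be >= 0")
    if radius_mm == 0:
        return RoiMask(mask.data.copy(), affine=mask.affine)
    fp = _ball_footprint(radius_mm, mask.spacing)
    out = ndimage.binary_dilation(mask.as_bool(), structure=fp)
    return RoiMask(out, affine=mask.affine)


def fill_holes(mask: RoiMask) -> RoiMask:
    """Fill background components not connected to the grid border.

    Background connectivity is 6 (face neighbors); foreground is never
    removed.
    """
    out = ndimage.binary_fill_holes(mask.as_bool())
    return RoiMask(out, affine=mask.affine)


def smooth_mask(mask: RoiMask, radius_mm: float) -> RoiMask:
    """Edge-preserving binary median filter with a radius_mm ball."""
    if radius_mm < 0:
        raise ParameterError("smoothing radius must be >= 0")
    if radius_mm == 0:
        return RoiMask(mask.data.copy(), affine=mask.affine)
    fp = _ball_footprint(radius_mm, mask.spacing)
    out = ndimage.median_filter(mask.data, footprint=fp, mode="constant", cval=0)
    return RoiMask(out, affine=mask.affine)


def build_pvs_roi(labels: LabelVolume,
                  params: RoiBuildParams | None = None
                  ) -> tuple[RoiMask, RoiMask]:
    """Build the PVS analysis region and the WMH exclusion mask.

    Returns (roi, wmh): roi is smoothed(include-label union) with enclosed
    holes filled, minus the ventricle mask dilated by
    ``ventricle_dilation_mm``; wmh is returned separately so the
    segmentation stage can exclude it from PVS foreground.
    """
    params = params or RoiBuildParams()
    base = labels.mask_for(*params.include_labels)
    if base.n_voxels == 0:
        raise DegenerateRoiError(
            f"no voxels carry labels {params.include_labels}")
    roi = smooth_mask(base, params.smoothing_radius_mm)
    roi = fill_holes(roi)
    vent = labels.mask_for("ventricle")
    if vent.n_voxels > 0:
        rim = dilate_mask(vent, params.ventricle_dilation_mm)
        roi = RoiMask(roi.as_bool() & ~rim.as_bool(), affine=labels.affine)
    wmh = labels.mask_for("wmh")
    if roi.n_voxels == 0:
        raise DegenerateRoiError("analysis region is empty after ROI cleanup")
    return roi, wmh
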