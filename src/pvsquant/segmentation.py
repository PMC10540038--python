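"""PVS segmentation filter chain.

The chain runs, in order: non-local-means denoising (Rician noise on
magnitude MRI), multiscale Frangi vesselness tuned for bright tubular
structures, standardization of the vesselness map by the interquartile range
of its positive in-ROI values, a fixed threshold (2.7 by default, calibrated
against visual ratings), exclusion of white matter hyperintensities,
26-connected component labeling with a minimum component size of 5 voxels,
and volume metrics (PVS volume in cm^3 and as a percentage of the analysis
region: the PVS volume fraction).

Vesselness at scale s uses the Hessian of the image smoothed with a
Gaussian of width s, normalized by s^2, with eigenvalues ordered
|l1| <= |l2| <= |l3|:

    R_A = |l2| / |l3|            (plate vs line)
    R_B = |l1| / sqrt(|l2 l3|)   (blobness)
    S   = sqrt(l1^2 + l2^2 + l3^2)

    V_s = (1 - exp(-R_A^2 / 2 a^2)) * exp(-R_B^2 / 2 b^2)
          * (1 - exp(-S^2 / 2 c^2))        if l2 < 0 and l3 < 0, else 0

and the final map is the voxelwise maximum of V_s over a geometric grid of
scales in [s_min, s_max] mm. The l2, l3 < 0 condition selects structures
brighter than their surroundings, as PVS are on T2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_nl_means, estimate_sigma

from .errors import (
    DegenerateMapError,
    DegenerateRoiError,
    GeometryError,
    ParameterError,
    ShapeError,
)
from .roi import RoiBuildParams, build_pvs_roi
from .volume import LabelVolume, RoiMask, Volume


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class NlmParams:
    """Non-local-means denoising parameters.

    patch_radius / search_radius are in voxels; h is the smoothing strength
    in intensity units (None = 0.8 x a wavelet-based noise-sigma estimate).
    """

    patch_radius: int = 1
    search_radius: int = 3
    h: float | None = None

    def __post_init__(self) -> None:
        if self.patch_radius < 1 or self.search_radius < 1:
            raise ParameterError("NLM radii must be >= 1")
        if self.h is not None and self.h <= 0:
            raise ParameterError("NLM smoothing strength h must be > 0")


@dataclass
class FrangiParams:
    """Multiscale Frangi vesselness parameters.

    alpha, beta weight the plate/line and blob discriminators; c is the
    structureness constant in raw intensity units (500 for the study's T2
    intensity range — rescale for data on another intensity scale). Scales
    are in mm, sampled geometrically from s_min to s_max.
    """

    alpha: float = 0.5
    beta: float = 0.5
    c: float = 500.0
    s_min: float = 0.1
    s_max: float = 5.0
    n_scales: int = 5

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.c) <= 0:
            raise ParameterError("alpha, beta, c must be > 0")
        if not (0 < self.s_min <= self.s_max):
            raise ParameterError("need 0 < s_min <= s_max")
        if self.n_scales < 1:
            raise ParameterError("n_scales must be >= 1")

    @property
    def scales_mm(self) -> np.ndarray:
        if self.n_scales == 1:
            return np.array([self.s_min])
        return np.geomspace(self.s_min, self.s_max, self.n_scales)


@dataclass
class SegmentationParams:
    """Thresholding and component-filtering parameters."""

    threshold: float = 2.7
    connectivity: int = 26
    min_component_voxels: int = 5

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ParameterError("threshold must be > 0")
        if self.connectivity not in (6, 18, 26):
            raise ParameterError("connectivity must be 6, 18 or 26")
        if self.min_component_voxels < 1:
            raise ParameterError("min_component_voxels must be >= 1")


@dataclass
class PVSComponents:
    """Labeled PVS clusters after size filtering."""

    labels: np.ndarray              # 0 background, 1..k component ids
    sizes: np.ndarray               # voxel count per retained component
    spacing: tuple[float, float, float]

    @property
    def n_components(self) -> int:
        return len(self.sizes)

    @property
    def total_voxels(self) -> int:
        return int(self.sizes.sum())

    def mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class PVSMetrics:
    """Volume metrics of a segmentation."""

    pvs_volume_cm3: float
    roi_volume_cm3: float
    volume_fraction_pct: float
    n_components: int

    def as_dict(self) -> dict:
        return {
            "pvs_volume_cm3": self.pvs_volume_cm3,
            "roi_volume_cm3": self.roi_volume_cm3,
            "volume_fraction_pct": self.volume_fraction_pct,
            "n_components": self.n_components,
        }


# ---------------------------------------------------------------------------
# Denoising
# ---------------------------------------------------------------------------

def denoise_nlm(vol: Volume, params: NlmParams | None = None) -> Volume:
    """Non-local-means denoising of a magnitude MR image."""
    params = params or NlmParams()
    patch = 2 * params.patch_radius + 1
    if patch > min(vol.shape):
        raise ParameterError("NLM patch larger than the image")
    data = vol.data.astype(np.float64)
    if params.h is None:
        sigma = float(estimate_sigma(data))
        h = 0.8 * sigma
        if h <= 0:          # noise-free input: nothing to remove
            return Volume(vol.data.copy(), affine=vol.affine)
    else:
        h = params.h
    out = denoise_nl_means(
        data, patch_size=patch, patch_distance=params.search_radius,
        h=h, fast_mode=True, preserve_range=True,
    )
    return Volume(out.astype(np.float32), affine=vol.affine)


# ---------------------------------------------------------------------------
# Hessian eigenvalues and Frangi vesselness
# ---------------------------------------------------------------------------

def _central_diff(data: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Second-order central difference with reflective boundaries."""
    fwd = np.roll(data, -1, axis=axis)
    bwd = np.roll(data, 1, axis=axis)
    # reflect: at the first/last slice the rolled neighbor wraps; replace it
    sl_lo = [slice(None)] * data.ndim
    sl_hi = [slice(None)] * data.ndim
    sl_lo[axis] = 0
    sl_hi[axis] = -1
    bwd[tuple(sl_lo)] = np.take(data, 1, axis=axis) if data.shape[axis] > 1 \
        else np.take(data, 0, axis=axis)
    fwd[tuple(sl_hi)] = np.take(data, -2, axis=axis) if data.shape[axis] > 1 \
        else np.take(data, -1, axis=axis)
    return (fwd - bwd) / (2.0 * h)


def _hessian_components(data: np.ndarray, scale_mm: float,
                        spacing: tuple[float, float, float]) -> list[np.ndarray]:
    """Six upper-triangle entries of the scale-normalized Hessian.

    The image is smoothed with a Gaussian of sigma = scale_mm (converted to
    voxels per axis, truncated at 4 sigma, reflective boundaries) and the
    Hessian is taken by repeated central differences of the smoothed image,
    then multiplied by scale_mm^2 so responses are comparable across scales.
    Differentiating the smoothed image numerically (rather than convolving
    with analytic Gaussian-derivative kernels) keeps sub-voxel scales
    well-behaved: a scale far below the grid spacing simply contributes a
    negligible, noise-level response instead of a degenerate one.
    """
    sig = [scale_mm / s for s in spacing]
    sm = ndimage.gaussian_filter(data, sig, mode="reflect", truncate=4.0)
    grad = [_central_diff(sm, ax, spacing[ax]) for ax in range(3)]
    norm = scale_mm ** 2
    out = []
    for (i, j) in ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)):
        out.append(norm * _central_diff(grad[i], j, spacing[j]))
    return out


def eigenvalues_by_magnitude(hxx, hxy, hxz, hyy, hyz, hzz) -> np.ndarray:
    """Eigenvalues of symmetric 3x3 fields, sorted by |value| ascending.

    Input arrays share a shape S; output has shape S + (3,) with
    |l1| <= |l2| <= |l3|.
    """
    shape = np.shape(hxx)
    H = np.empty(shape + (3, 3), dtype=np.float64)
    H[..., 0, 0] = hxx
    H[..., 0, 1] = H[..., 1, 0] = hxy
    H[..., 0, 2] = H[..., 2, 0] = hxz
    H[..., 1, 1] = hyy
    H[..., 1, 2] = H[..., 2, 1] = hyz
    H[..., 2, 2] = hzz
    ev = np.linalg.eigvalsh(H)                 # ascending by value
    order = np.argsort(np.abs(ev), axis=-1, kind="stable")
    return np.take_along_axis(ev, order, axis=-1)


def hessian_eigenvalues(vol: Volume, scale_mm: float) -> np.ndarray:
    """Magnitude-ordered eigenvalues of the scale-normalized Hessian.

    Returns an array of shape vol.shape + (3,).
    """
    comps = _hessian_components(vol.data.astype(np.float64), scale_mm,
                                vol.spacing)
    return eigenvalues_by_magnitude(*comps)


def _vesselness_from_eigs(ev: np.ndarray, alpha: float, beta: float,
                          c: float) -> np.ndarray:
    """Frangi bright-tube vesselness from magnitude-ordered eigenvalues."""
    l1, l2, l3 = ev[..., 0], ev[..., 1], ev[..., 2]
    bright = (l2 < 0) & (l3 < 0)
    a2, a3 = np.abs(l2), np.abs(l3)
    with np.errstate(divide="ignore", invalid="ignore"):
        ra2 = np.where(a3 > 0, (a2 / np.maximum(a3, 1e-300)) ** 2, 0.0)
        rb2 = np.where(a2 * a3 > 0,
                       l1 ** 2 / np.maximum(a2 * a3, 1e-300), 0.0)
    s2 = l1 ** 2 + l2 ** 2 + l3 ** 2
    v = ((1.0 - np.exp(-ra2 / (2 * alpha ** 2)))
         * np.exp(-rb2 / (2 * beta ** 2))
         * (1.0 - np.exp(-s2 / (2 * c ** 2))))
    return np.where(bright, v, 0.0)


def frangi_vesselness(vol: Volume, roi: RoiMask,
                      params: FrangiParams | None = None) -> Volume:
    """Multiscale Frangi vesselness map, zero outside the ROI.

    The per-scale response uses the scale-normalized Hessian; the final map
    is the voxelwise maximum over geometrically spaced scales. Values lie in
    [0, 1).
    """
    params = params or FrangiParams()
    if not vol.same_grid(roi):
        raise ShapeError("volume and ROI are on different grids")
    if roi.n_voxels == 0:
        raise DegenerateRoiError("empty ROI")
    if min(vol.spacing) <= 0:
        raise GeometryError(f"degenerate spacing {vol.spacing}")
    inside = roi.as_bool()
    data = vol.data.astype(np.float64)
    best = np.zeros(vol.shape, dtype=np.float64)
    for s in params.scales_mm:
        comps = _hessian_components(data, float(s), vol.spacing)
        ev = eigenvalues_by_magnitude(*[c[inside] for c in comps])
        v = _vesselness_from_eigs(ev, params.alpha, params.beta, params.c)
        best[inside] = np.maximum(best[inside], v)
    return Volume(best.astype(np.float32), affine=vol.affine)


# ---------------------------------------------------------------------------
# Standardization, thresholding, components, metrics
# ---------------------------------------------------------------------------

def iqr_standardize(vmap: Volume, roi: RoiMask,
                    method: Literal["divide", "robust_z"] = "divide"
                    ) -> Volume:
    """Standardize a vesselness map by the IQR of positive in-ROI values.

    "divide" (default) divides by the IQR so zeros stay zero and a single
    threshold transfers across subjects; "robust_z" subtracts the median of
    the positive values first.
    """
    if not vmap.same_grid(roi):
        raise ShapeError("map and ROI are on different grids")
    vals = vmap.data[roi.as_bool()]
    pos = vals[vals > 0].astype(np.float64)
    if pos.size < 4:
        raise DegenerateMapError(
            f"only {pos.size} positive in-ROI vesselness values")
    q25, q75 = np.percentile(pos, [25.0, 75.0])
    iqr = float(q75 - q25)
    if iqr <= 0:
        raise DegenerateMapError("zero IQR of positive in-ROI vesselness")
    out = vmap.data.astype(np.float64)
    if method == "divide":
        out = out / iqr
    elif method == "robust_z":
        med = float(np.median(pos))
        out = np.where(out > 0, (out - med) / iqr, 0.0)
    else:
        raise ParameterError(f"unknown standardization method {method!r}")
    return Volume(out.astype(np.float32), affine=vmap.affine)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def segment_components(svmap: Volume, roi: RoiMask,
                       wmh: RoiMask | None = None,
                       params: SegmentationParams | None = None
                       ) -> PVSComponents:
    """Threshold the standardized map and label PVS clusters.

    Foreground is {in ROI, not WMH, value >= threshold}; clusters are
    maximal under the requested connectivity (26 by default) and clusters
    smaller than min_component_voxels are dropped. An empty result is valid.
    """
    params = params or SegmentationParams()
    if not svmap.same_grid(roi):
        raise ShapeError("map and ROI are on different grids")
    fg = roi.as_bool() & (svmap.data >= params.threshold)
    if wmh is not None:
        if not svmap.same_grid(wmh):
            raise ShapeError("map and WMH mask are on different grids")
        fg &= ~wmh.as_bool()
    return label_components(fg, svmap.spacing, params)


def label_components(fg: np.ndarray, spacing, params: SegmentationParams
                     ) -> PVSComponents:
    """Connected-component labeling + minimum-size filter on a binary field."""
    structure = _STRUCTURES[params.connectivity]
    lab, n = ndimage.label(fg, structure=structure)
    if n == 0:
        return PVSComponents(lab, np.zeros(0, dtype=int), tuple(spacing))
    counts = np.bincount(lab.ravel())[1:]
    keep = np.flatnonzero(counts >= params.min_component_voxels) + 1
    if keep.size == 0:
        return PVSComponents(np.zeros_like(lab), np.zeros(0, dtype=int),
                             tuple(spacing))
    remap = np.zeros(n + 1, dtype=lab.dtype)
    remap[keep] = np.arange(1, keep.size + 1)
    out = remap[lab]
    sizes = counts[keep - 1]
    return PVSComponents(out, sizes.astype(int), tuple(spacing))


def compute_pvs_metrics(comp: PVSComponents, roi: RoiMask) -> PVSMetrics:
    """PVS volume (cm^3) and volume fraction (% of the analysis region)."""
    if comp.labels.shape != roi.shape:
        raise ShapeError("components and ROI are on different grids")
    if roi.n_voxels == 0:
        raise DegenerateRoiError("empty ROI has no volume fraction")
    voxvol = float(np.prod(comp.spacing))
    pvs_mm3 = comp.total_voxels * voxvol
    roi_mm3 = roi.n_voxels * voxvol
    return PVSMetrics(
        pvs_volume_cm3=pvs_mm3 / 1000.0,
        roi_volume_cm3=roi_mm3 / 1000.0,
        volume_fraction_pct=100.0 * pvs_mm3 / roi_mm3,
        n_components=comp.n_components,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All parameters of the end-to-end segmentation chain."""

    nlm: NlmParams = field(default_factory=NlmParams)
    roi: RoiBuildParams = field(default_factory=RoiBuildParams)
    frangi: FrangiParams = field(default_factory=FrangiParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    #: keep WMH voxels in the volume-fraction denominator (they stay part of
    #: the analyzed tissue even though they are excluded from PVS foreground)
    wmh_in_denominator: bool = True
    denoise: bool = True
    iqr_method: Literal["divide", "robust_z"] = "divide"


@dataclass
class PipelineResult:
    components: PVSComponents
    metrics: PVSMetrics
    roi: RoiMask
    wmh: RoiMask
    vesselness: Volume | None = None
    standardized: Volume | None = None


def run_pvs_pipeline(vol: Volume, labels: LabelVolume,
                     config: PipelineConfig | None = None,
                     keep_maps: bool = False) -> PipelineResult:
    """Run denoise -> ROI -> Frangi -> IQR -> threshold -> components -> metrics."""
    config = config or PipelineConfig()
    if not vol.same_grid(labels):
        raise ShapeError("image and labels are on different grids")
    roi, wmh = build_pvs_roi(labels, config.roi)
    img = denoise_nlm(vol, config.nlm) if config.denoise else vol
    vmap = frangi_vesselness(img, roi, config.frangi)
    svmap = iqr_standardize(vmap, roi, method=config.iqr_method)
    comp = segment_components(svmap, roi, wmh, config.segmentation)
    denom_roi = roi
    if not config.wmh_in_denominator and wmh.n_voxels:
        denom_roi = RoiMask(roi.as_bool() & ~wmh.as_bool(), affine=roi.affine)
    metrics = compute_pvs_metrics(comp, denom_roi)
    return PipelineResult(
        components=comp, metrics=metrics, roi=roi, wmh=wmh,
        vesselness=vmap if keep_maps else None,
        standardized=svmap if keep_maps else None,
    )
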