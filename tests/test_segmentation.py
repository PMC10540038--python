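import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pvsquant as pq
from pvsquant import (
    DegenerateMapError,
    FrangiParams,
    NlmParams,
    ParameterError,
    RoiMask,
    SegmentationParams,
    ShapeError,
    Volume,
    compute_pvs_metrics,
    denoise_nlm,
    frangi_vesselness,
    iqr_standardize,
    segment_components,
)
from pvsquant.segmentation import (
    eigenvalues_by_magnitude,
    label_components,
    run_pvs_pipeline,
)

from conftest import flood_fill_label


# ---------------------------------------------------------------------------
# Denoising
# ---------------------------------------------------------------------------

def test_nlm_reduces_noise_on_phantom():
    spec = pq.PhantomSpec(shape=(32, 32, 32), noise_sigma=0.0)
    clean, _ = pq.generate_phantom(spec)
    noisy = pq.add_rician_noise(clean, 30.0, seed=1)
    den = denoise_nlm(noisy, NlmParams(patch_radius=1, search_radius=2))
    rmse_noisy = np.sqrt(np.mean((noisy.data - clean.data) ** 2))
    rmse_den = np.sqrt(np.mean((den.data - clean.data) ** 2))
    assert rmse_den < rmse_noisy


def test_nlm_constant_image_unchanged():
    vol = Volume(np.full((16, 16, 16), 100.0, dtype=np.float32))
    out = denoise_nlm(vol)
    np.testing.assert_array_equal(out.data, vol.data)


def test_nlm_param_validation():
    with pytest.raises(ParameterError):
        NlmParams(patch_radius=0)
    with pytest.raises(ParameterError):
        NlmParams(h=0.0)
    vol = Volume(np.zeros((2, 2, 2)))
    with pytest.raises(ParameterError):
        denoise_nlm(vol, NlmParams(patch_radius=2))


# ---------------------------------------------------------------------------
# Hessian eigenvalues and Frangi vesselness
# ---------------------------------------------------------------------------

def test_eigenvalues_by_magnitude_invariants():
    rng = np.random.default_rng(0)
    for _ in range(200):
        a = rng.normal(size=(3, 3))
        h = (a + a.T) / 2
        ev = eigenvalues_by_magnitude(h[0, 0], h[0, 1], h[0, 2],
                                      h[1, 1], h[1, 2], h[2, 2])
        assert ev.shape == (3,)
        mags = np.abs(ev)
        assert mags[0] <= mags[1] + 1e-12 and mags[1] <= mags[2] + 1e-12
        assert ev.sum() == pytest.approx(np.trace(h), abs=1e-9)
        assert np.prod(ev) == pytest.approx(np.linalg.det(h), abs=1e-9)


def test_frangi_zero_on_constant_volume():
    vol = Volume(np.full((20, 20, 20), 500.0, dtype=np.float32))
    roi = RoiMask(np.ones((20, 20, 20)))
    v = frangi_vesselness(vol, roi, FrangiParams(n_scales=3))
    assert (v.data == 0).all()


def test_frangi_range_and_roi_support(segmented_phantom):
    truth, roi, _, vmap, _ = segmented_phantom
    assert vmap.data.min() >= 0.0
    assert vmap.data.max() < 1.0
    assert (vmap.data[~roi.as_bool()] == 0).all()


def test_frangi_shift_invariance():
    rng = np.random.default_rng(2)
    base = rng.normal(500, 50, size=(36, 36, 36)).astype(np.float32)
    roi_full = RoiMask(np.ones((36, 36, 36)))
    params = FrangiParams(s_min=1.0, s_max=2.0, n_scales=2)
    v1 = frangi_vesselness(Volume(base), roi_full, params).data
    shifted = np.roll(base, 3, axis=0)
    v2 = frangi_vesselness(Volume(shifted), roi_full, params).data
    # compare away from the wrap seam and the smoothing/stencil support
    # (sigma 2 truncated at 4 plus two difference stencils ~ 10 voxels)
    inner = (slice(14, 22), slice(14, 22), slice(14, 22))
    np.testing.assert_allclose(v2[inner], np.roll(v1, 3, axis=0)[inner],
                               atol=1e-6)


def test_frangi_validation():
    vol = Volume(np.zeros((8, 8, 8)))
    with pytest.raises(ShapeError):
        frangi_vesselness(vol, RoiMask(np.ones((9, 9, 9))))
    with pytest.raises(pq.DegenerateRoiError):
        frangi_vesselness(vol, RoiMask(np.zeros((8, 8, 8))))
    with pytest.raises(ParameterError):
        FrangiParams(alpha=0.0)
    with pytest.raises(ParameterError):
        FrangiParams(s_min=2.0, s_max=1.0)


def test_frangi_scales_geometric():
    p = FrangiParams(s_min=0.1, s_max=5.0, n_scales=5)
    s = p.scales_mm
    assert s[0] == pytest.approx(0.1) and s[-1] == pytest.approx(5.0)
    np.testing.assert_allclose(np.diff(np.log(s)), np.log(s[1] / s[0]))


# ---------------------------------------------------------------------------
# IQR standardization
# ---------------------------------------------------------------------------

def test_iqr_standardize_quantile_oracle():
    vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    data = np.zeros((2, 2, 2), dtype=np.float32)
    data.flat[:] = vals
    vmap = Volume(data)
    roi = RoiMask(np.ones((2, 2, 2)))
    q25, q75 = np.percentile(vals, [25, 75])
    out = iqr_standardize(vmap, roi)
    np.testing.assert_allclose(out.data.ravel(), vals / (q75 - q25),
                               rtol=1e-6)
    rz = iqr_standardize(vmap, roi, method="robust_z")
    np.testing.assert_allclose(
        rz.data.ravel(), (vals - np.median(vals)) / (q75 - q25), rtol=1e-6)


def test_iqr_standardize_degenerate_inputs():
    roi = RoiMask(np.ones((2, 2, 2)))
    flat = Volume(np.full((2, 2, 2), 3.0, dtype=np.float32))
    with pytest.raises(DegenerateMapError):
        iqr_standardize(flat, roi)            # zero IQR
    sparse = Volume(np.zeros((2, 2, 2), dtype=np.float32))
    with pytest.raises(DegenerateMapError):
        iqr_standardize(sparse, roi)          # < 4 positive values
    with pytest.raises(ParameterError):
        iqr_standardize(Volume(np.arange(8, dtype=np.float32).reshape(2, 2, 2)
                               + 1), roi, method="nope")


@settings(max_examples=25, derandomize=True)
@given(scale=st.floats(0.1, 10.0))
def test_iqr_standardize_scale_invariant(scale):
    rng = np.random.default_rng(9)
    data = rng.random((4, 4, 4)).astype(np.float32)
    roi = RoiMask(np.ones((4, 4, 4)))
    a = iqr_standardize(Volume(data), roi).data
    b = iqr_standardize(Volume(data * scale), roi).data
    np.testing.assert_allclose(a, b, rtol=5e-4)


# ---------------------------------------------------------------------------
# Components and metrics
# ---------------------------------------------------------------------------

def test_label_components_matches_flood_fill():
    rng = np.random.default_rng(1)
    for conn in (6, 26):
        field = rng.random((15, 15, 15)) < 0.15
        params = SegmentationParams(connectivity=conn, min_component_voxels=5)
        comp = label_components(field, (1.0, 1.0, 1.0), params)
        kept, n_vox = flood_fill_label(field, connectivity=conn, min_size=5)
        assert comp.n_components == len(kept)
        assert comp.total_voxels == n_vox
        got_sets = [set(map(tuple, np.argwhere(comp.labels == k)))
                    for k in range(1, comp.n_components + 1)]
        assert sorted(map(sorted, got_sets)) == sorted(map(sorted, kept))


def test_segment_components_threshold_and_wmh():
    data = np.zeros((6, 6, 6), dtype=np.float32)
    data[1, 1:6, 1] = 3.0                      # 5-voxel line, above threshold
    data[3, 0:5, 3] = 2.0                      # below threshold
    svmap = Volume(data)
    roi = RoiMask(np.ones((6, 6, 6)))
    comp = segment_components(svmap, roi, params=SegmentationParams(
        threshold=2.7))
    assert comp.n_components == 1 and comp.total_voxels == 5
    # threshold is inclusive
    comp2 = segment_components(svmap, roi, params=SegmentationParams(
        threshold=3.0))
    assert comp2.total_voxels == 5
    # WMH voxels are excluded from foreground
    wmh = np.zeros((6, 6, 6))
    wmh[1, 1:6, 1] = 1
    comp3 = segment_components(svmap, roi, RoiMask(wmh),
                               SegmentationParams(threshold=2.7))
    assert comp3.total_voxels == 0


def test_min_size_filter_drops_small_components():
    data = np.zeros((8, 8, 8), dtype=np.float32)
    data[1, 1:5, 1] = 5.0                      # 4 voxels: dropped
    data[5, 1:7, 5] = 5.0                      # 6 voxels: kept
    comp = segment_components(Volume(data), RoiMask(np.ones((8, 8, 8))))
    assert comp.n_components == 1
    assert list(comp.sizes) == [6]


def test_empty_segmentation_is_valid():
    comp = segment_components(Volume(np.zeros((5, 5, 5))),
                              RoiMask(np.ones((5, 5, 5))))
    assert comp.n_components == 0 and comp.total_voxels == 0
    m = compute_pvs_metrics(comp, RoiMask(np.ones((5, 5, 5))))
    assert m.pvs_volume_cm3 == 0.0 and m.volume_fraction_pct == 0.0


def test_metrics_arithmetic_anisotropic():
    labels = np.zeros((10, 10, 10), dtype=np.int32)
    labels[:5, :10, :5] = 1                    # 250 voxels
    aff = np.diag([1.0, 2.0, 0.5, 1.0])        # voxel volume 1 mm^3
    comp = pq.PVSComponents(labels=labels, sizes=np.array([250]),
                            spacing=(1.0, 2.0, 0.5))
    roi = RoiMask(np.ones((10, 10, 10)), affine=aff)
    m = compute_pvs_metrics(comp, roi)
    assert m.pvs_volume_cm3 == pytest.approx(0.25)
    assert m.roi_volume_cm3 == pytest.approx(1.0)
    assert m.volume_fraction_pct == pytest.approx(25.0)
    assert m.n_components == 1


def test_segmentation_params_validation():
    with pytest.raises(ParameterError):
        SegmentationParams(threshold=0.0)
    with pytest.raises(ParameterError):
        SegmentationParams(connectivity=10)
    with pytest.raises(ParameterError):
        SegmentationParams(min_component_voxels=0)


# ---------------------------------------------------------------------------
# End-to-end chain on a phantom
# ---------------------------------------------------------------------------

def test_threshold_monotone_retained_volume(segmented_phantom):
    truth, roi, wmh, _, svmap = segmented_phantom
    prev = np.inf
    for tau in pq.make_threshold_grid():
        comp = segment_components(svmap, roi, wmh,
                                  SegmentationParams(threshold=float(tau)))
        assert comp.total_voxels <= prev
        prev = comp.total_voxels


def test_pipeline_recovers_tubes(tube_phantom, segmented_phantom):
    _, vol, truth = tube_phantom
    res = run_pvs_pipeline(vol, truth.tissue_labels)
    got = res.components.mask()
    want = truth.pvs_mask.as_bool()
    inter = (got & want).sum()
    dice = 2 * inter / max(got.sum() + want.sum(), 1)
    assert dice > 0.5
    rel_err = abs(res.metrics.pvs_volume_cm3 * 1000
                  - truth.total_pvs_volume_mm3) / truth.total_pvs_volume_mm3
    assert rel_err < 0.5
    assert 0 < res.metrics.volume_fraction_pct < 100


def test_pipeline_grid_mismatch_raises(tube_phantom):
    _, vol, truth = tube_phantom
    small = pq.LabelVolume(truth.tissue_labels.data[:-1])
    with pytest.raises(ShapeError):
        run_pvs_pipeline(vol, small)
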