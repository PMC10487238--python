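"""Nucleus detection, podocyte classification and NQO1-area segmentation."""

import numpy as np
import pytest

from podoquant import (
    GlomerulusROI,
    MultiplexImage,
    SegmentationParams,
    ThresholdSet,
    classify_podocyte_nuclei,
    generate_tile,
    segment_nqo1_area,
    segment_nuclei,
)
from podoquant.segmentation import NucleusObject


def _square_roi(side=64):
    return GlomerulusROI(
        "c", "g",
        [(-0.5, -0.5), (side - 0.5, -0.5), (side - 0.5, side - 0.5), (-0.5, side - 0.5)],
    )


def _gaussian_blob_image(centres, peak=2000, background=100, sigma=3.0, side=64):
    """Hoechst plane with Gaussian-profile nuclei; other channels flat."""
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    hoechst = np.full((side, side), float(background))
    for cx, cy in centres:
        hoechst += (peak - background) * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)
        )
    planes = np.zeros((5, side, side), dtype=np.uint16)
    planes[0] = np.rint(hoechst).astype(np.uint16)
    planes[1:] = background
    # pixel size 1 um/px keeps the blob area inside the default [15, 120] um2 gate
    return MultiplexImage(planes=planes, pixel_size_um=1.0)


def test_flat_hoechst_gives_no_nuclei():
    img = _gaussian_blob_image([], background=0)
    assert segment_nuclei(img, _square_roi()) == []


def test_single_nucleus_centroid_recovered():
    img = _gaussian_blob_image([(32, 32)])
    nuclei = segment_nuclei(img, _square_roi())
    assert len(nuclei) == 1
    cx, cy = nuclei[0].centroid
    assert abs(cx - 32) <= 1 and abs(cy - 32) <= 1


def test_two_separated_nuclei_both_recovered():
    centres = [(20, 20), (44, 44)]  # separation 34 px >= 6 sigma
    nuclei = segment_nuclei(_gaussian_blob_image(centres), _square_roi())
    assert len(nuclei) == 2
    found = sorted((n.centroid for n in nuclei))
    for (fx, fy), (tx, ty) in zip(found, centres):
        assert abs(fx - tx) <= 1 and abs(fy - ty) <= 1


def test_missing_intersection_returns_empty():
    img = _gaussian_blob_image([(32, 32)])
    far_roi = GlomerulusROI("c", "g", [(500, 500), (510, 500), (510, 510), (500, 510)])
    assert segment_nuclei(img, far_roi) == []


def test_segmentation_is_deterministic(default_scene, default_thresholds):
    img, roi, _ = generate_tile(default_scene, 77)
    a = segment_nuclei(img, roi)
    b = segment_nuclei(img, roi)
    assert len(a) == len(b)
    for na, nb in zip(a, b):
        assert na.centroid == nb.centroid
        np.testing.assert_array_equal(na.mask, nb.mask)


def _fake_nucleus(p57_mean, nucleus_id=1):
    return NucleusObject(
        nucleus_id=nucleus_id,
        mask=np.ones((2, 2), dtype=bool),
        centroid=(1.0, 1.0),
        area_um2=20.0,
        mean_intensity={
            "hoechst": 1000.0, "p57": p57_mean,
            "nfe2l2": 0.0, "nfe2l1": 0.0, "nqo1": 0.0,
        },
    )


def _thresholds(p57=100.0):
    return ThresholdSet(
        thresholds={"p57": p57, "nfe2l2": 50.0, "nfe2l1": 50.0, "nqo1": 50.0}
    )


def test_p57_exactly_at_threshold_is_negative():
    """Positivity is strictly above the threshold."""
    out = classify_podocyte_nuclei([_fake_nucleus(100.0)], _thresholds(100.0))
    assert out[0].is_podocyte is False


def test_p57_well_above_threshold_is_positive():
    out = classify_podocyte_nuclei([_fake_nucleus(1000.0)], _thresholds(100.0))
    assert out[0].is_podocyte is True


def test_classification_matches_generator_truth(default_scene, default_thresholds):
    img, roi, truth = generate_tile(default_scene, 3)
    nuclei = classify_podocyte_nuclei(segment_nuclei(img, roi), default_thresholds)
    assert len(nuclei) == len(truth.centres_px)
    n_pos = sum(n.is_podocyte for n in nuclei)
    assert n_pos == int(truth.is_podocyte.sum())
    for n in nuclei:
        d = np.hypot(
            truth.centres_px[:, 0] - n.centroid[0],
            truth.centres_px[:, 1] - n.centroid[1],
        )
        assert bool(truth.is_podocyte[d.argmin()]) == n.is_podocyte


def test_classification_idempotent_and_threshold_monotone():
    nuclei = [_fake_nucleus(m, i) for i, m in enumerate([10.0, 120.0, 400.0])]
    once = classify_podocyte_nuclei(nuclei, _thresholds(100.0))
    twice = classify_podocyte_nuclei(once, _thresholds(100.0))
    assert [n.is_podocyte for n in once] == [n.is_podocyte for n in twice]
    stricter = classify_podocyte_nuclei(once, _thresholds(300.0))
    for before, after in zip(once, stricter):
        assert not (after.is_podocyte and not before.is_podocyte)


def test_nqo1_all_background_gives_zero_area():
    planes = np.full((5, 64, 64), 40, dtype=np.uint16)
    img = MultiplexImage(planes=planes, pixel_size_um=0.25)
    out = segment_nqo1_area(img, _square_roi(), _thresholds())
    assert out.area_um2 == 0.0
    assert not out.mask.any()


def test_nqo1_disk_area_matches_analytic_circle():
    side, radius = 96, 20
    planes = np.full((5, side, side), 10, dtype=np.uint16)
    yy, xx = np.mgrid[0:side, 0:side]
    disk = (xx - 48) ** 2 + (yy - 48) ** 2 <= radius**2
    planes[4][disk] = 250  # 5x the threshold
    img = MultiplexImage(planes=planes, pixel_size_um=0.5)
    roi = _square_roi(side)
    out = segment_nqo1_area(img, roi, _thresholds())
    analytic = np.pi * radius**2 * img.pixel_size_um**2
    assert abs(out.area_um2 - analytic) / analytic < 0.03


def test_nqo1_whole_roi_positive_equals_roi_interior():
    planes = np.full((5, 64, 64), 500, dtype=np.uint16)
    img = MultiplexImage(planes=planes, pixel_size_um=0.25)
    roi = _square_roi()
    out = segment_nqo1_area(img, roi, _thresholds())
    np.testing.assert_array_equal(out.mask, roi.mask(img.shape))


def test_nqo1_small_speckles_removed():
    planes = np.full((5, 64, 64), 10, dtype=np.uint16)
    planes[4][5, 5] = 999  # single hot pixel: 0.0625 um2 << 2 um2 minimum
    img = MultiplexImage(planes=planes, pixel_size_um=0.25)
    out = segment_nqo1_area(img, _square_roi(), _thresholds())
    assert out.area_um2 == 0.0


def test_podocyte_count_bounded_by_nucleus_count(default_scene, default_thresholds):
    img, roi, _ = generate_tile(default_scene, 11)
    nuclei = classify_podocyte_nuclei(segment_nuclei(img, roi), default_thresholds)
    nqo1 = segment_nqo1_area(img, roi, default_thresholds)
    assert sum(n.is_podocyte for n in nuclei) <= len(nuclei)
    assert nqo1.area_um2 <= roi.mask(img.shape).sum() * img.pixel_size_um**2


def test_uniform_intensity_nucleus_mean_within_dilution_bound():
    """A uniform-intensity nucleus on zero background measures in [0.8 v, v]."""
    side, v = 64, 3000
    planes = np.zeros((5, side, side), dtype=np.uint16)
    yy, xx = np.mgrid[0:side, 0:side]
    disk = (xx - 32) ** 2 + (yy - 32) ** 2 <= 5**2
    planes[0][disk] = v
    img = MultiplexImage(planes=planes, pixel_size_um=1.0)
    nuclei = segment_nuclei(img, _square_roi())
    assert len(nuclei) == 1
    measured = nuclei[0].mean_intensity["hoechst"]
    assert 0.8 * v <= measured <= v


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SegmentationParams(min_nucleus_area_um2=50, max_nucleus_area_um2=10)
    with pytest.raises(ValueError):
        SegmentationParams(smoothing_sigma_px=0)
    with pytest.raises(ValueError):
        SegmentationParams(hoechst_threshold_mode="fixed")
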