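"""Puncta detection: cropping, adaptive thresholding, size filtering,
summaries, correlation, and the exhaustive flood-fill oracle."""

import numpy as np
import pytest

from chromoquant.nuclei import NucleusMeasurement, NucleusROI, subtract_background, segment_nuclei
from chromoquant.pipeline import match_rois_to_truth
from chromoquant.puncta import (
    PunctaParams,
    PunctaSet,
    Punctum,
    correlate_arc_puncta,
    crop_nucleus,
    detect_puncta,
    summarize_puncta,
)
from chromoquant.scene import generate_widefield_scene

from conftest import SMALL_BG_RADIUS, SMALL_PUNCTA_PARAMS, SMALL_SEG_PARAMS, small_scene_config


def _toy_roi(shape=(60, 60), box=(20, 25, 40, 50)):
    r0, c0, r1, c1 = box
    mask = np.ones((r1 - r0, c1 - c0), bool)
    return NucleusROI(
        id=0, bbox=box, mask=mask,
        centroid=((r0 + r1 - 1) / 2, (c0 + c1 - 1) / 2),
        area=int(mask.sum()), image_shape=shape,
    )


# ------------------------------------------------------------------ cropping


def test_zero_pad_crop_equals_bounding_box():
    roi = _toy_roi()
    img = np.arange(3600.0).reshape(60, 60)
    crop, mask, offset = crop_nucleus(img, roi, pad=0)
    assert crop.shape == (20, 25)
    assert offset == (20, 25)
    assert mask.all()


def test_crop_roundtrip_reembeds_exactly():
    roi = _toy_roi()
    rng = np.random.default_rng(0)
    img = rng.uniform(size=(60, 60))
    crop, _, (r0, c0) = crop_nucleus(img, roi, pad=5)
    assert np.array_equal(img[r0 : r0 + crop.shape[0], c0 : c0 + crop.shape[1]], crop)


def test_crop_centroid_coordinate_arithmetic():
    roi = _toy_roi()
    img = np.zeros((60, 60))
    crop, mask, (r0, c0) = crop_nucleus(img, roi, pad=3)
    rr, cc = np.nonzero(mask)
    assert rr.mean() + r0 == pytest.approx(roi.centroid[0])
    assert cc.mean() + c0 == pytest.approx(roi.centroid[1])


def test_crop_outside_image_raises():
    roi = _toy_roi(shape=(30, 30), box=(20, 25, 40, 50))
    with pytest.raises(ValueError):
        crop_nucleus(np.zeros((30, 30)), roi, pad=0)
    with pytest.raises(ValueError):
        crop_nucleus(np.zeros((60, 60)), roi, pad=-1)


# ----------------------------------------------------------------- detection


def _blob(shape, cy, cx, radius, amp, power=3):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return amp * np.exp(-((r2 / (2 * (radius / 1.1) ** 2)) ** power))


def test_uniform_crop_has_no_puncta():
    crop = np.full((40, 40), 12.0)
    mask = np.ones((40, 40), bool)
    ps = detect_puncta(crop, mask, PunctaParams())
    assert len(ps) == 0


def test_planted_blobs_detected_with_centroid_accuracy():
    mask = np.ones((100, 100), bool)
    centers = [(25.0, 30.0), (70.0, 40.0), (50.0, 75.0)]
    crop = np.full((100, 100), 10.0)
    for cy, cx in centers:
        crop += _blob((100, 100), cy, cx, radius=6.0, amp=100.0)
    ps = detect_puncta(crop, mask, PunctaParams(min_area=10, max_area=500))
    assert len(ps) == 3
    got = sorted(p.centroid for p in ps.puncta)
    for (gy, gx), (cy, cx) in zip(got, sorted(centers)):
        assert abs(gy - cy) <= 1.0 and abs(gx - cx) <= 1.0


def test_oversized_blob_excluded_by_area_filter():
    mask = np.ones((80, 80), bool)
    crop = np.full((80, 80), 5.0) + _blob((80, 80), 40, 40, radius=20.0, amp=100.0)
    # the big blob covers ~30% of the crop, so use a permissive k=1 threshold
    wide = detect_puncta(crop, mask, PunctaParams(intensity_k=1.0, min_area=10, max_area=5000))
    assert len(wide) == 1
    area = wide.puncta[0].area
    tight = detect_puncta(
        crop, mask, PunctaParams(intensity_k=1.0, min_area=10, max_area=area - 1)
    )
    assert len(tight) == 0


def test_empty_mask_and_stack_handling():
    crop = np.zeros((10, 10))
    with pytest.raises(ValueError):
        detect_puncta(crop, np.zeros((10, 10), bool), PunctaParams())
    stack = np.zeros((3, 10, 10))
    with pytest.raises(ValueError):
        detect_puncta(stack, np.ones((10, 10), bool), PunctaParams())
    ps = detect_puncta(
        stack, np.ones((10, 10), bool), PunctaParams(use_max_projection=True)
    )
    assert len(ps) == 0


def test_count_monotone_in_intensity_k(small_scene):
    cfg, image, _ = small_scene
    dapi = subtract_background(image[0], SMALL_BG_RADIUS)
    rois = segment_nuclei(dapi, SMALL_SEG_PARAMS)
    assert rois
    crop, mask, _ = crop_nucleus(dapi, rois[0], pad=5)
    counts = []
    for k in (1.0, 1.5, 2.0, 2.5, 3.0, 4.0):
        p = PunctaParams(intensity_k=k, min_area=20, max_area=600)
        counts.append(len(detect_puncta(crop, mask, p)))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def _flood_fill_components(bw):
    """Independent 8-connected component labeling by BFS flood fill."""
    seen = np.zeros_like(bw, dtype=bool)
    comps = []
    rows, cols = bw.shape
    for r in range(rows):
        for c in range(cols):
            if bw[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], []
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (
                                0 <= yy < rows and 0 <= xx < cols
                                and bw[yy, xx] and not seen[yy, xx]
                            ):
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                comps.append(frozenset(comp))
    return set(comps)


def test_detection_matches_flood_fill_oracle_on_small_crops():
    rng = np.random.default_rng(7)
    params = PunctaParams(intensity_k=1.0, min_area=1, max_area=32 * 32)
    for _ in range(20):
        crop = rng.normal(10, 4, size=(24, 28))
        mask = rng.random((24, 28)) > 0.2
        if not mask.any():
            continue
        vals = crop[mask]
        thr = vals.mean() + params.intensity_k * vals.std()
        expected = _flood_fill_components((crop > thr) & mask)
        ps = detect_puncta(crop, mask, params)
        got_areas = sorted(p.area for p in ps.puncta)
        assert got_areas == sorted(len(c) for c in expected)
        assert len(ps) == len(expected)


def test_planted_count_recovery_mae_below_one():
    """Across >= 100 synthetic nuclei the detected puncta count tracks the
    planted count with mean absolute error <= 1."""
    from chromoquant.pipeline import analyze_scene

    errs = []
    for seed in range(26):
        cfg = small_scene_config(seed=300 + seed)
        image, truth = generate_widefield_scene(cfg)
        res = analyze_scene(
            image, "e1", "stimulated", background_radius=SMALL_BG_RADIUS,
            seg_params=SMALL_SEG_PARAMS, puncta_params=SMALL_PUNCTA_PARAMS,
        )
        matched = match_rois_to_truth(res.rois, truth)
        for m, ps in zip(res.measurements, res.puncta_sets):
            nuc = matched.get(m.nucleus_id)
            if nuc is not None:
                errs.append(abs(len(ps.puncta) - nuc.puncta_count))
    assert len(errs) >= 100
    assert np.mean(errs) <= 1.0


# ----------------------------------------------------------------- summaries


def test_summary_of_empty_set_is_missing_not_zero():
    count, mean_area = summarize_puncta(PunctaSet(0, [], threshold=1.0))
    assert count == 0
    assert mean_area is None


def test_summary_mean_area():
    puncta = [Punctum((0.0, 0.0), 4, 1.0), Punctum((5.0, 5.0), 6, 1.0)]
    count, mean_area = summarize_puncta(PunctaSet(0, puncta, threshold=1.0))
    assert count == 2
    assert mean_area == pytest.approx(5.0)


# --------------------------------------------------------------- correlation


def _ms(arc, count, area=None, nid=0):
    return NucleusMeasurement(nid, "e1", "stimulated", float(arc),
                              puncta_count=count, mean_puncta_area=area)


def test_perfectly_linear_relation_gives_r_of_one():
    ms = [_ms(x, 2 * x + 1, nid=i) for i, x in enumerate([1, 2, 3, 4, 5])]
    res = correlate_arc_puncta(ms, "puncta_count")
    assert res.coefficient == pytest.approx(1.0)
    assert res.n == 5


def test_degenerate_inputs_rejected():
    ms = [_ms(5.0, c, nid=i) for i, c in enumerate([1, 2, 3])]
    with pytest.raises(ValueError, match="variance"):
        correlate_arc_puncta(ms, "puncta_count")
    with pytest.raises(ValueError):
        correlate_arc_puncta(ms[:2], "puncta_count")


def test_pearson_matches_textbook_formula():
    x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
    y = np.array([2.0, 3.0, 3.0, 6.0, 9.0])
    ms = [_ms(xi, yi, nid=i) for i, (xi, yi) in enumerate(zip(x, y))]
    res = correlate_arc_puncta(ms, "puncta_count")
    # closed form computed independently
    r_hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert res.coefficient == pytest.approx(r_hand)


def test_missing_mean_areas_excluded_from_correlation():
    ms = [_ms(1.0, 1, area=None, nid=0)] + [
        _ms(x, 1, area=10.0 * x, nid=i + 1) for i, x in enumerate([2, 3, 4, 5])
    ]
    res = correlate_arc_puncta(ms, "mean_puncta_area")
    assert res.n == 4
    assert res.coefficient == pytest.approx(1.0)
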