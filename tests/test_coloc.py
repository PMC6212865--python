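"""Colocalization statistics: background model, object calls, Pearson/Manders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesicoloc import (
    BackgroundModel,
    ObjectCall,
    SimulationConfig,
    VesicleROI,
    classify_objects,
    detect_vesicles,
    estimate_background,
    percent_positive,
    pixel_coloc,
    simulate_field,
)
from vesicoloc.pipeline_io import ground_truth_label_map


def _roi_at(pixels, label_id=1):
    pix = np.asarray(pixels)
    return VesicleROI(
        label_id=label_id,
        centroid=(float(pix[:, 0].mean()), float(pix[:, 1].mean())),
        pixels=pix,
        area=len(pix),
        mean_marker_intensity=0.0,
    )


# ---------------------------------------------------------------------------
# background


def test_background_constant_field():
    img = np.full((64, 64), 100.0)
    lm = np.zeros((64, 64), dtype=int)
    lm[10:20, 10:20] = 1
    bg = estimate_background(img, lm)
    assert bg.median == 100.0
    assert bg.mad == 0.0


def test_background_excludes_roi_and_dilation():
    img = np.full((64, 64), 100.0)
    lm = np.zeros((64, 64), dtype=int)
    lm[20:30, 20:30] = 1
    img[17:33, 17:33] = 1e4  # bright block extending 3 px beyond the ROI
    bg = estimate_background(img, lm, dilation_radius=3)
    assert bg.median == 100.0


def test_background_poisson_median_near_mean():
    meds = []
    for seed in range(10):
        cfg = SimulationConfig(
            image_height=256,
            image_width=256,
            n_vesicles=10,
            background_level=50.0,
            read_noise_sigma=0.0,
            seed=seed,
        )
        stack, gt = simulate_field(cfg)
        lm = ground_truth_label_map(gt.vesicles, (256, 256))
        meds.append(estimate_background(stack.channel("cargo"), lm).median)
    assert abs(np.mean(meds) - 50.0) <= 1.0


def test_background_low_coverage_flag_and_empty_error():
    img = np.full((32, 32), 5.0)
    lm = np.ones((32, 32), dtype=int)
    lm[0, :16] = 0  # only 16 background pixels survive (no dilation)
    bg = estimate_background(img, lm, dilation_radius=0)
    assert bg.low_coverage and bg.n_pixels_used == 16
    with pytest.raises(ValueError, match="no background"):
        estimate_background(img, np.ones((32, 32), dtype=int), dilation_radius=0)


# ---------------------------------------------------------------------------
# object calls


def test_constant_cargo_all_negative():
    # mad = 0 degenerate background: positive only strictly above the median
    img = np.full((64, 64), 100.0)
    rois = [_roi_at([(10, 10), (10, 11)]), _roi_at([(30, 30), (30, 31)], 2)]
    bg = BackgroundModel(median=100.0, mad=0.0, n_pixels_used=4000)
    calls = classify_objects(img, rois, bg)
    assert all(not c.is_positive for c in calls)


def test_call_rule_arithmetic():
    bg = BackgroundModel(median=100.0, mad=2.0, n_pixels_used=4000)
    img = np.full((64, 64), 100.0)
    img[10, 10] = img[10, 11] = 100.0 + 10 * 1.4826 * 2.0
    rois = [_roi_at([(10, 10), (10, 11)])]
    calls = classify_objects(img, rois, bg, k=3.0)
    assert calls[0].is_positive
    assert calls[0].threshold_used == pytest.approx(100.0 + 3 * 1.4826 * 2.0)
    assert calls[0].is_positive == (calls[0].cargo_mean > calls[0].threshold_used)


def test_calls_match_ground_truth_with_perfect_masks():
    cfg = SimulationConfig(n_vesicles=50, coloc_fraction=0.4, seed=19)
    stack, gt = simulate_field(cfg)
    lm = ground_truth_label_map(gt.vesicles, stack.channel("cargo").shape)
    from vesicoloc import label_map_to_rois

    rois = label_map_to_rois(lm)
    bg = estimate_background(stack.channel("cargo"), lm)
    calls = classify_objects(stack.channel("cargo"), rois, bg)
    truth = gt.vesicles.set_index("vesicle_id")["is_cargo_positive"]
    for roi, call in zip(rois, calls):
        assert call.is_positive == bool(truth[roi.label_id - 1])


def test_raising_k_never_increases_positives():
    cfg, stack, gt = _noisy_case()
    lm = ground_truth_label_map(gt.vesicles, stack.channel("cargo").shape)
    from vesicoloc import label_map_to_rois

    rois = label_map_to_rois(lm)
    bg = estimate_background(stack.channel("cargo"), lm)
    counts = [
        sum(c.is_positive for c in classify_objects(stack.channel("cargo"), rois, bg, k=k))
        for k in (0.5, 1.0, 2.0, 3.0, 5.0, 10.0, 50.0)
    ]
    assert counts == sorted(counts, reverse=True)


def _noisy_case():
    cfg = SimulationConfig(n_vesicles=30, coloc_fraction=0.5, cargo_amplitude=30.0, seed=23)
    stack, gt = simulate_field(cfg)
    return cfg, stack, gt


# ---------------------------------------------------------------------------
# percent positive


def test_percent_positive_counts():
    def call(flag, i):
        return ObjectCall(label_id=i, cargo_mean=0.0, threshold_used=0.0, is_positive=flag)

    s = percent_positive([call(True, 1), call(True, 2), call(False, 3), call(False, 4)])
    assert (s.n_objects, s.n_positive, s.percent_positive) == (4, 2, 50.0)
    s = percent_positive([call(True, i) for i in range(7)])
    assert s.percent_positive == 100.0
    assert s.ci_low < 100.0 and s.ci_high == pytest.approx(100.0)  # Wilson interval


def test_percent_positive_empty_is_undefined_not_zero():
    s = percent_positive([])
    assert s.undefined and np.isnan(s.percent_positive)


@given(st.lists(st.booleans(), min_size=1, max_size=60), st.randoms())
@settings(max_examples=50, deadline=None)
def test_percent_positive_permutation_invariant(flags, rnd):
    calls = [
        ObjectCall(label_id=i, cargo_mean=0.0, threshold_used=0.0, is_positive=f)
        for i, f in enumerate(flags)
    ]
    shuffled = list(calls)
    rnd.shuffle(shuffled)
    a, b = percent_positive(calls), percent_positive(shuffled)
    assert a.percent_positive == b.percent_positive == 100.0 * sum(flags) / len(flags)


def test_ground_truth_bypass_exact():
    cfg = SimulationConfig(
        image_height=1024, image_width=1024, n_vesicles=200, coloc_fraction=0.3, seed=101
    )
    _, gt = simulate_field(cfg)
    calls = [
        ObjectCall(label_id=int(v.vesicle_id), cargo_mean=0.0, threshold_used=0.0,
                   is_positive=bool(v.is_cargo_positive))
        for v in gt.vesicles.itertuples()
    ]
    s = percent_positive(calls)
    assert s.percent_positive == 100.0 * gt.vesicles["is_cargo_positive"].sum() / 200


# ---------------------------------------------------------------------------
# pixel colocalization


def _brute_force_coloc(a, b, mask, thr_a, thr_b):
    """Independent direct-summation oracle for Pearson and Manders."""
    av = [a[i, j] for i, j in zip(*np.nonzero(mask))]
    bv = [b[i, j] for i, j in zip(*np.nonzero(mask))]
    n = len(av)
    am = sum(av) / n
    bm = sum(bv) / n
    num = sum((x - am) * (y - bm) for x, y in zip(av, bv))
    den = (sum((x - am) ** 2 for x in av) * sum((y - bm) ** 2 for y in bv)) ** 0.5
    r = num / den
    m1 = sum(x for x, y in zip(av, bv) if y > thr_b) / sum(av)
    m2 = sum(y for x, y in zip(av, bv) if x > thr_a) / sum(bv)
    return r, m1, m2


def test_pearson_self_and_anti_correlation_exact():
    rng = np.random.default_rng(0)
    a = rng.random((32, 32)) * 100
    mask = np.ones((32, 32), dtype=bool)
    r_self = pixel_coloc(a, a, mask, threshold_mode="fixed", thresholds=(50, 50)).pearson_r
    r_anti = pixel_coloc(a, 200.0 - a, mask, threshold_mode="fixed", thresholds=(50, 50)).pearson_r
    assert abs(r_self - 1.0) < 1e-12
    assert abs(r_anti + 1.0) < 1e-12


def test_pixel_coloc_matches_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(20):
        a = rng.random((8, 8)) * 10
        b = rng.random((8, 8)) * 10
        mask = rng.random((8, 8)) > 0.4
        if mask.sum() < 4:
            continue
        res = pixel_coloc(a, b, mask, threshold_mode="fixed", thresholds=(5.0, 5.0))
        r, m1, m2 = _brute_force_coloc(a, b, mask, 5.0, 5.0)
        assert res.pearson_r == pytest.approx(r, abs=1e-12)
        assert res.manders_m1 == pytest.approx(m1, abs=1e-12)
        assert res.manders_m2 == pytest.approx(m2, abs=1e-12)
        assert res.mask_area == int(mask.sum())


def test_disjoint_supports_zero_manders():
    a = np.zeros((16, 16))
    b = np.zeros((16, 16))
    a[:8] = 10.0
    b[8:] = 10.0
    mask = np.ones((16, 16), dtype=bool)
    res = pixel_coloc(a, b, mask, threshold_mode="fixed", thresholds=(1.0, 1.0))
    assert res.manders_m1 == 0.0 and res.manders_m2 == 0.0


def test_pearson_affine_invariance_and_undefined_flags():
    rng = np.random.default_rng(3)
    a = rng.random((16, 16)) * 50
    b = rng.random((16, 16)) * 50
    mask = np.ones((16, 16), dtype=bool)
    base = pixel_coloc(a, b, mask, threshold_mode="fixed", thresholds=(25, 25))
    # Pearson is invariant under any positive affine map of one channel
    affine = pixel_coloc(3.0 * a + 7.0, b, mask, threshold_mode="fixed", thresholds=(25 * 3 + 7, 25))
    assert affine.pearson_r == pytest.approx(base.pearson_r, abs=1e-12)
    # Manders is invariant under positive *scaling* with fixed relative thresholds
    scaled = pixel_coloc(3.0 * a, b, mask, threshold_mode="fixed", thresholds=(25 * 3, 25))
    assert scaled.manders_m1 == pytest.approx(base.manders_m1, abs=1e-12)
    assert scaled.manders_m2 == pytest.approx(base.manders_m2, abs=1e-12)
    const = pixel_coloc(np.full((16, 16), 5.0), b, mask, threshold_mode="fixed", thresholds=(1, 1))
    assert const.pearson_undefined and np.isnan(const.pearson_r)
    zero = pixel_coloc(np.zeros((16, 16)), b, mask, threshold_mode="fixed", thresholds=(1, 1))
    assert zero.m1_undefined and np.isnan(zero.manders_m1)


def test_pixel_coloc_accepts_label_map_mask_and_rejects_empty():
    _, stack, _ = _detected_case()
    marker = stack.channel("marker")
    cargo = stack.channel("cargo")
    _, lm = detect_vesicles(marker)
    res = pixel_coloc(marker, cargo, lm, threshold_mode="otsu")
    assert -1.0 <= res.pearson_r <= 1.0
    assert 0.0 <= res.manders_m1 <= 1.0
    assert 0.0 <= res.manders_m2 <= 1.0
    with pytest.raises(ValueError, match="empty"):
        pixel_coloc(marker, cargo, np.zeros_like(lm))


def _detected_case():
    cfg = SimulationConfig(n_vesicles=30, coloc_fraction=0.6, seed=55)
    stack, gt = simulate_field(cfg)
    return cfg, stack, gt


def test_estimator_recovery_through_detection():
    # full detect -> classify -> percent chain recovers the realized fraction
    errs = []
    for seed in range(5):
        cfg = SimulationConfig(
            image_height=900, image_width=900, n_vesicles=100, coloc_fraction=0.4, seed=seed
        )
        stack, gt = simulate_field(cfg)
        rois, lm = detect_vesicles(stack.channel("marker"))
        bg = estimate_background(stack.channel("cargo"), lm)
        calls = classify_objects(stack.channel("cargo"), rois, bg)
        s = percent_positive(calls)
        errs.append(abs(s.percent_positive - 100.0 * gt.realized_cargo_fraction()))
    assert np.mean(errs) < 5.0
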