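"""Landmark bands, measure recovery, girth model and validation stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from goatpheno.calibration import calibrate
from goatpheno.morphometry import (
    MeasureError,
    body_length,
    chest_depth,
    chest_girth,
    chest_width,
    ellipse_perimeter_quadrature,
    ground_row,
    height_at_withers,
    measure_animal,
    predict_weight,
    validate_measures,
)
from goatpheno.segmentation import segment
from goatpheno.synth import generate_scene
from goatpheno.types import BodyMeasures, GoatMask, SceneParams


@pytest.fixture(scope="module")
def measured(cfg, sign_scene, rear_scene):
    rec, truth = sign_scene
    mask = segment(rec, cfg)
    cal = calibrate(rec, cfg.sign)
    rrec, _ = rear_scene
    rmask = segment(rrec, cfg)
    return rec, truth, mask, cal, rmask


def test_ground_row_matches_truth(cfg, measured):
    _, truth, mask, _, _ = measured
    assert abs(ground_row(mask, cfg.morphometry) - truth.ground_row) <= 2


def test_ground_row_translation_equivariance(cfg, measured):
    _, _, mask, _, _ = measured
    g = ground_row(mask, cfg.morphometry)
    shifted = np.zeros_like(mask.mask)
    shifted[10:, :] = mask.mask[:-10, :]
    assert ground_row(GoatMask(mask=shifted), cfg.morphometry) == g + 10


def test_ground_row_fails_on_rocks(cfg):
    rec, _ = generate_scene(
        SceneParams(pose="sign", seed=13, defects=frozenset({"rocks"})), cfg.sign
    )
    mask = segment(rec, cfg, refine=False)
    with pytest.raises(MeasureError):
        ground_row(mask, cfg.morphometry)


def test_height_recovery_within_two_percent(cfg, measured):
    _, truth, mask, cal, _ = measured
    hw = height_at_withers(mask, cal.scale, config=cfg.morphometry)
    assert hw == pytest.approx(truth.measures.hw, rel=0.02)


def test_height_linear_in_scale(cfg, measured):
    _, _, mask, cal, _ = measured
    hw1 = height_at_withers(mask, cal.scale, config=cfg.morphometry)
    hw2 = height_at_withers(mask, 2 * cal.scale, config=cfg.morphometry)
    assert hw2 == pytest.approx(2 * hw1, rel=1e-9)


def test_height_ordering_preserved(cfg):
    heights = []
    for hw in (50.0, 70.0):
        rec, _ = generate_scene(SceneParams(pose="sign", seed=17, hw=hw), cfg.sign)
        mask = segment(rec, cfg)
        heights.append(height_at_withers(mask, 0.1, config=cfg.morphometry))
    assert heights[0] < heights[1]


def test_body_length_recovery_and_mirror_symmetry(cfg, measured):
    _, truth, mask, cal, _ = measured
    bl = body_length(mask, cal.scale, config=cfg.morphometry)
    assert bl == pytest.approx(truth.measures.bl, rel=0.02)
    mirrored = GoatMask(mask=mask.mask[:, ::-1])
    assert body_length(mirrored, cal.scale, config=cfg.morphometry) == pytest.approx(
        bl, rel=1e-6
    )


def test_head_excluded_from_body_length(cfg):
    # the head extends ~12 cm beyond the shoulder; BL must not include it
    p = SceneParams(pose="sign", seed=19, bl=70.0)
    rec, _ = generate_scene(p, cfg.sign)
    mask = segment(rec, cfg)
    bl = body_length(mask, 0.1, config=cfg.morphometry)
    assert bl == pytest.approx(70.0, rel=0.02)


def test_chest_depth_and_width_recovery(cfg, measured):
    _, truth, mask, cal, rmask = measured
    d = chest_depth(mask, cal.scale, config=cfg.morphometry)
    w = chest_width(rmask, cal.scale, config=cfg.morphometry)
    assert d == pytest.approx(truth.measures.chest_depth, rel=0.02)
    assert w == pytest.approx(truth.measures.chest_width, rel=0.02)


def test_dilated_rear_mask_widens_by_twice_the_dilation(cfg, measured):
    from scipy import ndimage as ndi

    _, _, _, cal, rmask = measured
    w0 = chest_width(rmask, cal.scale, config=cfg.morphometry)
    dil = ndi.binary_dilation(rmask.mask, structure=np.ones((5, 5), bool))
    w1 = chest_width(GoatMask(mask=dil), cal.scale, config=cfg.morphometry)
    assert w1 - w0 == pytest.approx(4 * cal.scale, abs=cal.scale / 2)


# ------------------------------------------------------------------ girth


def test_girth_circle_limit():
    for d in (10.0, 25.0, 60.0):
        assert chest_girth(d, d) == pytest.approx(np.pi * d, abs=1e-9)


@pytest.mark.parametrize("ratio", [1.0, 1.5, 2.0, 2.5, 3.0])
def test_girth_matches_quadrature(ratio):
    depth, width = 30.0, 30.0 / ratio
    exact = ellipse_perimeter_quadrature(depth, width)
    assert abs(chest_girth(depth, width) - exact) / exact <= 1e-3


@given(
    d=st.floats(5.0, 80.0),
    w=st.floats(5.0, 80.0),
    eps=st.floats(0.1, 5.0),
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_girth_strictly_increasing_in_each_axis(d, w, eps):
    assert chest_girth(d + eps, w) > chest_girth(d, w)
    assert chest_girth(d, w + eps) > chest_girth(d, w)


def test_girth_respects_perimeter_bound():
    g = chest_girth(30.0, 20.0)
    assert g <= np.pi * (30.0 + 20.0)


# ----------------------------------------------------------------- weight


def test_weight_passthrough_coefficients():
    m = BodyMeasures(cg=75.0)
    assert predict_weight(m, "girth_passthrough") == pytest.approx(75.0)


def test_weight_scales_cubically():
    m1 = BodyMeasures(cg=60.0, bl=70.0)
    m2 = BodyMeasures(cg=120.0, bl=140.0)
    assert predict_weight(m2) == pytest.approx(8 * predict_weight(m1))


def test_weight_k_inverse_solve():
    cg, bl, target = 70.0, 75.0, 40.0
    k = cg**2 * bl / target
    assert predict_weight(BodyMeasures(cg=cg, bl=bl), "girth2_length", k) == pytest.approx(
        target
    )


def test_weight_missing_measure_flags():
    m = BodyMeasures(hw=60.0)
    assert predict_weight(m) is None
    assert m.flags["bw"] == "MISSING_REQUIRED_MEASURE"


# ------------------------------------------------------------- validation


def _tables(x, y):
    ids = [f"g{i}" for i in range(len(x))]
    return (
        pd.DataFrame({"sample_id": ids, "hw": x}),
        pd.DataFrame({"sample_id": ids, "hw": y}),
    )


def test_pearson_identity_and_affine_invariance():
    x = np.array([50.0, 60.0, 70.0, 80.0])
    d, m = _tables(x, x)
    assert validate_measures(d, m, ("hw",))["hw"]["r"] == pytest.approx(1.0)
    d, m = _tables(x, 2 * x + 5)
    assert validate_measures(d, m, ("hw",))["hw"]["r"] == pytest.approx(1.0)


def test_pearson_zero_variance_reported_undefined():
    d, m = _tables([50.0, 60.0, 70.0], [5.0, 5.0, 5.0])
    res = validate_measures(d, m, ("hw",))["hw"]
    assert res["r"] is None and res["n"] == 3


@given(
    st.lists(
        st.tuples(st.floats(-100, 100), st.floats(-100, 100)), min_size=4, max_size=30
    )
)
@settings(deadline=None, max_examples=40, derandomize=True)
def test_pearson_matches_two_pass_textbook_formula(pairs):
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.std(x) < 1e-6 or np.std(y) < 1e-6:
        return
    d, m = _tables(x, y)
    r = validate_measures(d, m, ("hw",))["hw"]["r"]
    # independent two-pass computation
    xc, yc = x - x.mean(), y - y.mean()
    expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    assert r == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------------- end to end


def test_measure_animal_full_set(cfg, measured):
    _, truth, mask, cal, rmask = measured
    m = measure_animal(mask, rmask, cal.scale, config=cfg.morphometry)
    t = truth.measures
    assert m.hw == pytest.approx(t.hw, rel=0.02)
    assert m.bl == pytest.approx(t.bl, rel=0.02)
    assert m.cg == pytest.approx(chest_girth(t.chest_depth, t.chest_width), rel=0.02)
    assert m.bw is not None and m.bw > 0


def test_measure_animal_without_rear_flags_width(cfg, measured):
    _, _, mask, cal, _ = measured
    m = measure_animal(mask, None, cal.scale, config=cfg.morphometry)
    assert m.chest_width is None and m.cg is None
    assert m.flags["chest_width"] == "REAR_POSE_MISSING"
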