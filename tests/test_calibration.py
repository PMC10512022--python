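"""Sign detection, spatial scale and colour-transform recovery."""

import numpy as np
import pytest

from goatpheno.calibration import (
    SignNotFoundError,
    calibrate,
    detect_sign,
    estimate_color_transform,
    spatial_scale,
)
from goatpheno.synth import generate_scene
from goatpheno.types import SceneParams, SignDetection, ValidationError


def _det_with_quad(w_px, h_px):
    quad = np.array([[0.0, 0.0], [0.0, w_px], [h_px, w_px], [h_px, 0.0]])
    return SignDetection(
        quadrilateral=quad, border_score=1.0, block_colors={}, skew_deg=0.0
    )


def test_scale_is_the_physical_to_pixel_ratio():
    det = _det_with_quad(400.0, 300.0)
    assert spatial_scale(det, 40.0, 30.0) == pytest.approx(0.1)


def test_degenerate_quad_raises():
    with pytest.raises(ValidationError):
        spatial_scale(_det_with_quad(0.5, 300.0), 40.0, 30.0)


def test_detected_corners_within_one_pixel(cfg, sign_scene):
    rec, truth = sign_scene
    det = detect_sign(rec, cfg.sign)
    assert np.abs(det.quadrilateral - truth.sign_quad).max() <= 1.0
    assert det.border_score >= 0.7 and not det.low_confidence


def test_scale_recovery_within_one_percent(cfg, sign_scene):
    rec, truth = sign_scene
    det = detect_sign(rec, cfg.sign)
    scale = spatial_scale(det, cfg.sign.width_cm, cfg.sign.height_cm)
    assert abs(scale - truth.scale) / truth.scale <= 0.01


def test_width_and_height_estimates_agree(cfg, sign_scene):
    rec, _ = sign_scene
    det = detect_sign(rec, cfg.sign)
    sides = [
        np.linalg.norm(det.quadrilateral[(i + 1) % 4] - det.quadrilateral[i])
        for i in range(4)
    ]
    w_est = cfg.sign.width_cm / ((sides[0] + sides[2]) / 2)
    h_est = cfg.sign.height_cm / ((sides[1] + sides[3]) / 2)
    assert abs(w_est - h_est) / w_est < 0.005


def test_no_sign_in_side_pose(cfg):
    rec, _ = generate_scene(SceneParams(pose="side", seed=1), cfg.sign)
    with pytest.raises(SignNotFoundError):
        detect_sign(rec, cfg.sign)


@pytest.mark.parametrize("skew", [5.0, 10.0, 15.0])
def test_skew_detected_and_scale_rotation_invariant(cfg, skew):
    p = SceneParams(
        pose="sign",
        seed=4,
        chest_depth=34.0,
        defects=frozenset({"skewed_sign"}),
        sign_skew_deg=skew,
    )
    rec, truth = generate_scene(p, cfg.sign)
    det = detect_sign(rec, cfg.sign)
    assert det.skew_deg == pytest.approx(skew, abs=1.0)
    scale = spatial_scale(det, cfg.sign.width_cm, cfg.sign.height_cm)
    assert abs(scale - truth.scale) / truth.scale < 0.01


def test_identity_when_measured_equals_reference(cfg):
    det = SignDetection(
        quadrilateral=np.zeros((4, 2)),
        border_score=1.0,
        block_colors={
            "border": cfg.sign.reference_border,
            "red": cfg.sign.reference_red,
            "green": cfg.sign.reference_green,
            "blue": cfg.sign.reference_blue,
        },
        skew_deg=0.0,
    )
    M, off, res = estimate_color_transform(det, cfg.sign)
    assert np.allclose(M, np.eye(3), atol=1e-9)
    assert np.allclose(off, 0.0, atol=1e-9)
    assert res == pytest.approx(0.0, abs=1e-9)


def test_rank_deficient_colors_raise(cfg):
    det = SignDetection(
        quadrilateral=np.zeros((4, 2)),
        border_score=1.0,
        block_colors={
            "border": (0, 0, 0),
            "red": (100, 0, 0),
            "green": (100, 0, 0),  # identical to red: rank deficient
            "blue": (0, 0, 100),
        },
        skew_deg=0.0,
    )
    with pytest.raises(ValidationError):
        estimate_color_transform(det, cfg.sign)


def test_gain_recovery_and_correction(cfg):
    p = SceneParams(
        pose="sign", seed=7, defects=frozenset({"lighting_shift"}), lighting_gain=0.8
    )
    rec, _ = generate_scene(p, cfg.sign)
    det = detect_sign(rec, cfg.sign)
    M, off, res = estimate_color_transform(det, cfg.sign)
    recovered = float(np.mean(1.0 / np.diag(M)))
    assert recovered == pytest.approx(0.8, rel=0.02)
    meas = np.array([det.block_colors[k] for k in ("red", "green", "blue")])
    corrected = meas @ M.T + off
    refs = np.array(
        [cfg.sign.reference_red, cfg.sign.reference_green, cfg.sign.reference_blue],
        float,
    )
    assert np.abs(corrected - refs).max() <= 2.0


def test_held_out_grey_patch_corrected(cfg):
    gain = 0.8
    p = SceneParams(
        pose="sign", seed=8, defects=frozenset({"lighting_shift"}), lighting_gain=gain
    )
    rec, _ = generate_scene(p, cfg.sign)
    cal = calibrate(rec, cfg.sign)
    grey = np.array([150.0, 150.0, 150.0])
    seen = np.round(grey * gain)  # what the camera recorded
    corrected = cal.apply(seen)
    assert np.abs(corrected - grey).max() <= 3.0


def test_transform_strictly_reduces_residual_vs_identity(cfg):
    p = SceneParams(
        pose="sign", seed=9, defects=frozenset({"lighting_shift"}), lighting_gain=1.25
    )
    rec, _ = generate_scene(p, cfg.sign)
    det = detect_sign(rec, cfg.sign)
    M, off, res = estimate_color_transform(det, cfg.sign)
    refs = np.array(
        [
            cfg.sign.reference_border,
            cfg.sign.reference_red,
            cfg.sign.reference_green,
            cfg.sign.reference_blue,
        ],
        float,
    )
    meas = np.array(
        [det.block_colors[k] for k in ("border", "red", "green", "blue")], float
    )
    identity_res = np.abs(meas - refs).mean()
    assert res < identity_res
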