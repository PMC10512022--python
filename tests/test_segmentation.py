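"""Chroma-key isolation, edge refinement and QC against generator truth."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.morphology import disk

from goatpheno.segmentation import (
    NoSubjectError,
    classify_blue,
    isolate_roi,
    qc_scene,
    refine_edges,
    segment,
)
from goatpheno.synth import BACKDROP_BLUE, generate_scene
from goatpheno.types import GoatMask, ImageRecord, SceneParams

from conftest import rect_scene


def test_uniform_blue_is_all_background(cfg):
    img = np.zeros((20, 30, 3), np.uint8)
    img[:] = BACKDROP_BLUE
    assert classify_blue(img, cfg.blue).all()


def test_uniform_red_is_no_background(cfg):
    img = np.zeros((20, 30, 3), np.uint8)
    img[..., 0] = 200
    assert not classify_blue(img, cfg.blue).any()


def test_scene_background_agreement(cfg, sign_scene):
    rec, truth = sign_scene
    bg = classify_blue(rec, cfg.blue)
    assert ((~bg) == truth.mask).mean() >= 0.99


def test_isolate_selects_goat_and_fills_sign_hole(cfg, sign_scene):
    rec, truth = sign_scene
    bg = classify_blue(rec, cfg.blue)
    m = isolate_roi(rec, bg, cfg.roi)
    # the sign's blue block punches a hole that must be filled back
    assert np.array_equal(m.mask, truth.mask)
    assert m.component_area == truth.mask.sum()


def test_isolate_excludes_small_offcentre_blobs(cfg):
    img = np.zeros((400, 400, 3), np.uint8)
    img[:] = BACKDROP_BLUE
    bg = np.ones((400, 400), bool)
    bg[150:260, 140:260] = False  # goat-sized, centred
    bg[20:32, 20:32] = False  # rock: below min area
    rec = ImageRecord(img, "sign", "x")
    m = isolate_roi(rec, bg, cfg.roi)
    assert m.mask[200, 200] and not m.mask[25, 25]


def test_isolate_tie_breaks_toward_centre(cfg):
    bg = np.ones((400, 400), bool)
    bg[170:230, 150:250] = False  # centred blob
    bg[20:80, 150:250] = False  # same area, off-centre (within offset prior)
    img = np.zeros((400, 400, 3), np.uint8)
    rec = ImageRecord(img, "sign", "x")
    m = isolate_roi(rec, bg, cfg.roi)
    assert m.mask[200, 200] and not m.mask[50, 200]


def test_isolate_no_subject_reports_candidates(cfg):
    bg = np.ones((300, 300), bool)
    bg[10:20, 10:20] = False
    rec = ImageRecord(np.zeros((300, 300, 3), np.uint8), "sign", "x")
    with pytest.raises(NoSubjectError) as exc:
        isolate_roi(rec, bg, cfg.roi)
    assert exc.value.candidates


def test_isolate_invariant_to_brightness(cfg, sign_scene):
    rec, _ = sign_scene
    base = segment(rec, cfg, refine=False).mask
    for gain in (0.8, 1.2):
        scaled = np.clip(np.round(rec.pixels.astype(float) * gain), 0, 255).astype(
            np.uint8
        )
        m = segment(ImageRecord(scaled, "sign", "x"), cfg, refine=False).mask
        assert np.array_equal(m, base)


# ------------------------------------------------------------------ refine


def test_refine_is_exact_on_converged_step_edge():
    rec, truth = rect_scene()
    out = refine_edges(rec, GoatMask(mask=truth.copy()), 5)
    assert np.array_equal(out.mask, truth)


@pytest.mark.parametrize(
    "structure", [np.ones((7, 7), bool), disk(3).astype(bool)], ids=["square", "disk"]
)
def test_refine_recovers_dilated_step_edge_exactly(structure):
    rec, truth = rect_scene()
    dil = ndi.binary_dilation(truth, structure=structure)
    out = refine_edges(rec, GoatMask(mask=dil), 5)
    assert np.array_equal(out.mask, truth)


def test_refine_recovers_eroded_step_edge_exactly():
    rec, truth = rect_scene()
    ero = ndi.binary_erosion(truth, structure=np.ones((5, 5), bool))
    out = refine_edges(rec, GoatMask(mask=ero), 5)
    assert np.array_equal(out.mask, truth)


def test_refine_on_goat_scene_is_near_exact(cfg, sign_scene, sign_mask):
    rec, truth = sign_scene
    assert (sign_mask.mask ^ truth.mask).sum() <= 5


def test_refine_blurred_edge_displacement_below_one_pixel(cfg):
    rec, truth = rect_scene()
    blur = np.stack(
        [ndi.gaussian_filter(rec.pixels[..., c].astype(float), 2.0) for c in range(3)],
        axis=-1,
    )
    rb = ImageRecord(np.clip(blur, 0, 255).astype(np.uint8), "side", "b")
    dil = ndi.binary_dilation(truth, structure=np.ones((7, 7), bool))
    out = refine_edges(rb, GoatMask(mask=dil), 5)
    bnd = out.mask ^ ndi.binary_erosion(out.mask)
    true_bnd = truth ^ ndi.binary_erosion(truth)
    dist = ndi.distance_transform_edt(~true_bnd)
    assert dist[bnd].mean() <= 1.0


def test_refine_is_idempotent(cfg, sign_scene, sign_mask):
    rec, _ = sign_scene
    again = refine_edges(rec, sign_mask, cfg.refine_window_px)
    boundary = sign_mask.mask ^ ndi.binary_erosion(sign_mask.mask)
    assert (again.mask ^ sign_mask.mask).sum() <= 0.001 * boundary.sum()


def test_refine_never_moves_farther_than_window():
    rec, truth = rect_scene()
    dil = ndi.binary_dilation(truth, structure=np.ones((7, 7), bool))
    out = refine_edges(rec, GoatMask(mask=dil), 5)
    changed = out.mask ^ dil
    dist_in = ndi.distance_transform_edt(dil)
    assert not changed.any() or dist_in[changed].max() <= 6.0


def test_refine_without_edge_evidence_falls_back_with_flag():
    img = np.full((100, 120, 3), 90, np.uint8)  # featureless frame
    m = np.zeros((100, 120), bool)
    m[30:70, 40:90] = True
    out = refine_edges(ImageRecord(img, "side", "x"), GoatMask(mask=m.copy()), 5)
    assert np.array_equal(out.mask, m)
    assert "REFINE_FALLBACK" in out.flags


def test_full_mask_accuracy_on_scene_sample(cfg):
    for seed in (21, 22, 23):
        rec, truth = generate_scene(SceneParams(pose="sign", seed=seed), cfg.sign)
        m = segment(rec, cfg)
        assert (m.mask == truth.mask).mean() >= 0.99


# ---------------------------------------------------------------------- qc


def test_qc_clean_scene_has_no_flags(cfg, sign_scene, sign_mask):
    rec, _ = sign_scene
    assert qc_scene(rec, sign_mask, cfg) == []


@pytest.mark.parametrize(
    "defect,flag",
    [
        ("dirty_tarp", "LOW_BLUE_COVERAGE"),
        ("rocks", "FEET_NOT_ON_GROUND_LINE"),
        ("handler_occluder", "SUBJECT_TOUCHES_BORDER"),
    ],
)
def test_qc_flags_injected_defects(cfg, defect, flag):
    rec, _ = generate_scene(
        SceneParams(pose="sign", seed=31, defects=frozenset({defect})), cfg.sign
    )
    m = segment(rec, cfg, refine=False)
    assert flag in qc_scene(rec, m, cfg)


def test_qc_never_raises_on_degenerate_mask(cfg):
    img = np.zeros((50, 50, 3), np.uint8)
    m = GoatMask(mask=np.zeros((50, 50), bool))
    flags = qc_scene(ImageRecord(img, "sign", "x"), m, cfg)
    assert isinstance(flags, list)
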