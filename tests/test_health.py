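"""FAMACHA scoring and tooth-age classing against generator truth."""

import numpy as np
import pytest

from goatpheno.health import RoiNotFoundError, famacha_score, tooth_age
from goatpheno.synth import _ellipse_mask, generate_eye_scene, generate_teeth_scene
from goatpheno.types import CalibrationResult, ImageRecord


def _eye_with_color(color):
    rec, _ = generate_eye_scene(1, seed=0, noise_sd=0.0)
    img = rec.pixels.copy()
    H, W = img.shape[:2]
    conj = _ellipse_mask((H, W), (H // 2 + H // 6, W // 2), (H // 10, W // 5))
    img[conj] = np.clip(np.round(color), 0, 255).astype(np.uint8)
    return ImageRecord(img, "eye", "sweep")


@pytest.mark.parametrize("cat", [1, 2, 3, 4, 5])
def test_zero_noise_is_exact_with_zero_distance(cfg, cat):
    rec, _ = generate_eye_scene(cat, cfg.famacha.references, seed=cat, noise_sd=0.0)
    res = famacha_score(rec, config=cfg.famacha)
    assert res.category == cat
    assert res.distance_to_ref[cat - 1] == pytest.approx(0.0, abs=1e-6)


def test_noisy_eyes_classified_correctly(cfg):
    correct = 0
    for cat in range(1, 6):
        for i in range(10):
            rec, _ = generate_eye_scene(
                cat, cfg.famacha.references, seed=100 * cat + i, noise_sd=4.0
            )
            correct += famacha_score(rec, config=cfg.famacha).category == cat
    assert correct >= 48  # >= 95 %


def test_equidistant_color_ties_to_more_anaemic(cfg):
    # bisect along the ref1-ref2 segment to a colour equidistant in Lab
    from goatpheno.health import _lab, classify_famacha_color

    r1 = np.array(cfg.famacha.references[0], float)
    r2 = np.array(cfg.famacha.references[1], float)
    lab1 = _lab(r1[None, None, :])[0, 0]
    lab2 = _lab(r2[None, None, :])[0, 0]
    lo, hi = 0.0, 1.0
    for _ in range(80):
        mid = (lo + hi) / 2
        lab = _lab((r1 * (1 - mid) + r2 * mid)[None, None, :])[0, 0]
        if np.linalg.norm(lab - lab1) < np.linalg.norm(lab - lab2):
            lo = mid
        else:
            hi = mid
    c = r1 * (1 - (lo + hi) / 2) + r2 * ((lo + hi) / 2)
    res = classify_famacha_color(c, cfg.famacha)
    assert abs(res.distance_to_ref[0] - res.distance_to_ref[1]) < 1e-6
    assert res.category == 2


def test_category_sweep_is_monotone(cfg):
    refs = np.array(cfg.famacha.references, float)
    cats = []
    for t in np.linspace(0.0, 1.0, 33):
        pos = t * 4
        i = min(int(pos), 3)
        c = refs[i] * (1 - (pos - i)) + refs[i + 1] * (pos - i)
        cats.append(famacha_score(_eye_with_color(c), config=cfg.famacha).category)
    assert cats[0] == 1 and cats[-1] == 5
    assert all(a <= b for a, b in zip(cats, cats[1:]))


def test_lighting_change_corrected_by_transform(cfg):
    gain = 0.8
    rec, _ = generate_eye_scene(2, cfg.famacha.references, seed=3, noise_sd=0.0)
    dim = np.clip(np.round(rec.pixels.astype(float) * gain), 0, 255).astype(np.uint8)
    cal = CalibrationResult(0.1, np.eye(3) / gain, np.zeros(3), 0.0)
    res = famacha_score(ImageRecord(dim, "eye", "x"), cal, cfg.famacha)
    assert res.category == 2


def test_conjunctiva_not_found_raises(cfg):
    img = np.full((100, 100, 3), 80, np.uint8)
    with pytest.raises(RoiNotFoundError):
        famacha_score(ImageRecord(img, "eye", "x"), config=cfg.famacha)


@pytest.mark.parametrize("pairs", [0, 1, 2, 3, 4])
def test_tooth_pairs_recovered(cfg, pairs):
    rec, truth = generate_teeth_scene(pairs, seed=pairs)
    res = tooth_age(rec, cfg.teeth)
    assert res.permanent_pairs == truth.permanent_pairs


def test_tooth_age_mapping(cfg):
    rec, _ = generate_teeth_scene(0, seed=0)
    assert tooth_age(rec, cfg.teeth).age_class == "<1 yr"
    rec, _ = generate_teeth_scene(4, seed=0)
    assert tooth_age(rec, cfg.teeth).age_class == ">=4 yr"


def test_pair_count_clamped_at_four(cfg):
    # render 9 large regions; the pair count must still clamp to 4
    img = np.full((300, 400, 3), (60, 42, 40), np.uint8)
    for i in range(9):
        c = 20 + i * 42
        img[100:160, c : c + 34] = (235, 228, 215)
    res = tooth_age(ImageRecord(img, "teeth", "x"), cfg.teeth)
    assert res.permanent_pairs == 4


def test_no_teeth_raises(cfg):
    img = np.full((200, 200, 3), (60, 42, 40), np.uint8)
    with pytest.raises(RoiNotFoundError):
        tooth_age(ImageRecord(img, "teeth", "x"), cfg.teeth)
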