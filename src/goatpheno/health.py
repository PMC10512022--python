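"""FAMACHA anaemia scoring and tooth-eruption age classing.

FAMACHA matches the colour of the lower-eyelid conjunctiva against five
reference shades (1 = healthy deep red .. 5 = severely anaemic pale);
matching happens in CIELAB after the sign-derived colour correction, so a
global lighting change that the transform models does not move the score.
Tooth age counts erupted permanent incisor pairs (0-4) in the close-up of
the lower jaw; the protocol's fixed close-up framing keeps tooth scale
roughly constant, so a simple area partition separates permanent from
deciduous teeth.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2lab

from .config import FamachaConfig, ToothConfig
from .types import CalibrationResult, FamachaResult, ImageRecord, ToothAgeClass, ValidationError


class RoiNotFoundError(RuntimeError):
    """The expected anatomical region could not be located."""


def _lab(rgb: np.ndarray) -> np.ndarray:
    return rgb2lab(np.clip(np.asarray(rgb, float) / 255.0, 0.0, 1.0))


def famacha_score(
    image: ImageRecord,
    transform: CalibrationResult | None = None,
    config: FamachaConfig | None = None,
) -> FamachaResult:
    """Score the conjunctiva colour against the five FAMACHA references.

    The conjunctiva ROI is the largest connected region inside the
    red-pink chromaticity band after colour correction; its mean corrected
    colour is matched to the nearest reference in CIELAB (Euclidean
    distance), ties broken toward the higher (more anaemic) category.
    """
    cfg = config or FamachaConfig()
    cal = transform or CalibrationResult.identity()
    px = cal.apply(image.pixels)
    r = px[..., 0]
    g = px[..., 1]
    b = px[..., 2]
    band = (
        (r >= cfg.red_min)
        & (r - g >= cfg.red_minus_green_min)
        & (r - b >= cfg.red_minus_blue_min)
    )
    labels, n = ndi.label(band, structure=np.ones((3, 3), int))
    if n == 0:
        raise RoiNotFoundError("conjunctiva not found")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < cfg.min_roi_px:
        raise RoiNotFoundError("conjunctiva not found")
    roi = labels == best
    mean_color = px[roi].reshape(-1, 3).mean(axis=0)
    return classify_famacha_color(mean_color, cfg)


def classify_famacha_color(
    color, config: FamachaConfig | None = None
) -> FamachaResult:
    """Match one (already colour-corrected) RGB triplet to the nearest
    FAMACHA reference in CIELAB; exact ties go to the more anaemic (higher)
    category, the clinically conservative choice."""
    cfg = config or FamachaConfig()
    mean_color = np.asarray(color, dtype=float)
    refs = np.asarray(cfg.references, dtype=float)
    lab_refs = _lab(refs[None, :, :])[0]
    lab_mean = _lab(mean_color[None, None, :])[0, 0]
    dists = np.linalg.norm(lab_refs - lab_mean, axis=1)
    best_d = dists.min()
    category = int(np.max(np.nonzero(dists <= best_d + 1e-9)[0])) + 1
    order = np.sort(dists)
    return FamachaResult(
        category=category,
        measured_color=tuple(float(v) for v in mean_color),
        distance_to_ref=tuple(float(d) for d in dists),
        confidence=float(order[1] - order[0]) if len(order) > 1 else float("inf"),
    )


def tooth_age(
    image: ImageRecord,
    config: ToothConfig | None = None,
) -> ToothAgeClass:
    """Count erupted permanent incisor pairs and map them to an age class.

    Tooth-coloured regions (bright, low chroma) are segmented and
    partitioned into permanent vs deciduous by area: permanent teeth must
    reach both a fraction of the largest tooth and an absolute fraction of
    the frame.  The pair count is clamped to [0, 4].
    """
    cfg = config or ToothConfig()
    px = image.pixels.astype(int)
    band = px.min(axis=2) >= cfg.brightness_min
    labels, n = ndi.label(band, structure=np.ones((3, 3), int))
    if n == 0:
        raise RoiNotFoundError("teeth not found")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    sizes = sizes[sizes >= 20]  # specks are noise, not teeth
    if sizes.size == 0:
        raise RoiNotFoundError("teeth not found")
    frame_area = px.shape[0] * px.shape[1]
    thresh = max(cfg.area_ratio * sizes.max(), cfg.min_area_frac * frame_area)
    permanent = int((sizes >= thresh).sum())
    pairs = min(max(permanent // 2, 0), 4)
    label = cfg.age_mapping.get(pairs)
    if label is None:
        raise ValidationError(f"age mapping lacks an entry for {pairs} pairs")
    return ToothAgeClass(permanent_pairs=pairs, age_class=label)
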