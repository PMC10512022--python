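"""Synthetic protocol scenes with exact ground truth.

Renders the study conditions the image-collection protocol prescribes: a
goat-shaped non-blue subject centred between a blue backdrop and a blue
ground tarp, photographed from >= 3 m at eye level with the black-bordered
calibration sign worn flat against the animal's right side.  The goat is a
2-D parametric silhouette (barrel, shaped topline, neck/head, four legs);
at protocol distance perspective effects are negligible, so a single
centimetres-per-pixel scale is valid across the subject plane and every
landmark is known exactly at render time.

Field defects seen during protocol development (handler limbs intruding,
rocks hiding the feet, a dirty tarp, lighting shifts, a skewed sign, a
missing ground tarp) can be injected individually; the defect inventory is
recorded in the ground truth so QC tests have an oracle.

Renders are hard-edged and noise-free by design: recovery tests then
measure algorithmic error, not synthetic sensor noise.  Close-up eye and
teeth scenes have their own generators.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import polygon as _draw_polygon

from .config import SignConfig, FamachaConfig, synthetic_cohort_config
from .types import (
    ImageRecord,
    SceneGroundTruth,
    SceneParams,
    BodyMeasures,
    ValidationError,
)

# Palette: protocol colours.  Goats have no blue regions; the backdrop and
# tarp are distinct blues so the chroma key sees both.
BACKDROP_BLUE = (30, 70, 200)
TARP_BLUE = (45, 95, 205)
DIRT_BROWN = (105, 82, 55)
EARTH_BROWN = (120, 95, 60)
ROCK_GRAY = (128, 125, 120)
SKIN_TONE = (205, 160, 135)
SCRUBS_BLUE = (40, 80, 195)
SIGN_WHITE = (246, 246, 244)

COAT_PALETTE = {
    "tan": (196, 154, 96),
    "brown": (120, 80, 50),
    "black": (35, 30, 28),
    "white": (235, 232, 225),
}

_DEFAULT_FRAMES = {"sign": (1100, 1400), "side": (1100, 1400), "rear": (1000, 1000)}


def _px(cm: float, s: float) -> int:
    return int(round(cm * s))


def _fill(img, rr, cc, color):
    img[rr, cc] = color


def _rect(img, r0, r1, c0, c1, color):
    img[r0:r1, c0:c1] = color


def _ellipse_mask(shape, center, radii):
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _side_silhouette(p: SceneParams, frame: tuple[int, int]):
    """Silhouette mask + landmark geometry for the side/sign poses.

    The animal faces right (the protocol photographs the right side).
    Returns a dict of pixel landmarks; all bands used by the morphometry
    stage (flat withers topline, vertical shoulder/pin faces, clear column
    behind the foreleg) hold by construction.
    """
    H, W = frame
    s = p.px_per_cm
    hw_px, bl_px, cd_px = _px(p.hw, s), _px(p.bl, s), _px(p.chest_depth, s)
    head_len = _px(12.0, s)

    crow, ccol = H // 2, W // 2
    g = crow + hw_px // 2
    w = g - hw_px
    x_sh = ccol + bl_px // 2
    x_pin = x_sh - bl_px + 1
    b = w + cd_px - 1  # belly row

    if w < 5 or g > H - 6 or x_pin < 5 or x_sh + head_len > W - 6:
        raise ValidationError(
            f"goat ({p.hw}x{p.bl} cm at {s} px/cm) does not fit in frame {frame}"
        )

    sil = np.zeros(frame, dtype=bool)

    # Body: flat belly, shaped topline.
    x1 = x_sh - _px(0.75 * bl_px / s, s)
    x2 = x_sh - _px(0.10 * bl_px / s, s)
    rump_drop = max(int(round(0.15 * hw_px)), 1)
    shoulder_drop = max(int(round(0.08 * hw_px)), 1)
    xs = np.arange(x_pin, x_sh + 1)
    top = np.full(xs.shape, w, dtype=int)
    rear = xs < x1
    top[rear] = w + np.round(rump_drop * (x1 - xs[rear]) / max(x1 - x_pin, 1)).astype(int)
    front = xs > x2
    top[front] = w + np.round(
        shoulder_drop * (xs[front] - x2) / max(x_sh - x2, 1)
    ).astype(int)
    rr = np.arange(H)[:, None]
    sil[:, x_pin : x_sh + 1] = (rr >= top[None, :]) & (rr <= b)

    # Legs: fore pair and hind pair each render as one near-leg rectangle.
    fl_l, fl_r = x_sh - _px(0.20 * bl_px / s, s), x_sh - _px(0.12 * bl_px / s, s)
    hl_l, hl_r = x_pin + _px(0.06 * bl_px / s, s), x_pin + _px(0.14 * bl_px / s, s)
    sil[b + 1 : g + 1, fl_l : fl_r + 1] = True
    sil[b + 1 : g + 1, hl_l : hl_r + 1] = True

    # Neck and head, ahead of the shoulder and below the withers so the
    # topline maximum in the withers band is the withers itself.
    n0, n1 = w + max(_px(0.02 * hw_px / s, s), 2), w + _px(0.20 * hw_px / s, s)
    sil[n0:n1, x_sh - _px(0.04 * bl_px / s, s) : x_sh + _px(0.06 * bl_px / s, s)] = True
    h0, h1 = n0 + max(_px(0.02 * hw_px / s, s), 2), n1 - 2
    sil[h0:h1, x_sh : x_sh + head_len] = True

    return {
        "sil": sil,
        "ground_row": g,
        "withers_row": w,
        "belly_row": b,
        "x_shoulder": x_sh,
        "x_pin": x_pin,
        "foreleg": (fl_l, fl_r),
        "hw_px": hw_px,
        "bl_px": bl_px,
        "cd_px": cd_px,
    }


def _rear_silhouette(p: SceneParams, frame: tuple[int, int]):
    H, W = frame
    s = p.px_per_cm
    hw_px, cw_px, cd_px = _px(p.hw, s), _px(p.chest_width, s), _px(p.chest_depth, s)
    crow, ccol = H // 2, W // 2
    g = crow + hw_px // 2
    w = g - hw_px
    b = w + cd_px - 1
    if w < 5 or g > H - 6 or ccol - cw_px // 2 < 5 or ccol + cw_px // 2 > W - 6:
        raise ValidationError("rear silhouette does not fit in frame")

    sil = np.zeros(frame, dtype=bool)
    r_mid = (w + b) // 2
    half_span = max((b - w) / 2.0, 1.0)
    rows = np.arange(w, b + 1)
    u = (rows - r_mid) / (half_span + 0.5)
    widths = np.round(cw_px * np.sqrt(np.clip(1.0 - 0.5 * u * u, 0.0, 1.0))).astype(int)
    widths[rows == r_mid] = cw_px
    for r, wd in zip(rows, widths):
        if wd <= 0:
            continue
        left = ccol - wd // 2
        sil[r, left : left + wd] = True

    lw = max(_px(0.18 * cw_px / s, s), 8)
    off = _px(0.22 * cw_px / s, s)
    sil[b + 1 : g + 1, ccol - off - lw : ccol - off] = True
    sil[b + 1 : g + 1, ccol + off : ccol + off + lw] = True
    return {"sil": sil, "ground_row": g, "withers_row": w, "cw_px": cw_px, "r_mid": r_mid}


def _paint_coat(img, sil, p: SceneParams, rng: np.random.Generator):
    """Colour the silhouette; for patched coats, grow elliptical patches of
    the secondary colours until their pixel share reaches the target."""
    colors = [tuple(int(v) for v in c) for c in p.coat_colors]
    img[sil] = colors[0]
    fractions = [1.0]
    if p.pattern == "patched" and len(colors) > 1:
        n_sec = len(colors) - 1
        area = int(sil.sum())
        target_each = p.patch_fraction / n_sec
        rr_all, cc_all = np.nonzero(sil)
        patch_masks = [np.zeros(sil.shape, bool) for _ in range(n_sec)]
        for k in range(n_sec):
            want = target_each * area
            for _ in range(40):
                have = patch_masks[k].sum()
                if have >= want * 0.98:
                    break
                remaining = want - have
                rad = max(int(np.sqrt(remaining / np.pi) * 0.9), 4)
                i = rng.integers(len(rr_all))
                em = _ellipse_mask(
                    sil.shape, (rr_all[i], cc_all[i]), (rad, int(rad * 1.3))
                )
                patch_masks[k] |= em & sil
            # Other secondaries must not overwrite this patch later.
            for j in range(k):
                patch_masks[k] &= ~patch_masks[j]
            img[patch_masks[k]] = colors[k + 1]
        sec_fracs = [m.sum() / max(sil.sum(), 1) for m in patch_masks]
        fractions = [1.0 - sum(sec_fracs)] + list(sec_fracs)
    return fractions


def _sign_geometry(sign: SignConfig, s: float, center_rc, skew_deg: float):
    """Corner coordinates for the white face, black ring, inner face and
    the three colour blocks, all optionally rotated about the centre."""
    margin = _px(1.0, s)  # white face margin outside the black outline
    W_px, H_px = _px(sign.width_cm, s), _px(sign.height_cm, s)
    bt = _px(sign.border_cm, s)

    def rect(h, w):
        # corners at pixel boundaries, clockwise from TL, centred on origin
        return np.array(
            [[-h / 2, -w / 2], [-h / 2, w / 2], [h / 2, w / 2], [h / 2, -w / 2]]
        )

    geoms = {
        "face": rect(H_px + 2 * margin, W_px + 2 * margin),
        "outer": rect(H_px, W_px),
        "inner": rect(H_px - 2 * bt, W_px - 2 * bt),
    }
    iw, ih = W_px - 2 * bt, H_px - 2 * bt
    gap = max(_px(0.8, s), 4)
    bw = (iw - 4 * gap) // 3
    bh = ih - 2 * gap
    lefts = [-iw / 2 + gap + i * (bw + gap) for i in range(3)]
    for name, left in zip(("red", "green", "blue"), lefts):
        geoms[name] = np.array(
            [
                [-bh / 2, left],
                [-bh / 2, left + bw],
                [bh / 2, left + bw],
                [bh / 2, left],
            ]
        )
    th = np.deg2rad(skew_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    out = {}
    for name, pts in geoms.items():
        rc = pts @ rot.T + np.asarray(center_rc, float)
        out[name] = rc
    return out


def _fill_poly(img, pts, color):
    rr, cc = _draw_polygon(pts[:, 0], pts[:, 1], shape=img.shape[:2])
    img[rr, cc] = color


def _render_sign(img, geo, sign: SignConfig):
    _fill_poly(img, geo["face"], SIGN_WHITE)
    _fill_poly(img, geo["outer"], sign.reference_border)
    _fill_poly(img, geo["inner"], SIGN_WHITE)
    _fill_poly(img, geo["red"], sign.reference_red)
    _fill_poly(img, geo["green"], sign.reference_green)
    _fill_poly(img, geo["blue"], sign.reference_blue)


def _poly_inside(pts, sil):
    rr, cc = _draw_polygon(pts[:, 0], pts[:, 1], shape=sil.shape)
    return bool(sil[rr, cc].all())


def generate_scene(
    params: SceneParams, sign_config: SignConfig | None = None
) -> tuple[ImageRecord, SceneGroundTruth]:
    """Render one protocol scene and its exact ground truth.

    Deterministic given ``params.seed``.  The sign pose carries the
    black-bordered calibration sign flat on the animal's side, above the
    belly underline and below the topline; the side ("naked") pose and the
    rear pose have no sign.
    """
    if params.pose not in ("sign", "side", "rear"):
        raise ValidationError(
            f"generate_scene renders sign/side/rear poses, not {params.pose!r}; "
            "use generate_eye_scene / generate_teeth_scene for close-ups"
        )
    sign_cfg = sign_config or synthetic_cohort_config().sign
    frame = params.frame or _DEFAULT_FRAMES[params.pose]
    rng = np.random.default_rng(params.seed)

    if params.pose == "rear":
        geo = _rear_silhouette(params, frame)
    else:
        geo = _side_silhouette(params, frame)
    sil = geo["sil"]
    g = geo["ground_row"]

    img = np.empty((*frame, 3), dtype=np.uint8)
    img[: g + 1] = BACKDROP_BLUE
    if "missing_ground_tarp" in params.defects:
        img[g + 1 :] = EARTH_BROWN
    else:
        img[g + 1 :] = TARP_BLUE

    coat_fracs = _paint_coat(img, sil, params, rng)

    sign_quad = None
    if params.pose == "sign":
        skew = params.sign_skew_deg if "skewed_sign" in params.defects else 0.0
        center = (
            (geo["withers_row"] + geo["belly_row"]) / 2.0 - 0.5,
            (geo["x_pin"] + geo["x_shoulder"]) / 2.0,
        )
        sgeo = _sign_geometry(sign_cfg, params.px_per_cm, center, skew)
        if not _poly_inside(sgeo["face"], sil):
            raise ValidationError(
                "calibration sign does not fit between topline and belly "
                f"({sign_cfg.width_cm}x{sign_cfg.height_cm} cm on a "
                f"{params.chest_depth} cm chest)"
            )
        if skew == 0.0:
            # axis-aligned: rasterise by slicing for pixel-exact geometry
            for name, color in (
                ("face", SIGN_WHITE),
                ("outer", sign_cfg.reference_border),
                ("inner", SIGN_WHITE),
                ("red", sign_cfg.reference_red),
                ("green", sign_cfg.reference_green),
                ("blue", sign_cfg.reference_blue),
            ):
                pts = sgeo[name]
                r0 = int(round(pts[0, 0] + 0.5))
                r1 = int(round(pts[2, 0] + 0.5))
                c0 = int(round(pts[0, 1] + 0.5))
                c1 = int(round(pts[2, 1] + 0.5))
                _rect(img, r0, r1, c0, c1, color)
            pts = sgeo["outer"]
            r0 = int(round(pts[0, 0] + 0.5))
            r1 = int(round(pts[2, 0] + 0.5))
            c0 = int(round(pts[0, 1] + 0.5))
            c1 = int(round(pts[2, 1] + 0.5))
            sign_quad = np.array(
                [
                    [r0 - 0.5, c0 - 0.5],
                    [r0 - 0.5, c1 - 0.5],
                    [r1 - 0.5, c1 - 0.5],
                    [r1 - 0.5, c0 - 0.5],
                ]
            )
        else:
            _render_sign(img, sgeo, sign_cfg)
            sign_quad = sgeo["outer"].copy()

    defect_list = sorted(params.defects)
    visible = sil.copy()

    if "rocks" in params.defects:
        rock = np.zeros(frame, bool)
        x0, x1 = geo.get("x_pin", frame[1] // 3), geo.get("x_shoulder", 2 * frame[1] // 3)
        for _ in range(6):
            cx = rng.integers(x0 - 20, x1 + 20)
            rad_r = rng.integers(50, 90)
            rad_c = rng.integers(70, 130)
            rock |= _ellipse_mask(frame, (g, cx), (rad_r, rad_c))
        rock[g + 1 :] = False
        # one detached rock beside the subject
        side_c = x1 + 180 if x1 + 260 < frame[1] else x0 - 180
        rock |= _ellipse_mask(frame, (g - 10, side_c), (45, 60)) & (
            np.arange(frame[0])[:, None] <= g
        )
        img[rock] = ROCK_GRAY
        visible &= ~rock

    if "handler_occluder" in params.defects:
        color = SCRUBS_BLUE if params.handler_blue else SKIN_TONE
        arm_c = geo.get("x_shoulder", frame[1] // 2) - geo.get("bl_px", 400) // 3
        wpx = _px(5.0, params.px_per_cm)
        top_r = geo["withers_row"] + 15
        arm = np.zeros(frame, bool)
        arm[0:top_r, arm_c : arm_c + wpx] = True
        img[arm & ~sil] = color

    if "dirty_tarp" in params.defects:
        bg = ~sil
        from scipy import ndimage as ndi

        keepout = ndi.binary_dilation(sil, iterations=10)
        dust_top = max(g - int(0.35 * g), 0)
        total_bg = bg.sum()
        dirty = np.zeros(frame, bool)
        for _ in range(400):
            if dirty.sum() >= 0.28 * total_bg:
                break
            cr = rng.integers(dust_top, frame[0])
            cc_ = rng.integers(0, frame[1])
            em = _ellipse_mask(frame, (cr, cc_), (rng.integers(25, 70), rng.integers(40, 110)))
            dirty |= em & bg & ~keepout
        img[dirty] = DIRT_BROWN

    if "lighting_shift" in params.defects:
        img = np.clip(
            np.round(img.astype(float) * params.lighting_gain), 0, 255
        ).astype(np.uint8)

    s = params.px_per_cm
    measures = BodyMeasures(
        hw=params.hw,
        bl=params.bl,
        chest_depth=params.chest_depth,
        chest_width=params.chest_width,
    )
    truth = SceneGroundTruth(
        mask=visible,
        scale=1.0 / s,
        ground_row=g,
        withers=(geo["withers_row"], geo.get("x_shoulder", frame[1] // 2) - geo.get("bl_px", 0) // 3)
        if params.pose != "rear"
        else None,
        shoulder=(geo["withers_row"] + geo.get("cd_px", 0) // 2, geo.get("x_shoulder"))
        if params.pose != "rear"
        else None,
        pin=(geo["withers_row"] + geo.get("cd_px", 0) // 2, geo.get("x_pin"))
        if params.pose != "rear"
        else None,
        sign_quad=sign_quad,
        measures=measures,
        coat_fractions=coat_fracs,
        defects=defect_list,
    )
    rec = ImageRecord(
        pixels=img,
        pose=params.pose,
        sample_id=f"synthetic-{params.seed}",
        source_path="<synthetic>",
    )
    return rec, truth


# ---------------------------------------------------------------- close-ups


def generate_eye_scene(
    category: int,
    reference_colors=None,
    seed: int = 0,
    noise_sd: float = 4.0,
    frame: tuple[int, int] = (300, 400),
) -> tuple[ImageRecord, SceneGroundTruth]:
    """Close-up eye scene: conjunctiva rendered at the FAMACHA category's
    reference colour plus bounded Gaussian noise, surrounded by lid and fur
    pixels outside the red-pink band."""
    if not 1 <= int(category) <= 5:
        raise ValidationError(f"FAMACHA category must be 1..5, got {category}")
    refs = tuple(reference_colors) if reference_colors is not None else FamachaConfig().references
    if len(refs) != 5:
        raise ValidationError("five reference colours required")
    rng = np.random.default_rng(seed)
    img = np.empty((*frame, 3), np.uint8)
    img[:] = (115, 95, 78)  # fur
    lid = _ellipse_mask(frame, (frame[0] // 2, frame[1] // 2), (frame[0] // 3, frame[1] // 3))
    img[lid] = (140, 120, 105)
    eye = _ellipse_mask(frame, (frame[0] // 2 - 10, frame[1] // 2), (frame[0] // 6, frame[1] // 4))
    img[eye] = (45, 35, 30)  # globe/iris
    conj = _ellipse_mask(
        frame, (frame[0] // 2 + frame[0] // 6, frame[1] // 2), (frame[0] // 10, frame[1] // 5)
    )
    base = np.array(refs[int(category) - 1], float)
    vals = base[None, :] + rng.normal(0.0, noise_sd, size=(int(conj.sum()), 3))
    img[conj] = np.clip(np.round(vals), 0, 255).astype(np.uint8)
    truth = SceneGroundTruth(
        famacha_category=int(category),
        conjunctiva_mask=conj,
        defects=[],
    )
    rec = ImageRecord(img, "eye", f"synthetic-eye-{seed}", source_path="<synthetic>")
    return rec, truth


def generate_teeth_scene(
    n_permanent_pairs: int,
    seed: int = 0,
    frame: tuple[int, int] = (300, 400),
) -> tuple[ImageRecord, SceneGroundTruth]:
    """Close-up lower-incisor row: ``n_permanent_pairs`` large (permanent)
    teeth centred, the remaining of the 8 positions small (deciduous)."""
    n = int(n_permanent_pairs)
    if not 0 <= n <= 4:
        raise ValidationError(f"permanent pairs must be 0..4, got {n}")
    img = np.empty((*frame, 3), np.uint8)
    img[:] = (60, 42, 40)  # mouth shadow
    gum_row = frame[0] // 2 + 30
    img[gum_row:, :] = (150, 96, 118)  # gum; kept outside the tooth band
    tooth = (235, 228, 215)
    big_w, big_h = 34, 48
    small_w, small_h = 16, 24
    gap = 10
    centre = frame[1] // 2
    # positions 0..7 left to right; permanent teeth occupy the central 2n
    xs = []
    pitch = big_w + gap
    for i in range(8):
        xs.append(centre + (i - 3.5) * pitch)
    for i, x in enumerate(xs):
        permanent = abs(i - 3.5) < n
        w_, h_ = (big_w, big_h) if permanent else (small_w, small_h)
        c0 = int(x - w_ / 2)
        img[gum_row - h_ : gum_row, c0 : c0 + w_] = tooth
    truth = SceneGroundTruth(permanent_pairs=n, defects=[])
    rec = ImageRecord(img, "teeth", f"synthetic-teeth-{seed}", source_path="<synthetic>")
    return rec, truth


# ------------------------------------------------------------------ cohort


def sample_cohort_params(
    n: int, seed: int, pose: str = "sign", defects: frozenset[str] = frozenset()
) -> list[SceneParams]:
    """Draw a cohort of anatomically plausible animals.

    Height at withers ~ U(40, 90) cm and chest width ~ U(12, 30) cm; chest
    depth follows conformation at U(0.42, 0.52) of height, clipped to
    [20, 40] cm, so legs always remain long enough to stand on.  Body
    length ~ U(50, 100) cm.  Coats are drawn from the tan/brown/black/white
    palette, solid or two-tone patched.
    """
    rng = np.random.default_rng(seed)
    palette = list(COAT_PALETTE.values())
    out = []
    for i in range(n):
        hw = rng.uniform(40.0, 90.0)
        bl = rng.uniform(50.0, 100.0)
        depth = float(np.clip(rng.uniform(0.42, 0.52) * hw, 20.0, 40.0))
        width = rng.uniform(12.0, 30.0)
        k = int(rng.integers(1, 3))
        idx = rng.choice(len(palette), size=k, replace=False)
        colors = [palette[j] for j in idx]
        pattern = "patched" if k > 1 else "solid"
        out.append(
            SceneParams(
                hw=hw,
                bl=bl,
                chest_depth=depth,
                chest_width=width,
                coat_colors=colors,
                pattern=pattern,
                pose=pose,
                defects=defects,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out
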