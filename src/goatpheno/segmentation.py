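"""Chroma-key subject isolation, boundary refinement and scene QC.

The protocol surrounds the animal with a blue backdrop and ground tarp
precisely because goats carry no blue; classifying blue in HSV makes the
key robust to the brightness shifts common in field photographs.  Subject
selection then applies the protocol's two priors — the goat has a limited
range of size and stands near the frame centre — before a gradient-snap
pass refines the boundary to sub-pixel edge evidence.
"""

from __future__ import annotations

import numpy as np
import shapely
from scipy import ndimage as ndi
from skimage import measure as skmeasure

from .config import BlueKeyConfig, RoiPriorConfig, PipelineConfig
from .types import GoatMask, ImageRecord, ValidationError


class NoSubjectError(RuntimeError):
    """No connected component satisfied the subject priors."""

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = candidates or []


def classify_blue(
    image: ImageRecord | np.ndarray, thresholds: BlueKeyConfig | None = None
) -> np.ndarray:
    """Binary background grid: True where the pixel is protocol blue.

    A pixel counts as background iff its hue lies in the configured blue
    band and both saturation and value exceed their minima.  Hue is
    brightness-invariant, so a uniform gain within the value floor leaves
    the classification unchanged.
    """
    t = thresholds or BlueKeyConfig()
    px = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    arr = px.astype(np.float32)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mx = arr.max(axis=-1)
    mn = arr.min(axis=-1)
    delta = mx - mn
    np.maximum(delta, 1e-6, out=delta)
    hue = np.where(
        mx == r,
        (g - b) / delta % 6.0,
        np.where(mx == g, (b - r) / delta + 2.0, (r - g) / delta + 4.0),
    )
    hue_deg = hue * 60.0
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-6), 0.0)
    val = mx / 255.0
    return (
        (hue_deg >= t.hue_lo_deg)
        & (hue_deg <= t.hue_hi_deg)
        & (sat >= t.sat_min)
        & (val >= t.val_min)
    )


def isolate_roi(
    image: ImageRecord,
    background: np.ndarray,
    priors: RoiPriorConfig | None = None,
) -> GoatMask:
    """Select the goat among non-background components using the size and
    centring priors; interior holes are filled, gaps connected to the
    outer background (e.g. between the legs) are preserved."""
    priors = priors or RoiPriorConfig()
    if background.shape != image.shape:
        raise ValidationError("background grid shape does not match image")
    H, W = background.shape
    frame_area = H * W
    diag = float(np.hypot(H, W))
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])

    fg = ~background
    labels, n = ndi.label(fg, structure=np.ones((3, 3), int))
    candidates = []
    for region in skmeasure.regionprops(labels):
        area_frac = region.area / frame_area
        offset = float(np.hypot(*(np.asarray(region.centroid) - center)))
        candidates.append(
            {
                "label": region.label,
                "area": int(region.area),
                "area_frac": area_frac,
                "centroid": tuple(region.centroid),
                "offset": offset,
                "bbox": tuple(region.bbox),
            }
        )
    qualifying = [
        c
        for c in candidates
        if priors.min_area_frac <= c["area_frac"] <= priors.max_area_frac
        and c["offset"] <= priors.max_centroid_offset_frac * diag
    ]
    if not qualifying:
        raise NoSubjectError(
            f"no subject found among {len(candidates)} components", candidates
        )
    # largest area; ties by centring, then topmost-leftmost bounding box
    qualifying.sort(key=lambda c: (-c["area"], c["offset"], c["bbox"][:2]))
    best = qualifying[0]
    mask = labels == best["label"]
    mask = ndi.binary_fill_holes(mask)

    border = (
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    nonmask = ~mask
    blue_cov = float(background[nonmask].sum() / max(nonmask.sum(), 1))
    return GoatMask(
        mask=mask,
        touches_border=bool(border),
        occluder_suspected=bool(border),
        blue_coverage=blue_cov,
        flags=[],
    )


def _structure_tensor(pixels: np.ndarray):
    """Colour structure tensor (Jrr, Jrc, Jcc) summed over channels.

    Sampling ``n^T J n`` along a contour normal n measures edge energy in
    that direction only, so a strong edge perpendicular to the normal (the
    other side of a corner) does not attract the snap.
    """
    Jrr = Jrc = Jcc = 0.0
    for c in range(3):
        ch = ndi.gaussian_filter(pixels[..., c].astype(float), 1.0)
        gr = ndi.sobel(ch, axis=0, mode="nearest")
        gc = ndi.sobel(ch, axis=1, mode="nearest")
        Jrr = Jrr + gr * gr
        Jrc = Jrc + gr * gc
        Jcc = Jcc + gc * gc
    return Jrr, Jrc, Jcc


def _fit_line(points: np.ndarray):
    """Total-least-squares line through points: (centroid, unit direction)."""
    c = points.mean(axis=0)
    d = points - c
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    return c, vt[0]


def _reconstruct_corners(
    moved: np.ndarray, corner_like: np.ndarray, reliable: np.ndarray, window_px: int
) -> np.ndarray:
    """Replace each corner run of snapped points by the intersection of the
    lines fitted to the reliable snapped segments on either side.

    A snapped boundary can only reach a sharp corner by extending the two
    adjacent edges; per-point normal snapping stops short.  Runs without
    stable support on both sides keep their interpolated positions.
    """
    n = len(moved)
    out = moved.copy()
    lab = corner_like.astype(int)
    # maximal circular runs of corner-like points
    starts = np.nonzero(lab & ~np.roll(lab, 1))[0]
    if lab.all():
        return out
    k = 8
    for s in starts:
        e = s
        while lab[(e + 1) % n]:
            e = (e + 1) % n
            if e == s:
                break
        run = [(s + i) % n for i in range(((e - s) % n) + 1)]
        # the first couple of reliable points next to a corner are still
        # slightly contaminated by it; skip them when fitting the edge lines
        skip = 2
        before, i, seen = [], (s - 1) % n, 0
        while len(before) < k and i not in run:
            if reliable[i]:
                seen += 1
                if seen > skip:
                    before.append(i)
            elif before:
                break
            i = (i - 1) % n
        after, i, seen = [], (e + 1) % n, 0
        while len(after) < k and i not in run:
            if reliable[i]:
                seen += 1
                if seen > skip:
                    after.append(i)
            elif after:
                break
            i = (i + 1) % n
        if len(before) < 3 or len(after) < 3:
            continue
        c1, d1 = _fit_line(moved[before])
        c2, d2 = _fit_line(moved[after])
        cross = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(cross) < np.sin(np.deg2rad(20.0)):
            continue  # nearly parallel: no stable intersection
        # solve c1 + a*d1 = c2 + b*d2
        rhs = c2 - c1
        a = (rhs[0] * d2[1] - rhs[1] * d2[0]) / cross
        x = c1 + a * d1
        mid = moved[run[len(run) // 2]]
        if np.hypot(*(x - mid)) <= window_px + len(run) + 3:
            out[run] = x
    return out


def refine_edges(
    image: ImageRecord, mask: GoatMask, window_px: int = 5
) -> GoatMask:
    """Snap each boundary point to the strongest colour edge along its
    local normal, moving at most ``window_px``.

    The contour of the current mask is walked in order; at every point the
    summed-channel gradient magnitude is sampled along the outward normal
    at quarter-pixel steps within the window, and the point moves to the
    (parabolically interpolated) maximum.  If re-rasterising the displaced
    contour breaks connectivity the unrefined mask is returned with a QC
    flag — never a crash.
    """
    m_full = mask.mask
    rr0, cc0 = np.nonzero(m_full)
    if rr0.size == 0:
        return mask
    # work in a padded crop around the subject; everything else is frozen
    H, W = m_full.shape
    pad = window_px + 8
    r0 = max(int(rr0.min()) - pad, 0)
    r1 = min(int(rr0.max()) + pad + 1, H)
    c0 = max(int(cc0.min()) - pad, 0)
    c1 = min(int(cc0.max()) + pad + 1, W)
    m = m_full[r0:r1, c0:c1]
    Jrr, Jrc, Jcc = _structure_tensor(image.pixels[r0:r1, c0:c1])
    contours = skmeasure.find_contours(m.astype(float), 0.5)
    if not contours:
        return mask
    step = 0.25
    offsets = np.arange(-window_px, window_px + step / 2, step)
    snapped_pts = []
    snapped_normals = []
    snapped_support = []
    for pts in contours:
        # closed contours repeat their first point at the end; drop it so
        # circular differences at the seam are well defined
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        # tangents via central differences on the closed contour
        tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
        norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
        ln = np.linalg.norm(norm, axis=1, keepdims=True)
        ln[ln == 0] = 1.0
        norm /= ln
        # orient normals outward
        probe = pts + 1.5 * norm
        pi = np.clip(np.round(probe).astype(int), 0, np.array(m.shape) - 1)
        if m[pi[:, 0], pi[:, 1]].mean() > 0.5:
            norm = -norm
        # sample directional edge energy n^T J n along each normal
        sample_pts = pts[None, :, :] + offsets[:, None, None] * norm[None, :, :]
        coords = [sample_pts[..., 0], sample_pts[..., 1]]
        srr = ndi.map_coordinates(Jrr, coords, order=1, mode="nearest")
        src = ndi.map_coordinates(Jrc, coords, order=1, mode="nearest")
        scc = ndi.map_coordinates(Jcc, coords, order=1, mode="nearest")
        nr = norm[None, :, 0]
        nc = norm[None, :, 1]
        vals = srr * nr * nr + 2.0 * src * nr * nc + scc * nc * nc
        vmax = vals.max(axis=0)
        # An ideal step edge yields a flat plateau of maximal response (the
        # bilinear samples between two equally strong pixels); the boundary
        # is the plateau midpoint.
        at_max = vals >= (vmax * 0.98 - 1e-9)[None, :]
        first = np.argmax(at_max, axis=0)
        last = len(offsets) - 1 - np.argmax(at_max[::-1], axis=0)
        t = (offsets[first] + offsets[last]) / 2.0
        # parabolic sub-step refinement where the maximum is unique
        inner = (first == last) & (first > 0) & (first < len(offsets) - 1)
        if inner.any():
            idx = np.nonzero(inner)[0]
            i = first[inner]
            y0, y1, y2 = vals[i - 1, idx], vals[i, idx], vals[i + 1, idx]
            denom = y0 - 2 * y1 + y2
            shift = np.zeros_like(y1)
            nz = np.abs(denom) > 1e-12
            shift[nz] = 0.5 * (y0[nz] - y2[nz]) / denom[nz]
            t[inner] = t[inner] + np.clip(shift, -0.5, 0.5) * step
        t = np.clip(t, -window_px, window_px)
        # A point is reliable when its normal crossed a genuine edge (strong
        # response) head-on (narrow plateau).  Corner points look along the
        # edge obliquely and are ambiguous: their displacement is replaced by
        # circular interpolation from reliable neighbours along the contour.
        plateau_w = offsets[last] - offsets[first]
        # Corners accumulate signed turning angle over a short window; the
        # one-pixel staircase of a shallow diagonal edge alternates signs
        # and cancels, so it is *not* flagged.  At corners the normal (and
        # hence the snap) is ill-defined.
        fwd = np.roll(pts, -1, axis=0) - pts
        fln = np.linalg.norm(fwd, axis=1, keepdims=True)
        fln[fln == 0] = 1.0
        fwd /= fln
        prev = np.roll(fwd, 1, axis=0)
        turn = np.arctan2(
            prev[:, 0] * fwd[:, 1] - prev[:, 1] * fwd[:, 0],
            np.einsum("ij,ij->i", prev, fwd),
        )
        n_pts = len(pts)
        win = min(5, n_pts)
        csum = np.cumsum(np.concatenate([turn, turn]))
        wsum = np.empty(n_pts)
        for i in range(n_pts):
            j = i + win
            wsum[i] = csum[j - 1] - (csum[i - 1] if i > 0 else 0.0)
        corner_like = np.abs(wsum) > np.deg2rad(60.0)
        corner_like = corner_like | np.roll(corner_like, win // 2)
        reliable = (
            (vmax >= max(0.3 * np.median(vmax), 1.0))
            & (plateau_w <= 1.25)
            & ~corner_like
        )
        if not reliable.any():
            return GoatMask(
                mask=m_full.copy(),
                touches_border=mask.touches_border,
                occluder_suspected=mask.occluder_suspected,
                blue_coverage=mask.blue_coverage,
                flags=list(mask.flags) + ["REFINE_FALLBACK"],
            )
        if not reliable.all():
            idx = np.arange(n_pts)
            good = np.nonzero(reliable)[0]
            # circular linear interpolation over contour index
            ext_x = np.concatenate([good, good + n_pts])
            ext_y = np.tile(t[good], 2)
            t = np.interp(idx + n_pts, ext_x, ext_y)
        moved = pts + t[:, None] * norm
        if corner_like.any() and reliable.any():
            moved = _reconstruct_corners(moved, corner_like, reliable, window_px)
        snapped_pts.append(moved)

    # Re-classify only the band around the current boundary by testing
    # pixel centres against the snapped closed contours (XOR across
    # contours handles holes).  Pixels beyond the window cannot change,
    # which enforces the movement bound by construction.
    dist_out = ndi.distance_transform_edt(~m)
    dist_in = ndi.distance_transform_edt(m)
    band = (dist_out <= window_px + 1) & (dist_in <= window_px + 1)
    band_idx = np.nonzero(band)
    pix = np.stack(band_idx, axis=1).astype(float)
    inside = np.zeros(len(pix), dtype=bool)
    for moved in snapped_pts:
        if len(moved) < 4:
            continue
        poly = shapely.Polygon(np.column_stack([moved[:, 1], moved[:, 0]]))
        if not poly.is_valid:
            poly = shapely.make_valid(poly)
        shapely.prepare(poly)
        inside ^= shapely.intersects_xy(poly, pix[:, 1], pix[:, 0])
    new_sub = m.copy()
    new_sub[band_idx] = inside
    new_sub = ndi.binary_fill_holes(new_sub)
    new_mask = m_full.copy()
    new_mask[r0:r1, c0:c1] = new_sub
    labels, n = ndi.label(new_mask, structure=np.ones((3, 3), int))
    ok = n == 1 and bool(new_mask.any())
    if not ok:
        out = GoatMask(
            mask=m_full.copy(),
            touches_border=mask.touches_border,
            occluder_suspected=mask.occluder_suspected,
            blue_coverage=mask.blue_coverage,
            flags=list(mask.flags) + ["REFINE_FALLBACK"],
        )
        return out
    return GoatMask(
        mask=new_mask,
        touches_border=mask.touches_border,
        occluder_suspected=mask.occluder_suspected,
        blue_coverage=mask.blue_coverage,
        flags=list(mask.flags),
    )


def _leg_extremities(mask: np.ndarray, tol_px: int, max_width_frac: float):
    """Connected column-runs of mask pixels reaching the lowest mask row.

    Returns (ground_row_estimate_components, mask_bottom_row).  Each
    component is (lowest_row, col_start, col_stop, width).
    """
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        return [], -1
    bottom = rr.max()
    band = mask[max(bottom - tol_px, 0) : bottom + 1]
    cols_present = band.any(axis=0)
    mask_width = cc.max() - cc.min() + 1
    comps = []
    in_run = False
    for c in range(len(cols_present) + 1):
        present = cols_present[c] if c < len(cols_present) else False
        if present and not in_run:
            start = c
            in_run = True
        elif not present and in_run:
            stop = c
            in_run = False
            colmask = mask[:, start:stop]
            low = np.nonzero(colmask.any(axis=1))[0].max()
            comps.append((int(low), start, stop, stop - start))
    legs = [c for c in comps if c[3] <= max_width_frac * mask_width]
    return legs, int(bottom)


def qc_scene(
    image: ImageRecord,
    mask: GoatMask,
    config: PipelineConfig | None = None,
) -> list[str]:
    """Coded QC flags for the failure modes seen in the field.

    Never raises: every check degrades to a flag.
    """
    cfg = config or PipelineConfig()
    flags: list[str] = []
    if mask.blue_coverage < cfg.qc.blue_coverage_min:
        flags.append("LOW_BLUE_COVERAGE")
    if mask.touches_border:
        flags.append("SUBJECT_TOUCHES_BORDER")

    try:
        bg = classify_blue(image, cfg.blue)
        fg = ~bg & ~ndi.binary_dilation(mask.mask, iterations=2)
        labels, n = ndi.label(fg, structure=np.ones((3, 3), int))
        if n:
            sizes = ndi.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
            dist = ndi.distance_transform_edt(~mask.mask)
            for lab in range(1, n + 1):
                if sizes[lab - 1] < cfg.qc.near_object_min_px:
                    continue
                if dist[labels == lab].min() <= cfg.qc.near_object_dist_px:
                    flags.append("NON_BLUE_OBJECT_NEAR_SUBJECT")
                    break
    except Exception:
        flags.append("QC_INCOMPLETE")

    try:
        legs, bottom = _leg_extremities(
            mask.mask, cfg.morphometry.ground_tol_px, cfg.morphometry.leg_max_width_frac
        )
        on_ground = [l for l in legs if l[0] >= bottom - cfg.morphometry.ground_tol_px]
        if len(on_ground) < 2:
            flags.append("FEET_NOT_ON_GROUND_LINE")
    except Exception:
        flags.append("FEET_NOT_ON_GROUND_LINE")
    return flags


def segment(
    image: ImageRecord, config: PipelineConfig | None = None, refine: bool = True
) -> GoatMask:
    """classify_blue -> isolate_roi -> refine_edges in one call."""
    cfg = config or PipelineConfig()
    bg = classify_blue(image, cfg.blue)
    mask = isolate_roi(image, bg, cfg.roi)
    if refine:
        mask = refine_edges(image, mask, cfg.refine_window_px)
    return mask
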