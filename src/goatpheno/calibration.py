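"""Calibration-sign detection, spatial scale and colour correction.

The protocol's sign carries a black outline for easy detection and blocks
of "pure" red, green and blue.  Because the sign is worn flat against the
animal's side, it sits in the subject plane and a single centimetres-per-
pixel scale derived from it is valid for the whole silhouette.  The block
and border colours, compared with their configured references, give an
affine colour correction that makes coat and conjunctiva colours
comparable across lighting conditions.
"""

from __future__ import annotations

import numpy as np
import shapely
from scipy import ndimage as ndi
from skimage import measure as skmeasure

from .config import SignConfig
from .types import CalibrationResult, ImageRecord, SignDetection, ValidationError


class SignNotFoundError(RuntimeError):
    """No dark-bordered quadrilateral with RGB blocks was found."""


def _order_corners(corners: np.ndarray) -> np.ndarray:
    """Order four (row, col) corners clockwise starting at top-left."""
    c = corners.mean(axis=0)
    ang = np.arctan2(corners[:, 1] - c[1], -(corners[:, 0] - c[0]))
    # clockwise on screen (rows grow downward) = ascending angle here
    order = np.argsort(ang)
    pts = corners[order]
    # rotate so the first corner is the one closest to the overall top-left
    start = np.argmin(pts.sum(axis=1))
    return np.roll(pts, -start, axis=0)


def _block_regions(px: np.ndarray, interior: np.ndarray):
    """Dominant-channel block masks within the sign interior."""
    r = px[..., 0].astype(int)
    g = px[..., 1].astype(int)
    b = px[..., 2].astype(int)
    margin = 30
    masks = {
        "red": (r > g + margin) & (r > b + margin),
        "green": (g > r + margin) & (g > b + margin),
        "blue": (b > r + margin) & (b > g + margin),
    }
    out = {}
    for name, m in masks.items():
        m = m & interior
        m = ndi.binary_erosion(m, iterations=2)
        out[name] = m
    return out


def detect_sign(image: ImageRecord, config: SignConfig | None = None) -> SignDetection:
    """Locate the black-bordered calibration sign.

    Candidate dark components are filled and fitted with their minimum
    rotated rectangle; a candidate qualifies when its interior shows the
    three colour blocks in the configured left-to-right red/green/blue
    order and enough of its perimeter is dark.  The best border score wins.
    """
    cfg = config or SignConfig()
    px = image.pixels
    dark = px.max(axis=2) < cfg.dark_value_max
    labels, n = ndi.label(dark, structure=np.ones((3, 3), int))
    H, W = dark.shape
    best = None
    for region in skmeasure.regionprops(labels):
        if region.area < 400 or region.area > 0.5 * H * W:
            continue
        comp = labels[region.slice] == region.label
        filled = ndi.binary_fill_holes(comp)
        # a border ring encloses a hole several times its own area; solid
        # dark blobs (e.g. a black goat) are skipped cheaply here
        if filled.sum() < 2.0 * region.area:
            continue
        rr, cc = np.nonzero(filled)
        pts = np.column_stack([cc + region.bbox[1], rr + region.bbox[0]])  # x, y
        hull = shapely.MultiPoint(pts).convex_hull
        rect = hull.minimum_rotated_rectangle
        if rect.geom_type != "Polygon":
            continue
        xy = np.asarray(rect.exterior.coords)[:4]
        quad = np.column_stack([xy[:, 1], xy[:, 0]])  # back to (row, col)
        quad = _order_corners(quad)
        # expand by half a pixel along both axes: hull vertices are pixel
        # centres, the physical edge lies half a pixel further out
        centre = quad.mean(axis=0)
        d = quad - centre
        nrm = np.linalg.norm(d, axis=1, keepdims=True)
        quad = quad + 0.5 * np.sqrt(2.0) * d / nrm

        # border score: fraction of points along the quad outline that are dark
        score = _border_score(dark, quad)
        if score < cfg.low_confidence_score:
            continue
        # interior colour blocks
        interior = np.zeros_like(dark)
        poly = shapely.Polygon(np.column_stack([quad[:, 1], quad[:, 0]]))
        inner = poly.buffer(-max(_quad_sides(quad).min() * 0.12, 3.0))
        if inner.is_empty:
            continue
        bbox = [int(max(0, np.floor(quad[:, 0].min()))), int(min(H, np.ceil(quad[:, 0].max()) + 1)),
                int(max(0, np.floor(quad[:, 1].min()))), int(min(W, np.ceil(quad[:, 1].max()) + 1))]
        rr2, cc2 = np.mgrid[bbox[0] : bbox[1], bbox[2] : bbox[3]]
        shapely.prepare(inner)
        inside = shapely.intersects_xy(inner, cc2.ravel(), rr2.ravel()).reshape(rr2.shape)
        interior[bbox[0] : bbox[1], bbox[2] : bbox[3]] = inside
        blocks = _block_regions(px, interior)
        if any(m.sum() < 100 for m in blocks.values()):
            continue
        # left-to-right order along the top edge direction must be R, G, B
        top_dir = quad[1] - quad[0]
        top_dir = top_dir / np.linalg.norm(top_dir)
        proj = {}
        for name, m in blocks.items():
            rrb, ccb = np.nonzero(m)
            proj[name] = float(np.dot([rrb.mean(), ccb.mean()] - centre, top_dir))
        if not (proj["red"] < proj["green"] < proj["blue"]):
            continue
        block_colors = {
            name: tuple(px[m].reshape(-1, 3).mean(axis=0)) for name, m in blocks.items()
        }
        border_mask = dark & ~interior
        border_px = px[labels == region.label]
        block_colors["border"] = tuple(border_px.reshape(-1, 3).mean(axis=0))
        skew = _skew_deg(quad)
        det = SignDetection(
            quadrilateral=quad,
            border_score=score,
            block_colors=block_colors,
            skew_deg=skew,
            low_confidence=score < cfg.min_border_score,
        )
        if best is None or det.border_score > best.border_score:
            best = det
    if best is None:
        raise SignNotFoundError(
            f"sign not found in {image.source_path or image.sample_id}"
        )
    return best


def _quad_sides(quad: np.ndarray) -> np.ndarray:
    return np.array(
        [np.linalg.norm(quad[(i + 1) % 4] - quad[i]) for i in range(4)]
    )


def _border_score(dark: np.ndarray, quad: np.ndarray, inset: float = 2.0) -> float:
    """Fraction of sampled outline points (inset toward the centre so they
    sit on the border stroke) classified dark."""
    centre = quad.mean(axis=0)
    shrink = quad + inset * (centre - quad) / np.linalg.norm(centre - quad, axis=1, keepdims=True)
    samples = []
    for i in range(4):
        a, b = shrink[i], shrink[(i + 1) % 4]
        npts = max(int(np.linalg.norm(b - a)), 2)
        ts = np.linspace(0, 1, npts, endpoint=False)
        samples.append(a[None, :] + ts[:, None] * (b - a)[None, :])
    s = np.concatenate(samples)
    ri = np.clip(np.round(s[:, 0]).astype(int), 0, dark.shape[0] - 1)
    ci = np.clip(np.round(s[:, 1]).astype(int), 0, dark.shape[1] - 1)
    return float(dark[ri, ci].mean())


def _skew_deg(quad: np.ndarray) -> float:
    """Magnitude of the angle between the top edge and the horizontal."""
    d = quad[1] - quad[0]
    ang = np.degrees(np.arctan2(-d[0], d[1]))  # rows grow downward
    ang = (ang + 180.0) % 180.0
    if ang > 90.0:
        ang -= 180.0
    return float(abs(ang))


def spatial_scale(det: SignDetection, width_cm: float, height_cm: float) -> float:
    """Centimetres per pixel from the sign's physical dimensions.

    Skew is corrected implicitly by measuring along the (possibly rotated)
    quadrilateral edges; the result averages the width- and height-based
    estimates.
    """
    sides = _quad_sides(det.quadrilateral)
    w_px = (sides[0] + sides[2]) / 2.0
    h_px = (sides[1] + sides[3]) / 2.0
    if w_px < 2.0 or h_px < 2.0:
        raise ValidationError("degenerate sign quadrilateral")
    return float((width_cm / w_px + height_cm / h_px) / 2.0)


def estimate_color_transform(
    det: SignDetection, config: SignConfig | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Affine RGB correction mapping measured sign colours to references.

    Returns ``(matrix, offset, residual)`` minimising
    ``||measured @ matrix.T + offset - reference||`` over the border and the
    three blocks in the least-squares sense.  With four well-spread colours
    the system is exactly determined; higher-order models would overfit.
    """
    cfg = config or SignConfig()
    refs = np.array(
        [
            cfg.reference_border,
            cfg.reference_red,
            cfg.reference_green,
            cfg.reference_blue,
        ],
        dtype=float,
    )
    meas = np.array(
        [
            det.block_colors["border"],
            det.block_colors["red"],
            det.block_colors["green"],
            det.block_colors["blue"],
        ],
        dtype=float,
    )
    A = np.column_stack([meas, np.ones(len(meas))])
    if np.linalg.matrix_rank(A) < 4:
        raise ValidationError(
            "sign colours are rank deficient; cannot fit a colour transform"
        )
    coef, *_ = np.linalg.lstsq(A, refs, rcond=None)
    matrix = coef[:3].T
    offset = coef[3]
    corrected = meas @ matrix.T + offset
    residual = float(np.abs(corrected - refs).mean())
    return matrix, offset, residual


def calibrate(
    image: ImageRecord, config: SignConfig | None = None
) -> CalibrationResult:
    """detect_sign -> spatial_scale + colour transform in one call."""
    cfg = config or SignConfig()
    det = detect_sign(image, cfg)
    scale = spatial_scale(det, cfg.width_cm, cfg.height_cm)
    matrix, offset, residual = estimate_color_transform(det, cfg)
    return CalibrationResult(
        scale=scale,
        color_matrix=matrix,
        color_offset=offset,
        residual=residual,
        source_pose=image.pose,
    )
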