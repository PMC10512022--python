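"""Calibrated coat colour and pattern summaries from the "naked" side view.

Coat colour only becomes comparable across animals and lighting once the
sign-derived colour correction has been applied; the summary is a small
set of corrected-RGB cluster centroids with pixel fractions, a
solid/patched call, and a down-sampled label grid (with run-length
encoding) as the vectorised pattern.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

from .config import CoatConfig
from .types import CalibrationResult, CoatSummary, GoatMask, ImageRecord, ValidationError


class InsufficientCoatError(RuntimeError):
    """The mask exposes too little coat to summarise."""


def coat_colors(
    image: ImageRecord,
    mask: GoatMask,
    transform: CalibrationResult | None = None,
    config: CoatConfig | None = None,
) -> CoatSummary:
    """Cluster the colour-corrected goat pixels into at most K coat colours.

    Clusters holding less than the merge fraction of pixels are folded into
    their nearest surviving centroid (suppresses shadow slivers); the coat
    is called solid when the top cluster holds at least the configured
    fraction.  Fixed seed and multiple restarts make the result
    reproducible bit for bit.
    """
    cfg = config or CoatConfig()
    if mask.mask.shape != image.shape:
        raise ValidationError("mask shape does not match image")
    area = int(mask.mask.sum())
    if area < cfg.min_area_px:
        raise InsufficientCoatError(f"insufficient coat area ({area} px)")
    cal = transform or CalibrationResult.identity()
    px = cal.apply(image.pixels[mask.mask]).reshape(-1, 3)

    uniq = np.unique(px, axis=0)
    k = int(min(cfg.k, len(uniq)))
    if k == 1:
        labels_flat = np.zeros(len(px), dtype=int)
        centroids = uniq.astype(float)
    else:
        km = KMeans(n_clusters=k, n_init=cfg.n_restarts, random_state=cfg.seed)
        labels_flat = km.fit_predict(px)
        centroids = km.cluster_centers_

    counts = np.bincount(labels_flat, minlength=len(centroids)).astype(float)
    fractions = counts / counts.sum()
    # fold sub-threshold clusters into their nearest surviving neighbour
    while (fractions > 0).sum() > 1 and fractions[fractions > 0].min() < cfg.merge_fraction:
        small = int(np.where(fractions > 0, fractions, np.inf).argmin())
        alive = [i for i in range(len(centroids)) if fractions[i] > 0 and i != small]
        tgt = alive[
            int(np.argmin([np.linalg.norm(centroids[i] - centroids[small]) for i in alive]))
        ]
        labels_flat[labels_flat == small] = tgt
        counts = np.bincount(labels_flat, minlength=len(centroids)).astype(float)
        # recompute the merged centroid as the mean of its members
        centroids[tgt] = px[labels_flat == tgt].mean(axis=0)
        fractions = counts / counts.sum()

    alive = np.nonzero(fractions > 0)[0]
    order = alive[np.argsort(-fractions[alive])]
    clusters = [
        (tuple(float(v) for v in centroids[i]), float(fractions[i])) for i in order
    ]
    relabel = {int(old): new for new, old in enumerate(order)}
    labels_flat = np.array([relabel[int(l)] for l in labels_flat])

    pattern_class = "solid" if clusters[0][1] >= cfg.solid_fraction else "patched"

    # down-sampled label grid over the mask bounding box (-1 outside mask)
    full = np.full(mask.mask.shape, -1, dtype=int)
    full[mask.mask] = labels_flat
    rr, cc = np.nonzero(mask.mask)
    sub = full[rr.min() : rr.max() + 1, cc.min() : cc.max() + 1]
    d = cfg.downsample
    H, W = sub.shape
    pattern_map = sub[: H - H % d or H, : W - W % d or W]
    if H >= d and W >= d:
        blocks = pattern_map.reshape(H // d, d, W // d, d)
        # majority label per block (-1 treated as a label)
        pattern_map = np.apply_along_axis(
            lambda v: np.bincount(v + 1).argmax() - 1,
            1,
            blocks.transpose(0, 2, 1, 3).reshape(H // d * (W // d), d * d),
        ).reshape(H // d, W // d)
    return CoatSummary(
        color_clusters=clusters, pattern_class=pattern_class, pattern_map=pattern_map
    )


def export_pattern_map(summary: CoatSummary, png_path, csv_path=None) -> None:
    """Write the pattern map as a PNG label image (labels 0..K-1 mapped to
    their cluster colours, -1 black) and optionally its run-length csv."""
    import csv as _csv

    from PIL import Image

    grid = np.asarray(summary.pattern_map)
    lut = np.zeros((len(summary.color_clusters) + 1, 3), np.uint8)
    for i, (color, _) in enumerate(summary.color_clusters):
        lut[i + 1] = np.clip(np.round(color), 0, 255)
    Image.fromarray(lut[grid + 1]).save(png_path, format="PNG")
    if csv_path is not None:
        with open(csv_path, "w", newline="") as f:
            w = _csv.writer(f)
            w.writerow(["row", "start_col", "length", "label"])
            w.writerows(pattern_rle(grid))


def pattern_rle(pattern_map: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Row-wise run-length encoding of a label grid.

    Returns (row, start_col, length, label) tuples, skipping outside-mask
    runs (label -1).
    """
    out = []
    for r, row in enumerate(np.asarray(pattern_map)):
        c = 0
        n = len(row)
        while c < n:
            lab = row[c]
            c2 = c
            while c2 < n and row[c2] == lab:
                c2 += 1
            if lab != -1:
                out.append((r, c, c2 - c, int(lab)))
            c = c2
    return out
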