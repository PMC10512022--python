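"""Image and table I/O: photographs with EXIF metadata in; phenotype
tables (csv / xlsx / xml) and labelled overlay images out.

EXIF GPS rational triplets are converted to decimal degrees (altitude in
metres) on read and are never fabricated: a file without metadata yields a
record without metadata.  The csv dialect is RFC 4180 with a header row;
xlsx is a single sheet; xml is a flat ``<animals><animal>...`` document
with one child element per field (schema documented in the methods note).
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw, UnidentifiedImageError

from .types import (
    DecodeError,
    GoatMask,
    ImageRecord,
    PhenotypeRecord,
    ValidationError,
    POSES,
)

_GPS_IFD = 0x8825
_EXIF_IFD = 0x8769
_TAG_MODEL = 272
_TAG_DT_ORIG = 36867


def _ratios_to_deg(values) -> float:
    d, m, s = (float(Fraction(v).limit_denominator(10**9)) if not isinstance(v, (int, float)) else float(v) for v in values)
    return d + m / 60.0 + s / 3600.0


def _read_exif(img: Image.Image):
    gps = timestamp = model = None
    try:
        exif = img.getexif()
    except Exception:
        return None, None, None
    if not exif:
        return None, None, None
    model = exif.get(_TAG_MODEL)
    model = str(model) if model else None
    try:
        sub = exif.get_ifd(_EXIF_IFD)
        ts = sub.get(_TAG_DT_ORIG)
        if ts:
            # EXIF "YYYY:MM:DD HH:MM:SS" -> ISO-8601
            ts = str(ts)
            date, _, time = ts.partition(" ")
            timestamp = f"{date.replace(':', '-')}T{time}" if time else date.replace(":", "-")
    except Exception:
        pass
    try:
        g = exif.get_ifd(_GPS_IFD)
        if g and 2 in g and 4 in g:
            lat = _ratios_to_deg(g[2])
            lon = _ratios_to_deg(g[4])
            if str(g.get(1, "N")).upper().startswith("S"):
                lat = -lat
            if str(g.get(3, "E")).upper().startswith("W"):
                lon = -lon
            alt = float(g[6]) if 6 in g else 0.0
            ref = g.get(5, 0)
            if isinstance(ref, bytes):
                ref = ref[0] if ref else 0
            if int(ref or 0) == 1:
                alt = -alt
            gps = (lat, lon, alt)
    except Exception:
        pass
    return gps, timestamp, model


def load_image(path: str | Path, pose: str, sample_id: str) -> ImageRecord:
    """Load a JPEG/PNG photograph into an :class:`ImageRecord`.

    EXIF GPS, timestamp and camera model fields populate the record when
    present in the file and stay absent otherwise.
    """
    if pose not in POSES:
        raise ValidationError(f"unknown pose {pose!r}; expected one of {POSES}")
    path = Path(path)
    try:
        with Image.open(path) as img:
            gps, timestamp, model = _read_exif(img)
            pixels = np.asarray(img.convert("RGB"), dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise DecodeError(f"cannot decode image file {path}: {exc}") from exc
    return ImageRecord(
        pixels=pixels,
        pose=pose,
        sample_id=sample_id,
        gps=gps,
        timestamp=timestamp,
        camera_model=model,
        source_path=str(path),
    )


def save_image(
    record: ImageRecord,
    path: str | Path,
    quality: int = 95,
) -> None:
    """Write a record to disk (format from the extension), embedding its
    GPS/timestamp/camera metadata as EXIF for JPEG output."""
    path = Path(path)
    img = Image.fromarray(record.pixels)
    exif = Image.Exif()
    if record.camera_model:
        exif[_TAG_MODEL] = record.camera_model
    if record.timestamp:
        exif.get_ifd(_EXIF_IFD)[_TAG_DT_ORIG] = record.timestamp.replace("-", ":").replace("T", " ")
    if record.gps is not None:
        lat, lon, alt = record.gps
        g = exif.get_ifd(_GPS_IFD)
        g[1] = "N" if lat >= 0 else "S"
        g[2] = _deg_to_ratios(abs(lat))
        g[3] = "E" if lon >= 0 else "W"
        g[4] = _deg_to_ratios(abs(lon))
        g[5] = 0 if alt >= 0 else 1
        g[6] = abs(float(alt))
    if path.suffix.lower() in (".jpg", ".jpeg"):
        img.save(path, exif=exif, quality=quality)
    else:
        img.save(path, exif=exif)


def _deg_to_ratios(deg: float):
    d = int(deg)
    m_full = (deg - d) * 60.0
    m = int(m_full)
    s = (m_full - m) * 60.0
    return (float(d), float(m), float(s))


# ------------------------------------------------------------- tables

COLUMNS = [
    "sample_id",
    "hw_cm",
    "bl_cm",
    "chest_depth_cm",
    "chest_width_cm",
    "cg_cm",
    "bw_kg",
    "pb_cm",
    "sb_cm",
    "famacha",
    "tooth_pairs",
    "tooth_age_class",
    "coat_pattern",
    "coat_colors",
    "coat_fractions",
    "qc_flags",
    "gps_lat",
    "gps_lon",
    "gps_alt_m",
    "timestamp",
    "camera_model",
]


def records_to_frame(records: Iterable[PhenotypeRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        m = rec.measures
        coat_colors = coat_fracs = None
        if rec.coat is not None:
            coat_colors = "|".join(
                ",".join(f"{v:.1f}" for v in c) for c, _ in rec.coat.color_clusters
            )
            coat_fracs = "|".join(f"{f:.4f}" for _, f in rec.coat.color_clusters)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "hw_cm": m.hw,
                "bl_cm": m.bl,
                "chest_depth_cm": m.chest_depth,
                "chest_width_cm": m.chest_width,
                "cg_cm": m.cg,
                "bw_kg": m.bw,
                "pb_cm": m.pb,
                "sb_cm": m.sb,
                "famacha": rec.famacha,
                "tooth_pairs": rec.tooth_age.permanent_pairs if rec.tooth_age else None,
                "tooth_age_class": rec.tooth_age.age_class if rec.tooth_age else None,
                "coat_pattern": rec.coat.pattern_class if rec.coat else None,
                "coat_colors": coat_colors,
                "coat_fractions": coat_fracs,
                "qc_flags": ";".join(rec.qc_flags) if rec.qc_flags else None,
                "gps_lat": rec.gps[0] if rec.gps else None,
                "gps_lon": rec.gps[1] if rec.gps else None,
                "gps_alt_m": rec.gps[2] if rec.gps else None,
                "timestamp": rec.timestamp,
                "camera_model": rec.camera_model,
            }
        )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_phenotypes(
    records: list[PhenotypeRecord], fmt: str, path: str | Path
) -> Path:
    """Write one row/element per animal; missing optional phenotypes
    serialise as empty cells, never as zero."""
    if not records:
        raise ValidationError("no records to write")
    path = Path(path)
    df = records_to_frame(records)
    if fmt == "csv":
        df.to_csv(path, index=False, lineterminator="\r\n")
    elif fmt == "xlsx":
        df.to_excel(path, index=False, sheet_name="phenotypes")
    elif fmt == "xml":
        root = ET.Element("animals")
        for _, row in df.iterrows():
            el = ET.SubElement(root, "animal")
            for col in COLUMNS:
                child = ET.SubElement(el, col)
                v = row[col]
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    child.text = ""
                else:
                    child.text = f"{v:.6f}".rstrip("0").rstrip(".") if isinstance(v, float) else str(v)
        tree = ET.ElementTree(root)
        ET.indent(tree)
        tree.write(path, encoding="unicode", xml_declaration=True)
    else:
        raise ValidationError(f"unsupported format {fmt!r} (csv, xlsx or xml)")
    return path


def read_phenotypes(path: str | Path, fmt: Optional[str] = None) -> pd.DataFrame:
    """Parse a phenotype table written by :func:`write_phenotypes`."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "xlsx":
        return pd.read_excel(path)
    if fmt == "xml":
        root = ET.parse(path).getroot()
        rows = []
        for el in root.findall("animal"):
            row = {}
            for child in el:
                txt = child.text or ""
                if txt == "":
                    row[child.tag] = None
                else:
                    try:
                        row[child.tag] = float(txt) if child.tag != "sample_id" else txt
                    except ValueError:
                        row[child.tag] = txt
            rows.append(row)
        return pd.DataFrame(rows, columns=COLUMNS)
    raise ValidationError(f"unsupported format {fmt!r}")


def read_manual_measures(path: str | Path) -> pd.DataFrame:
    """Manual (traditional) measure csv: sample_id, HW, BL, CG, PB, SB, BW
    with lengths in cm and weight in kg.  Column names are lower-cased."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample_id" not in df.columns:
        raise ValidationError("manual measure table needs a sample_id column")
    return df


# ---------------------------------------------------------- overlays


def write_labeled_image(
    image: ImageRecord,
    mask: Optional[GoatMask],
    annotations: Optional[dict],
    path: str | Path,
) -> Path:
    """Write a lossless PNG review overlay.

    ``annotations`` may contain ``segments`` (list of ((r0, c0), (r1, c1),
    color) strokes, e.g. the height line from withers to ground) and
    ``quad`` (the calibration quadrilateral).  The overlay is drawn on a
    copy; pixels outside overlay strokes (and the optional mask tint) stay
    identical to the source.
    """
    if mask is not None and mask.mask.shape != image.shape:
        raise ValidationError("mask shape does not match image")
    px = image.pixels.copy()
    if mask is not None:
        tint = np.array([0, 255, 0], dtype=float)
        sel = mask.mask
        px[sel] = np.clip(
            0.5 * px[sel].astype(float) + 0.5 * tint, 0, 255
        ).astype(np.uint8)
    img = Image.fromarray(px)
    draw = ImageDraw.Draw(img)
    ann = annotations or {}
    for (r0, c0), (r1, c1), color in ann.get("segments", []):
        draw.line([(c0, r0), (c1, r1)], fill=tuple(color), width=1)
    quad = ann.get("quad")
    if quad is not None:
        pts = [(float(c), float(r)) for r, c in np.asarray(quad)]
        draw.polygon(pts, outline=(255, 255, 0))
    out = Path(path)
    img.save(out, format="PNG")
    return out
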