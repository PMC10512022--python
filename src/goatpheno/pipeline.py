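"""Per-animal orchestration from a pose manifest.

Only two photographs (the sign view and the rear view) are needed for a
full set of body measures; the eye and teeth close-ups add the health
phenotypes and the "naked" side view adds the coat summary.  Every stage
failure is captured as a coded flag on the record — one bad pose never
sinks the others.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io_formats
from .calibration import SignNotFoundError, calibrate
from .coat import InsufficientCoatError, coat_colors
from .config import PipelineConfig
from .health import RoiNotFoundError, famacha_score, tooth_age
from .morphometry import MeasureError, measure_animal
from .segmentation import NoSubjectError, qc_scene, segment
from .types import (
    BodyMeasures,
    CalibrationResult,
    DecodeError,
    ImageRecord,
    PhenotypeRecord,
    ValidationError,
)

log = logging.getLogger("goatpheno")

MEASURE_POSES = ("sign", "rear")


@dataclass
class AnimalManifest:
    """One animal's pose photographs plus free-text demographics.

    Demographics come from the manifest rather than sign OCR: the field
    protocol records them on paper as well as on the hand-written sign.
    """

    sample_id: str
    paths: dict[str, str]  # pose -> image path
    demographics: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.paths:
            raise ValidationError(f"manifest for {self.sample_id} lists no poses")
        vals = list(self.paths.values())
        if len(set(vals)) != len(vals):
            raise ValidationError(f"duplicate image paths for {self.sample_id}")


def read_manifest(path: str | Path) -> list[AnimalManifest]:
    """Parse the manifest csv (columns: sample_id, pose, path, plus any
    demographic columns), grouping rows by animal."""
    rows = list(csv.DictReader(open(path, newline="")))
    if not rows:
        raise ValidationError(f"empty manifest {path}")
    animals: dict[str, AnimalManifest] = {}
    for row in rows:
        sid = row["sample_id"].strip()
        pose = row["pose"].strip()
        extra = {
            k: v
            for k, v in row.items()
            if k not in ("sample_id", "pose", "path") and v
        }
        if sid not in animals:
            animals[sid] = AnimalManifest(sample_id=sid, paths={pose: row["path"]}, demographics=extra)
        else:
            animals[sid].paths[pose] = row["path"]
            animals[sid].demographics.update(extra)
    return [animals[k] for k in sorted(animals)]


def _load_pose(
    manifest: AnimalManifest, pose: str, flags: list[str]
) -> Optional[ImageRecord]:
    if pose not in manifest.paths:
        flags.append(f"{pose.upper()}_POSE_MISSING")
        return None
    try:
        return io_formats.load_image(manifest.paths[pose], pose, manifest.sample_id)
    except (DecodeError, ValidationError) as exc:
        flags.append(f"{pose.upper()}_POSE_UNREADABLE")
        log.warning("%s: %s", manifest.sample_id, exc)
        return None


def process_animal(
    manifest: AnimalManifest, config: PipelineConfig | None = None
) -> PhenotypeRecord:
    """Run load -> segment -> calibrate -> measure -> health -> coat for the
    available poses.  Missing poses yield absent phenotypes plus a flag;
    single-stage errors become flags, never crashes."""
    cfg = config or PipelineConfig()
    flags: list[str] = []
    record = PhenotypeRecord(sample_id=manifest.sample_id)

    sign_img = _load_pose(manifest, "sign", flags)
    rear_img = _load_pose(manifest, "rear", flags)
    side_img = _load_pose(manifest, "side", flags)
    eye_img = _load_pose(manifest, "eye", flags)
    teeth_img = _load_pose(manifest, "teeth", flags)

    for img in (sign_img, rear_img, side_img):
        if img is not None:
            record.gps = record.gps or img.gps
            record.timestamp = record.timestamp or img.timestamp
            record.camera_model = record.camera_model or img.camera_model

    calibration: Optional[CalibrationResult] = None
    sign_mask = rear_mask = None
    if sign_img is not None:
        try:
            calibration = calibrate(sign_img, cfg.sign)
        except (SignNotFoundError, ValidationError) as exc:
            flags.append("SIGN_NOT_FOUND")
            log.warning("%s: %s", manifest.sample_id, exc)
        try:
            sign_mask = segment(sign_img, cfg)
            flags.extend(sign_mask.flags)
            flags.extend(qc_scene(sign_img, sign_mask, cfg))
        except NoSubjectError:
            flags.append("NO_SUBJECT_SIGN_VIEW")
            sign_mask = None
    if rear_img is not None:
        try:
            rear_mask = segment(rear_img, cfg)
            flags.extend(f"REAR_{f}" for f in qc_scene(rear_img, rear_mask, cfg))
        except NoSubjectError:
            flags.append("NO_SUBJECT_REAR_VIEW")
            rear_mask = None

    if calibration is not None and sign_mask is not None:
        try:
            record.measures = measure_animal(
                sign_mask, rear_mask, calibration.scale, config=cfg.morphometry
            )
            flags.extend(sorted(set(record.measures.flags.values())))
        except (MeasureError, ValidationError) as exc:
            flags.append("MEASURES_FAILED")
            log.warning("%s: measures failed: %s", manifest.sample_id, exc)
    elif sign_img is not None and calibration is None:
        record.measures = BodyMeasures()
    if eye_img is not None:
        try:
            if calibration is None:
                flags.append("FAMACHA_UNCALIBRATED")
            res = famacha_score(eye_img, calibration, cfg.famacha)
            record.famacha = res.category
        except RoiNotFoundError:
            flags.append("CONJUNCTIVA_NOT_FOUND")
    if teeth_img is not None:
        try:
            record.tooth_age = tooth_age(teeth_img, cfg.teeth)
        except RoiNotFoundError:
            flags.append("TEETH_NOT_FOUND")
    if side_img is not None:
        try:
            side_mask = segment(side_img, cfg)
            if calibration is None:
                flags.append("COAT_UNCALIBRATED")
            record.coat = coat_colors(side_img, side_mask, calibration, cfg.coat)
        except (NoSubjectError, InsufficientCoatError, ValidationError):
            flags.append("COAT_NOT_EXTRACTED")

    record.qc_flags = flags
    log.info(
        "%s: measures=%s famacha=%s teeth=%s coat=%s flags=%s",
        manifest.sample_id,
        record.measures.hw is not None,
        record.famacha,
        record.tooth_age.permanent_pairs if record.tooth_age else None,
        record.coat.pattern_class if record.coat else None,
        flags,
    )
    return record


def run_batch(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    fmt: str = "csv",
    labeled_images: bool = False,
) -> dict:
    """Process every animal in the manifest; per-animal failures are logged
    and skipped.  Output ordering is deterministic by sample_id."""
    cfg = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifests = read_manifest(manifest_path)
    records, failed = [], 0
    for man in manifests:
        try:
            rec = process_animal(man, cfg)
            records.append(rec)
            if labeled_images and "sign" in man.paths:
                _write_overlay(man, rec, cfg, out_dir)
        except Exception as exc:  # per-animal isolation
            failed += 1
            log.error("%s: failed: %s", man.sample_id, exc)
    table = None
    if records:
        table = io_formats.write_phenotypes(records, fmt, out_dir / f"phenotypes.{fmt}")
    flagged = sum(1 for r in records if r.qc_flags)
    summary = {
        "processed": len(records),
        "flagged": flagged,
        "failed": failed,
        "table": str(table) if table else None,
    }
    log.info(
        "batch done: %d processed, %d flagged, %d failed",
        summary["processed"], flagged, failed,
    )
    return summary


def _write_overlay(man: AnimalManifest, rec: PhenotypeRecord, cfg, out_dir: Path):
    try:
        img = io_formats.load_image(man.paths["sign"], "sign", man.sample_id)
        mask = segment(img, cfg)
        ann = {}
        try:
            from .calibration import detect_sign

            det = detect_sign(img, cfg.sign)
            ann["quad"] = det.quadrilateral
        except Exception:
            pass
        io_formats.write_labeled_image(img, mask, ann, out_dir / f"{man.sample_id}_sign.png")
    except Exception as exc:
        log.warning("%s: overlay failed: %s", man.sample_id, exc)
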