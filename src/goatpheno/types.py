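"""Domain containers shared across the pipeline.

Coordinate convention used everywhere in this package: 0-based
``(row, column)`` with the origin at the top-left corner and rows
increasing downward; bounding boxes and bands are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: The five protocol poses.  The original protocol's front pose was dropped.
POSES = ("rear", "sign", "side", "eye", "teeth")


class ValidationError(ValueError):
    """Raised when an input violates a precondition."""


class DecodeError(IOError):
    """Raised when an image file cannot be decoded."""


@dataclass
class ImageRecord:
    """A loaded photograph plus pose label and extracted metadata.

    ``gps`` is ``(latitude_deg, longitude_deg, altitude_m)`` in decimal
    degrees / metres; EXIF rational triplets are converted on read and
    never fabricated when absent.
    """

    pixels: np.ndarray  # (H, W, 3) uint8
    pose: str
    sample_id: str
    gps: Optional[tuple[float, float, float]] = None
    timestamp: Optional[str] = None
    camera_model: Optional[str] = None
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] == 0 or px.shape[1] == 0:
            raise ValidationError(
                f"pixels must be a non-empty (H, W, 3) array, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            raise ValidationError(f"pixels must be uint8, got {px.dtype}")
        if self.pose not in POSES:
            raise ValidationError(
                f"unknown pose {self.pose!r}; expected one of {POSES}"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class GoatMask:
    """Binary foreground mask with provenance flags and QC diagnostics."""

    mask: np.ndarray  # (H, W) bool
    component_area: int = 0
    centroid: tuple[float, float] = (0.0, 0.0)
    touches_border: bool = False
    occluder_suspected: bool = False
    blue_coverage: float = 1.0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        self.mask = m
        if self.component_area == 0:
            self.component_area = int(m.sum())
        if self.centroid == (0.0, 0.0) and m.any():
            rr, cc = np.nonzero(m)
            self.centroid = (float(rr.mean()), float(cc.mean()))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class SignDetection:
    """The calibration sign located in an image.

    ``quadrilateral`` holds the four outer corners of the black outline,
    ordered clockwise from top-left, as (row, col) floats.
    """

    quadrilateral: np.ndarray  # (4, 2) float, (row, col)
    border_score: float
    block_colors: dict[str, tuple[float, float, float]]
    skew_deg: float
    low_confidence: bool = False


@dataclass
class CalibrationResult:
    """Centimetres-per-pixel scale plus an affine colour correction."""

    scale: float  # cm per pixel
    color_matrix: np.ndarray  # (3, 3)
    color_offset: np.ndarray  # (3,)
    residual: float  # mean per-channel error on the sign patches
    source_pose: str = "sign"

    def apply(self, rgb: np.ndarray) -> np.ndarray:
        """Colour-correct an (..., 3) array, clamping to [0, 255]."""
        arr = np.asarray(rgb, dtype=float)
        out = arr @ self.color_matrix.T + self.color_offset
        return np.clip(out, 0.0, 255.0)

    @classmethod
    def identity(cls, scale: float = 1.0, source_pose: str = "sign") -> "CalibrationResult":
        return cls(scale, np.eye(3), np.zeros(3), 0.0, source_pose)


@dataclass
class BodyMeasures:
    """Calibrated body measures in centimetres (weight in kg).

    ``pb`` / ``sb`` (pin-bone and shoulder-bone widths) are manual-only
    validation inputs and are never computed digitally.
    """

    hw: Optional[float] = None  # height at withers
    bl: Optional[float] = None  # body length
    chest_depth: Optional[float] = None  # side view
    chest_width: Optional[float] = None  # rear view
    cg: Optional[float] = None  # chest girth (derived)
    bw: Optional[float] = None  # predicted body weight, kg
    pb: Optional[float] = None
    sb: Optional[float] = None
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("hw", "bl", "chest_depth", "chest_width", "cg"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if self.cg is not None and self.chest_depth and self.chest_width:
            bound = np.pi * (self.chest_depth + self.chest_width)
            if self.cg > bound + 1e-9:
                raise ValidationError(
                    f"girth {self.cg:.2f} exceeds perimeter bound {bound:.2f}"
                )


@dataclass
class FamachaResult:
    """FAMACHA conjunctiva score (1 = healthy red, 5 = severely anaemic)."""

    category: int
    measured_color: tuple[float, float, float]
    distance_to_ref: tuple[float, ...]
    confidence: float  # margin between best and second-best distance


@dataclass
class ToothAgeClass:
    """Age class from the number of erupted permanent incisor pairs."""

    permanent_pairs: int
    age_class: str


@dataclass
class CoatSummary:
    """Calibrated coat colour clusters and pattern summary."""

    color_clusters: list[tuple[tuple[float, float, float], float]]  # (RGB, fraction)
    pattern_class: str  # "solid" | "patched"
    pattern_map: np.ndarray  # down-sampled label grid, -1 outside mask


@dataclass
class PhenotypeRecord:
    """One animal's extracted phenotypes plus QC flags and metadata."""

    sample_id: str
    measures: BodyMeasures = field(default_factory=BodyMeasures)
    famacha: Optional[int] = None
    tooth_age: Optional[ToothAgeClass] = None
    coat: Optional[CoatSummary] = None
    qc_flags: list[str] = field(default_factory=list)
    gps: Optional[tuple[float, float, float]] = None
    timestamp: Optional[str] = None
    camera_model: Optional[str] = None

    def __post_init__(self) -> None:
        if self.famacha is not None and not 1 <= int(self.famacha) <= 5:
            raise ValidationError(f"famacha must be in [1, 5], got {self.famacha}")


@dataclass
class SceneParams:
    """Parameters of one synthetic protocol scene.

    Dimensions are centimetres; ``px_per_cm`` is the render resolution at
    the subject plane (camera at >= 3 m, eye level, sign in the goat's
    plane, so one scale is valid for the whole subject).
    """

    hw: float = 60.0
    bl: float = 70.0
    chest_depth: float = 30.0
    chest_width: float = 20.0
    coat_colors: Sequence[tuple[int, int, int]] = ((196, 154, 96),)
    pattern: str = "solid"  # "solid" | "patched"
    patch_fraction: float = 0.4  # target fraction of secondary colours
    pose: str = "sign"
    px_per_cm: float = 10.0
    frame: Optional[tuple[int, int]] = None  # rows, cols; pose default if None
    camera_distance_m: float = 3.0
    defects: frozenset[str] = frozenset()
    handler_blue: bool = False  # handler occluder in blue scrubs vs skin tone
    lighting_gain: float = 1.0  # used when 'lighting_shift' defect active
    sign_skew_deg: float = 10.0  # used when 'skewed_sign' defect active
    seed: int = 0

    KNOWN_DEFECTS = frozenset(
        {
            "handler_occluder",
            "rocks",
            "dirty_tarp",
            "lighting_shift",
            "missing_ground_tarp",
            "skewed_sign",
        }
    )

    def __post_init__(self) -> None:
        for name in ("hw", "bl", "chest_depth", "chest_width", "px_per_cm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.chest_depth > self.hw:
            raise ValidationError("chest_depth cannot exceed height at withers")
        if self.pose not in POSES:
            raise ValidationError(f"unknown pose {self.pose!r}")
        self.defects = frozenset(self.defects)
        unknown = self.defects - self.KNOWN_DEFECTS
        if unknown:
            raise ValidationError(f"unknown defects: {sorted(unknown)}")
        if self.camera_distance_m < 3.0 and not self.defects:
            raise ValidationError("camera distance below protocol minimum of 3 m")
        if not self.coat_colors:
            raise ValidationError("at least one coat colour required")


@dataclass
class SceneGroundTruth:
    """Exact render-time truth used by recovery tests."""

    mask: Optional[np.ndarray] = None  # goat silhouette, bool
    scale: Optional[float] = None  # cm per pixel
    ground_row: Optional[int] = None
    withers: Optional[tuple[int, int]] = None  # (row, col)
    shoulder: Optional[tuple[int, int]] = None
    pin: Optional[tuple[int, int]] = None
    sign_quad: Optional[np.ndarray] = None  # (4, 2) row, col clockwise from TL
    measures: Optional[BodyMeasures] = None
    coat_fractions: Optional[list[float]] = None
    famacha_category: Optional[int] = None
    conjunctiva_mask: Optional[np.ndarray] = None
    permanent_pairs: Optional[int] = None
    defects: list[str] = field(default_factory=list)
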