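"""Pipeline configuration with field-protocol defaults.

All thresholds that the protocol leaves unquantified (size priors,
centring tolerance, blue band) are exposed here rather than hard-coded.
Configs load from YAML mappings whose keys mirror the dataclass fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import yaml


@dataclass
class BlueKeyConfig:
    """Chroma-key band for the blue backdrop/tarp, in HSV.

    Hue in degrees; classification is hue-based so it tolerates the
    brightness shifts common in field images.
    """

    hue_lo_deg: float = 190.0
    hue_hi_deg: float = 250.0
    sat_min: float = 0.25
    val_min: float = 0.15


@dataclass
class RoiPriorConfig:
    """Subject-isolation priors: the goat has a limited range of size and
    stands near the frame centre."""

    min_area_frac: float = 0.02
    max_area_frac: float = 0.40
    max_centroid_offset_frac: float = 0.25  # fraction of the frame diagonal


@dataclass
class SignConfig:
    """Calibration sign geometry and reference colours.

    The physical dimensions refer to the outer edge of the black outline.
    Block references default to the nominal "pure" primaries; measured
    values from a real card should override them.
    """

    width_cm: float = 40.0
    height_cm: float = 30.0
    border_cm: float = 2.0
    reference_border: tuple[int, int, int] = (0, 0, 0)
    reference_red: tuple[int, int, int] = (255, 0, 0)
    reference_green: tuple[int, int, int] = (0, 255, 0)
    reference_blue: tuple[int, int, int] = (0, 0, 255)
    dark_value_max: int = 80  # max(R,G,B) below this counts as outline-black
    min_border_score: float = 0.7
    low_confidence_score: float = 0.5


@dataclass
class MorphometryConfig:
    """Fractional landmark bands (the protocol abandoned physical bone
    marking, so landmarks are located by silhouette geometry alone)."""

    withers_band: tuple[float, float] = (0.20, 0.45)  # of body span, from front
    chest_band: tuple[float, float] = (0.45, 0.75)  # of body height, above ground
    rear_barrel_band: tuple[float, float] = (0.20, 0.70)  # of mask height, from top
    depth_band_rel: tuple[float, float] = (0.02, 0.10)  # of span, behind foreleg
    leg_band_frac: float = 0.25  # bottom fraction of mask holding the legs
    leg_max_width_frac: float = 0.20  # of mask width; wider blobs are not legs
    ground_tol_px: int = 5
    weight_formula: str = "girth2_length"
    weight_k: float = 10838.0  # BW(kg) = CG^2 * BL / k, all cm


@dataclass
class FamachaConfig:
    """FAMACHA references (1 = healthy red .. 5 = pale) and the red-pink
    chromaticity band used to locate the conjunctiva."""

    references: tuple[tuple[int, int, int], ...] = (
        (190, 35, 45),
        (205, 75, 80),
        (220, 115, 120),
        (235, 160, 165),
        (245, 205, 208),
    )
    red_min: int = 120
    red_minus_green_min: int = 30
    red_minus_blue_min: int = 25
    min_roi_px: int = 200


@dataclass
class ToothConfig:
    """Tooth segmentation band and the pairs -> age-class mapping."""

    brightness_min: int = 170  # min channel value for tooth-coloured pixels
    area_ratio: float = 0.5  # permanent if area >= ratio * largest tooth
    min_area_frac: float = 0.004  # and >= this fraction of the frame
    age_mapping: dict[int, str] = field(
        default_factory=lambda: {
            0: "<1 yr",
            1: "1-2 yr",
            2: "2-3 yr",
            3: "3-4 yr",
            4: ">=4 yr",
        }
    )


@dataclass
class CoatConfig:
    k: int = 3
    merge_fraction: float = 0.05
    solid_fraction: float = 0.90
    downsample: int = 8
    min_area_px: int = 1000
    n_restarts: int = 10
    seed: int = 0


@dataclass
class QcConfig:
    blue_coverage_min: float = 0.80
    near_object_dist_px: int = 80
    near_object_min_px: int = 500


@dataclass
class PipelineConfig:
    blue: BlueKeyConfig = field(default_factory=BlueKeyConfig)
    roi: RoiPriorConfig = field(default_factory=RoiPriorConfig)
    sign: SignConfig = field(default_factory=SignConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    famacha: FamachaConfig = field(default_factory=FamachaConfig)
    teeth: ToothConfig = field(default_factory=ToothConfig)
    coat: CoatConfig = field(default_factory=CoatConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    refine_window_px: int = 5

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {
            "blue": BlueKeyConfig,
            "roi": RoiPriorConfig,
            "sign": SignConfig,
            "morphometry": MorphometryConfig,
            "famacha": FamachaConfig,
            "teeth": ToothConfig,
            "coat": CoatConfig,
            "qc": QcConfig,
        }
        kwargs = {}
        for name, klass in sections.items():
            sub = dict(data.get(name, {}))
            for k, v in list(sub.items()):
                if isinstance(v, list):
                    sub[k] = _to_tuple(v)
                if k == "age_mapping" and isinstance(v, dict):
                    sub[k] = {int(p): str(lbl) for p, lbl in v.items()}
            kwargs[name] = klass(**sub)
        if "refine_window_px" in data:
            kwargs["refine_window_px"] = int(data["refine_window_px"])
        return cls(**kwargs)


def _to_tuple(v):
    return tuple(_to_tuple(x) if isinstance(x, list) else x for x in v)


def synthetic_cohort_config() -> PipelineConfig:
    """Configuration matched to the synthetic-scene generator.

    The sign is 24x16 cm so it fits between topline and belly underline on
    the smallest-chested animals, and block references sit at 180 rather
    than 255 so lighting gains up to 1.3 do not saturate the primaries.
    """

    cfg = PipelineConfig()
    cfg.sign = SignConfig(
        width_cm=24.0,
        height_cm=16.0,
        border_cm=1.6,
        reference_red=(180, 0, 0),
        reference_green=(0, 180, 0),
        reference_blue=(0, 0, 180),
    )
    return cfg
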