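# goatpheno

Digital goat phenotypes from posed field photographs.

Community-scale goat improvement programmes need body measures, anaemia
scores and coat descriptions from thousands of animals, collected by
teams with cameras rather than specialists with measuring sticks.  A
field image-collection protocol makes that possible: each animal is
photographed against a blue backdrop and blue ground tarp — rear view,
right-side view wearing a black-bordered calibration sign, an unobscured
("naked") side view, and eye and teeth close-ups — from at least 3 m at
eye level.  `goatpheno` turns those photographs into calibrated
phenotypes:

- **Segmentation** — chroma-key the blue surround in HSV (goats have no
  blue), pick the goat by its size and centring priors, then refine the
  boundary by snapping every contour point to the strongest directional
  colour edge (structure-tensor energy `nᵀJn` along the local normal).
- **Calibration** — find the sign's black outline, fit its minimum
  rotated rectangle, and derive the cm-per-pixel scale from the sign's
  physical size; the "pure" red/green/blue blocks plus the black border
  give an affine RGB correction that makes colours comparable across
  lighting.
- **Morphometry** — height at withers (HW), body length (BL, point of
  shoulder to pin bone) and chest depth from the sign view; chest width
  from the rear view; chest girth (CG) from an elliptical cross-section
  via Ramanujan's second approximation,
  `CG ≈ π(a+b)(1 + 3h/(10+√(4−3h)))`, `h = ((a−b)/(a+b))²` with
  semi-axes a = depth/2, b = width/2.  A pluggable tape formula
  (default `BW = CG²·BL/k`) predicts body weight.
- **Health** — FAMACHA anaemia category (1 healthy red … 5 pale) by
  nearest-reference matching of the corrected conjunctiva colour in
  CIELAB; tooth age from the count of erupted permanent incisor pairs.
- **Coat** — corrected-colour k-means clusters with pixel fractions, a
  solid/patched call and a down-sampled pattern map from the naked side
  view.
- **Synthetic scenes** — a first-class generator renders
  protocol-compliant goats (parametric silhouette, sign in the body
  plane, blue surround) with exact ground truth, plus the field defects
  that plagued real collections (handler limbs, rocks over the feet,
  dirty tarp, lighting shifts, skewed sign).  Every stage is tested
  against it.

## Worked example

```python
import dataclasses
from goatpheno.config import synthetic_cohort_config
from goatpheno.synth import generate_scene, sample_cohort_params
from goatpheno.segmentation import segment
from goatpheno.calibration import calibrate
from goatpheno.morphometry import measure_animal

cfg = synthetic_cohort_config()
params = sample_cohort_params(1, seed=42)[0]   # HW 78.70, BL 71.94 cm
sign_img, truth = generate_scene(params, cfg.sign)
mask = segment(sign_img, cfg)
cal = calibrate(sign_img, cfg.sign)            # 0.10003 cm/px (true 0.1)
rear_img, _ = generate_scene(dataclasses.replace(params, pose="rear", frame=None), cfg.sign)
m = measure_animal(mask, segment(rear_img, cfg), cal.scale, config=cfg.morphometry)
print(m.hw, m.bl, m.cg, m.bw)
```

prints `78.72 71.82 102.60 69.77`: height and length recovered within
0.15 % of the rendered animal, a 102.6 cm girth from the elliptical
combination of 39.8 cm chest depth and 24.6 cm rear width, and a 69.8 kg
tape-formula weight estimate.

For photographs on disk, the CLI drives the same pipeline from a pose
manifest (`sample_id,pose,path,...` csv):

```
goatpheno process --manifest m.csv --out results/ --format csv --labeled-images
goatpheno synth --n 10 --seed 1 --out scenes/        # synthetic scenes + truth
goatpheno validate --digital d.csv --manual m.csv --out r.csv
```

`process` writes one row per animal (csv/xlsx/xml), review overlays, and
QC flags (`LOW_BLUE_COVERAGE`, `FEET_NOT_ON_GROUND_LINE`, …) wherever a
scene violated the protocol.

## Layout

```
src/goatpheno/
  types.py          # ImageRecord, GoatMask, BodyMeasures, ... containers
  config.py         # every protocol threshold, YAML-loadable
  synth.py          # synthetic scene generator + ground truth
  segmentation.py   # chroma key, ROI priors, edge refinement, QC
  calibration.py    # sign detection, spatial scale, colour transform
  morphometry.py    # HW / BL / chest / girth / weight / validation
  health.py         # FAMACHA and tooth age
  coat.py           # coat colour clusters and pattern map
  io_formats.py     # images + EXIF, csv/xlsx/xml tables, overlays
  pipeline.py       # per-animal orchestration from a manifest
  benchmark.py      # synthetic-cohort recovery benchmark
  cli.py            # process / synth / validate commands
```

See `docs/methods.md` for the models, parameter choices and known
limitations.
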