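# Methods

## The measurement model

The field protocol fixes the geometry that makes single-image metrology
sound: the camera stands at least 3 m away at the animal's eye level, the
calibration sign is worn flat against the right side of the body, and the
animal stands on a ground tarp in the frame centre.  Under those
conditions perspective foreshortening across the subject plane is
negligible, so one centimetres-per-pixel scale — physical sign size
divided by detected sign size — applies to the whole silhouette, and all
body measures reduce to pixel geometry on a binary mask.

Processing per animal is a pure pipeline: load → chroma-key segment →
refine boundary → detect sign → scale + colour transform → landmark
bands → measures → health and coat phenotypes.  No stage mutates
another's inputs; every stage failure degrades to a coded QC flag on the
output record.

## Chroma-key segmentation

Background classification runs in HSV: a pixel is background iff its hue
lies in the blue band (default 190°–250°) with saturation ≥ 0.25 and
value ≥ 0.15.  Hue is invariant to uniform lighting gain, which is the
dominant field disturbance; the saturation and value floors keep dark
shadows and grey rocks out of the background class.  Subject selection
applies the protocol's two priors as configurable numbers: component
area within 2–40 % of the frame and centroid within 25 % of the frame
diagonal from centre.  Ties on area break toward the centred component,
then toward the topmost-leftmost bounding box.  Holes that are connected
to the outer background (the gap between the legs) survive; interior
holes (the sign's blue block reading as "background" inside the body)
are filled.

## Boundary refinement

The refinement stage walks the mask contour in order and moves each
point along its outward normal to the strongest colour edge within a
±5 px window.  The edge response is the directional energy `nᵀJn` of the
colour structure tensor `J = Σ_c ∇I_c ∇I_cᵀ` (Gaussian σ = 1), sampled
at quarter-pixel steps; using directional energy rather than gradient
magnitude stops points near corners from locking onto the perpendicular
edge.  On an ideal step edge the response has a flat two-sample plateau
whose midpoint is the sub-pixel boundary, so the snap takes the plateau
midpoint (tolerance 2 % of the maximum) and falls back to parabolic
interpolation when the maximum is unique.

Three classes of contour points carry no usable evidence and have their
displacement interpolated from reliable neighbours along the contour:
points with negligible response, points whose response plateau is wider
than 1.25 px (oblique grazing), and corner points, identified by more
than 60° of signed turning accumulated over a five-point window (the
alternating ±45° turns of a rasterised diagonal cancel and are *not*
corners).  Corner runs are then reconstructed as the intersection of
total-least-squares lines fitted to the snapped segments on either side,
skipping the two nearest (still contaminated) points — a snapped
boundary can only reach a sharp corner by extending its adjacent edges.

Band re-classification tests pixel centres against the snapped closed
polygon (point-in-polygon, XOR across contours), touching only pixels
within window + 1 of the current boundary, which enforces the movement
bound by construction.  If the result is no longer a single component
the stage returns the unrefined mask with a `REFINE_FALLBACK` flag.  On
scenes whose silhouette edges are ideal colour steps this refinement is
pixel-exact, including recovery from a 3 px dilation or erosion; at
concave junctions between near-parallel offset edges (where no line
intersection exists) residual errors of a few pixels remain.

## Sign calibration

Candidate signs are dark connected components (max channel < 80) whose
filled area is at least twice their own — a border ring encloses a hole
several times its area, while a solid dark blob (a black goat) does not.
The filled component's minimum rotated rectangle, expanded half a pixel
to the physical pixel footprint, is accepted when ≥ 70 % of its outline
samples are dark and its interior shows the three dominance-classified
colour blocks in red–green–blue order along the top edge (scores in
[0.5, 0.7) return with a low-confidence flag).  Scale averages the
width- and height-based estimates along the rectangle edges, which makes
it invariant to in-plane rotation.

The colour correction is affine (3×3 matrix + offset) fitted by least
squares from the four measured sign colours (border black + three
blocks) to their configured references.  With four reference colours the
system is exactly determined; higher-order models would overfit.
Corrected values clamp to [0, 255].  Because the protocol mounts the
large sign only on the side harness, the rear view normally has no sign;
its measures reuse the sign-view scale silently (same camera distance),
and a flag is raised only when the sign view itself yields no sign.

## Morphometry

Landmarks come from fixed fractional bands on the silhouette (the field
protocol abandoned physical bone marking), all config-exposed:

- **Ground row**: median of the two lowest leg extremes, where legs are
  narrow (< 20 % of mask width) column runs reaching the lowest mask
  rows; robust to one lifted foot, and fails loudly ("legs not
  resolved") when rocks merge the feet into one wide blob.
- **Shoulder and pin**: foremost and rearmost mask pixels within the
  chest-height band, 45–75 % of body height above ground.  The animal
  faces right by protocol; a topline check (the rump end sits lower than
  the head end) mirrors masks that face left.
- **Withers**: topline maximum within the front 20–45 % of the
  shoulder-to-pin span — the head, ahead of the shoulder, never enters
  the band.  HW = (ground − withers row) × scale.
- **Chest depth**: median vertical extent over the column band 2–10 % of
  the span behind the foreleg's rear edge ("just behind the elbows");
  **chest width**: maximal horizontal extent within 20–70 % of the rear
  mask's height.
- **Girth**: perimeter of the ellipse with axes (depth, width) by
  Ramanujan's second approximation, below 0.1 % error for the axis
  ratios goats present (tested against arc-length quadrature up to ratio
  3).  The elliptical cross-section is this package's model for
  combining the two views; it also supplies the sanity bound
  CG ≤ π(depth + width).
- **Weight**: pluggable formula, default the conventional smallstock
  tape estimate BW = CG²·BL/k with k = 10838 (cm³ → kg), recorded with
  its name; it is a convenience output, not a validated model.

Validation against manual measures is a per-measure Pearson correlation
over paired complete cases with n reported; zero-variance inputs yield
an undefined r rather than a number.

## FAMACHA, teeth, coat

The conjunctiva ROI is the largest connected region inside a red-pink
chromaticity band (R ≥ 120, R−G ≥ 30, R−B ≥ 25) after colour
correction; its mean colour is matched to the nearest of five reference
shades in CIELAB (Euclidean).  Exact ties go to the higher, more anaemic
category — the clinically conservative direction.  The reference ramp
shipped here is a documented pale-to-red gradient, not a scan of the
physical card; real deployments should measure their card and override
the config, which the generator shares, keeping simulation and scoring
self-consistent.

Teeth are bright low-chroma regions (min channel ≥ 170); a region is a
permanent incisor when its area reaches both 50 % of the largest tooth
and 0.4 % of the frame (the absolute floor handles the all-deciduous
mouth, where every tooth is "as large as the largest").  Half the count,
clamped to [0, 4] pairs, maps through a configurable age table.

Coat pixels (corrected) are clustered with k-means (K ≤ 3, 10 restarts,
fixed seed); clusters under 5 % fold into their nearest neighbour to
suppress shadow slivers; the coat is solid when the top cluster holds
≥ 90 %.  The "vectorised" pattern is the cluster-label grid
down-sampled 8× by block majority, exportable as run-length csv.

## The synthetic scene generator

The generator renders the study conditions, not photorealism: a 2-D
parametric silhouette (flat-bellied barrel with shaped topline, vertical
shoulder and pin faces, four legs as two near-leg rectangles, neck and
head carried just below the withers, facing right) on a blue backdrop
and tarp, at 0.1 cm/px in 1100×1400 (side) / 1000×1000 (rear) frames —
sized so the largest protocol-plausible animals (HW 90 cm) fit with
margins.  The sign renders as a white face, black outline and three
colour blocks inside the body silhouette, above the belly underline and
below the topline; the generator refuses geometries where it cannot fit.
Renders are hard-edged and noise-free so that recovery tests measure
algorithmic error; lighting gain, dirt, rocks, handler limbs (skin-tone
or chroma-key-invisible blue scrubs), a missing tarp and a skewed sign
are injected as explicit defects with a recorded inventory.

Cohorts draw HW ~ U(40, 90) cm, BL ~ U(50, 100) cm and chest width ~
U(12, 30) cm independently; chest depth follows conformation as
U(0.42, 0.52)·HW clipped to [20, 40] cm, because an independent draw can
produce animals whose chest reaches nearly to the ground — no real goat,
and no leg-based ground detection, survives that.  Coats come from a
tan/brown/black/white palette, solid or two-tone patched.  The synthetic
cohort config uses a 24×16 cm sign (the 40×30 cm field default cannot
fit between topline and belly on a 20 cm chest) and block references at
180 rather than 255 so lighting gains up to 1.3 do not saturate the
primaries.

What passing synthetic tests shows — and what it does not: the pipeline
recovers exactly what the geometry encodes, under the defects modelled.
Real photographs add fur texture, soft shadows, lens distortion, motion
blur and anatomical variation the silhouette model does not represent;
the field correlations used as lower bounds were measured on real
animals, and clean-scene recovery exceeding them demonstrates the
implementation, not field performance.

## Output formats

Tables write as RFC 4180 csv (CRLF records, header row), single-sheet
xlsx, or flat xml of the form

```xml
<animals>
  <animal>
    <sample_id>G001</sample_id>
    <hw_cm>61.2</hw_cm>
    ...
    <camera_model/>
  </animal>
</animals>
```

with one child element per column and empty elements (never zero) for
missing values.  Overlay PNGs are lossless, drawn on a copy, and leave
every pixel outside the strokes and mask tint untouched.  EXIF GPS
rationals convert to decimal degrees and metres on read and are never
fabricated.

## Numerical and degenerate-input choices

Bounding boxes are half-open, coordinates 0-based (row, col), origin
top-left.  The plateau tolerance (2 %), corner-turn threshold (60° over
5 points), reliability floor and all landmark bands are constants chosen
once from the geometry arguments above and exposed in config.  Problem
sizes in the shipped tests — a 200-animal cohort for correlations, 100+
scenes for mask accuracy, 50 for calibration, 250 eyes, 30 scenes per
QC defect — are the package's benchmark conditions.  Degenerate inputs
(empty masks, 0-byte files, rank-deficient sign colours, all-deciduous
mouths, zero-variance validation columns) raise typed errors or return
explicit undefined results; the batch pipeline converts them to flags.

## Known limitations

- No lens-distortion correction; the protocol's ≥ 3 m distance keeps it
  small but wide-angle phone lenses at shorter range would bias scale.
- Width and depth come from different photographs; a goat that moves
  between poses adds girth error the ellipse model cannot see.
- FAMACHA references are config, not the licensed card; absolute
  category boundaries are only as good as the measured references.
- The silhouette landmark bands assume a standing, roughly level,
  right-facing animal; sitting or grazing postures are out of scope and
  surface as QC failures rather than wrong numbers.
- Multi-animal frames and learned segmentation are out of scope.
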