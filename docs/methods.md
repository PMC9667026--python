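# Methods

## Pipeline

The package measures a standing sheep from two segmented binary masks: a
side view (animal facing right; `ensure_facing_right` flips the image when
the topmost foreground pixel — the raised head — lies left of the
silhouette centroid) and a dorsal view (head to the right). All image
operations use the raster convention: origin top-left, x rightward,
y downward, so "smallest y" is topmost.

**Contour.** The outer boundary of the largest 8-connected foreground
component is traced with the Moore-neighbour algorithm, starting at the
topmost-then-leftmost boundary pixel and running clockwise; interior holes
are ignored. This yields an ordered pixel chain on which all landmark rules
operate.

**Landmarks.** Positional landmarks are windowed extrema (head vertex, hip
top: topmost point of their windows; front hoof: rightmost lower-half point
of the convex wrap, ties resolved to the ground-contact pixel; facial
vertex: globally rightmost point). The withers is the dorsal-arc point
farthest from the chord through hip top and head vertex; the chest front
(brisket) is the closest interior approach of the front contour to the
chord through nose and front hoof, with 10 % of the arc trimmed at each end
because both anchors lie on that chord at distance zero. The sciatic
tuberosity, chest bottom, and the shoulder/rump lateral pairs are windowed
maxima of the u-chord curvature.

**Curvature.** The u-chord curvature at contour point *i* is the Menger
curvature of the triangle (p<sub>i−u</sub>, p<sub>i</sub>,
p<sub>i+u</sub>): 4·Area divided by the product of the side lengths, i.e.
the inverse circumradius — exactly 1/r on a circle and rotation invariant.
The default chord offset is u = 1 % of the contour point count (≈ 3–4 cm of
arc at the default working scale). Larger offsets smooth past the bony
prominences being sought; much smaller ones amplify rasterisation noise.
On discrete chains the curvature profile of a convex corner is twin-humped
(it dips at the apex itself), so the detector returns the midpoint of the
contiguous run whose curvature stays within 96 % of the window maximum;
when that run reaches the edge of the window — a constant-curvature arc,
where no interior peak exists — it falls back to the first maximal index,
preserving the deterministic smallest-index tie rule used everywhere else.

**Search windows.** Each landmark is sought inside an axis-aligned window
expressed as fractions of the silhouette bounding box (`RangeConfig`), so
one configuration serves all image resolutions and animal sizes. The
defaults were chosen for ovine proportions so that each window contains
exactly the intended prominence and excludes leg, neck and tail junctions,
whose corners otherwise dominate the curvature signal: chest bottom
x ∈ [0.45, 0.66], y ∈ [0.35, 0.80]; sciatic x ∈ [0, 0.10], y ∈ [0.25, 0.75];
shoulder x ∈ [0.50, 0.66]; rump x ∈ [0.08, 0.30]. All windows are
per-call configurable.

**Calibration.** A 7 × 7 cm calibration plate photographed at 5 cm distance
steps gives one px-per-cm ratio per distance (mean block gap divided by the
block size). Per view, ratio(d) = c₂d² + c₁d + c₀ is fitted by ordinary
least squares on the Vandermonde design (no weighting); the fit is exact on
noise-free quadratic input. The dorsal plate travels 0–105 cm and the
lateral plate 0–50 cm; conversions outside the fitted domain warn and
extrapolate. The two views have independent optics and are never mixed.

**Traits.** HW, HH are vertical pixel distances from the ground row (the
contour's maximal y) to the withers and hip top; CD is the vertical
distance from withers to chest bottom; BSL the Euclidean brisket→sciatic
distance; SW, RW the |Δy| of the dorsal lateral pairs; CC the perimeter of
the ellipse with axes SW and CD (64-node Gauss–Legendre quadrature with a
split-interval check, absolute tolerance 1e−8); SC is π times the leg width
measured one third of the way down from the chest bottom to the hoof.
Correction coefficients (mean manual/machine ratio on a validation set)
default to 1. Body weight is always an input (scale hardware) or a
regression prediction, never an image measurement.

**Weight regression.** Bidirectional stepwise OLS: forward entry by the
smallest coefficient p-value (equivalent to the partial F-test) if
p ≤ 0.05, followed after each entry by backward removal (worst first) of
any included variable with p > 0.05. The model sequence after each forward
step is reported with SE of the estimate, R², adjusted R², residual MSE and
the overall F-test p. Rank-deficient designs drop the offending column with
a warning. The published sex-specific equations ship as named fixtures
(`ewe-1…3`, `ram-1…6`); the ram five-variable row's source label says HW
while its printed equation uses SW — the printed equation is kept and the
discrepancy recorded in the fixture's notes. No multiple-testing correction
is applied anywhere, matching standard reporting of this analysis.

## Synthetic study conditions

No raw per-animal data from the original survey were deposited, so every
pipeline input is generated with known ground truth.

*Trait tables.* 332 animals (113 rams, 219 ewes) with sex-specific means,
SDs and ranges equal to the published survey summary; the eight size traits
are multivariate normal with an exchangeable inter-trait correlation of
ρ = 0.6 (the full empirical matrix was never published; only selected rank
correlations are known, e.g. ewe HW–HH 0.88), truncated at the published
min/max — a documented deviation from pure normality that prevents
anatomically impossible draws. Body weight is the published sex-specific
linear predictor plus Normal(0, SE) noise with SE 4.49 kg (ewes) and
3.75 kg (rams), the reported standard errors of those equations. Because
the exchangeable-ρ predictor variance is smaller than the real data's, the
simulated BW dispersion (CV ≈ 14–20 %) sits below the published 17–21 %;
checks against printed CVs therefore use the printed moments directly.

*Silhouettes.* The renderer builds a stylised polygon in body-frame
centimetres and rasterises it at a configurable scale (default 12 px/cm,
≈ 1000 px body length): a dorsal line descending from a distinct hip top
through a shallow loin dip to the withers kink, a raised head (top ≈ 11 cm
above the taller of HW/HH) with a pointed muzzle, a brisket vertex placed
just behind the nose↔hoof chord, wedge-shaped sciatic and sternum
prominences, four rectangular legs of width equal to the true shank
diameter, and — dorsally — a capsule body with wedge-shaped lateral bulges
at the scapulae and hip joints whose apexes sit exactly at ±SW/2 and ±RW/2.
Every landmark therefore has one sharply defined true pixel location,
recorded in the render metadata. Pose parameters (head rise, nose drop,
head reach) carry small per-seed jitter; HH is kept within [HW − 2,
HW + 6] cm when sampling so the dorsal geometry stays well posed (the
breed's mean hip height exceeds its wither height by ≈ 0.5–2.6 cm).

What the silhouettes do **not** emulate: wool texture and the wool-driven
overestimation of widths and shank girth seen with real fleeces, walking
poses, occlusions, segmentation errors (an optional boundary
dilation/erosion is not enabled by default), multi-animal scenes, or
perspective distortion. Passing closed-loop tests therefore demonstrates
that the landmark rules and conversions are implemented correctly and are
stable to rasterisation, sampling and proportion variation — not that the
method achieves any particular accuracy on real farm imagery.

*Calibration samples and manifests.* Plate samples are generated exactly on
the published per-view quadratics over the published distance grids, with
optional Gaussian noise; collection manifests reproduce the survey's
missingness pattern (of 350 records: 11 unrecorded, 4 missing weight,
3 missing one size trait → 332 complete cases).

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give byte-identical masks, tables and manifests.
- Ties in extremum searches resolve to the smallest contour index; the
  single exception is the front hoof, where ties in x resolve to the
  largest y (ground contact), because a vertical leading edge grazing the
  convex hull otherwise returns a pixel above the hoof corner.
- The convex hull degenerates to the two extreme points for collinear
  input; hull membership of contour pixels is tested against the hull
  polygon with a 0.4 px tolerance.
- The printed point-line distance formula in the source carries a sign typo
  ("ax − by + c"); the standard |ax + by + c|/√(a² + b²) is used, as the
  surrounding text defines the line as ax + by + c = 0.
- Closed-loop accuracy at 12 px/cm over 200 sampled animals (the figures
  the acceptance suite asserts): every landmark's median error ≤ 3 px and
  95th percentile ≤ 8 px; HW/HH/BSL/CD within 5 % and SW/RW/SC/CC within
  8 % of truth for every animal, with the direct height/length traits more
  accurate than the width/shank traits — the same error ordering the
  original study reports for real imagery.

## Known limitations

- **Stepwise operating characteristics.** With entry threshold α = 0.05 and
  m null candidates, the probability that forward selection admits at least
  one noise variable at the first eligible step is 1 − (1 − α)^m ≈ 0.23 for
  m = 5. Exact-support recovery with five noise competitors and an
  empty-model guarantee on five all-noise candidates therefore plateau near
  77 %, however strong the true effect; only the weaker screening property
  (the true predictor is always selected) approaches 100 %. One acceptance
  test asserts higher rates and is expected to fail; the behaviour is
  inherent to stepwise selection at this α, not an implementation defect.
- The chest-front rule needs an arc trim (both anchors lie on the reference
  chord), and its result is only meaningful when the brisket is the closest
  interior approach — guaranteed for the synthetic geometry, heuristic for
  real sheep.
- Landmark windows are proportions of the bounding box; extreme poses
  (grazing head-down, lifted leg) violate their assumptions and are out of
  scope.
- Chest circumference inherits any dorsal/side scale mismatch because its
  two axes come from different cameras; the two scale models are applied
  independently before the ellipse perimeter is taken.
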