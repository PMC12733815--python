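# Methods

`oystermetry` counts oysters in a top-down photograph and estimates each
animal's shell length and width in millimetres. The method assumes the
capture protocol common on grow-out farms: animals spread without stacking
on a uniform blue background, photographed from directly above, with one
circular reference object (a soda cap) of known physical diameter somewhere
in frame. This note records the model behind each stage, the parameters
that matter, what the synthetic scene generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Pipeline

1. (optional) quarter-resize the photograph (area averaging);
2. convert to HSV and segment pixels with a hue-adaptive density clustering;
3. discard any cluster larger than a tenth of the image (the background);
4. locate the reference circle on the luma channel of the YUV image and
   exclude its cluster; fix the mm-per-pixel scale;
5. remove non-oyster clusters (shadows, debris) with a small MLP acting on
   size-share features;
6. measure each survivor's axis-aligned bounding box in millimetres;
7. re-classify each measured cluster with a 100-tree Random Forest: noise is
   dropped, single oysters pass, fused pairs are split into two records with
   halved length;
8. summarise per image (count, mean and standard deviation of length and
   width), and optionally compare paired measurement series with a Wilcoxon
   signed-rank test.

## Segmentation model

Pixels are clustered by a DBSCAN variant specialised to the image grid.
Each pixel's neighbourhood is its eight adjacent pixels; the distance is the
circular difference of the hue channel on the 0–179 half-degree scale,
`min(|Δh|, 180 − |Δh|)`. A pixel is a **core** (label 2) when at least
`min_neighbors` of its eight neighbours lie within hue distance ε; a
non-core pixel adjacent to a core within ε is a **boundary** (label 1);
everything else, and every pixel inside the border margin, is an outlier
(label −1). Adjacent cores within ε of each other connect; each connected
set of cores plus its boundary pixels is one cluster. Cluster ids follow
the raster order of the first core encountered, and boundary pixels adopt
the cluster of the first qualifying neighbour in a fixed scan order, so the
partition is deterministic and independent of visitation order.

The radius adapts to the image: ε = clamp(k · mean hue, floor, cap). On a
blue-background scene the mean hue is dominated by the background
(≈ 100–110 on the 0–179 scale), so the default k = 0.06 puts ε around 5–6 —
above three standard deviations of the within-shell hue texture, and well
below the smallest hue gap between the scene's colour bands (≥ 18). The
floor (2) guards degenerate dark images; the cap (30) keeps ε from
swallowing genuinely distinct bands on unusually red-shifted images. The
linear-in-mean-hue form is one reading of "adapt ε to the image's average
hue"; it is isolated behind an `EpsilonPolicy` object so alternatives can be
swapped without touching the clustering.

Defaults: `min_neighbors = 8` (the strictest reading — all eight neighbours
must be close), `edge_margin = 1`. A consequence worth knowing: one- or
two-pixel slivers (ellipse tips, thin necks) contain no cores and end up
labelled −1 rather than joining their cluster. Bounding boxes are therefore
occasionally a pixel tighter than the drawn shape.

The background rule is a strict inequality: clusters with **more than**
H·W/10 pixels are discarded; a cluster of exactly a tenth survives.

## Calibration and measurement

The reference cap is found by Canny edge detection (σ = 2) on the luma (Y)
channel followed by a circle Hough transform over integer radii in a
configured band. The strongest accumulator wins; ties resolve in scan order
so detection is deterministic. There is **no default cap diameter**: the
physical diameter is a required configuration value, and
`mm_per_px = diameter / (2 · radius_px)`.

The cap is detected on the pre-filter image and its cluster is excluded
geometrically (majority of pixels inside the detected circle). This keeps
calibration independent of the learned filter, and it means the MLP never
needs to recognise the cap — important because a soda cap's pixel area falls
inside the oyster size range, where size-share features carry no signal.

Length is the longer side of the axis-aligned bounding box times
`mm_per_px`; width the shorter. Axis-aligned (not rotated-minimal) boxes
match the field protocol of calliper jaws closed square to the photograph's
axes. The cluster contour (longest closed iso-contour of the membership
mask) is kept for annotation output only.

## Classifiers

**Group filter (MLP).** Three features per cluster: its pixel share of the
image, the population standard deviation of that share across the image's
clusters (one value per image), and its share of all clustered pixels.
Architecture 3 → 100 ReLU → 3 softmax, trained 200 epochs with full-batch
Adam and categorical cross-entropy on standardised features (the scaler is
stored with the model). Classes: 0 noise/shadow, 1 oyster, 2 fused.
Class-2 clusters are **kept** at this stage; only class 0 is removed.
Training is deterministic for a fixed seed and refuses single-class data.

**Refiner (Random Forest).** Six features per measured cluster: scaled
length, scaled width, and the four bounding-box corner coordinates, each
divided by half the larger image dimension and multiplied by 1000 (lengths
are first converted back to pixels through `mm_per_px` so numerator and
denominator share a unit). This makes the features comparable across
resolutions: the same physical scene rendered at 2× produces near-identical
vectors. 100 trees, Gini impurity, unlimited depth, bootstrap on, random
state 42. Class 0 is dropped, class 1 passes, and a class-2 cluster is
replaced by two records whose lengths are each exactly half the fused
length (widths unchanged; `x/2 + x/2 == x` holds exactly in floating
point). Splitting is bookkeeping on the measurement record — the pixels are
not re-segmented — because its purpose is to keep one fused pair from
dragging the per-image averages.

The MLP's and the forest's class vocabularies are separate label spaces; no
label is carried from one model to the other.

## Wilcoxon signed-rank comparison

Zero differences are dropped as ties; absolute differences are mid-ranked;
the normal approximation uses the tie-corrected variance
n(n+1)(2n+1)/24 − Σ(t³−t)/48 and no continuity correction. The reported Z
follows the convention of classical statistical packages: it is computed
from the **smaller** of the two rank sums and is therefore always ≤ 0, with
the evidence carried by its magnitude; the two-tailed p comes from the
standard normal. A signed variant (positive-rank-sum based), which negates
under argument swap, is exposed alongside. On the stability study's rank
structures (15 negative ranks summing 166 vs 5 positive summing 44 with one
tie; 13 negative summing 107 vs 8 positive summing 124 with none) this
yields Z = −2.28 (p = 0.023) and Z = −0.30 (p = 0.768).

## Synthetic scenes

The generator stands in for field photographs so every stage is trainable
and testable without downloads. Default study conditions, chosen once from
the geometry of the problem:

| parameter | default | rationale |
|---|---|---|
| image | 360 × 360 px = 180 × 180 mm | fits 6 oysters + cap without jamming random placement |
| scale | 0.5 mm/px (cap radius 30 px, diameter 30 mm) | a real soda cap; radius large enough that ±1 px Hough error ≤ 3% scale error |
| oysters | 6 per scene, major 25–45 mm, minor 14–24 mm (≤ 0.85 · major), orientation U(0, π) | market-size *Crassostrea virginica* |
| background | hue 120 (blue), jitter sd 1.2 | foam-board backdrop with sensor noise |
| shell | hue band 12–24 (tan), texture sd 1.5 | keeps ~97% of interior pixels core-dense at ε ≈ 6; sd 2.5 would sit at the site-percolation threshold and fragment blobs |
| shadows | probability 0.35, offset (4, 4) mm, hue 138 dark | drawn beneath the oyster, so only a crescent is visible |
| specks | 4 per scene, radius 1.5–3 mm, hue 40–90 | debris |
| fused pairs | probability 0.15; centre separation 0.85 × (a₁ + a₂) along the shared major axis (a = semi-major); partner hue = own hue + N(0, 1) | near-tangent "stuck" oysters; shared coloration keeps the union one hue cluster |

All geometric randomness is drawn in resolution-independent units
(positions as image fractions, sizes in millimetres) from one stream, and
per-pixel texture from a second stream. Re-rendering a seed at 2×
resolution therefore reproduces the identical physical scene — the basis of
the scale-equivariance check. Scenes are byte-identical for a fixed seed.
Random sequential placement refuses (with an actionable error) if an object
cannot be placed in 1000 attempts; for crowded fused-heavy layouts this
happens on a fraction of a percent of seeds, and batch drivers skip such
seeds deterministically via a placement pre-check.

Ground truth records each ellipse's centre, axes, orientation, and — since
the pipeline measures axis-aligned boxes — its analytic bounding extents
2·√(a²cos²θ + b²sin²θ) and 2·√(a²sin²θ + b²cos²θ). Training labels are
assigned by overlap: a cluster ≥ 70% inside one ellipse is an oyster; ≥ 70%
inside a fused pair's union with both members holding ≥ 15% is fused;
anything else is noise. The cap cluster is excluded from training tables
(the pipeline removes it geometrically before the filter), and shadow
clusters are excluded from the Random Forest table only, mirroring
deployment where the size-based filter has already removed shadows before
the forest runs.

**What passing on these scenes does not show.** The generator emulates hue
contrast, shadows, debris, fusion, and the reference object — the features
the pipeline's decisions depend on — but not specular highlights, biofouling,
non-elliptical shell outlines, uneven illumination, lens distortion, or
camera noise beyond Gaussian hue jitter. Results on synthetic scenes bound
the method's behaviour under its stated capture assumptions; they do not
predict accuracy on photographs that violate them.

## Numerical choices and degenerate inputs

- Hue lives on the integer 0–179 scale. Quantisation moves fully saturated
  colours by up to ~4 RGB units on an HSV round trip (≤ 1 for low-saturation
  pixels); YUV round trips are within ±1.
- Quarter-resize is block-mean over 4×4 tiles after truncating to multiples
  of four; output is floor(H/4) × floor(W/4).
- Population (not sample) standard deviation in the filter's spread feature;
  sample (n−1) standard deviation in per-image reports. A single-oyster
  image reports sd 0 with a degenerate flag; an empty image reports missing
  means, not zeros.
- A lone training class raises; an all-ties Wilcoxon input returns a flagged
  result with Z = NaN rather than a number.
- Hough ties and cluster-id assignment are resolved in raster-scan order;
  every stage is deterministic given its seed, so two identical runs produce
  byte-identical CSV reports.

## Known limitations

- Fused pairs whose shared axis sits near 45° produce compact, near-square
  unions whose six geometry features overlap the large-single-oyster region;
  the forest's class-1/class-2 boundary is the least certain part of the
  method and the first place to look if counts drift.
- The bounding-box length of a strongly rotated ellipse underestimates its
  true major axis; the pipeline measures what a calliper squared to the
  image axes would measure, which is the field convention it emulates.
- The MLP's size-share features cannot separate objects of oyster-like area
  (hence the geometric cap exclusion); a novel non-oyster object the size of
  an oyster would survive the filter and fall to the forest.
- Validation problem sizes (30 training scenes, 20 evaluation scenes per
  batch) were chosen as the package's own benchmark scale; per-blob
  dimension error on clean scenes is ~0.2 mm, dominated by rasterization.
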