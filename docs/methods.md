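# Methods

## Scene composition model

A synthetic scene is a sequence of copy-paste events on a square canvas
(default 1024 px).  Each pasting trial draws a sprite uniformly from the pool
and a rotation angle uniformly from [0°, 360°); the rotated raster (bilinear
interpolation, expanded bounding box) is placed at integer coordinates drawn
uniformly over positions that keep it fully inside the canvas.  The trial is
accepted iff the *overlap fraction* — the share of the candidate's alpha
support (alpha > 0.5) already covered by seed pixels — does not exceed the
threshold (default 0.25).  A rejected trial redraws only the position for the
same rotated sprite; every trial, accepted or not, consumes one unit of the
per-scene budget (default 70 trials).  These two defaults reproduce the
densities seen in real scans of piled seeds, where moderate touching is
common but deep stacking is not.

The overlap denominator is the *candidate's* area.  The alternative
conventions (occluded seed's area, union) are defensible; the candidate-based
fraction was chosen because it yields a single scalar per trial and directly
bounds how much of the incoming seed may be hidden.

Accepted sprites are alpha-composited.  Extraction produces binary alpha;
before blending, the alpha channel is Gaussian-blurred (sigma 1 px) inside a
3-px band around the support boundary, softening the cut-out edge without
moving the alpha-0.5 level appreciably.  The label map assigns the new
instance id to the support, overwriting older ids (foreground replacement):
earlier instances' visible masks shrink exactly where they are occluded.
Visible masks, tight bboxes and label map therefore agree by construction,
and the composition loop asserts the overlap bound for every accepted paste.

Finally the canvas is center-cropped (1024 → 768, offset 128 per side), so
seeds straddling the new border are truncated — mirroring real scans —
and instances left without visible pixels are dropped.  A symmetric center
crop was chosen as the least-surprising of the possible crop anchors.

Datasets derive image *i*'s generator from `SeedSequence([rng_seed, i])`, so
any single pair can be regenerated in isolation, and the whole dataset is
bit-reproducible.  Images are RGB PNG; label maps 16-bit single-channel PNG
(id 0 = background, ids in paste order); annotations COCO 1.0 JSON with
uncompressed column-major RLE; the manifest records config and seed
derivation.  The reference configuration produces 1200 pairs split
989/11/200 by a seeded uniform shuffle.

## Sprite pools

Real pools are built by chroma-keying: a pixel is foreground when its
Euclidean RGB distance from the sampled background color exceeds a tolerance
(default 60 of 255).  The largest connected component is kept, interior
holes filled, the raster cropped tight, and outside pixels zeroed.  The
tolerance default suits backgrounds chosen for separability (e.g. blue or
black scanner lids); it is configurable because husk colors vary.

The fixture generator stands in for scanned pools during development and
testing.  Each "cultivar" draws a base length (60–110 px), aspect ratio
(1.6–3.0), superellipse exponent (1.5–3.0) and a warm seed-like base color;
individual sprites jitter multiplicatively around these and carry
multiplicative Gaussian pixel noise (CV 8%) as texture.  With 20 cultivars ×
20 sprites this emulates a 400-sprite pool at the scale of real barley seeds
on a 1024-px canvas (~100 seeds/scene at acceptance equilibrium).  What the
fixture does *not* emulate: awns, husk texture anisotropy, specular
highlights, shadows, embryo notches, and non-convex damage — so green tests
demonstrate the pipeline's correctness on well-behaved silhouettes, not
robustness to those real-world complications.

## Evaluation metrics

Matching is greedy over detections in descending confidence (ties keep input
order): each detection takes the unmatched ground-truth instance of highest
IoU ≥ threshold (GT ties break to the lower index), otherwise it is a false
positive.  Recall₅₀ uses bbox IoU at 0.5; the APs use mask IoU, computed on
the union of the two bboxes (masks vanish outside their bboxes, making dense
scenes cheap).  AP is the all-points area under the precision–recall curve
with the monotone envelope (each precision replaced by the maximum at equal
or higher recall) — the convention of the common detection benchmarks, which
"rectangle approximation of the AUC" descriptions refer to.  AP@[.5:.95] is
the unweighted mean over the ten thresholds 0.50, 0.55, …, 0.95.  Dataset
aggregation is a macro mean over images (one cultivar per image in the
intended use, so macro = per-cultivar averaging).  Conventions for empty
images: recall and AP are 1.0 when an image has no ground truth and no
detections, 0.0 if spurious detections exist — a perfect detector scores
perfectly on an empty image.

Recall's bbox matching and AP's mask matchings are computed independently.

`metrics.degrade_truths` simulates an imperfect detector (erosion,
translation jitter, drops, random scores) for pipeline calibration; the
end-to-end test requires AP to fall strictly as degradation grows.

## Screening cascade

Stages run in order, each on the survivors of the previous one, per
population (image): (1) remove instances whose bbox enters the 5-px border
band; (2) remove instances strictly below the population's 25% solidity
quantile; (3) remove instances strictly outside the 5%/95% LWR quantiles.
Quantiles are type-7 (linear interpolation), the default of the numerical
ecosystem this field uses.  The "lower-quartile threshold" reading — cutoff
*equals* Q25, removal strictly below — was preferred over an IQR-fence
interpretation because the former names the quantile as the threshold
directly.  Consequences worth knowing: stage 2 removes ~25% of any
continuous population, ragged or not (the filter is distributional, not
absolute), and re-filtering survivors removes another quarter — the cascade
is deliberately one-shot.  All thresholds and the margin are config-exposed.

## Morphometry

Contours are traced by marching squares at iso-level 0.5 on a zero-padded
copy of the mask, after Gaussian smoothing of the float mask (sigma 1 px).
The smoothing matters: iso-contours of a hard binary raster are pixel
staircases that overestimate perimeter by ~6%, which would push a disc's
circularity to ~0.89; with smoothing the traced circumference of a
100-px-radius disc is within 0.5% of 2πr and circularity is 0.99.  If
smoothing collapses a very thin mask below the iso-level, tracing falls back
to the unsmoothed raster.  The outermost contour (largest enclosed area) is
used; orientation is normalized to positive shoelace area.

Length and width are the major/minor axis lengths of the ellipse with the
mask's normalized second central moments (rotation-invariant, unlike bbox
sides); solidity and eccentricity come from the same region properties;
perimeter is the traced polygon's arc length, so circularity = 4πA/P² and
the EFD input share one boundary definition.  Optional dpi converts px to mm
(25.4/dpi; 600 dpi is typical for flat-bed seed scans).

EFD coefficients follow Kuhl & Giardina: the closed polygon is parameterized
by chord length and each harmonic's (aₙ, bₙ, cₙ, dₙ) evaluated by the exact
closed form for piecewise-linear traversals.  Normalization rotates the
parameter origin to the first-harmonic ellipse's semi-major axis (choosing
the axis of larger magnitude), rotates the coordinate frame onto it, and
divides by its length — after which a₁ = 1 and b₁ = c₁ = 0 identically, and
coefficients are invariant to similarity transforms and starting point
(verified to 1e-4 on dense polygons; the pinned constants to 1e-6).  One
consequence of chord-length parameterization worth noting: the first
harmonic of a 2:1 ellipse has d₁ ≈ 0.587, not the axis ratio 0.5 — the
traversal speed is not angle-uniform, and the numerical-integration oracle
in the test suite confirms the closed form to 1e-6.  Features flatten the
4×20 array harmonic-major and drop the three constants, leaving 77 values.

PCA is computed by SVD on centered columns; the eight descriptors are
standardized (their units differ), EFD features are not (they share the
dimensionless post-normalization scale).  Component signs are fixed so each
component's largest-magnitude loading is positive.  The transform is exactly
invertible, which `latent_axis_contours` uses: a position on one axis (other
axes zero) maps back to a 77-vector, the constants (1, 0, 0) are re-inserted,
and the coefficient array is rendered as a contour — reconstructing the shape
gradient a component encodes.  Mean cultivar contours average normalized
coefficient arrays element-wise before reconstruction.

## Numerical and testing choices

Problem sizes in the test suite: the reference-shape check generates the
full 1200-pair dataset from a 400-sprite fixture pool (~6 minutes on one
CPU); the end-to-end chain uses 50 scenes; analytic oracles (disc, ellipse,
random star polygons) run at sub-second scale.  Degenerate inputs are
errors, not silent results: empty masks/contours, multi-component masks in
`compute_descriptors`, empty candidate masks in overlap computation,
zero-variance columns under standardization, split counts that do not sum.

## Known limitations

- Composited scenes have no shadows, lighting gradients or lens effects;
  domain gap beyond pose/occlusion randomization is out of scope.
- The screening quantiles assume a roughly homogeneous population per image;
  mixed-cultivar images would shift the thresholds.
- Fixture silhouettes are symmetric superellipses; pipeline behavior on
  strongly concave or awned seeds is untested by design.
- The overlap-threshold denominator and the crop anchor are conventions;
  both are configurable where alternatives might matter.
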