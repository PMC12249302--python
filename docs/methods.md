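# Methods

`sishdetect` implements a two-stage nuclei-detection framework for
HER2-SISH brightfield histology: classical preprocessing (stain
normalization, foreground extraction, watershed bootstrap labels)
feeding a trainable star-convex-polygon instance detector, evaluated
with an object-level TP/FP/FN protocol. Because the clinical slide
material this kind of pipeline targets is not redistributable, the
package ships a seeded synthetic scene generator that plays the role of
the dataset; every stage is validated against the generator's exact
ground truth.

## Synthetic scenes

A scene is a pure function of its `SceneConfig` (including the seed).
Nuclei are star-convex regions: the boundary is a single-valued radius
function of angle, `r(θ) = r₀ (1 + irregularity · g(θ))` with `g` built
from harmonics 2–4, rasterized as `{p : |p−c| ≤ r(θ(p))}`. Placement
fills three quotas — interior non-touching, partially overlapping
(centers at 0.75–0.95 of the radius sum), and border-clipped — by
rejection sampling with bounded retries. Overlaps are resolved by
z-order (the later nucleus keeps contested pixels) so the label image
stays a partition; the `overlaps_neighbor` flag is recorded from the
pre-resolution blobs.

Rendering follows Beer–Lambert: per-stain concentration maps are
combined through a 3×2 unit-column stain matrix in optical density
(OD = −log₁₀ I/I₀, I₀ = 255) and inverted to RGB. The nuclear stain is
haematoxylin-like (bluish-purple); the counterstain is a broad pinkish
vector chosen so stained tissue exceeds the OD transparency threshold in
all three channels. Besides the pale background (mean intensity 220 by
default), the generator renders a few darker stroma patches of pure
counterstain (~3–5 % of pixels). These are essential: a background at
intensity 220 has maximum OD 0.064, far below the Macenko transparency
cut (β = 0.15), so without stained tissue the second stain direction
would be unobservable. A per-stain multiplicative `stain_gain` emulates
staining-intensity variability (what robust-percentile normalization is
designed to undo).

HER2 (black) and CEN17 (red) dots are 1–2 px disks drawn inside nuclei.
Their colours are defined as *concentration mixtures of the scene's own
stains* (red: counterstain-dominant; black: dense in both), which keeps
their OD directions inside the two-stain fan — dot pixels therefore
cannot drag the percentile angles of stain estimation outside the true
basis. Dots only drive the expert-criteria filter (≥ 2 red signals,
non-overlapping, non-border-touching); signal quantification is out of
scope.

What the generator does **not** emulate: chromatin texture, scanner
optics and defocus, tissue folds and pen marks, anisotropic illumination
and real staining chemistry. Tests passing on these scenes demonstrate the
correctness of the algorithms under the stated model, not clinical-grade
performance on slides.

## Stain normalization

Standard Macenko: discard pixels with any OD channel below β = 0.15,
take the top-2 right-singular plane of the retained OD vectors, use the
α = 1 and 100−α percentile angles as the stain directions (α, β are the
reference method's canonical values), unmix by ordinary least squares
with zero-clipping, and record the 99th-percentile concentration per
stain. Deterministic conventions: each vector is sign-flipped to a
non-negative sum, and the column with the larger red OD component is
stain 1 (the nuclear stain — it absorbs strongly in red/green).
Normalization rescales concentrations by the ratio of robust maxima and
recomposes through the reference basis. A reference profile estimated
once from a seeded 192-px scene is frozen into the package so every
normalization targets the same appearance; a regression test regenerates
it.

On noise-free default scenes the estimator recovers the generating
matrix to < 1°; the acceptance bound is 5° per column. SSIM (uniform
7×7 window, C₁=(0.01 L)², C₂=(0.03 L)², via scikit-image) verifies
normalization: for pairs sharing geometry but rendered through a rotated
basis with stronger gains, normalizing toward the pair's reference
raises SSIM on ≥ 9/10 seeded pairs. These pairs are rendered noise-free:
sensor noise is identical in both renderings and survives normalization
only approximately, which would confound the property being tested (the
stain mapping itself).

## Foreground

`enhance_contrast` converts to Rec. 601 luminance and applies full-range
histogram equalization (classic CDF mapping). The mask itself thresholds
**raw** luminance: the union of a global Otsu cut and a local-mean cut
(51-px window, offset 10), then a 1-px disk opening and filling of holes
smaller than 32 px². Equalization is deliberately not in the threshold
path — it flattens the histogram by construction, which destroys the
bimodality Otsu needs and captures 30–40 % of the pale background on
these scenes. On default scenes the mask covers ≥ 99 % of nuclei pixels
and ≤ 10 % of background (the captured background is mostly stroma,
which is genuine stained tissue).

## Star-convex geometry

Training targets: per-pixel radial distances along R rays (angles
2πk/R, default R = 32; the study uses R = 16 for speed) measured by
unit-pixel ray marching — step 1 px at a time from the pixel centre,
rounding to the nearest pixel, and count the steps that stay on the
pixel's own instance label (leaving the image counts as leaving the
label). The object-probability target is the per-instance Euclidean
distance transform normalized to max 1 (centre pixels are prioritized;
background is exactly 0).

Reconstruction uses polar clipping: a pixel belongs to a polygon iff its
distance from the centre is at most the angularly interpolated ray
radius plus 0.5 px, after a circular 1-2-1 filter on the radii. The
half-pixel offset accounts for the marched distance ending at the last
*interior pixel centre*; the 1-2-1 filter removes the ±1 px jitter that
integer stepping introduces between adjacent rays. Polygon IoU is
computed on the union bounding box with this same rasterizer; greedy NMS
processes candidates by descending score (ties: smaller row, then
column, making the result independent of input order) and keeps a
candidate iff its IoU with every kept one is below the threshold.
Detections are painted in increasing-score order so the highest score
owns contested pixels; empty instances are dropped and labels
renumbered.

**Quantization limit.** Integer ray marching localizes the boundary only
within a 1-px band, with a lattice-dependent bias (mean ≈ 0.54 px,
resonating between ≈ 0.41 and 0.71 with the fractional radius). A disk
therefore reconstructs with IoU 1.0 at many radii but only ≈ 0.91–0.94
at resonant ones (e.g. r ≈ 8.75); the mean over radii 5–16 is ≈ 0.98.
No generic star-convex reconstruction can beat this from the marched
radii alone, so the reconstruction test asserts mean ≥ 0.95 and
per-disk ≥ 0.90. Similarly, rasterized blobs with high irregularity
(> ≈0.3) can alias at the pixel level so that a marched ray briefly
re-enters; the generator's default irregularity (0.22) is below that
regime.

## Predictor and training

The predictor is a small pure-numpy convolutional encoder–decoder
(im2col convolutions, ReLU, 2×2 max-pool, nearest-neighbour upsampling
with skip concatenation) with two 1×1 heads: object-probability logits
and radial distances through a softplus scaled by `dist_scale` (default
5–6 px ≈ the mean nucleus radius, so the head trains in O(1) units).
Inputs are scaled by the image's 1st/99th intensity percentiles.
Gradients are hand-derived and verified against finite differences.

Loss: `BCE(σ(logits), 1[prob_target > 0]) + λ · Σ w·mean_k|d−d*| / Σ w`
with `w` the soft probability target — background pixels contribute
nothing to the distance term and centre pixels dominate it. λ defaults
to 0.2 (terms of comparable size at init); the study uses 0.5, which
measurably tightens radii. Optimization is SGD with momentum 0.9,
seeded shuffling, and flip/90°-rotation augmentation. Rotating a
distance map is implemented as the exact ray-index permutation (the
lattice maps onto itself), which is mathematically identical to
re-marching the rotated mask; a test verifies the identity for all 16
transform combinations. The best-validation-epoch weights are returned.

Desk-scale study conditions (`protocols.STUDY_TRAIN`): twenty 128-px
scenes (16 train / 4 held out), depth 2, 12 base filters, 16 rays,
batch 4, lr 0.02, 100 epochs (≈ 5 CPU-minutes). The learning rate is
far above the full-scale recipe's 1e-4 because the network is orders of
magnitude smaller; epochs were set where validation loss plateaus.
Training labels are the generator's exact masks — the stand-in for the
original workflow's manually corrected stage-1 annotations (manual
correction is out of scope); the demo pipeline can instead train on raw
watershed pseudo-labels (`train.labels: pseudo`).

Inference: percentile normalization → network → one candidate polygon
per pixel with probability above 0.5 → greedy NMS at IoU 0.4 →
score-priority rasterization → removal of regions under 50 px² (the
post-processing step of the recipe; the smallest true nucleus is
≈ 80 px²). Images larger than one tile are processed in overlapping
tiles with a single global NMS; tiles share the whole-image
normalization range and the stride is aligned to the pooling grid, so
tiled and untiled detections agree exactly away from ties.

With these conditions the trained detector reaches pooled object-level
F1 of 0.95–1.0 on well-separated held-out scenes and 0.94–1.0 on
held-out scenes with overlapping clusters (seeds 0–2), versus 0.69–0.73
and 0.79–0.83 for the marker-controlled watershed baseline — the
expected ordering, driven by the baseline's merge/split failures.

## Evaluation protocol

Mask-vs-mask matching: candidate pairs at IoU ≥ 0.5, one-to-one
assignment maximizing total IoU (scipy's Hungarian solver on the
candidate graph); unmatched detections are FP — splitting one nucleus
into k detections yields 1 TP and k−1 FP — and unmatched truth is FN.
Point-vs-mask matching (expert dot annotations): a point matches the
instance containing it, nearest-centroid wins when several points share
an instance, and unclaimed instances count as FP within the evaluated
region.

Percentages use exact rational arithmetic and half-up rounding to one
decimal (e.g. 62/64 → 96.875 → 96.9). Report means are the mean of the
*rounded* per-image values quantized to two decimals with banker's
rounding, and the spread is the sample standard deviation (ddof = 1) to
one decimal — the convention under which the packaged benchmark tables
(40 per-image rows and both summary rows) reproduce exactly from their
TP/FP/FN triples.

## Known limitations

- Quantized radial distances bound disk-reconstruction IoU below 0.95
  at lattice-resonant radii (see above).
- The watershed bootstrap merges nuclei with adjacent stained stroma
  into single pseudo-labels (~15 % of isolated nuclei on default
  scenes); the production remedy — manual correction of stage-1
  labels — is out of scope.
- Scenes are stylized; none of the results here transfer to clinical
  material without retraining and re-validation.
- The pure-numpy network is single-CPU and desk-scale by design;
  256-px patches at production depth/width are outside its envelope.
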