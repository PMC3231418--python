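# Methods

This note records the scientific and numerical choices behind `oatfrost`:
the model, its tunable parameters, what the synthetic generator does and
does not emulate, and the places where the design was genuinely open.

## Colour model

RGB rasters are normalised to unit range (dividing by the dtype's full
scale, e.g. 255) and mapped to CIE XYZ by the classical CIE-primaries
matrix; Lab follows with the piecewise compression `f(t)` (cube root above
t = 0.008856, linear `7.787 t + 16/116` below).

Two points are configurable because the convention is not unique:

- **L\* below the breakpoint.**  The default is the linear branch
  `L* = 903.3 (Y/Yn)`, which joins the upper branch continuously (the two
  formulas agree to 8·10⁻⁴ at the breakpoint) and is exactly what the
  shared `f(t)` implies, since `116 f(t) − 16 = 903.3 t` on the linear
  segment.  A discontinuous cube-root variant (`low_branch="cube_root"`)
  is provided for comparison with sources that print it that way; for
  vegetation images the choice is immaterial because Y/Yn < 0.009 only in
  near-black pixels.
- **White point.**  No measurement of the illuminant is assumed; the
  default reference white is the image of RGB = (1,1,1) under the matrix
  (the equal-energy white of this primary set, (1.000, 1.001, 1.000)), so
  that a saturated-white pixel maps to L\* = 100, a\* = b\* = 0 exactly.
  Any positive tristimulus triple can be supplied instead.

For thresholding, channels are quantized to integer histogram bins:
L\* to 101 levels over [0, 100], a\* and b\* to 221 levels over
[−110, 110] (1 bin ≈ 1 Lab unit; counts configurable).  Values outside
the nominal ranges are clipped.

## Thresholding

All three thresholders share one convention: level `v` belongs to the
lower region iff `v ≤ t`, so a valid threshold lies in
[min occupied level, max occupied level).  Argmax/argmin plateaus break
to the smallest level, which makes every result deterministic.

- **Isodata** starts from the floor of the histogram mean and iterates
  `t ← ⌊(μ₁(t) + μ₂(t))/2⌋` until it stops changing; the result is a
  fixpoint of that update.  A visited-set guards against cycling.
- **Otsu** maximizes `σ²_B(t) = [μ_T w(t) − μ(t)]² / (w(t)(1 − w(t)))`
  over candidates with both classes non-empty.
- **Fuzzy entropy** assigns each level a membership
  `μ_F = 1 / (1 + |i − μ_c(t)| / C)` toward its side's class mean and
  minimizes the mean Shannon entropy of the memberships (normalized by
  ln 2, so the measure lies in [0, 1]; `0·ln 0 ≡ 0`).  The default
  distance normalizer is `C` = span of occupied levels, the classical
  formulation: it keeps memberships in [½, 1] and the measure invariant
  to rescaling the grey axis.  Setting
  `membership_normalization="none"` gives the unnormalized variant
  (`C = 1`); on wide histograms that variant's entropy keeps falling as
  pixels get *farther* from the class means (μ_F → 0 is also "crisp"), so
  its argmin drifts to extreme levels — it is provided for comparison,
  and both variants are verified against exhaustive search.
- **Fusion**: the per-channel operating threshold is
  `⌊(t_I + t_O + t_F)/3⌋`; averaging smooths whichever component lands
  high or low.  Floor (rather than round) keeps thresholds integer bin
  indices; the one-bin difference is immaterial downstream.

**Multi-level thresholds** are grown by re-thresholding one existing
partition's sub-histogram at a time.  The partition chosen is the one
with the largest population-weighted within-partition variance (total
squared deviation), mirroring the variance logic of the merge criterion;
degenerate partitions (mass at fewer than two levels) are skipped, and a
requested count that cannot be reached raises an error carrying the
partial result.  Because every component threshold lies strictly inside
its partition's occupied range, the fused list is always strictly
increasing.

## Classification

Pixel codes count the thresholds strictly below the value; with `M`
thresholds per channel and `n = M + 1` partitions, the packed label
`p̃ = n² ĩ_L + n ĩ_a + ĩ_b` is a bijection between code triplets and
{0 … n³−1}.

Class statistics are computed on the *continuous* Lab values, not the
quantized bins.  Two spread measures are available:

- `variance_form="as_printed"` (default): `σ_k` is the mean Euclidean
  distance of members to the class mean, scaled by 1/d (d = 3).  This is
  a *distance*, whereas the between-class separation
  `σ_kh = ‖μ_k − μ_h‖²/d` is a *squared* distance; the merge rule
  compares them directly, so the criterion is scale-dependent (it fires
  more readily when spreads are numerically large relative to 1).
- `variance_form="squared"`: `σ_k` is the mean squared deviation per
  channel, dimensionally commensurate with `σ_kh`.

Merging: any pair with `σ_k ≥ σ_kh` or `σ_h ≥ σ_kh` is a candidate; the
pair with the largest violation `max(σ_k, σ_h) − σ_kh` merges first, the
fused class keeping the label of the smaller-variance member, and
statistics are recomputed after every merge.  The loop terminates in at
most (classes − 1) merges.  An optional population floor
(`min_population`, default 1 = off) folds classes smaller than the floor
into their nearest neighbour by `σ_kh` before the criterion runs.

**Number of classes.**  Two workflows:

- *Dynamic* (`target_classes=None`): if an entire merge pass fuses
  nothing, the partition is judged too coarse, the threshold count is
  incremented and clustering restarts, until a fusion occurs.  On
  low-noise scenes with well-separated classes this loop may never fuse
  anything at any threshold count — splitting a tight class produces
  fragments whose separation slightly exceeds their truncated spread —
  so when the probe exhausts `max_thresholds` (default 6) the *coarsest*
  stable partition (one threshold per channel) is returned: by the
  method's own criterion every probed partition was already properly
  separated, and finer thresholds only subdivide classes the merger then
  declines to reunite.
- *Survey* (`target_classes=K`): one threshold per channel already yields
  up to 8 classes, so the coarsest partition whose stable class count
  reaches K is used, and the merge criterion is then relaxed — the pair
  with the greatest overlap (largest `max(σ_k, σ_h) − σ_kh`) is fused
  repeatedly until exactly K classes remain.  The threshold count grows
  only when the stable count is below K; since the method only merges, a
  K that even the finest probe cannot reach raises an error.

**Semantic roles.**  Mapping four clusters onto GO/DO/HD/SG is the
expert's task in a real survey; the built-in heuristic is a convenience:
SG = lowest L\* (the shadow class), GO = most negative a\* of the rest
(greenest), DO = most positive b\* of the remaining two (yellowest),
HD = the remainder.  Ties resolve by class label with a warning, and the
mapping is returned alongside the statistics so a user can override it.

**Damage report.**  Usable area = area(GO) + w·area(HD).  Field experts
place the usable share of the half-dried class at 40–60%; the default
w = 0.5 is that range's midpoint.

## Validation

Sample units are polygons, not pixels.  The sample-size design is the
multinomial one: `n_s = ⌈B Π(1−Π)/b²⌉` with `B = χ²(1, 1 − b/k)` and
`b` the desired accuracy (default 0.05); the worst-case class fraction
(the Π maximizing Π(1−Π)) is used unless a class is specified, and `B`
may be overridden to reproduce published tables.  Apportionment of `n_s`
across classes is largest-remainder, which always sums exactly.

Scoring follows the fuzzy rules: a unit whose polygon overlaps its
reference class on 100% of its surface is *absolutely correct* (diagonal);
at least 50% overlap is *acceptable*, tallied in the left counter of the
cell whose row is the majority non-reference classified class; below 50%
it is an *error* in the right counter of the majority classified class's
row.  One boundary case is not covered by the stated rules: the reference
class can be the plurality while still holding < 50% of the surface; the
row then falls back to the majority *non-reference* class so the tally
stays off-diagonal.  Units are pixel-weighted by default (each polygon
contributes its area, so the grand total is the sampled surface, matching
worked tables whose totals run to tens of thousands); unit weighting
(one count per polygon) is available.

Accuracies are exact ratios, reported alongside nearest-integer percents;
commission/omission errors are the exact complements of classifier's/
expert's accuracy.  Collapsing each (acceptable; unacceptable) pair by
addition reproduces the deterministic matrix, which guarantees
deterministic ≤ fuzzy for every measure.

The package ships a worked four-class survey matrix
(`oatfrost.examples.synthetic_survey_matrix`) for exercising the accuracy
measures at realistic magnitudes; its marginal totals follow a published
survey of this design and the off-diagonal cells that only the marginals
constrain were completed synthetically (see the docstring).

## Synthetic scenes

The generator emulates the class-mixture statistics of a four-texture
field photograph, not its photometry:

- **Geometry**: a Gaussian random field smoothed at `patch_scale`
  (default 24 px) is quantile-sliced at the cumulative class fractions,
  giving contiguous blobs whose empirical areas match the targets almost
  exactly (the slice is exact up to ties on the continuous field).
- **Palette** (role, mean RGB, fraction): GO (50,110,40) 35%,
  DO (180,170,80) 16%, HD (130,110,85) 16%, SG (25,30,25) 33% — green,
  straw-yellow, dull tan, dark ground.  The half-dried colour is browner
  than the dried one deliberately: the four roles must separate *per Lab
  channel* (L\* isolates shadow, a\* the green class, b\* dried from
  half-dried vegetation), because each channel contributes a single
  threshold in the survey workflow.  An intermediate colour placed
  between green and yellow on every axis cannot be isolated by any
  single-threshold-per-channel coding, no matter how large its joint RGB
  distance to the neighbours.  With the default palette each class mean
  keeps a margin of several noise standard deviations to every fused
  threshold.
- **Illumination**: a horizontal multiplicative ramp with peak-to-peak
  relative span `gradient_amplitude` (default 0.2, i.e. ±10%).  Lab
  absorbs most of it: a scale factor s multiplies a\*/b\* by only s^{1/3}.
- **Noise**: additive Gaussian, per channel, `noise_sd` in 8-bit counts.
  The default 1.5 models a scene-scale raster downsampled from a
  multi-megapixel frame — area-averaging ~36 native pixels per raster
  pixel suppresses several counts of sensor noise — and satisfies the
  recovery regime (minimum inter-class RGB distance ≈ 78, over 50× the
  noise sd).  Noise matters more than it may appear: the fuzzy scoring
  rules count a sample unit as fully correct only at *exactly* 100%
  overlap, so the deterministic overall accuracy equals the weight share
  of perfectly pure polygons, and with ~10²-pixel polygons that requires
  per-pixel error rates below ~10⁻⁴ — i.e. thresholds several noise-sd
  away from every class mean.  At noise_sd ≳ 4 one-sided tail crossings
  are frequent enough that perfectly pure polygons become rare and the
  deterministic polygon-level accuracy drops even while pixel-level
  agreement stays above 99%.

What the generator does **not** model: plant morphology and within-class
texture, specular highlights, mixed boundary pixels (class edges are
hard), sensor demosaicing, and non-Gaussian noise.  Passing tests on
these scenes therefore demonstrate the correctness and stability of the
algorithmic chain under the stated mixture conditions — not performance
on real canopy photographs, where within-class texture variance is far
larger and the merge criterion consequently fires much more readily.

**Reference polygons** are axis-aligned rectangles (side lengths 8–20 px
by default) placed by rejection sampling wholly inside single-role
regions, so each sample unit contains pixels of one class only, as the
sampling scheme requires.  Rasterization is boundary-inclusive.

## Problem sizes

The end-to-end recovery study (tests and acceptance script) uses ten
512×512 scenes with 20 polygons per class — 80 sample units per scene, a
scale at which no single unit carries more than a few percent of the
pixel weight.  Threshold-oracle checks run on ≥100 random histograms of
up to 64 levels against exhaustive search.  The whole suite completes in
well under a minute on one CPU.

## Known limitations

- The merge criterion in its printed form compares a distance with a
  squared distance; both behaviours are available, but neither makes the
  criterion scale-free.  On data whose within-class spread is ≪ 1 Lab
  unit or ≫ 10 Lab units the criterion's sensitivity changes character.
- The dynamic class-count loop assumes that over-partitioning will
  eventually trigger a fusion; the coarsest-partition fallback covers the
  (synthetic, low-noise) regime where it does not.
- The GO/DO/HD/SG role heuristic presumes the canonical colour ordering;
  unusual palettes (e.g. a half-dried class greener than the healthy one)
  need a manual mapping.
- Polygons are validated in image coordinates; georeferencing and
  cross-image registration are out of scope.
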