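# Methods

## Scope and data model

The package operates on 2-D 8-bit grayscale images (`L = 256` gray levels
throughout; histograms always carry `n = L` bins and equalization maps use
`n_out = n`).  Images are plain integer numpy arrays; masks are 0/1 arrays
of the same shape.  Everything downstream of image loading is deterministic
given the configured seeds: generators, training, and the pipeline use
`numpy.random.default_rng` instances created locally — there is no hidden
global random state.

## Contrast-limited adaptive equalization

Global equalization maps level `i` to `round_half_up((n-1) · CDF(i))`,
where the CDF is the cumulative pixel fraction.  Rounding is half-up (not
banker's) so the map is a fixed, reproducible function of the histogram.
The map is monotone non-decreasing by construction, and the top occupied
level always maps to `n-1`.

The adaptive variant divides the image into a `grid_rows × grid_cols` tile
grid (default 8×8; when a dimension is not divisible the last tile absorbs
the remainder).  Per tile:

* the clip ceiling is `max(ceil(clip_norm · tile_pixels), ceil(N_avg), 1)`
  with `N_avg = tile_pixels / n` the mean count per bin.  `clip_norm` is a
  fraction of the tile's pixel count (default 0.03), the convention used by
  mainstream CLAHE implementations; the `ceil(N_avg)` floor guarantees the
  clipped mass can always be re-housed (a ceiling below the mean bin
  occupancy cannot hold the tile's mass at all).  `clip_norm: null`
  disables clipping, which is also the exact-reduction case: a 1×1 grid
  with no clipping is bit-for-bit identical to global equalization.
* clipping caps each bin at the ceiling and redistributes the excess
  uniformly — `floor(excess/n)` to every bin, the remainder one count per
  bin from bin 0 — then re-clips, repeating until the excess stops
  decreasing; any final residual is placed one count at a time into bins
  strictly below the ceiling, in index order.  The scheme is deterministic,
  conserves total mass exactly, and leaves every bin at or below the
  ceiling (both properties are tested over seeded histograms, and an
  infeasible ceiling raises a typed error rather than looping).

Each output pixel is the bilinear blend of the LUTs of its (up to) four
nearest tile centers, evaluated at the pixel's input level; pixels outside
the outermost centers use the one or two available maps with weight one on
the nearest.  The blended value is rounded half-up.  Degenerate weights are
handled exactly (a single tile contributes weight 1.0), which is what makes
the reduction case bit-identical rather than approximately equal.

Entropy `E = -Σ p_i log2 p_i` (base 2, `0·log 0 := 0`) is exposed as a
diagnostic; it is maximal at `log2 n` (8 bits) exactly for the uniform
histogram.

## Otsu segmentation

`otsu_threshold` searches all splits `t ∈ [0, n-2]` with both classes
occupied and maximizes `σ_b²(t) = ω₀ω₁(μ₀-μ₁)²`; ties go to the smallest
`t`.  Class 0 is levels `≤ t` (closed), class 1 is levels `> t`.  The
between-class form is used with the square — the decomposition
`σ² = σ_ω²(t) + σ_b²(t)`, which the tests verify to 1e-9 relative
tolerance at every split, forces it.  Occupied-class checks are done on
integer masses, not float cumulative probabilities, so splits adjacent to
empty tails are classified correctly.  The unnormalized class first moments
(`Σ p_i·i` per class) are exposed as diagnostics (`moment0`, `moment1`)
but all statistics use conventionally normalized class means.

The pipeline's detection stage applies Otsu iteratively: threshold, keep
the foreground (polarity `above` by default — lesions are assumed
hyperintense; `below` is available), and re-run Otsu on the foreground's
histogram until the foreground occupies at most `max_region_fraction` of
the image (default 0.1) or no valid split remains.  The rationale: a
whole-head image is dominated by the background/tissue bimodality, and a
lesion is a tiny minority class (≈1–2 % of pixels) that Otsu's
balanced-split objective will not select directly; iterating hones in on
the intensity tail, and 0.1 reflects that a lesion on a single axial slice
rarely exceeds a few percent of the frame.  Each split strictly shrinks the
foreground, so the iteration terminates (it is additionally capped at 8
rounds).  The candidate region is the largest 8-connected component of the
final mask with at least `min_area` pixels (default 25); absence of a
candidate is a first-class outcome (predicted tumor-free), never an error.
An optional 3×3 binary opening (`segment.opening`, off by default) removes
speckle before component extraction.

Thresholds are computed on the **original** intensities by default
(`segment.source: original`).  Tile-wise equalization deliberately discards
the global intensity ranking — each tile's brightest content is pushed
toward the top of the range — so thresholding the CLAHE output cannot
isolate a globally hyperintense minority blob (empirically, the within-head
distribution of the equalized phantom is near-uniform and the "candidate"
becomes an arbitrary half of the tissue).  The enhanced image is where the
candidate's intensity features are measured, which is where contrast
normalization helps the classifier.  Setting `segment.source: enhanced`
restores thresholding on the equalized image for data where that is
appropriate (e.g. already skull-stripped, globally low-contrast slices).

## Region features and normalization

Eight features per candidate: area (pixel count), perimeter, circularity
`4πA/P²`, eccentricity, centroid row/column as fractions of the image
extent, and the mean and standard deviation of intensity inside the region.
Perimeter is the Crofton-weighted boundary length of
`skimage.measure.regionprops`, which is approximately unbiased for smooth
blobs (a rasterized disc of radius 10 scores circularity ≈ 0.98; naive
4-edge counting would give ≈ 0.66 and make circularity useless as a
compactness measure).  A single-pixel region (perimeter 0) gets
circularity 1 by convention.

Features are min–max normalized against ranges fitted on the training set;
test-time values outside the training range are clamped to [0, 1] (unseen
data legitimately exceeds training ranges), and a feature that was constant
in training maps to 0.5.  Normalization is required by the classifier: the
max–min similarity is only bounded and maximal-at-equality on the unit
hypercube.

## Max–min LVQ classifier

Similarity: `S(x, w) = Σ min(x_i, w_i) / Σ max(x_i, w_i)`, a standard
fuzzy/Jaccard-type measure on `[0,1]^d` — symmetric, in [0, 1], and equal
to 1 iff `x = w`.  Two all-zero vectors make the public similarity
undefined (typed error); the internal vectorized matcher scores that pair 1
(they are equal), which only matters transiently during training.

Classification takes, per class, the maximum similarity over that class's
codebook vectors, and returns the class attaining the global maximum; ties
break to the first class in codebook order (order of first appearance in
the training labels).

Training is LVQ1: the codebook is initialized from class-stratified samples
(3 per class by default) drawn with the configured seed; each epoch visits
the data in a fresh seeded shuffle and moves the globally most similar
reference toward the sample if the classes match, away otherwise, with
learning rate `α_t = α₀(1 - t/T)` (defaults `α₀ = 0.1`, `T = 50` epochs),
clamping to [0, 1] after every update so the similarity contract stays
valid.  Identical data and seed give an identical codebook.  The tracked
training loss is `1 - mean(best similarity to the true class)` — an
artifact definition of this package, monotone in match quality.

## Weight quantization and SQNR

Codebook weights are quantized with a uniform mid-rise quantizer on [0, 1]:
cell index `k = clip(floor(w·2^β), 0, 2^β-1)`, reconstruction
`(k + 0.5)/2^β`.  Reconstruction points are fixed points; the maximum
error is the half-step `2^{-(β+1)}`.  SQNR is
`10·log10(mean(w²)/mean((w̃-w)²))` in dB, reported as `inf` when the noise
power is zero.  The dB-per-bit efficiency κ is **estimated** by a
least-squares line fit of SQNR against β (for uniform weights it lands at
≈ 6.02 dB/bit, the classic uniform-quantizer law); it is never assumed.

## Synthetic phantoms

`make_phantom` renders: a dark background; an elliptical brain (default
semi-axes 42 %/36 % of the image extent, centered) whose tissue texture is
a smooth random field compressed into the contrast window (default
[100, 140] — deliberately narrow so the tissue occupies ~16 % of the
8-bit range and equalization has something to do); a smooth low-order
polynomial + low-frequency cosine bias field scaled to ±`bias_amplitude`
(default 10 intensity units); additive Gaussian noise (`noise_sigma`
default 5); and optionally a hyperintense elliptical tumor
(`intensity_delta` default 80) that must lie entirely inside the brain,
with its rasterization as the ground-truth mask.  Labels are `tumor` iff
the mask is non-empty.  `make_cohort` jitters tumor position (within 45 %
of the brain semi-axes) and size (semi-axes 5–9 px) per sample from one
seed; `round(n · tumor_fraction)` samples carry tumors.

What the phantoms emulate: low tissue contrast, smooth intensity
inhomogeneity, sensor noise, and a compact hyperintense lesion.  What they
do **not** emulate: anatomy (gyri, ventricles, skull), partial-volume
effects, texture heterogeneity inside lesions, non-ellipsoidal lesion
shapes, or any MR physics.  Passing the end-to-end benchmark therefore
demonstrates that the pipeline's machinery is correct and internally
consistent under controlled conditions — not clinical performance.  The
feature set and classifier would need re-validation on real data.

`make_cluster_dataset` provides truncated-Gaussian class clouds on
`[0,1]^d` with a guaranteed minimum center separation (a multiple of the
cloud sigma, default 0.05) for exercising the classifier in isolation.
Note the separation parameter is a lower bound on center distance; producing
genuinely overlapping classes requires a large sigma, not a small
separation.

## Study sizes and runtimes

The validation suite uses: 200 seeded histograms for the threshold-oracle
comparison; 100 for clipping accounting; 3 classes × 100 samples in
`[0,1]^6` at 5σ separation (70/30 split) for classifier recovery; 10⁵
uniform weights over β ∈ {2..10} for the SQNR law; and a 100-phantom
training cohort with a 50-phantom (25 tumor) evaluation cohort at 128×128
resolution for the end-to-end benchmark.  The training cohort size was
fixed at 100 because LVQ1's codebook is sample-order sensitive and smaller
cohorts left visible variance in the false-positive rate.  The entire suite
runs in well under a minute on one CPU.

## Known limitations

* Iterated Otsu assumes the lesion is an intensity outlier; an isointense
  lesion is invisible to this pipeline by design.
* One candidate per image: multifocal disease reduces to the largest focus.
* The max–min similarity treats features symmetrically; features that are
  uninformative but high-variance dilute it.  With 8 engineered features
  this is acceptable; with many features a weighting would be needed.
* `clip_norm` interacts with tile size through the ceiling formula; very
  small tiles push the ceiling to its feasibility floor where equalization
  degenerates toward a linear ramp.
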