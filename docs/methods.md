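# Methods

## Model

`rfstacks` segments the glomerular basement membrane (GBM) in TEM images by
pixel-wise classification with a two-level random-forest ensemble.

**Level 1 — one forest.** Each forest is a bagged ensemble of `T` decision
trees of depth ≤ `D` (Gini splits, √F random feature subsets per split,
bootstrap resamples), applied per pixel to a feature vector and combined by
*hard* majority voting: a pixel is membrane iff strictly more than half the
trees vote membrane. An exact tie counts as background — the conservative
choice for a thin foreground class. This hard-vote rule is implemented
directly over the trees rather than through averaged class probabilities,
so the vote fraction is always a multiple of 1/T.

**Level 2 — stacking across grayscale bins.** Training images are assigned
to `N` contiguous half-open bins `[lo, lo+w), …` of mean GBM intensity
(mean of the image over its mask). Defaults follow the clinical
configuration: `N = 37`, bin start 73.5, bin width 2, so bin 1 is
[73.5, 75.5) and bin 37 is [145.5, 147.5). Means outside the range clamp to
the nearest bin with a warning. Two integrations are built per session
(one image drawn per bin, `M` pixels sampled per image):

- *Full view (RFS₁)*: all `M·N` samples pooled into one forest.
- *Zoom view (RFS₂)*: one forest per bin. On a test image the bank yields
  `N` coarse results CR₁…CR_N, fused by:
  1. probability map `p(i,j) = n(i,j)/N`, the exact fraction of coarse
     results marking pixel `(i,j)` (no smoothing);
  2. two-cluster fuzzy C-means (FCM) on the scalar `p` values; membrane is
     the cluster with the larger centroid;
  3. morphological cleanup: binary opening with a disc (radius 1) then
     removal of 8-connected components smaller than 50 px;
  4. iterative refinement: with retained set S (initially all coarse
     results when `w₁ = 1`, otherwise the top ⌈w₁·N⌉ by mean pairwise
     Jaccard to the others), loop — build the probability map of S,
     bipartition (FCM), clean up → consensus C; recompute Jᵢ = J(CRᵢ, C)
     for *all* i; new S = {i : Jᵢ ≥ w₂}. Stop when S is unchanged, S would
     become empty (previous S kept), or after `max_iters` (10) passes.

The two candidates R₁ (full view, cleaned with the same cleanup so the
comparison is fair; switch `cleanup_r1`/`--no-cleanup-r1`) and R₂ (refined
zoom-view consensus) are both returned; the final selection is a human
decision by design, with an optional auto-selector that takes the
higher-Jaccard candidate when a gold mask is supplied.

## Feature stack

Fourteen feature families in the trainable-segmentation tradition, one
channel per (family, scale) where the family is scale-parameterized, with
reflection at borders and a deterministic channel order recorded in
`channel_names` (models refuse to predict on mismatched configurations):

| family | definition | channels |
|---|---|---|
| mean/min/max/median | disc-footprint local statistics | 1 per scale each |
| variance | E[x²] − E[x]² over the disc | 1 per scale |
| Sobel | gradient magnitude of the Gaussian-smoothed image | 1 per scale |
| Hessian | both eigenvalues of the Gaussian Hessian | 2 per scale |
| difference of Gaussians | all pairs σᵢ < σⱼ from the scale list | C(S,2) |
| Gaussian blur | σ = scale | 1 per scale |
| entropy | 256-bin local entropy over a disc | 1 per scale |
| Kuwahara | mean of the least-variance diagonal quadrant window | 1 per scale |
| membrane projections | 19×19 line kernels at 6 orientations (30° steps), reduced by sum/mean/std/median/max/min | 6 |
| Lipschitz | lower Lipschitz cover (slope 10), chamfer passes | 1 |
| neighbors | raw shifted values at the 8 unit offsets | 8 |

Default scales are {1, 2, 4, 8, 16} px. Anisotropic diffusion and bilateral
filtering are implemented but disabled by default: diffusion is slow and
degrades membrane accuracy in this pipeline. Features are computed in
float64 and stored as float32 without normalization (trees are invariant to
monotone per-feature scaling). Families are computed independently, so
disabling one leaves the remaining channels bit-identical.

## Fuzzy C-means details

The bipartition runs classical FCM (fuzzifier m = 2.0, tolerance 1e-5 on
the maximum membership change, ≤ 300 iterations) on the *unique* values of
the probability map weighted by their pixel counts — algebraically
identical to pixel-wise FCM but O(#distinct values) per iteration, and the
map has at most N+1 distinct values. Centroids are initialized
deterministically at the extreme observed values; values coinciding with a
centroid get crisp membership. A constant map is degenerate and returns an
empty mask with a warning; inside the refinement loop a constant *nonzero*
map (e.g. a single retained coarse result) falls back to 0.5-thresholding
so a lone good result is not discarded.

## Synthetic data

The generator emulates the documented properties of clinical GBM TEM
images; it is the package's test bed, not a physical image-formation model.
Per image: a smooth random curve — an open cubic spline across the frame
(strip), a radially perturbed ellipse (closed), or their union (compound) —
is dilated to a smoothly varying half-width (default 3–8 px) to form the
mask. Membrane pixels are painted with a smooth integer texture whose mask
mean is corrected to equal the target mean exactly (before noise);
the background sits `gbm_contrast` (default 30) gray levels *brighter*
(electron-dense membrane; sign configurable). Organelle-like elliptical
blobs at membrane-±15 gray levels (default ≈1 per 10⁴ px) reproduce the
low-contrast confusability of foot processes; a linear illumination ramp
(default 10 gray levels peak-to-peak) and additive Gaussian noise (default
σ = 6) are applied last, clipped to [0, 255]. Degenerate geometry is
retried a bounded number of times, then raises. Identical spec + seed gives
bit-identical output.

What it does *not* model: real organelle texture and membranes' internal
lamina, immune deposits, membrane fractures, staining artifacts, or the
actual noise spectrum of a TEM camera. Passing tests therefore demonstrate
the pipeline's mechanics and its grayscale-stratification behavior, not
clinical accuracy.

## Benchmark problem sizes

The generalization benchmark (`run_benchmark`) uses a scaled-down study:
5 grayscale bins of width 14 spanning membrane means 75–145, 3 training
images per bin, M = 500, T = 25, D = 9, 100×140 px frames, feature scales
{1, 2, 4}, and 10 test images (2 per bin, fresh seeds). These sizes keep a
full train-and-evaluate cycle around ten seconds on one CPU while
preserving the phenomenon under study: forests are grayscale-local, the
pooled forest is not.

## Numerical and design choices

- Seeds: every stochastic step derives a child seed from the master via
  `numpy.random.SeedSequence` (kept below 2³¹), so runs replay
  bit-identically; model archives are versioned and refuse mismatched
  format versions.
- Vote tie at exactly 0.5 → background; 8-connectivity for components;
  0-based row-major coordinates.
- Balanced sampling (⌈M/2⌉ membrane, ⌊M/2⌋ background, without
  replacement) is the default: the membrane covers a small area fraction
  and proportional sampling under-represents it; a too-small class falls
  back to proportional with a warning.
- Grayscale bins use width 2 from 73.5 (the configuration consistent with
  the published bin boundaries); both start and width are configurable.
- The refinement's w₁ ranking (mean pairwise Jaccard) and its stopping
  rules are this package's reconstruction of a procedure whose published
  description is schematic; the reconstruction is pinned down by a
  brute-force re-enactment test on tiny inputs.

## Known limitations

- With a small zoom bank (N = 5 in the benchmark), forests trained on
  brighter bins can "flood" darker test images (label nearly every pixel
  membrane), because absolute-intensity features extrapolate out of range.
  One or two floods among five coarse results can poison the first
  consensus, and the w₂ filter then sometimes retains a flooding result
  while dropping a good one — so iterative refinement is roughly neutral
  on average at this bank size (it helps on some images and hurts on
  others), while the FCM step itself is a large, consistent gain over
  plain voting. A large bank dilutes floods; the full-view candidate R₁ is
  unaffected either way, which is the method's rationale for emitting both
  candidates.
- The zoom-view path can fail outright (Jaccard ≈ 0) on images where most
  coarse results are poor; this is a property of the method, not a defect
  of the implementation.
- Segmentation quality numbers here come from synthetic images and are not
  comparable to clinical accuracy figures.
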