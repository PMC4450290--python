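# Methods

## The segmentation model

`asymseg` segments skull-stripped, bias-corrected T1-weighted brain MR
volumes into CSF, gray matter and white matter.  The intensity histogram
of such a volume is modelled as a three-component mixture, but — unlike
the classical Gaussian-mixture EM — each component is an *asymmetric*
Gaussian with independent flank widths:

    A(z; μ, σ², r) = √(2/π) / (σ(1+r)) · { exp(−(z−μ)²/(2σ²))      z > μ
                                         { exp(−(z−μ)²/(2r²σ²))    z ≤ μ

σ ("first-side" SD) governs the right flank (z > μ), and the left-flank
SD is r·σ.  r = 1 recovers the symmetric Gaussian.  The normaliser
√(2/π)/(σ(1+r)) is the unique constant that makes the two-branch density
integrate to one for any r > 0 (the right half-integral is σ√(π/2), the
left rσ√(π/2)); we verify this by quadrature in the test suite.  The
motivation is empirical: tissue intensity distributions on real T1 images
are skewed — CSF especially spreads across the low end of the histogram —
so a symmetric fit misestimates one flank and the class boundary with it.

Useful closed forms (used in tests): the right lobe carries mass 1/(1+r)
and is half-normal with scale σ; the left lobe carries r/(1+r) with scale
rσ; the mean is μ + σ√(2/π)(1−r), so r > 1 shifts mass left of the mode
and produces negative skewness.

## Fitting procedure

1. **Histogram.** Foreground intensities (nonzero voxels of the
   skull-stripped volume) are binned into 256 equal-width bins — the
   8-bit convention; the method treats intensity as discrete histogram
   positions and 256 bins keeps the error criterion stable.
2. **Mode splitting.** The counts are smoothed with a centered moving
   average (window 5 bins) and cut at interior local minima — bins where
   the first finite difference changes sign from negative to positive
   with upward concavity, flat runs collapsing to their central bin.
   When noise produces more than two candidate minima, the two kept are
   those separating the three most prominent peaks (scipy peak
   prominence).  The three modes are CSF, GM, WM in increasing-intensity
   order (T1 convention).
3. **Per-mode location and right-flank scale.**  μ is initialised at the
   peak of the smoothed mode counts — the asymmetric density is maximal
   exactly at μ, so the peak locates it without the offset σ√(2/π)(1−r)
   that a symmetric moment fit acquires on skewed data (about 10
   intensity units at r = 2.5, σ = 8, far too large for reliable class
   boundaries).  σ_first is the right-flank conditional RMS deviation,
   which is exactly σ for the model's half-normal right branch.  Because
   the discrete smoothed peak can sit up to about a bin away from the
   density maximum, μ is then refined on a half-bin grid (±2 bins around
   the peak), scoring every candidate by the same fit error that drives
   the r search and keeping the best.  A symmetric single-component EM
   fit of the mode is *not* used for μ: its estimate is the mode's sample
   mean, which the skew displaces systematically.  (The classical
   mixture EM — Gaussian densities, posterior E-step, weighted-moment
   M-step, monotone likelihood ascent — is implemented in full in
   `asymseg.em` and serves as the symmetric baseline segmentation.)
4. **Asymmetry search.**  With (μ, σ_first) fixed, r starts at 1 and
   moves in multiplicative 10% steps; if the first upward step increases
   the error, the search reverses to factors of 1/1.1.  Each candidate
   is scored by the mean absolute per-bin count difference
   (1/N)Σ|f_i − g_i| between the observed mode counts f and the model
   counts g (mode total × bin-midpoint density × bin width).  Absolute
   differences are used because signed ones cancel and make the
   criterion useless.  The search stops when the error falls below a
   threshold, after two consecutive error increases, or at the bounds
   r ∈ [0.2, 5]; the r of minimum observed error is kept, so the fit is
   never worse than the symmetric start.  The stopping threshold is
   0.05 × RMS of the mode's counts — scale-invariant and small relative
   to signal; it, the step, and the bounds are all configurable.
5. **Weights.** Component weights are the mode count fractions.

## Labeling, overlap detection, refinement

Membership probabilities are Bayes posteriors with the asymmetric
densities (computed in log space); voxels take the argmax class, ties
going to the lowest class index.  Optional region growing propagates
labels breadth-first from high-confidence seeds (max posterior ≥ 0.95)
through 26-connected neighbors; a neighbor confident in its own class
(≥ 0.5) keeps it, a low-confidence neighbor inherits from the voxel that
reached it; each voxel is visited once.

Voxels whose maximum posterior falls below τ = 0.9 form the **overlap
mask** — the intensity-ambiguous voxels, concentrated where adjacent
class densities cross.  The **target area** for texture analysis is the
overlap voxels plus their 18-connected neighbors.

For refinement, 3-D gray-level co-occurrence matrices are computed in a
21×21×21 window around each voxel of interest, for distances d = 1..5
and the 13 unique 3-D directions, on intensities quantized to N_g = 32
equal-width levels (a compromise between GLCM sparsity in the window and
discrimination; configurable).  Accumulation is symmetric (pair +
reverse), the standard Haralick practice; windows are clipped at volume
edges; background (level 0) never participates in pairs.  Each GLCM
yields the canonical Haralick-13 descriptors (log base 2, 0·log 0 = 0;
the sum-variance center is the sum average; correlation and
information-correlation guards return 0 for degenerate marginals);
per-feature mean and *population* standard deviation across the 13
directions give 26 values per distance, 130 per VOI.

Stepwise discriminant analysis (forward partial-F entry at 3.84,
backward removal below 2.71 — conventional defaults — capped at 20
features) reduces the 130 features; one-against-the-rest soft-margin
SVMs (RBF kernel, C = 100, γ = 1/(n_features × mean feature variance)
after standardisation) are trained on a stratified sample — half
confident non-overlap voxels, half overlap voxels carrying their current
argmax label, with a 5% per-class floor — and every overlap voxel is
reassigned to the class with the largest decision value.  Non-overlap
voxels are never modified, so a clean volume with an empty overlap mask
passes the refinement unchanged.  Laplacian and χ² kernels are exposed
as configuration hooks only.

## Evaluation

Per-tissue agreement uses the Jaccard index J = |S1∩S2|/|S1∪S2| and the
Kappa (Dice) index k = |S1∩S2|/(½(|S1|+|S2|)), both in percent, related
by k = 2J/(J+1); the identity is verified internally to 1e−9 on every
report.  Both sets empty counts as 100, exactly one empty as 0.  CSF
agreement on expert-labeled real data is conventionally not comparable
across datasets; reporting code should flag it, and the library computes
it regardless.

## The phantom generator

The generator replaces external simulated/real brain databases with
ground-truthed volumes that have exactly the statistical structure the
method assumes:

* **Geometry** — three nested ellipsoid shells on a zero background
  (CSF outer shell, GM middle, WM core), default 64³ grid.  This gives
  genuine 3-D tissue borders for the overlap/SVM stages without
  anatomical realism; the ground-truth label map is exact by
  construction.
* **Intensities** — per-voxel i.i.d. draws from that voxel's class
  density.  Defaults emulate T1 contrast on a 0–255 scale:
  CSF (μ=40, σ=6, r=2.0 — the heavy low-side tail of CSF), GM (105, 6,
  1.3), WM (170, 6, 1.2).
* **Noise** — Rician: √((signal+g₁)² + g₂²) with independent zero-mean
  Gaussians of scale noise_sigma × WM mean; 0–0.09 covers the usual
  0–9% percent-noise settings of simulated databases.  Background stays
  exactly zero.
* **Bias field** — optional multiplicative degree-2 polynomial in
  (x, y, z) with random coefficients, scaled to a chosen peak fractional
  deviation and renormalised to mean 1 (the 0.2/0.4 settings mirror
  common 20%/40% inhomogeneity conditions).

What the phantom deliberately does **not** model: anatomy, partial-volume
mixing at borders, spatially correlated noise, or intensity
nonstationarity beyond the smooth bias.  Consequences for interpreting
results: because intensities are i.i.d. within a class, low-confidence
(overlap) voxels are intensity-tail draws spread through class
interiors rather than concentrated at geometric borders, and
segmentation accuracy on the phantom is substantially higher than on
real brains at the same noise level.  Passing phantom tests demonstrates
the correctness of the machinery and the internal consistency of the
model, not clinical-grade accuracy.

## Numerical and design choices

* Histogram fitting operates on binned counts as frequency weights, not
  raw voxels — equivalent up to binning and far faster at megavoxel
  scale.
* EM (baseline): deterministic K-quantile initialisation, relative
  log-likelihood tolerance 1e−6, 500 iteration cap (flagged, not
  raised), variance floored at one bin width squared; empty classes are
  floored, never silently dropped.
* All argmax tie-breaks go to the lowest class index, everywhere.
* Empty GLCMs (no valid pairs in a clipped window) are excluded from the
  direction aggregation; a distance with none contributes zeros.  A VOI
  whose window is entirely background raises; in the pipeline such
  voxels keep their EM label and are logged.
* All randomness flows from one master seed expanded into per-stage
  seeds (`numpy` SeedSequence), making the whole pipeline reproducible.
* Problem sizes: tests and the acceptance script run on 64³ phantoms
  (≈73k foreground voxels) with a 2,000-voxel training sample for the
  refinement SVM — ample for three classes in a ≤20-dimensional selected
  feature space at this grid size; the per-volume budget of 10,000
  samples remains the default for full-resolution brains.

## Known limitations

* The mode splitter requires three separable histogram modes; heavily
  overlapped or pathological histograms raise an "insufficient modes"
  error advising stronger smoothing rather than guessing.
* The r search is one-dimensional per mode with μ and σ fixed; it is not
  a joint maximum-likelihood fit, and strongly truncated modes (cut
  points deep inside a flank) bias r slightly toward symmetry.
* Quantization to 32 levels bounds texture resolution; very low-contrast
  volumes may need a finer setting.
* No spatial prior (MRF) and no partial-volume model; voxels are
  classified on intensity and local texture only.
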