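# Methods

This note documents the models, estimators and design choices behind
`thermocad`, in the spirit of a statistical-software methods appendix: what
each stage assumes, which knobs matter, and what the synthetic benchmark does
and does not demonstrate.

## The pipeline

A thermogram is a 2-D map of emitted heat.  Tumours run hotter than the
surrounding tissue (elevated metabolism, angiogenesis), so the diagnostic
signal lives in the hottest segmented region: its *shape* (boundary
irregularity), its *texture* (spatial gray-level statistics) and the
*complexity* of its intensity pattern.  The pipeline is

1. Otsu foreground thresholding and HSI pseudo-coloring;
2. fuzzy c-means (FCM) clustering of the (hue, saturation, intensity)
   triple; the cluster with the highest mean source intensity is the region
   of interest (ROI);
3. 21 GLCM texture descriptors + 4 chaotic indices per image (25 features);
4. wrapper feature selection (NSGA-III; GA/PSO/DE baselines);
5. five classifiers under stratified 10-fold cross-validation.

## Segmentation

**Otsu.** Exhaustive scan of the intensity histogram (256 bins for 8-bit
input, 1024 otherwise) for the threshold maximizing between-class variance;
ties go to the smallest threshold.  A constant image has no between-class
structure and is rejected.

**FCM.** Canonical fuzzy c-means with fuzziness exponent m = 2 and k = 4
clusters by default: memberships u_ij = 1/Σ_l (d_ij/d_lj)^{2/(m−1)}, centers
as u^m-weighted means, iterated until the largest center shift < 1e−5 (cap
300 iterations).  Initialization is seeded k-means++-style spreading, so runs
are reproducible.  The weighted objective Σ u^m d² is recorded every
iteration and asserted non-increasing.

**Scale separation.** Clustering runs on a Gaussian-smoothed copy of the
image (σ = 4 px): lesions carry fine internal texture, and without smoothing
the hot region fragments across intensity clusters.  The coarse mask is then
consolidated (closing + hole filling) and its boundary *refined on the raw
pixels*: Otsu re-thresholding inside a dilated neighbourhood of the coarse
mask, keeping the largest connected component.  Coarse localization tolerates
texture; refinement restores the true outline, which matters because the
boundary's fractal dimension is itself a feature.  Axilla/sternum exclusion
bands (top fraction of the torso box, central vertical band) are available
and default to off for phantoms, which have no axillae.

## Texture features

The GLCM is the normalized joint histogram of gray-level pairs at offset
(distance, angle).  Defaults: 16 equal-width levels over the ROI min–max,
distance 1, the four directions 0°/45°/90°/135°, symmetric counting,
descriptors averaged over directions.  Non-rectangular ROIs are handled with
a sentinel background level whose row/column are discarded before
normalization, so pairs that cross the ROI boundary never contribute.

All 21 descriptors are computed from the normalized matrix with the standard
Haralick / Soh–Tsatsoulis / Clausi formulas.  Naming notes: `homogeneity` is
Σ P/(1+|i−j|), `idm` the classic inverse difference moment Σ P/(1+(i−j)²),
`idn` and `inn` their Clausi-normalized variants (dividing |i−j| by L and
(i−j)² by L²).  Degenerate matrices (zero marginal variance, e.g. a constant
ROI) report correlation 1 and information measures 0 — the
perfectly-predictable limit.  Sum variance is centred on the sum average.
A Daubechies-4 level-1 wavelet variant (periodization mode, so constants stay
constant) computes the same descriptors on the approximation band; raw-ROI
descriptors are the default feature path.

## Chaotic indices

**Serialization.** The ROI gray levels are read in a deterministic scan
order (row-major default; column-major and Hilbert-curve orders available)
into a 1-D sequence of length = ROI pixel count.

**Box-counting dimension (FD).** Occupied-box counts N(s) on grids anchored
at the bounding-box corner, box sizes powers of two from 2 up to half the
larger bounding-box extent; D is the least-squares slope of log N(s) against
log(1/s).  The estimator is exact on the calibration sets: Sierpinski
triangle (3^d pixels, D = log 3/log 2), one-pixel line (D = 1), filled square
(D = 2).  The per-image feature applies it to the **ROI boundary curve**
(mask minus its erosion): a boundary dimension lives on the [1, 2) scale that
reported lesion FDs occupy, and it responds monotonically to outline
irregularity, which the dimension of a filled region (≈2 regardless) does
not.  `fd_on="filled"` switches to the boundary-plus-interior set.

**Time-delay embedding.** Delay τ by the first minimum of the auto mutual
information, guarded by the autocorrelation 1/e time (a strongly chaotic map
loses memory in one step; its MI curve decays into a noise floor whose
wiggles are not real minima).  Dimension m by false nearest neighbours
(< 5 % at tolerance 15, capped at 10).  Theiler window m·τ throughout.  The
cohort feature path fixes (m, τ) = (3, 2) so the LLE/CD columns are
comparable across images; the automatic path is used for standalone series.

**Largest Lyapunov exponent (Jacobian method).** At each orbit point a local
linear map is fitted by least squares over its k ≈ 2m+4 nearest neighbours
(Theiler-excluded).  The fit is performed *in the local tangent frame*: the
SVD of the neighbour displacement matrix gives the directions the data
actually explores (singular values above 5 % of the leading one), and the map
is estimated between consecutive frames.  The leading growth vector is
propagated through the chain with renormalization at every step (the
one-column QR product); λ₁ is the mean log growth.  The tangent-frame
restriction is what keeps the estimator well-posed on thin attractors: a
noise-free sine fills a 1-D curve inside the 2-D embedding, and a full-space
fit there is rank-deficient — its spurious normal-direction components bias
λ₁ by ±0.2–0.6.  Calibration: logistic map r = 4 gives 0.6930 (exact ln 2 =
0.6931), sine gives −0.0001 (exact 0), Hénon gives 0.423 (literature 0.419).
A constant series is degenerate and reports 0 with a warning.

**KS entropy.** Sample-entropy form −ln(C_{m+1}(r)/C_m(r)) with Chebyshev
template matching, self-matches excluded, both template lengths sharing the
same N − m starting points (so a constant series gives exactly 0).  Defaults
m = 2, r = 0.2·SD, which also makes the estimate invariant under affine
rescaling of the series.  Verified to 1e−12 against direct O(N²)
enumeration.

**Correlation dimension.** C(r) = fraction of Theiler-excluded point pairs
closer than r; CD is the slope of log C over log r on radii log-spaced
between the 0.5th and 10th percentile of pairwise distances.  The scaling
region sits deliberately at small radii: for a uniform square the correlation
integral πr² − 8r³/3 + r⁴/2 bends well below slope 2 once r reaches the
median inter-point distance, so mid-range radii systematically underestimate
the dimension.  A fit with R² < 0.98 warns.  Point clouds larger than
`max_points` are strided down before the O(N²) pair count.

## Phantom generator

The generator defines the study conditions; its defaults are fixed, not
tuned per experiment.  A phantom is a 128×128 8-bit image: cold background
(30), warm torso ellipse (120) with two smooth breast mounds (+25), and one
elliptical hot spot (mean 205) whose

- **boundary** is a circle perturbed by Fourier modes 2–40 with a 1/k^0.6
  amplitude spectrum scaled by `boundary_roughness` ∈ [0, 1].  The
  multi-scale spectrum is essential: a low-order-only perturbation is a
  smooth curve of box dimension 1 at any amplitude, whereas broadband
  roughness raises the measured boundary dimension monotonically
  (≈0.98 → ≈1.14 over roughness 0.1 → 0.55 on ground-truth masks);
- **interior texture** is a seeded Gaussian random field with correlation
  length `texture_corr_len`, scaled by `texture_contrast` gray levels, plus
  i.i.d. noise of `noise_sd`.

Class defaults (jittered per image so the classes overlap): benign roughness
0.18, correlation length 5 px, contrast 12, noise 1.5; malignant 0.55 /
2.2 px / 22 / 4.0.  The noise difference is deliberate: entropy estimators
with r ∝ SD respond to *relative* disorder, and with equal absolute noise the
weaker benign texture field would be relatively noisier, inverting the
intended entropy direction.  With these conditions, over ≥50 phantoms per
class, malignant phantoms score higher boundary FD, KS entropy, GLCM
contrast/entropy/dissimilarity (rank-test p < 0.01), and combining both
feature families beats either alone under cross-validation.

What the phantoms do **not** emulate: bioheat (Pennes) physics, camera noise
models and calibration drift, patient-to-patient anatomy, multi-view
acquisition, and axillary/sternal hot structures.  Passing the phantom
benchmark therefore demonstrates that the pipeline recovers planted,
class-consistent structure of the kind reported for clinical cohorts — not
clinical performance.  Reference series (logistic, Hénon, sine, noise) and
binary sets (Sierpinski, line, square) provide closed-form oracles for the
estimators; the sine's default period is 128/π, incommensurate with the
sampling grid, because an integer period yields finitely many distinct delay
vectors and degenerates any neighbour-based estimator.

## Feature selection

Fitness of a subset = misclassification rate of KNN (k = 5) under a seeded
stratified 5-fold inner CV on the standardized table (cached per genome);
the subset-size objective is |subset|/d.  An empty genome is repaired to the
best univariate feature (largest |t|) rather than penalized, keeping both
objectives in [0, 1].

- **NSGA-III** (population 30, 20 generations): random parent selection,
  uniform crossover (2·round(0.7·30/2) offspring), bit-flip mutants
  (round(0.4·30) of them, rate 0.1 per bit); environmental selection by
  non-dominated sorting plus reference-point niching (Das–Dennis points,
  ~one per population slot) on ideal/nadir-normalized objectives.
- **GA** (population 30): roulette selection with exponential pressure 8,
  uniform crossover p_c = 0.8, mutants p_m = 0.3 at per-bit rate 0.02,
  elitist merge-and-truncate (best J non-increasing by construction).
- **PSO** (swarm 20): continuous positions in [0, 1]^d thresholded at 0.5,
  inertia 1 damped ×0.99 per iteration, c₁ = c₂ = 2, velocity clamp 0.5.
- **DE** (population 20): rand/1/bin with scale factor U(0.2, 0.8) per
  component, crossover probability 0.2, greedy replacement.

Single-objective methods minimize J = error + w·nf_frac with w = 0.01 — small
enough that J is dominated by error, large enough to break ties toward
smaller subsets.  All methods are bit-reproducible for a fixed seed and also
report the non-dominated front of everything they evaluated.

The error-versus-subset-size curve takes, for each size k on the Pareto set,
the best error among subsets of that size; the **elbow** is the smallest k
whose marginal error decrease per additional feature drops to ε = 0.01
(i.e. past it, an extra feature buys less than one inner-CV percentage
point).  On planted tables (3 informative features at effect size d = 2 among
17 noise columns, n = 200) the scalar-best subset contains all three
informative features in 10/10 seeds and the elbow averages ≈3.6.

## Classification and evaluation

Features are standardized on training-fold statistics only; the selection
fitness uses its own inner CV — the label-shuffle control (≈50 % accuracy)
is the regression test that no statistic leaks across folds.

- **SVM**: soft-margin RBF machine, C = 1, kernel width σ = median pairwise
  training distance (gamma = 1/2σ²).
- **KNN**: majority of the 5 nearest Euclidean neighbours; voting ties break
  by total inverse neighbour distance.
- **Pseudoquadratic discriminant**: per-class Gaussians with Moore–Penrose
  pseudo-inverted covariances and pseudo-log-determinants (product of
  non-null eigenvalues), robust to singular covariances on small folds.
- **Pattern net / fitting net**: one hidden layer of 10 tanh units;
  pattern net has 2 outputs trained on one-hot targets (argmax decision),
  fitting net a single output thresholded at 0.5.  Both minimize sum-squared
  error by Levenberg–Marquardt with an analytic Jacobian: λ starts at 1e−3,
  ×10 on rejection / ÷10 on acceptance, at most 200 accepted steps, stopping
  early on a vanishing gradient; if damping overflows, best-so-far weights
  are kept with a warning.  Weight initialization is seeded.

Folds are stratified (class ratios within one sample per fold).  Metrics are
computed per fold and averaged (zero-denominator folds excluded with a
warning); pooled confusion counts are reported alongside.  The positive
class is malignant/sick.  A 70/30 stratified holdout mode exists for
comparison; 10-fold CV is the headline protocol.

## Problem sizes

The shipped benchmark uses 100 phantoms per class (128×128 px, lesion radius
15–21 px, ROI ≈ 700–1700 px), five CV seeds, and 10 selection seeds for the
planted-recovery experiment; the full test suite and the acceptance script
each run in a few minutes on one CPU.  These sizes give rank tests and CV
accuracies stable to ~1–2 percentage points; scaling n_per_class up tightens
them further but changes no direction.

## Known limitations

- FCM clusters on (h, s, i), which for a grayscale source is a monotone
  transform of intensity — the pseudo-color step matters for visualization
  and for hue-based exclusion rules, less for clustering power.
- The LLE of short raster-scan sequences (< ~500 samples) is a rough
  complexity score, not a converged dynamical invariant; the cohort feature
  path accepts shorter ROIs deliberately.
- The correlation dimension of high-entropy image series saturates near the
  embedding dimension; it remains discriminative as a feature but should not
  be read as an attractor dimension.
- Hilbert-order serialization requires padding to a power-of-two grid; ROI
  pixels keep their curve order, but locality at the pad boundary is
  imperfect.
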