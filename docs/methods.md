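# Methods

## Model

The package treats a nonlinear embedding as a regression target. Given a
data matrix `X ∈ ℝ^{n×p}` (nonnegative intensities; pixels × m/z channels,
loci × genomic bins, samples × transcripts), a subset `S` of the rows is
embedded with a reference method and the mapping is then *learned*:

1. **Subsampling.** Deterministic every-*n*-th selection starting at index 0
   (count = ⌈n/step⌉), or a seeded uniform random subset. Every-*n*-th is the
   default for raster data because it preserves spatial coverage.
2. **Reference embedding.** Exact-gradient t-SNE (no Barnes–Hut
   approximation) with perplexity 30, early exaggeration 4, or UMAP with 30
   nearest neighbors and minimum distance 0.3; both use the correlation
   distance `1 − ρ(x_i, x_j)` between sample vectors and 3 output dimensions
   by default (2 supported). Coordinates are min–max normalized to the unit
   cube per dimension; a zero-range dimension maps to the constant 0 and is
   flagged non-invertible. The unit cube is what makes corner queries
   ([1 0 0] = red, etc.) and RGB rendering well-defined.
3. **Surrogate networks.** Feed-forward regressors (default two tanh hidden
   layers of 128 and 64 units, linear output) trained on the subset:
   forward (features → coordinates), inverse (coordinates → features), or
   cross (modality-A features → modality-B coordinates, aligned by explicit
   sample-id pairing). Inputs are z-scored and targets min–max scaled with
   statistics of the *training split only*; the constants are stored in the
   fitted map and reapplied at prediction time.

### Training procedure

The subset is split 70/15/15 into training/test/validation (sizes within
one sample of the exact fractions, seeded permutation). Optimization is
Adam (learning rate 1e-3, minibatch 64) for at most 1000 epochs with early
stopping: training stops when the validation MSE has not improved by a
relative 1e-5 for 60 consecutive epochs, and the best-validation-epoch
weights are restored. Regularization is an L2 weight penalty whose strength
is, by default, selected from the grid {1e-4, 1e-2, 1} by validation loss.
This mirrors what evidence-based Bayesian regularization does — adapt the
shrinkage to the problem — and matters in practice: large imaging subsets
want weak decay, while small matched-cohort cross maps (≈10² pairs against
10²–10³ features) overfit badly without strong decay. If the best
validation MSE never beats a constant (training-mean) predictor, the fit
warns that the map is uninformative.

Diagnostics stored on the results object: per-output-dimension r² (squared
Pearson correlation) on the train/test/validation splits, and for inverse
maps additionally the per-held-out-sample r² between each true spectrum and
its reconstruction (mean and minimum). The headline fidelity statistic is
the *minimum* per-dimension test r² for the forward map (conservative
aggregate) and the *mean* per-spectrum reconstruction r² for the inverse
map. A per-feature minimum is deliberately not used for the inverse
direction: with hundreds of channels it is an extreme order statistic
dominated by the least informative channel, not a summary of
reconstruction quality.

### Determinism

Predictions are computed in fixed 512-row tiles, padded to full tile size,
because BLAS matrix products are not bitwise reproducible across batch
shapes. This makes a fitted map's output a pure function of each input row:
chunked streaming over arbitrarily large data (`chunk_size` is rounded to a
tile multiple) is bit-identical to whole-matrix evaluation. The t-SNE and
UMAP backends, data splits, and generators are all seeded.

## Downstream operations

* **Pseudo-spectra.** `reverse_query` evaluates the inverse map at any point
  of the unit cube (warning outside [−0.5, 1.5]ᵈ); contributions are signed.
  `centroid_spectrum` queries at the mean coordinate of a sample mask.
  `rank_drivers` orders features by |contribution| (ties broken by ascending
  m/z); `ppm_match` annotates a driver mass against a user-supplied table at
  a ppm tolerance (default 5 ppm), with signed error `(m_table − m_query)/
  m_query · 10⁶`. No database ships with the package.
* **Rendering and segmentation.** A normalized 3-D embedding renders with
  coordinates as RGB channels (reading a sample's pixel recovers its
  coordinates exactly; empty raster cells are black); 2-D embeddings use a
  bilinear four-corner color square (blue/red/green/yellow). Segmentation is
  by closed axis-aligned boxes in embedding space.
* **Novelty flagging.** Primary score: Euclidean distance from a projected
  sample to its k-th nearest (default k=10) training embedding point;
  secondary: correlation distance between a spectrum and its round-trip
  reconstruction `g(f(x))`. The threshold is an empirical quantile (default
  0.99, linear-interpolation estimator) of the training set's leave-self-out
  k-NN distances.
* **Classification.** Leave-one-out LDA on reduced coordinates, closed form,
  with pooled within-class covariance ridged by `ε·I`, `ε = 10⁻⁶·trace/d`,
  and priors proportional to class frequency. Partition agreement is the
  plain (unadjusted) Rand index.
* **Hi-C binning.** 3-column contact lists (`pos1 pos2 count`, 0-based
  bin-start coordinates) are additively binned with floor division into an
  asymmetric matrix — fine rows (default 1 kb, the samples) × coarse columns
  (default 50 kb, the features). Mirroring (on by default, for
  intrachromosomal upper-triangle lists) adds each off-diagonal contact at
  the transposed position; exact-diagonal records are added once. Fully zero
  rows and columns are removed with surviving indices reported. Counts stay
  un-normalized.
* **Spectra preprocessing.** imzML pixels (continuous or processed mode) are
  aggregated onto caller-supplied m/z bin edges; `rebin_spectrum` does
  interpolated rebinning onto a uniform grid (default 0.002 Da); ion images
  integrate intensities over a peak window per pixel.

## Synthetic data

Three generators emulate the statistical structure of the real inputs; all
are pure functions of their spec and seeds.

**MSI-like images.** Contiguous vertical-stripe regions on a raster. Region
mean spectra are a shared log-normal base spectrum (σ = 1) modulated
per-region (σ = 0.6); each region has one planted marker feature uniquely
elevated 8-fold (and suppressed 10-fold elsewhere). Within regions, smooth
spatial gradients (per-region log-normal loadings, σ = 0.4, linear in
raster position) emulate the intensity gradients of real tissue sections;
they are what gives the embedding learnable within-region structure —
without them the within-cluster arrangement of a t-SNE is a pure function
of independent pixel noise and no surrogate could reproduce it. Pixel noise
is multiplicative log-normal (σ = 0.15) plus an additive Gaussian floor (2%
of the median intensity), clipped at zero — a standard caricature of MS
intensity noise; it has no heteroscedastic detector model, peak shapes,
isotopes or chemical baseline, so passing tests show surrogate fidelity on
clustered spectra, not robustness to real instrument artifacts. Structure
(means, markers, gradients) derives from the spec seed alone, so a
replicate "serial section" with a new noise seed shares its chemistry
exactly.

**Matched omics.** Two modalities share a latent class variable
(default 3 classes, n = 200). Class separability is specified as the
aggregate (whole-profile Mahalanobis) offset, independent of feature count:
modality B (transcriptomics-like, p = 2000) gets 20; modality A
(metabolomics-like, p = 300) gets 3 — present but weak — plus a rank-4
nuisance component of scale 8 emulating the dominant cell-line/batch
variation of real metabolic profiles. A's own embedding therefore organizes
by nuisance while a supervised projection into B's space recovers class,
which is the structural situation the cross map exists for. Latent Gaussian
profiles are exponentiated (×0.25) to nonnegative intensities.

**Outlier sets.** Clustered training data (4 clusters), an in-distribution
replicate, and a novel cluster whose mean is displaced from its parent
cluster by `offset` multiplicative-noise standard deviations per feature on
the log scale — offset 0 is statistically indistinguishable from training
data, offset 5 is well separated.

## Problem sizes

The defaults of the MSI-like generator are 50,000 pixels × 500 features
(six regions). The benchmark script runs at 20,000 × 500 with an every-10th
subsample, i.e. exact t-SNE at n = 2,000 — chosen so the full from-scratch
pipeline completes in a few CPU-minutes while keeping the subset an order
of magnitude above the 3×perplexity floor. The test suite uses 6,000 × 300
with an every-5th subsample (n = 1,200) and, for the cross-omics and
novelty checks, cohorts of 200 and 1,500 samples. Fidelity is not
flattered by the smaller sizes: fewer training samples make the ≥ 0.95
held-out r² bar harder, not easier.

## Numerical choices and edge cases

* Correlation distance is undefined for zero-variance sample vectors; the
  embedding front-ends reject them rather than emit NaN.
* `embedding_r2` raises on zero-variance dimensions; per-dimension r² of
  constant *target* channels inside training diagnostics is recorded as NaN
  and excluded from summaries.
* Driver ranking resolves |contribution| ties by ascending m/z so rankings
  are total and reproducible.
* Quantile thresholds use numpy's linear-interpolation estimator.
* LDA argmax ties resolve to the first class in sorted label order.
* Delimited matrices are written with 17 significant digits and parsed with
  round-trip float precision, so write→read is bit-exact.

## Known limitations

* The surrogate reproduces the reference embedding's *geometry*; it inherits
  any distortion the reference method introduced. Fidelity r² is measured
  against the reference, not against a ground-truth manifold.
* Forward-map generalization depends on the new data lying in the training
  distribution; the novelty score exists precisely because extrapolated
  coordinates are unreliable.
* Inverse-map pseudo-spectra are relative contributions, not calibrated
  intensities, and may be negative.
* The exact t-SNE backend is O(n²) in the subset size; subsets much beyond
  a few thousand samples should use UMAP or accept long runtimes.
* Hi-C support covers un-normalized single-resolution contact lists, not
  KR/ICE normalization or genome-wide multi-chromosome assembly beyond
  caller-ordered concatenation.
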