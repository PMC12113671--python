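# Methods

## Problem

Freeze-damaged corn (maize) seeds germinate poorly, and damage is not
visible from the outside. Visible/near-infrared hyperspectral imaging
(400–1000 nm) of single kernels, followed by chemometric classification
into three severity categories (1 = normal/unfrozen, 2 = slightly frozen,
3 = severely frozen), provides a nondestructive screen. The two faces of a
kernel behave differently: the embryo (germ) face holds the metabolically
active tissue and responds to freezing more strongly than the starchy
endosperm face, so the package treats the imaged side as an explicit
experimental factor.

## Pipeline

1. **Reflectance calibration.** Raw counts are converted to relative
   reflectance with dark-current and white-reference cubes,
   `I = (I_o − I_B) / (I_W − I_B)`. The division cancels both sensor dark
   current and spatial non-uniformity of the line light. A zero
   white-minus-dark denominator aborts by default (an option masks such
   voxels as NaN instead); silent NaN propagation would corrupt downstream
   mean spectra.
2. **Waveband trimming.** The detector's extreme bands are noisy; on a
   477-band 400–1000 nm grid the conventional cut keeps 1-based bands
   36–455, i.e. 420 bands spanning roughly 450–979 nm. Band indexing
   presented to users is 1-based inclusive (the only convention under
   which 455 − 36 + 1 = 420); storage is 0-based half-open. Because the
   instrument's exact band centers are not published, emulated grids use
   477 evenly spaced centers, and trimming by wavelength window
   (450 ≤ λ ≤ 979) is offered alongside index trimming and is the CLI
   default.
3. **Segmentation.** Seeds lie on a dark background. One gray band
   (700 nm endosperm face, 500 nm embryo face; configurable — the pairing
   of band to face is a convention, not a physical necessity), a 1–99
   percentile linear contrast stretch, Otsu's 256-bin threshold, and
   8-connected components with a 50-px minimum area yield per-seed masks;
   the strictly monotone stretch cannot move Otsu's class partition.
   Per-seed spectra are arithmetic pixel means.
4. **Preprocessing arms.** `none`, SNV (per-spectrum standardization with
   sample sd, removing multiplicative scatter and additive baseline), and
   5-3 smoothing (Savitzky–Golay, 5-point window, 3rd-order polynomial,
   one pass, polynomial-evaluated boundaries). Both are row-local, so they
   cannot leak information across the train/test split. The smoothing pass
   count is exposed as a knob defaulting to 1; repeated application of a
   5-point smoother hundreds of times would flatten all absorption
   structure and is never useful on 420-band spectra.
5. **Wavelength selection** (always on the training partition only):
   * *SPA* — successive projections. From a start band, each step appends
     the band whose mean-centered column has the largest norm after
     orthogonal projection onto the complement of the selected set
     (Gram–Schmidt deflation), minimizing collinearity. Candidate subsets
     are every start band × every chain length 1–20; they are scored by
     unshuffled stratified 5-fold cross-validated misclassification of an
     LDA, minimum wins, ties toward smaller subsets then smaller start
     index. The CV criterion and tie-break are this package's choices; the
     1–20 size range is the method's convention.
   * *2DCOS* — two-dimensional correlation spectroscopy with freeze
     severity as the external perturbation. The perturbation series is the
     three class-mean training spectra ordered normal → slight → severe;
     dynamic spectra are deviations from the series mean and the
     synchronous spectrum is their covariance, Φ = ỸᵀỸ/(m−1) (the 1/(m−1)
     normalization is conventional; any positive constant leaves peak
     positions unchanged). Selected wavelengths are local maxima of the
     diagonal autocorrelation curve with relative prominence ≥ 0.05 of the
     curve maximum (default; the threshold is a package choice — small
     published 2DCOS selections imply aggressive pruning of minor maxima).
   * *SPA+2DCOS fusion* — sorted de-duplicated union of the two sets,
     preserving per-wavelength provenance tags.
6. **Split and models.** Kennard–Stone max–min Euclidean selection run
   independently within each class, training target `round(n_c · 2/3)`:
   classes of 800/640/480 seeds give 533/427/320 training and 267/213/160
   testing samples. First pick is the mutually farthest pair; later picks
   maximize the minimum distance to the chosen set; ties break to the
   lowest row index, making the split fully deterministic. Classifiers:
   KNN (k = 5), LDA (2 discriminant components — full rank for three
   classes, so identical to the unrestricted LDA rule), SVM with RBF
   kernel (C = 10, gamma = 1/(n_bands · Var(X)), i.e. scikit-learn's
   "scale"). k, C and gamma are package defaults, overridable per run.
7. **Metrics** (percent, from a K×K confusion matrix with rows = actual):
   accuracy = 100·trace/N; per-class sensitivity (one-vs-rest recall)
   = 100·cm[c,c]/rowsum_c; chance accuracy
   `Accuracy_RND = 100·Σ_c rowsum_c·colsum_c / N²`, the expected accuracy
   of a classifier reproducing the predicted-class marginals at random;
   and the skill score accuracy − Accuracy_RND, whose ideal value for
   three balanced classes is 100 − 33.3 = 66.7. Display rounding is one
   decimal, ties to even; differences are taken between rounded terms.

## Synthetic data

No seed-image dataset is deposited, so the generator supplies the study
conditions for every test:

* **Grid**: 420 evenly spaced bands over 450–979 nm (477 over 400–1000 nm
  for trim tests). **Class sizes**: 800/640/480.
* **Class structure**: a smooth kernel-reflectance base curve (two broad
  Gaussian humps), a severity offset strictly increasing with damage
  (0/0.02/0.04 endosperm; 0/0.035/0.07 embryo — damaged seeds image
  brighter, the embryo face separates roughly twice as strongly), and four
  Gaussian damage features at 730/810/880/950 nm whose amplitude grows
  with severity (0.012 per class step endosperm, 0.022 embryo), so the
  class-dependent band response is concentrated in 700–979 nm.
* **Severity jitter**: each seed's true damage is its class index plus
  Gaussian jitter (0.32 class units endosperm, 0.26 embryo, truncated to
  the class range). Damage is a continuum that the categories bin, so
  boundary seeds genuinely overlap the neighboring class — this is what
  keeps the benchmark discriminative rather than saturated, produces the
  neighbor-class confusion pattern seen in real matrices, and makes the
  embryo side the easier task. Jitter magnitudes were calibrated once so
  full-scale default runs land test accuracies of roughly 88–94%
  (endosperm) and 94–98% (embryo).
* **Nuisance terms**: per-seed multiplicative gain U(0.85, 1.15) and
  additive baseline U(−0.03, 0.03) (so SNV has real work to do) and
  i.i.d. per-band Gaussian noise (sd 0.008). Draws are clipped to
  [0, 1.2].
* **Cubes**: seed ellipses painted into a dark scene
  (background reflectance 0.04) and re-embedded into counts as
  `raw = dark + R·(white − dark)` with optional lateral white-field
  gradient, so calibration inverts the construction exactly and noiseless
  scenes segment pixel-exactly.

What the generator does **not** emulate: within-seed texture and
morphology (each seed is spectrally homogeneous inside its ellipse),
touching kernels, specular glare, wavelength-correlated detector noise,
and any biophysical (Kubelka–Munk) light-transport model. Passing tests
therefore demonstrate correctness of the algorithms and sane behavior
under scatter/noise/label-overlap — not performance on real seed images.

## Numerical choices and caveats

* All selection and model fitting is deterministic given the RNG seed;
  CV folds are unshuffled; KS ties break to the lowest index; SPA ties
  break to smaller subsets.
* Otsu's threshold is computed on a 256-bin histogram. When the histogram
  has an empty gap between modes, any threshold inside the gap induces the
  same partition; tests compare achieved between-class variance, not the
  tie representative.
* **Stratified KS is not a valid basis for a label-permutation null.**
  Re-running the per-class KS split on permuted labels encodes label
  information into the split geometry (every test point acquires a
  same-class training representative nearby) and scores several points
  above chance even for pure-noise labels — measured +4.5 ± 0.8 points
  with LDA at n = 192, versus ≈ 0 with a random stratified split. The
  permutation-null test therefore fixes the split from the true design
  before permuting labels. Users comparing models against chance should
  do the same.
* Degenerate inputs raise typed errors: constant images (Otsu), constant
  spectra (SNV), fewer than 5 bands (smoothing), fewer than 2 series
  spectra (2DCOS), classes smaller than the fold count (SPA scoring),
  overlapping seed ellipses (layouts).

## Problem sizes used by the test suite

Stochastic suites run at reduced scale, chosen as a sensible benchmark
size for a laptop-class machine: 25 replicates of 144 seeds
(60/48/36) × 40 bands for the selection-and-classification recovery
properties, 50 replicates of 72 seeds × 25 bands for the permutation
null, and 100 replicates of 120 samples × 15 bands for SPA's
planted-band recovery. Exact worked-example checks (metrics, fusion
arithmetic, split counts) run at the benchmark's full printed sizes.

## Known limitations

* The SPA subset-scoring criterion (CV-LDA) is one reasonable choice; SPA
  variants scored by PLS/MLR RMSE exist and can select different subsets.
* With only m = 3 severity steps the synchronous 2DCOS spectrum has rank
  ≤ 2; its diagonal is a coarse variance summary, and peak positions are
  sensitive to the class-mean estimates at small n.
* Real acquisition effects (wavelength miscalibration, smile/keystone,
  detector nonlinearity) are out of scope; inputs are assumed calibrated
  to relative reflectance by the provided black/white correction.
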