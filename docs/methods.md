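# Methods

## Signal model and assumptions

The pipeline assumes each subject contributes, per MRI contrast, three
consecutive 2D tumor slices and binary tumor masks of the same shape. The
biological hypothesis it operationalizes: 1p/19q co-deleted gliomas keep a
consistent texture through the tumor volume, wildtype gliomas do not. All
stages are deterministic given the inputs and a seed; randomness enters only
through the phantom generator and the classifier's undersampling/fold
shuffling.

### Normalization

Intensities are z-scored over mask-foreground pixels only: with background
zeros included, the statistics would be dominated by the rectangle size
rather than tumor intensity. σ is the population standard deviation
(divide by the pixel count); the sample version is available via
`population=False`. Constant ROIs (σ = 0) and ROIs with fewer than two
foreground pixels are rejected rather than silently returned. The three
per-slice crops are zero-padded to the maximum bounding-box height and width
with centered placement. Centering is a choice — any fixed placement yields a
valid lag analysis — but it keeps the tumor near lag 0 where the
cross-correlation mass concentrates.

### Cross-correlation and VoCC

The full-lag cross-correlation uses zero padding outside the image support
("full" mode), computed by `scipy.signal.correlate`; a literal quadruple-loop
evaluation is kept in the package for verification and agrees with the FFT
path to ≤ 1e−10 on random inputs. The VoCC curve is the sample variance
(denominator = rows − 1, i.e. 2M−2) of each correlation column over the row
lags, indexed by column lag. The transposed variant (variance over column
lags per row lag) exists behind `transpose=True` but is not the default, as
the conventional curve is indexed by horizontal lag.

### Spectral stage

VoCC curves live on unit-spaced integer lags, so the Lomb–Scargle
periodogram coincides with the classical periodogram; the Lomb–Scargle form
is retained because it is the canonical estimator for this statistic and is
verified in the uniform limit against a DFT oracle. The curve is
mean-centered first — without centering the DC component swamps every other
feature of the spectrum. Power at each frequency equals half the fitted sum
of squares of the least-squares sinusoid at that frequency (the tau-shifted
Scargle statistic); the test suite enforces this identity directly.

The default frequency grid runs from 1/(oversample·T) to the Nyquist limit
0.5 cycles/lag in steps of 1/(oversample·T), with T the lag-axis span and
`oversample=4`. Oversampling fourfold is the standard compromise between peak
localization and cost for periodogram scans.

**First-peak exclusion.** Both classes share a dominant low-frequency peak
reflecting the smooth ROI envelope, so it carries no class information and is
removed: the cut falls just past the first interior local minimum that
follows the first local maximum of the inner-product spectrum (falling back
to the leading strictly-decreasing run when no interior minimum exists). The
cut index is located once, on the inner-product spectrum, and the same index
is applied to both pair periodograms — locating it independently per spectrum
could leave the three spectra on different grids and make the features
incomparable across subjects.

**Features.**

* *Difference energy* is |ΣP₁₂ − ΣP₂₃| normalized by ΣP₁₂ + ΣP₂₃. The raw
  absolute difference scales with the subject's overall VoCC magnitude (ROI
  size, texture energy), which says nothing about across-slice consistency;
  empirically the raw statistic fails to order the classes at all on phantom
  cohorts (rank-sum p ≈ 0.7) while the normalized form separates them at
  p < 1e−5. The raw variant remains available via
  `normalize_difference=False`.
* *Total volumetric energy* is the plain sum of the inner-product spectrum's
  power over retained grid points. No Δf weighting is applied: all spectra
  in a cohort share the grid construction, so the weighting would be a
  common constant.
* *Cutoff frequency* is the smallest frequency from which the inner-product
  power stays below ε·max(power), with ε = 0.01 ("nearly zero") by default
  and configurable; if the spectrum never settles below the threshold the
  largest grid frequency is returned.

Energies scale homogeneously under VoCC scaling (power ∝ k², volumetric
energy ∝ k⁴, normalized difference energy invariant) — frozen as a
regression test.

### RUSBoost

The classifier is the two-class AdaBoost.M2 scheme with random undersampling
before each weak fit:

1. initialize example weights to 1/n;
2. per round: undersample the majority class (without replacement) to the
   minority count, renormalize the restricted weights, fit the weak learner;
3. evaluate the pseudo-loss δₜ = ½ Σ wₖ (1 − hₜ(xₖ, yₖ) + hₜ(xₖ, ȳₖ)) on the
   **full** training set with the current weights, using the weak learner's
   class probabilities as h;
4. aₜ = δₜ/(1−δₜ); multiply each weight by aₜ^{½(1 + h(x,y) − h(x,ȳ))} and
   renormalize;
5. predict by argmax over classes of Σₜ log(1/aₜ)·hₜ(x, ·).

Choices the formulation leaves open, fixed here:

* weak learner: depth-2 `DecisionTreeClassifier` (configurable); deep enough
  for one interaction, weak enough to boost;
* δₜ ≥ 0.5: retry with a fresh undersample up to 5 times, then stop early and
  keep the ensemble built so far;
* δₜ = 0 (perfect weak hypothesis): aₜ floored at 1e−12 to keep the vote
  weight finite;
* a weak hypothesis constant on its balanced sample is skipped with a
  warning; an ensemble with no usable hypothesis is an error;
* exact vote ties break toward the minority class, consistent with the
  method's purpose of protecting it;
* every round's resampled class counts, pseudo-loss, and post-update weight
  sum are recorded on the model (`model.trace`) so the boosting contract is
  auditable.

Evaluation is stratified k-fold (default k = 10, shuffled, seeded) with one
pooled confusion matrix; precision/recall/F are reported per class, and
accuracy and rank-based AUC are reported as distinct quantities (the two are
not interchangeable and are never conflated). Metrics with zero denominators
are NaN and flagged, never coerced to 0.

## Phantom generator

Phantoms exist to exercise the pipeline end to end, emulating exactly the
property the method consumes — relative across-slice texture consistency —
and nothing else:

* textures are white Gaussian noise blurred with an isotropic Gaussian kernel
  (σ = `texture_correlation_length`, default 3 px), standardized to unit
  variance;
* co-deleted-like subjects share one base texture across the 3 slices plus
  independent per-slice jitter of sd `slice_noise_sd` (default 0.1). The
  jitter is itself a correlated field at the same correlation length: white
  jitter would move the class toward a *whiter* texture family than the
  independent-texture class, letting a classifier separate on smoothness
  instead of consistency, and `slice_noise_sd` would stop acting as a clean
  effect-size dial;
* non-deleted-like subjects draw all 3 textures independently;
* masks are centered filled ellipses (minor/major axis ratio
  `mask_ellipticity` = 0.65) with a few percent per-slice axis jitter —
  always connected and nonempty;
* two contrasts are emitted as independent draws with different correlation
  lengths (T2W 1.6× T1C) purely to exercise the per-contrast pipeline;
* default cohort counts are 102 co-deleted : 57 non-deleted, the ~2:1
  imbalance of the motivating study; grades are assigned by the study's
  printed per-class G-II fractions;
* the master seed fans out through `numpy.random.SeedSequence`, so cohorts
  are reproducible subject by subject and manifests are byte-identical across
  reruns.

What phantoms do **not** model: MRI physics (no Rician noise, bias fields,
partial-volume effects), grade-dependent heterogeneity, registration error,
or realistic tumor shapes. Passing phantom tests demonstrates that the
machinery measures across-slice consistency correctly and that the classifier
recovers a consistency signal when present — not clinical accuracy on real
cohorts.

## Problem sizes used in validation

End-to-end checks use 30 + 15 subjects at 64 × 64 ROIs with 10-fold CV over
5 seeds, and class-contrast checks use 20 phantoms per class — cohort shapes
small enough to iterate on while keeping every fold stratifiable at k = 10.
The null calibration removes the effect entirely (every stack independently
textured, labels arbitrary) and checks that accuracy falls back to within
3 standard errors of the majority-class rate; because undersampling trains on
balanced data, null accuracy gravitates toward 0.5 rather than the majority
rate, and the band accommodates both.

## Known limitations

* The VoCC curve is indexed by column lag only; structure that varies purely
  along rows is summarized indirectly through the variance over row lags.
* Plain (unnormalized) cross-correlation makes VoCC sensitive to mask size;
  the z-scoring and the scale-free difference energy mitigate but do not
  remove this.
* With three features and small cohorts the classifier can saturate
  (pseudo-loss hitting 0.5 stops boosting early); the early-stop rule keeps
  the ensemble valid but effective P may be well below the requested
  iteration count.
* T1C and T2-W stacks are processed fully independently; no resampling to a
  common resolution is attempted when contrasts differ in slice thickness.
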