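# voccspec

Texture-consistency analysis of 3-slice tumor ROI stacks for predicting
1p/19q co-deletion status in low-grade glioma, with a fully synthetic phantom
generator so the whole pipeline runs and validates without any imaging data.

## The problem

The combined loss of chromosome arms 1p and 19q is a favorable prognostic
marker in low-grade glioma, normally confirmed by biopsy + FISH. Co-deleted
tumors tend to have texture that stays *consistent* from one MRI slice to the
next, while non-deleted (wildtype) tumors look heterogeneous across slices.
`voccspec` turns that qualitative observation into a classifier operating on
three consecutive tumor slices per subject and contrast (T1C, T2-W), each
with a binary tumor mask.

## The method

For each subject the tumor ROI is cropped at the mask's bounding box,
z-scored over foreground pixels, and the three slices are zero-padded to a
common M×N. For each consecutive slice pair (X, Y) the full-lag 2D
cross-correlation

    C(i, j) = Σₘ Σₙ X(m, n) · Y(m − i, n − j),   −(M−1) ≤ i, −(N−1) ≤ j

is collapsed into the **variance of cross-correlation (VoCC)** curve: the
sample variance of C(·, j) over the 2M−1 row lags, one value per column lag
j. Consistent across-slice texture makes the pair-(1,2) and pair-(2,3) VoCC
curves nearly coincide; independent texture makes them diverge.

Each VoCC curve is mean-centered and converted to a classical Lomb–Scargle
power spectral density sampled at the integer lag positions. The elementwise
product of the two pair spectra (the *inner-product spectrum*) keeps only the
periodic structure present in both slice pairs — the volumetric signature.
After excluding the leading low-frequency peak (present in both classes),
three features are extracted per subject and contrast:

1. **difference energy** — normalized gap between the two periodograms' total
   power, |ΣP₁₂ − ΣP₂₃| / (ΣP₁₂ + ΣP₂₃); low when texture persists;
2. **total volumetric energy** — total power of the inner-product spectrum;
   high when peaks coincide across slice pairs;
3. **cutoff frequency** — where the inner-product spectrum drops below 1 % of
   its maximum and stays there.

Classification uses **RUSBoost** (written here from the AdaBoost.M2
formulation): each boosting round fits a weak decision tree on a random 1:1
undersample of the majority class, evaluates the pseudo-loss δₜ on the full
weighted set, updates example weights by aₜ = δₜ/(1−δₜ), and votes with
weights log(1/aₜ). This protects the minority (non-deleted) class in the
~2:1-imbalanced cohort. Evaluation is stratified 10-fold cross-validation
with pooled confusion counts, per-class precision/recall/F-score, accuracy,
and rank-based AUC reported separately.

## Worked example

Simulate a 30 + 15 phantom cohort with a strong consistency effect and run
the full pipeline:

```bash
voccspec simulate --n-codeleted 30 --n-nondeleted 15 --seed 7 --out demo_cohort
voccspec classify --manifest demo_cohort/manifest.csv --out demo_out --seed 7
```

which prints

```
wrote 90 manifest rows to demo_cohort/manifest.csv
T1C: accuracy=0.978 auc=1.000
T2W: accuracy=0.956 auc=0.978
metrics written to demo_out/metrics.json
```

90 manifest rows are 45 subjects × 2 contrasts. The pipeline recovers the
class labels almost perfectly on both synthetic contrasts: 44/45 subjects
correct on T1C (one co-deleted subject misclassified — precision 1.0 /
recall 0.97 for the co-deleted class), 43/45 on T2-W. `demo_out/` also
contains `features.csv` (one row per subject per contrast with the three
spectral features), `vocc_curves.csv`, and `spectra.csv` for plotting. The
first feature row,

```
difference_energy,total_volumetric_energy,cutoff_frequency,subject_id,contrast,label,grade
0.03316,1.411e+20,0.1107,sub0001,T1C,co-deleted,G-II
```

shows the co-deleted signature: near-zero difference energy (the two pair
periodograms agree) and large volumetric energy (their peaks coincide).

The same stages are available as library calls
(`voccspec.vocc_pair`, `voccspec.subject_spectral_features`,
`voccspec.stratified_kfold_cv`, ...) and as `voccspec features` /
`voccspec run-all --config run.yaml` subcommands.

## Limitations

Phantoms model across-slice texture consistency with smoothed Gaussian random
fields, not MRI physics; results on them validate the machinery, not clinical
performance. See `docs/methods.md` for the model details, parameter defaults,
and numerical choices.
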