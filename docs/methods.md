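# Methods

## Problem and pipeline

After endovascular repair (EVAR) of an abdominal aortic aneurysm, the
thrombus-filled sac between the stent-graft and the aneurysm wall either
shrinks/stabilises or keeps expanding; expansion signals elevated rupture
risk and often requires re-intervention. The package implements a pipeline
that predicts later expansion from the *texture* of the sac on the first
post-operative contrast CT: an expanding sac tends to contain unevenly
distributed contrast (endoleak inflow), visible as grey-level heterogeneity,
while a depressurised sac is homogeneous.

The stages are:

1. **Quantization** of the masked sac ROI (single largest axial slice) to
   G = 16 grey levels, equal-width bins over the in-mask min–max.
2. **Texture features**: 13 grey-level co-occurrence (GLCM/Haralick)
   features, 7 run-length (GLRLM/Galloway) features and 5 grey-level
   difference (GLDM) features, each computed per direction
   (0°, 45°, 90°, 135°) and averaged (isotropy assumption).
3. **Reference standard**: a patient is labeled *expansion* when the
   relative sac volume change between the two follow-ups,
   (V2 − V1)/V1, strictly exceeds 2%; otherwise *non-expansion*.
   Type-I endoleaks (attachment-site leaks, a dominant predictor on their
   own) are excluded before texture modelling.
4. **Classification**: a three-layer backpropagation MLP (one logistic
   hidden layer) evaluated under 100 independent stratified 70:15:15
   train/validation/test splits, with per-repeat ROC/AUC and Youden-cutoff
   confusion metrics averaged across repeats.
5. **Comparison arms**: univariable screening (normality check + two-sample
   t test for continuous variables; chi-square/Fisher for categorical,
   selection at P < 0.1 or forced) feeding a binary logistic regression,
   whose predicted probabilities enter the same ROC machinery.

## Texture conventions

* Quantization is per-ROI min–max (not a fixed HU window): it makes the
  features invariant to affine intensity rescaling, the convention of
  classic texture work. Levels are 1-based {1..G} so formulas dividing by
  i² are always defined. A ROI smaller than G pixels quantizes with a
  warning rather than an error, so degenerate single-pixel ROIs remain
  analysable in tests.
* GLCM pairs are counted in both orders (symmetric matrix) and normalized
  per direction; pairs crossing the mask are skipped. Feature names map to
  the Haralick 1973 set (inertia ≡ contrast, deficit/inverse difference
  moment ≡ IDM, the "two information measures" ≡ IMC1/IMC2). Logs are base
  2 with 0·log 0 ≡ 0; IMC2 clips the radicand at 0; correlation of a
  zero-variance marginal is defined as 0. Sum variance is centred on the
  sum average (the standard correction of Haralick's f7). Averaging is at
  the feature level by default; averaging the four matrices first is an
  option (`average="matrices"`) since the isotropy wording is ambiguous.
* GLRLM runs are maximal same-level pixel stretches along a direction;
  a masked-out pixel **breaks** the run (decision: skipping over holes
  would couple distant pixels). Features use the Galloway/Chu conventions
  {SRE, LRE, GLN, RP, RLN, LGLRE, HGLRE}.
* GLDM histograms |level(x) − level(x+δ)| for δ ∈ {(0,d), (d,0), (d,d),
  (d,−d)}; its five features are contrast, ASM, entropy, mean and an IDM
  with denominator k² + 1. The feature list follows the classical Weszka
  set (contrast rather than "correlation", which cannot be formed from a
  1-D difference histogram).
* Default inter-pixel distance d = 1 for all three families (configurable).

## Evaluation conventions

* The empirical ROC sweeps all distinct score thresholds; AUC is the
  trapezoidal area, identical to the tie-corrected Mann–Whitney statistic.
* The operating cutoff maximizes Youden's J = sens + spec − 1 over the
  midpoints between consecutive distinct scores (plus the two extremes), so
  a reported cutoff sits mid-interval; ties break toward higher
  specificity. A patient is called positive when score > cutoff. PPV/NPV
  are computed on the test partition as observed (no prevalence
  reweighting) and are NaN when no positive/negative call is made.
* Splits are stratified per class by largest-remainder rounding (92
  patients → 64/14/14), drawn independently per repeat from a seeded
  generator, and depend only on the id *set*, not on manifest row order.
* The MLP has one hidden layer of width 10 (the cohort has ~25 features and
  ~90 patients; a wider net would only overfit), logistic activations,
  cross-entropy loss, adam updates (learning rate 0.01), at most 500
  epochs, and early stopping with patience 20 on the validation split's
  cross-entropy; the best-validation weight state is restored. Features are
  z-scored with train-split statistics only — the validation and test
  splits never influence scaling or stopping. Aggregation averages
  per-repeat metrics; a pooled-score ROC across repeats is available as an
  alternative. No class reweighting is applied (the ~32:60 imbalance is
  modest).

## The phantom generator

Patient CTs cannot be shipped, so the package generates a phantom cohort
that carries exactly the statistical structure the pipeline assumes:

* **Geometry**: a bright circular stent lumen (3× thrombus intensity)
  inside a sac annulus on a 96×96 16-bit raster; the annulus is the ROI.
* **Stable sac**: stationary correlated Gaussian noise (SD 80, blur
  σ = 1 px) around a mean of 1000 arbitrary HU-like units.
* **Expansion-prone sac**: additionally, 4 isotropic Gaussian contrast
  pockets (amplitude 500, σ = 5 px) at uniformly random in-mask centres —
  the "uneven contrast distribution" mechanism. The pocket count is fixed
  per image (not Poisson) for determinism; `pocket_amplitude` is the
  single separation knob (0 ⇒ the groups are exchangeable pixel-for-pixel).
  No quantitative description of real endoleak appearance exists, so pocket
  shape/amplitude are modelling choices exposed in `PhantomParams`, chosen
  once to produce the strong texture separation the method is designed to
  detect.
* **Volumes**: V1 is log-normal, moment-matched to mean 156.9 / SD 133.6 cc
  (the printed SD is near the mean, so a normal draw would go negative);
  V2 = V1·(1+Δ) with Δ ~ N(9.8%, 9.9%) for expanders and N(−8.7%, 10.7%)
  for non-expanders.
* **Endoleaks**: per-group type-I/type-II frequencies 6/38, 6/38 (expanders)
  and 1/61, 6/61 (non-expanders). Default assignment uses exact
  largest-remainder counts (so the default 99-patient cohort reproduces the
  7-type-I/12-type-II tally and the 99 → 92 exclusion arithmetic exactly);
  a Bernoulli mode draws per patient instead.
* **Clinical covariates** (age, sex, pressures, lipids, smoking, alcohol,
  diameter …) are drawn from distributions matching the cohort-wide
  summaries and **independently of the group** — the study found no
  significant clinical predictor, so on phantoms every clinical/imaging arm
  has expected AUC 0.5 by construction.

What the phantoms do *not* emulate: 3D sac geometry, beam hardening and
stent metal artefacts, scanner/protocol variation, anatomically realistic
endoleak shapes, and any correlation between clinical covariates and
outcome. Passing tests therefore demonstrate that the pipeline's machinery
is correct and that it detects the heterogeneity mechanism when present —
not that the discrimination levels transfer to patient data.

### Label noise and the discrimination benchmark

Images follow the generating *group*, while downstream labels follow the 2%
volume rule applied to (V1, V2). Because the volume draw is independent of
the image, roughly 21% of expander-group draws fall under the 2% threshold
and ~16% of non-expander draws above it; this label noise caps the
achievable rule-label AUC near 0.81 regardless of classifier quality. The
end-to-end discrimination benchmark therefore classifies the generating
group (pocketed vs homogeneous sac — the image-level ground truth), which
isolates the texture channel; the analysis driver additionally reports the
noisier rule-labeled variant for completeness. The volume rule itself is
validated separately on exact boundary/scale/idempotence cases.

## Problem sizes and numerical notes

* Oracle-equivalence tests compare every matrix entry and all 25 features
  against independent nested-loop enumerations on 200 random masked images
  up to 8×8 with G ≤ 6, at 1e−9.
* The end-to-end benchmark uses the 99-patient default cohort with 25
  split repeats (the evaluation is seed-reproducible; more repeats only
  narrow the mean's dispersion). The analysis drivers default to 25 repeats
  as well, configurable via `--repeats`.
* Generator calibration is checked at n = 2000 expanders (sample mean of Δ
  within 3 standard errors of the configured 9.8%).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-patient image seeds are derived from the
  cohort seed, and cohort generation, splitting and MLP training are each
  bit-reproducible from their seed.

## Known limitations

* 2D single-slice analysis only; no 3D co-occurrence or size-zone variants.
* The logistic comparison arms are evaluated in-sample (as is conventional
  for odds-ratio tables), not under the repeated-split protocol.
* Fisher's exact test is used only for 2×2 tables; larger sparse tables
  fall back to chi-square.
* The KS normality check uses the Lilliefors estimated-parameter
  correction and is approximate; a normality failure logs a note but does
  not switch the t test to a rank test.
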