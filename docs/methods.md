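# Methods

## Problem and model

The package classifies lesions on endoscopic-ultrasound (EUS) still frames
as pancreatic cancer (PC, label 1) or chronic pancreatitis (CP, label 0)
from second-order texture alone. The underlying assumption is the classical
one in ultrasound tissue characterization: the scatterer micro-structure of
carcinoma and of fibrotic/calcified pancreatitis differs, and that
difference survives in the local speckle statistics of the B-mode image
even when the gross appearance is ambiguous.

All analysis runs on the largest axis-aligned rectangle inscribed in the
hand-drawn region of interest (ROI). A rectangle, rather than the masked
polygon itself, keeps every feature defined on a gap-free raster of
homogeneous geometry, so cases differ in content rather than in support.
The rectangle is found exactly (per-row histogram / monotone-stack dynamic
programme, verified against exhaustive search); ties are broken toward
larger height, then smaller origin row, then smaller origin column, so the
crop is a deterministic function of the mask.

## Feature inventory

105 features in 9 categories. Only part of the inventory is uniquely
determined by the headline numbers it reproduces (the 16-feature optimum
subset names 5 of the categories); the remaining categories are this
package's choice of the standard texture families a Matlab-era CAD pipeline
would compute:

| category | count | notes |
|---|---|---|
| histogram | 10 | moments on raw intensities; energy/entropy on the 256-bin normalized histogram |
| glcm | 2 × 16 | Haralick statistics at offsets d = 1, 2; 4 directions symmetrized and averaged |
| glrlm | 11 | run-length statistics, 4 directions averaged; grey level i weighted (i+1) |
| glds | 5 | statistics of |Δlevel| pooled over the 4 unit displacements |
| wavelet entropy / std / energy | 3 × 10 | per subband of a 3-level db4 decomposition, symmetric padding |
| laws | 9 | mean |response| to the 3×3 Laws masks, normalized by the L3L3 response |
| gradient | 8 | Sobel-magnitude statistics and the >10%-of-max edge fraction |

Naming conventions adopted for the translated feature labels of the
clinical report: "invariant moment" → inverse difference moment,
"consistency" → angular second moment (and histogram energy),
"absolute value" → dissimilarity, "variance of differences" → the GLDS
variance. All 16 reported optimum features exist under these names
(`REFERENCE_SELECTED_FEATURES`).

Numerical conventions, applied uniformly: logarithms base 2 with
0·log 0 := 0; skewness/kurtosis (excess) of a zero-variance sample := 0;
correlation and IMC1 of a degenerate co-occurrence matrix := 0; an all-zero
wavelet subband has entropy and standard deviation 0. Constant images
therefore produce a finite, NaN-free vector.

Grey levels for the matrix features default to G = 64 (min–max quantized
over the sub-image's own range), balancing matrix occupancy against
resolution at typical ROI sizes of 10³–10⁴ px. Min–max quantization makes
the matrix features invariant to affine intensity rescaling — deliberate,
since overall gain is operator-dependent on EUS — which also means additive
noise raises co-occurrence contrast only on a *fixed* grey scale, not
through the per-image quantizer; the corresponding property test uses a
fixed full-range 0–255 → 64-bin map.

The minimum analysable sub-image is 8×8: a 3-level dyadic decomposition
needs it, although at that size the coarse subbands are boundary-dominated
(accepted, and the PyWavelets warning is silenced at the call site).

## Selection

Stage 1 ranks features by d = |median₁ − median₀| / (MAD₁ + MAD₀ + ε),
ε = 10⁻¹². The median gap is the discriminative signal; the MAD sum makes
the score unit-free and robust, which a raw median gap across features of
wildly different scales is not. Ties break by canonical inventory order, so
the ranking is invariant to row order.

Stage 2 (default) is ranked-incremental: the k-th candidate subset is the
first k ranked features, scored by mean half-and-half accuracy (CCR) with
an independent seed; the optimum is the argmax, smallest k on ties. This
mirrors a selection curve built by "adding the ranked features one by one".
Classic greedy SFS (each step adds the CCR-maximizing remaining candidate)
is available via `SfsConfig(mode="greedy")`.

Selection on the pooled cohort before validation leaks label information
into the reported CCR — the historical protocol this pipeline reproduces
does exactly that, and the package keeps it as the default because the
selection curve is part of what is being reproduced. For an unbiased
estimate, `half_and_half_eval(..., features=None, select_k=k)` re-ranks
inside every training half (nested selection); the null-cohort calibration
below uses this mode, since with pooled selection even an exchangeable
cohort scores above chance.

## Classification and validation

Features are z-scored with training-half statistics (zero-variance features
get scale 1 and are flagged). The SVM is RBF-kernel libsvm with C = 1 and
γ = 1/k for k features — fixed, so runs are reproducible without tuning;
the optional grid search (C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, powers of 4, inner
stratified 5-fold CCR) exists for users who want tuned performance.
Predictions are taken from the decision function with the documented tie
rule: decision value 0 → CP. Class imbalance is not reweighted by default
(a `class_weight` knob exists).

Half-and-half validation: per trial, each class is split uniformly at
random, floor(n/2) to training; trial t uses seed `seed + t`. Metrics are
computed per trial and averaged; the dispersion is the standard error
sd/√n_trials. Per-trial averaging is not collapsible: the mean PPV is not
derivable from mean sensitivity/specificity and prevalence, which is why
aggregate metric sets from such protocols can look mutually inconsistent.
Metrics with a zero denominator in a trial (e.g. PPV with no positive
calls) are flagged undefined and excluded from that metric's average, with
a count. Leave-one-out pools all N held-out predictions into a single
confusion matrix (n_trials = 1, SE = 0).

## Synthetic speckle generator

Fully developed ultrasound speckle is Rayleigh-distributed envelope noise
with a correlation length set by the system point-spread function. The
generator reproduces exactly these two properties: the magnitude of a
complex Gaussian white-noise field smoothed by a Gaussian kernel of width
`correlation_length`, rescaled to mean `echogenicity`, plus
Poisson-distributed Gaussian bright blobs (σ = 1.5 px, rate per 10³ px²)
emulating hyperechoic foci, plus additive Gaussian sensor noise, clipped
and rounded to 8-bit. Per-image seeds derive from the master seed by a
fixed multiplicative hash (`derive_seed`), so cohorts are reproducible
across platforms and any image can be regenerated in isolation.

Default class conditions: PC — correlation length 2 px, echogenicity 85,
focus rate 0.2, focus amplitude 35; CP — correlation length 4 px,
echogenicity 115, focus rate 1.5, focus amplitude 50; noise σ = 5 for both.
These encode the qualitative clinical contrast (carcinoma darker and finer,
pancreatitis brighter with calcific foci) at a separation the pipeline
resolves essentially perfectly. `correlation_pair(a, b)` builds matched
classes differing *only* in correlation length, the single-knob contrast
used for calibration studies.

What the generator does **not** emulate: anatomy, attenuation and focal
zones, scan-conversion interpolation, real grey-level transfer curves, and
inter-patient heterogeneity. Passing the synthetic benchmarks therefore
demonstrates that the pipeline's machinery is correct and well calibrated —
recovering a known texture contrast, staying at chance under
exchangeability, and protocol agreement — not that any particular clinical
accuracy would be achieved on real EUS images.

## Benchmark problem sizes

The packaged studies use cohorts of 60 + 60 images of 64×64 px (feature
extraction ≈ 15 ms/image), 10–20 half-and-half trials inside the selection
curve, 20–50 trials for reported metrics, and full leave-one-out at
N = 120; the whole acceptance study completes in seconds on one core.
Validation-protocol counts for the clinical roster (262 PC / 126 CP →
131 + 63 per side, 200 trials) are exercised at the split level, where cost
is negligible.

## Known limitations

* The ROI polygon must be simple; self-intersecting outlines are rejected
  rather than repaired.
* One rectangle per ROI: thin or crescent-shaped lesions yield small
  rectangles and correspondingly noisy matrix features.
* The published per-metric clinical values cannot be reproduced without the
  original images; the package reproduces the protocol and the printed
  curve optimum, and calibrates the machinery on synthetic cohorts instead.
* Half-and-half and SFS seeds interact: changing `SfsConfig.seed` can move
  the optimum k on nearly-flat CCR curves (ties are common at strong
  separation); the smallest-k tie rule keeps this deterministic.
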