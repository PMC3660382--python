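# eustex

Texture-based computer-aided differentiation of **pancreatic cancer (PC)**
and **chronic pancreatitis (CP)** on endoscopic-ultrasound (EUS) still
images.

Distinguishing a pancreatic carcinoma from focal chronic pancreatitis on EUS
is hard even for experienced endoscopists: both appear as hypo/heterogeneous
masses, and the reader's experience dominates the call. `eustex` implements
the quantitative alternative: the speckle texture inside the lesion is
summarized by a large battery of classical texture statistics, a compact
discriminative subset is selected in two stages, and a support vector
machine (SVM) classifies the lesion, validated by repeated random splits and
by leave-one-out.

The package is aimed at medical-image-analysis researchers who want a fully
reproducible, scriptable reference pipeline — and, because clinical EUS
cohorts are rarely shareable, it ships a seeded synthetic speckle generator
so every stage can be exercised and benchmarked without patient data.

## Pipeline

1. **ROI → sub-image** (`roi_imaging`). The lesion boundary is a hand-drawn
   polygon; analysis uses the maximum-area axis-aligned rectangle inscribed
   in the rasterized ROI, found exactly by a maximal-rectangle dynamic
   programme. Grey levels are min–max quantized to G = 64 bins for the
   matrix-based features.
2. **105 features, 9 categories** (`texture_features`): first-order
   histogram statistics (10); Haralick grey-level co-occurrence statistics
   at offsets d = 1, 2 — ASM, contrast, correlation, variance, inverse
   difference moment, sum/difference statistics, entropy, IMC1/2,
   dissimilarity, autocorrelation, max probability (2 × 16); run-length
   statistics (11); grey-level difference statistics (5); per-subband
   Shannon entropy, standard deviation and energy of a 3-level db4 wavelet
   decomposition (3 × 10); Laws 3×3 texture-energy measures (9); gradient
   statistics (8).
3. **Two-stage selection** (`feature_selection`). Stage 1 scores each
   feature *j* by the robust class separation

   d_j = |med₁(x_j) − med₀(x_j)| / (MAD₁(x_j) + MAD₀(x_j))

   and keeps the top m = 25. Stage 2 adds the ranked features one by one
   and scores every prefix by the correct-classification rate (CCR) of the
   SVM under repeated half-and-half validation; the optimum subset size k\*
   is the CCR argmax.
4. **Classification** (`classifier`). Z-scoring fitted on training data
   only, then an RBF-kernel SVM (libsvm via scikit-learn) with C = 1,
   γ = 1/k; an optional inner 5-fold grid search over C ∈ {2⁻⁵…2¹⁵},
   γ ∈ {2⁻¹⁵…2³} is available.
5. **Dual validation** (`evaluation`): 200 stratified half-and-half trials
   (metric mean ± standard error) and leave-one-out cross-validation
   (pooled confusion matrix). Reported metrics: accuracy, sensitivity,
   specificity, PPV, NPV, with PC as the positive class.

## Worked example

Synthetic two-class cohort, 30 + 30 images of 64×64 px, identical except
for the speckle correlation length (2.0 px vs 2.15 px — a deliberately
subtle contrast):

```python
from eustex import (correlation_pair, cohort_feature_table, rank_features,
                    sfs_curve, SfsConfig, half_and_half_eval, loocv_eval)
from eustex.evaluation import report_table

pc, cp = correlation_pair(2.0, 2.15)
table = cohort_feature_table(pc, cp, 30, 30, size=(64, 64), seed=5)
ranking = rank_features(table, m=25)
trace = sfs_curve(table, ranking, SfsConfig(n_trials=10, seed=5005))
print(f"optimum: k={trace.optimum_k}, CCR={trace.optimum_ccr:.2f}%")
half = half_and_half_eval(table, trace.optimum_features, n_trials=50, seed=5)
loo = loocv_eval(table, trace.optimum_features)
print(report_table(half, loo))
```

prints

```
optimum: k=1, CCR=83.67%
Parameter            Half-and-half     Leave-one-out
Accuracy             85.27 ± 0.69%            83.33%
Sensitivity          90.53 ± 1.08%            86.67%
Specificity          80.00 ± 1.69%            80.00%
PPV                  83.07 ± 1.20%            81.25%
NPV                  90.43 ± 1.00%            85.71%
```

A single texture feature already carries most of the (small) class
difference, the half-and-half mean accuracy of 85.3% comes with its
standard error over 50 random splits, and leave-one-out agrees within two
points — the two protocols mutually support each other. Widening the
correlation-length gap to 2 px vs 6 px drives every metric to 100%.

The same run is available from the shell:

```bash
eustex simulate --out cohort --n-pc 30 --n-cp 30 --size 64 --seed 5
eustex run --images cohort --out run --seed 5
```

which writes `features.csv`, `ranking.json`, `sfs_trace.json`,
`report.json` and `report.txt` into `run/`, each stamped with the
configuration hash and master seed.

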