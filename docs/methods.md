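# Methods

## Scope and model

`immunopet` estimates a tumor's cytolytic immune activity from its FDG-PET
uptake pattern. The working hypothesis is radiogenomic: the spatial
organization of glucose metabolism in a lesion carries information about the
immune state of its microenvironment, so a 3-D convolutional network trained
against an RNA-derived label can read that state noninvasively for every
lesion in a whole-body scan. The package implements the full chain —
segmentation, cube extraction and augmentation, CNN regression with
cross-validation, per-patient biomarker aggregation, and the outcome
statistics — plus a synthetic phantom generator that realizes the hypothesis
explicitly so the chain can be validated end to end.

## Image handling

Volumes are 3-D arrays in `(z, y, x)` order with per-axis voxel spacing in
mm; NIfTI-1 is the on-disk format and a JSON sidecar carries dose/weight
metadata. SUV conversion is `v · body_weight_g / injected_dose_Bq`
(unit-canceling under the usual 1 g/mL tissue convention). Isotropic
resampling is trilinear with `grid_mode` cell semantics, which conserves
total activity (sum × voxel volume) for smooth fields to well under the 5%
tolerance asserted in tests; masks are resampled nearest-neighbour.
Out of scope: DICOM series ingestion, attenuation/scatter corrections,
dynamic PET.

## Adaptive-threshold segmentation

The user (here: the phantom generator) supplies an axis-aligned seed box
around the lesion. The threshold is

    T = β · I₇₀ + I_background,     β = 0.3 by default,

with `I₇₀` the mean uptake of seed-box voxels **strictly above** 70% of the
seed-box maximum, and `I_background` the mean uptake of a shell
(`background_shell_vox` = 2 voxels) dilated around the box, excluding shell
voxels above 70% of the maximum (tumor spill-in). If that exclusion empties
the shell — e.g. a perfectly uniform volume — the unfiltered shell mean is
used and a warning issued; the uniform case then yields `T = 1.3c`, above
the uptake everywhere, and segmentation correctly reports that nothing lies
above threshold. The mask keeps voxels `≥ T` inside the box, restricted to
the 26-connected component containing the seed-box maximum. Degenerate
lesions (`I₇₀ ≤ I_background`) produce a warning, not an error. The
threshold is scale-equivariant, so masks are invariant to global intensity
rescaling; the suite checks exact agreement with an independent brute-force
voxel-loop implementation on 50 random phantoms. MTV is voxel count × voxel
volume / 1000 (mL).

## Cubes and augmentation

The network input is a cube centred on the mask centroid, cut from the
isotropically resampled volume with surrounding context retained — the cube
*contains* the lesion rather than being masked to it, since peritumoral
uptake is plausibly informative. Border regions are zero-padded; a lesion
whose bounding box exceeds the cube raises an explicit error. Default cube:
**32 mm side, 16 voxels at 2 mm** — sized to the phantom lesion scale
(8–14 mm radius) and to keep 10-fold CV training tractable on a single CPU;
larger cubes are a config change. Intensities are divided by the cube
maximum (`norm_mode="max"`), making inputs scanner-scale invariant; the
alternative `none` is exposed.

Augmentation generates 15 copies per cube, each rotated about the z, then y,
then x axis by independent uniform angles in [0°, 90°], trilinear with zero
fill. Exact multiples of 90° map the grid onto itself, so those rotations
are exact voxel permutations (asserted bit-exactly). Copies are generated
once per sample from a per-sample seed and reused across epochs by default;
per-epoch regeneration is available (`regenerate_per_epoch`) but costs more
interpolation time than it buys at this scale.

## CNN regressor

A deliberately small sequential network: three blocks of
[3×3×3 conv → ReLU → 2×2×2 max-pool] with 4, 8, 16 channels, global average
pooling, and a single linear output; MSE loss, Adam at 1e-3, 3 epochs over
the 15-fold-augmented training set (≈ 48 passes over each original cube),
batch 64, He initialization. Convolutions are evaluated channels-last as 27
offset GEMMs (one per kernel tap), which is substantially faster in numpy
than an im2col gather at these tensor sizes; the input layer skips its input
gradient. Gradients were verified against finite differences.

Cross-validation partitions samples by a seeded shuffle into folds whose
sizes differ by at most one. Each fold's model trains on the originals plus
the augmented copies of the *training* folds only — no augmented view of a
validation sample ever enters training — and validation predictions are
pooled out-of-fold, one per sample. Inference on new lesions uses the mean
of the 10 fold models (an ensemble avoids a refit-on-all pass). All
randomness (fold assignment, initialization, batch order, rotation angles)
derives from integer seeds; repeated runs are bit-identical.

On the default synthetic study (300 single-lesion phantoms, seed 1) the
pooled out-of-fold Spearman correlation with the RNA-derived CytAct is
≈ 0.87, and ≈ −0.07 when training labels are shuffled — the recovery is
texture-driven, not memorization. These are the quantities
`scripts/acceptance.py` recomputes.

## Immune scores

Expression matrices are genes × samples, symbols canonicalized to upper
case (exact match, no alias resolution), raw counts transformed
`log2(x + 1)` before scoring. Z-scores use the sample standard deviation
(n−1); zero-variance genes raise an error naming the gene. CytAct is the
mean of z-scored GZMA and PRF1; the IFN-γ score averages IDO1, CXCL9,
CXCL10, IFNG, HLA-DRA and STAT1. The six IFN-γ genes are z-scored before
averaging by default for cross-gene comparability — a deliberate
interpretation, consistent with CytAct's construction; a raw-mean variant is
available (`zscore=False`). CytAct is invariant to per-gene affine rescaling
and averages to zero over the cohort by construction.

## Multi-lesion biomarkers

Target lesions follow the RECIST floors: lymph nodes ≥ 15 mm short axis,
all other sites ≥ 10 mm long axis. Per patient, the representative
biomarker is the **minimum** predicted CytAct (the least immunogenic lesion
is the one that escapes), with mean and maximum reported for comparison;
heterogeneity is the sample variance (n−1) of the lesion predictions,
defined only for patients with ≥ 2 lesions. Dichotomization labels a
patient "high" when the minimum CytAct is **strictly above** the cutoff —
values exactly at the cutoff go "low", since the cutoff is the optimal ROC
point for detecting responders among higher values. The conventional
reference cutoff −0.107 is exported as a default; synthetic studies use the
Youden cutoff of their own ROC. Lesion-wise association analyses treat
lesions as independent observations by default (matching common lesion-wise
reporting); this ignores within-patient clustering and is flagged as a
limitation.

## Statistics

* Spearman: midrank rho; p by full permutation enumeration for n ≤ 9, else
  the t approximation.
* Wilcoxon rank-sum: two-sided; exact enumeration of all group assignments
  (midranks, so ties are handled) for combined n ≤ 12 with
  `p = min(1, 2·min(P(W ≤ w), P(W ≥ w)))`; otherwise the normal
  approximation with tie and continuity corrections.
* ROC: AUC by the midrank Mann–Whitney identity (equals all-pairs
  concordance with ties counted ½); the optimal cutoff maximizes Youden's J
  under the rule "positive ⇔ score > cutoff" (smallest cutoff on ties);
  95% CI by DeLong's structural components.
* Logistic regression: statsmodels ML fit with Wald p-values; perfect or
  quasi-perfect separation is detected (diverging coefficients or a
  saturated fit) and raises an error pointing to the provided Firth
  penalized-likelihood fallback.
* Survival: Kaplan–Meier product-limit curves, the two-group log-rank test,
  and a Cox fit on the group indicator with Efron tie handling (lifelines);
  a group with zero events flags the hazard ratio undefined rather than
  reporting a spurious number.
* No multiple-testing correction is applied; p-values are reported raw.

The exact-vs-approximate switchover points (9, 12) were chosen for
desk-scale exactness; they are constants, not tuning knobs.

## Synthetic data generator

The generator encodes one latent per-lesion immune score `u` three ways.

**Imaging.** Each lesion is an ellipsoid (radius 8–14 mm, ±15% per-axis
aspect jitter) pasted at an integer-voxel position into a 32³ volume at
2 mm spacing, background SUV 1.0, peak uptake ~6. Texture carries the
signal: rim-to-core contrast `c(u) = −0.35 + 1.3·expit(1.2u)` (cold-rim at
very low `u`, hot-rim at high `u`; strictly increasing) and an intra-lesion
speckle gain `2 + 4·expit(u)` multiplying the voxel noise. The volume is
smoothed with a 1 mm-σ Gaussian (a light reconstruction PSF) before noise
(SUV σ 0.08) is added; with `noise_sd = 0` the generator is fully
deterministic and lesions with equal parameters are voxel-identical up to
placement. The parameter-level texture link is exactly monotone in `u`; the
voxel-measured rim/core statistic keeps Spearman ≈ 0.97 with `u` under
default noise (PSF blurring of small lesions accounts for the gap from 1).
Not emulated: scanner PSF anisotropy, respiratory motion, attenuation
artifacts, inter-scanner harmonization — so passing tests demonstrate
recovery of a *planted* texture code, not performance on real scans.

**Expression.** GZMA and PRF1 log2 values are affine in `u` plus N(0, 0.15)
noise, so CytAct recovers `z(u)` exactly at zero noise and at Spearman
≈ 0.99 at default noise; the six IFN-γ genes load on a factor correlated
with `u` at a configurable target (default 0.5); two housekeeping genes are
included as scoring-neutral filler.

**Outcomes.** Patients draw 1–4 lesions (default ICB mix 35/30/20/15%,
about two lesions per patient). In the heterogeneity-trait mode used for
ICB cohorts, each patient has a latent mean (σ 0.8) and a lognormal
within-patient spread (median 0.5, log-σ 1.6, clipped to [0.1, 2.5]) — some
patients' lesions are immunologically uniform, others' widely divergent.
Lesion size change is `a − b·u + e·sd(u_patient) + ε` with a = −45%,
b = 20%/unit, e = 25%/unit (the variance-linked resistance; set 0 to
disable), ε σ 4%, clipped at −100%. Best response is PR iff **all** lesions
shrink ≥ 30% (RECIST partial-response convention), PD if any lesion grows,
SD otherwise — so the worst lesion drives response. PFS/OS are exponential
with log-hazard `−c·min(u) + d·var(u)` (c = 1, d = 0.5; OS hazard at half
the PFS rate), with random censoring (rate 0.2) and a 30-month horizon.
When no trained model is supplied, predicted CytAct is surrogated as
`u + N(0, 0.4)`, matching the measured accuracy of the trained CNN
(out-of-fold ρ ≈ 0.9). Defaults were fixed once against the marginals of a
published metastatic-LUAD ICB cohort (roughly half of patients responding,
two lesions per patient, a strong negative lesion-wise score/size-change
correlation) and are not adjusted per experiment.

## Problem sizes and numerical choices

The standard validation study uses 300 phantoms with 10-fold CV (≈ 7 minutes
per full CV run on one CPU) and 20 replicate ICB cohorts of 40 patients;
these sizes are the package's chosen balance of statistical resolution and
desk-scale runtime. Ties in max-pooling split gradients evenly; ROC cutoff
ties resolve to the smallest cutoff; the segmentation seed point is the
first occurrence of the seed-box maximum in C order. Float32 is used inside
the network, float64 elsewhere.

## Known limitations

* The CNN architecture and training schedule are minimal by design; real
  radiogenomic signal would likely need larger cubes, more capacity, and
  harmonized multi-scanner inputs.
* The phantom texture code is a stand-in for unknown real structure; all
  recovery results are conditional on the generator's assumptions.
* The ICB outcome model is a simulation device (exponential hazards, linear
  size-change link), not a fitted clinical model.
* Lesion-wise analyses ignore within-patient correlation by default.
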