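# immunopet

**Noninvasive tumor immune profiling from FDG-PET images.**

Tissue-based immunotherapy biomarkers (PD-L1 immunohistochemistry, RNA
signatures) need a biopsy, usually of a single lesion — yet metastatic
patients carry many lesions with divergent immune microenvironments, and the
*least* immunogenic one often decides the outcome of immune checkpoint
blockade (ICB). `immunopet` implements a whole-body alternative: estimate
the **cytolytic activity score (CytAct)** of every FDG-avid lesion directly
from its PET uptake pattern with a 3-D convolutional network, then turn the
per-lesion estimates into patient-level biomarkers.

The pipeline:

1. **Segmentation** — semi-automatic adaptive thresholding of a user-boxed
   lesion: `T = β·I₇₀ + I_background` with β = 0.3, where `I₇₀` is the mean
   uptake of voxels above 70% of the seed-box maximum and `I_background` the
   mean uptake of a shell just outside the box. Conventional features
   (SUVmax, SUVmean, MTV) come along for free.
2. **CytAct regression** — the target is the per-sample mean of z-scored
   log2 *GZMA* and *PRF1* expression, `CytAct_s = ½(z(GZMA)_s + z(PRF1)_s)`,
   a compact proxy for cytotoxic CD8⁺ T-cell activity (a 6-gene IFN-γ score
   is also provided). A small 3-D CNN regresses CytAct from a fixed-size
   normalized cube around each segmented lesion, trained with 10-fold
   cross-validation and 15-fold random-rotation augmentation (three
   independent angles in [0°, 90°] per copy).
3. **ICB biomarkers** — RECIST target-lesion selection (lymph nodes ≥ 15 mm
   short axis, other lesions ≥ 10 mm long axis), the **minimum** predicted
   CytAct across a patient's lesions as the representative biomarker (the
   worst lesion drives progression), the inter-lesion **variance** as an
   immune-heterogeneity measure, and dichotomization at an ROC-derived
   cutoff.
4. **Statistics** — Spearman correlation (exact permutation p for n ≤ 9),
   Wilcoxon rank-sum (exact enumeration for n ≤ 12), ROC/AUC with Youden
   cutoff and DeLong CI, logistic regression (with a Firth fallback for
   separated data), Kaplan–Meier, log-rank, and Cox hazard ratios.
5. **Synthetic phantoms** — a seeded generator of PET phantom cohorts whose
   lesion texture (rim-to-core contrast, speckle) monotonically encodes a
   latent immune score, with matched expression matrices and multi-lesion
   ICB outcome tables. Every stage of the pipeline is testable end-to-end
   without patient data.

## Worked example

```bash
python examples/04_icb_biomarkers.py
```

simulates 40 ICB patients with 1–4 lesions each (response requires *every*
lesion to shrink ≥ 30%) and prints:

```
responders                     : 14/40
AUC, minimum lesion CytAct     : 0.937 (95% CI 0.87-1.00)
AUC, maximum lesion CytAct     : 0.613
Youden-optimal cutoff          : -0.736
PFS hazard ratio (high group)  : 0.26 (log-rank p = 0.0013)
variance, nonresp vs resp      : two-sided rank-sum p = 0.0790 (26 multi-lesion patients)
```

The minimum-lesion CytAct discriminates responders far better than the
maximum (one resistant lesion is enough to progress), patients above the
cutoff progress at about a quarter of the rate of the rest, and
nonresponders tend to have more heterogeneous (higher-variance) lesions.
The other examples cover segmentation + PET features, immune-score
computation, and a few-minute CNN training run.

A thin CLI mirrors the stages (`immunopet simulate|segment|score|train|
predict|biomarker|stats|all`); the importable API is the primary surface.

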