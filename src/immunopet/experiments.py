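"""Canned simulation experiments: latent-score recovery and biomarker checks.

These are the package's headline self-validation runs — each builds a
synthetic cohort from scratch, runs the relevant slice of the pipeline and
measures how well the known ground truth is recovered.  Both the test suite
and ``scripts/acceptance.py`` drive them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import (
    AugmentationPolicy,
    ModelConfig,
    OutcomeSpec,
    PhantomSpec,
    cytact,
    gen_expression,
    gen_icb_cohort,
    gen_latent_scores,
    gen_phantom_cohort,
    patient_biomarker_table,
    roc_analysis,
    survival_analysis,
    train_cv,
)
from .cnn import CVResult
from .pipeline import cubes_from_cohort, segment_cohort

#: lesion-count distribution of a metastatic ICB cohort (1-4 lesions)
ICB_LESION_PROBS = (0.35, 0.30, 0.20, 0.15)


def cytact_recovery_experiment(
    n: int = 300,
    seed: int = 1,
    folds: int = 10,
    shuffle_labels: bool = False,
    cfg: ModelConfig | None = None,
    verbose: bool = False,
) -> CVResult:
    """Train the CNN on a synthetic cohort and pool out-of-fold predictions.

    Phantoms encode a latent immune score in lesion texture; matched
    expression yields the CytAct training target.  With
    ``shuffle_labels=True`` the targets are permuted — the negative control
    whose pooled correlation should sit at zero.
    """
    spec = PhantomSpec(n_patients=n, rng_seed=seed)
    vols, truth_masks, table = gen_phantom_cohort(spec)
    seg_masks, _ = segment_cohort(vols, truth_masks)
    cubes = cubes_from_cohort(vols, seg_masks, table, side_mm=32.0)
    expr = gen_expression(table.set_index("lesion_id")["u"], rng_seed=seed + 1)
    y = cytact(expr).loc[table["lesion_id"]].to_numpy()
    if shuffle_labels:
        y = y.copy()
        np.random.default_rng(seed + 2).shuffle(y)
    cfg = cfg or ModelConfig(rng_seed=seed)
    cv, _ = train_cv(
        cubes, y, cfg=cfg, folds=folds,
        policy=AugmentationPolicy(rng_seed=seed), verbose=verbose,
    )
    return cv


@dataclass
class ICBReplicate:
    """One simulated ICB cohort's biomarker summary."""

    auc_min: float
    auc_mean: float
    auc_max: float
    youden_cutoff: float
    hr_high_vs_low: float  # PFS hazard ratio of the high-CytAct group
    hetero_p_onesided: float  # P(nonresponder variance > responder variance)
    n_patients: int
    n_multilesion: int


def icb_biomarker_replicate(seed: int, n_patients: int = 40) -> ICBReplicate:
    """Simulate one ICB cohort and evaluate the patient-level biomarkers.

    Response is driven by the worst lesion, so the minimum predicted CytAct
    should discriminate responders at least as well as the maximum; the
    high-CytAct group (split at the Youden cutoff) should have a PFS hazard
    ratio below 1; and nonresponders should show higher inter-lesion
    variance (one-sided Wilcoxon rank-sum).
    """
    latent = gen_latent_scores(PhantomSpec(
        n_patients=n_patients,
        lesions_per_patient_probs=ICB_LESION_PROBS,
        hetero_traits=True,
        rng_seed=seed,
    ))
    lesion_df, patient_df = gen_icb_cohort(latent, OutcomeSpec(rng_seed=seed + 1))
    bio = patient_biomarker_table(lesion_df).merge(patient_df, on="patient_id")

    roc_min = roc_analysis(bio["min_cytact"], bio["responder"])
    auc_mean = roc_analysis(bio["mean_cytact"], bio["responder"]).auc
    auc_max = roc_analysis(bio["max_cytact"], bio["responder"]).auc

    group = np.where(bio["min_cytact"] > roc_min.optimal_cutoff, "high", "low")
    hr_high = np.nan
    if len(set(group)) == 2 and bio["pfs_event"].sum() > 0:
        fit = survival_analysis(bio["pfs_months"], bio["pfs_event"], group)
        if fit.hr_defined:
            hr_high = 1.0 / fit.hazard_ratio  # fit reports "low" vs "high"

    multi = bio[bio["cytact_variance"].notna()]
    het_p = np.nan
    if multi["responder"].nunique() == 2:
        het_p = float(sps.mannwhitneyu(
            multi.loc[~multi["responder"], "cytact_variance"],
            multi.loc[multi["responder"], "cytact_variance"],
            alternative="greater",
        ).pvalue)

    return ICBReplicate(
        auc_min=roc_min.auc,
        auc_mean=auc_mean,
        auc_max=auc_max,
        youden_cutoff=roc_min.optimal_cutoff,
        hr_high_vs_low=float(hr_high),
        hetero_p_onesided=het_p,
        n_patients=len(bio),
        n_multilesion=len(multi),
    )


def icb_replicate_summary(seeds, n_patients: int = 40) -> dict:
    """Run :func:`icb_biomarker_replicate` over seeds and summarize."""
    reps = [icb_biomarker_replicate(s, n_patients) for s in seeds]
    auc_wins = [r.auc_min >= r.auc_max for r in reps]
    hrs = [r.hr_high_vs_low for r in reps if np.isfinite(r.hr_high_vs_low)]
    het = [r.hetero_p_onesided for r in reps if np.isfinite(r.hetero_p_onesided)]
    return {
        "replicates": reps,
        "frac_auc_min_ge_max": float(np.mean(auc_wins)),
        "frac_hr_high_lt_1": float(np.mean([h < 1 for h in hrs])),
        "median_auc_min": float(np.median([r.auc_min for r in reps])),
        "median_auc_max": float(np.median([r.auc_max for r in reps])),
        "median_hr_high": float(np.median(hrs)) if hrs else float("nan"),
        "median_hetero_p": float(np.median(het)) if het else float("nan"),
    }
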