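"""End-to-end orchestration: simulate -> segment -> score -> train -> predict
-> biomarker -> stats, with a reproducible run directory.

The pipeline operates on synthetic cohorts by default (see
:mod:`immunopet.synthetic`); each stage writes its artifacts under the run
directory and a final ``metrics.json`` summarizes the run.  A run is fully
determined by its :class:`RunConfig`, which is serialized alongside the
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    AugmentationPolicy,
    ModelConfig,
    OutcomeSpec,
    PhantomSpec,
    SeedBox,
    ThresholdParams,
    cytact,
    extract_cube,
    gen_expression,
    gen_icb_cohort,
    gen_phantom_cohort,
    gen_latent_scores,
    patient_biomarker_table,
    pet_features,
    predict_cytact,
    rank_sum_test,
    roc_analysis,
    save_ensemble,
    segment_tumor,
    spearman_rho,
    survival_analysis,
    train_cv,
)
from .pet_io import PETVolume, SegmentationMask
from .segmentation import SegmentationError


class PipelineError(RuntimeError):
    pass


def seed_box_from_mask(mask: SegmentationMask, pad: int = 3) -> SeedBox:
    """Axis-aligned box around a known lesion, padded — the stand-in for the
    user-drawn box of the semi-automatic workflow."""
    idx = np.argwhere(mask.data)
    if idx.size == 0:
        raise PipelineError("cannot derive a seed box from an empty mask")
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, mask.data.shape)
    return SeedBox(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])


def segment_cohort(
    vols: list[PETVolume],
    masks: list[SegmentationMask],
    beta: float = 0.3,
    pad: int = 3,
) -> tuple[list[SegmentationMask], pd.DataFrame]:
    """Segment every lesion with the adaptive threshold; returns masks and a
    PET-feature table (SUVmax, SUVmean, MTV)."""
    seg_masks, rows = [], []
    for i, (vol, truth) in enumerate(zip(vols, masks)):
        params = ThresholdParams(seed_box=seed_box_from_mask(truth, pad=pad), beta=beta)
        seg = segment_tumor(vol, params)
        feats = pet_features(vol, seg)
        seg_masks.append(seg)
        rows.append({"index": i, **feats.to_dict(), "n_voxels": seg.n_voxels})
    return seg_masks, pd.DataFrame(rows)


def cubes_from_cohort(vols, seg_masks, table, side_mm: float):
    return [
        extract_cube(
            vol, seg, side_mm=side_mm,
            patient_id=str(row.patient_id), lesion_id=str(row.lesion_id),
        )
        for vol, seg, row in zip(vols, seg_masks, table.itertuples(index=False))
    ]


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    seed: int = 0
    training: PhantomSpec = field(default_factory=PhantomSpec)
    icb: PhantomSpec = field(default_factory=lambda: PhantomSpec(
        n_patients=29, lesions_per_patient_probs=(0.35, 0.30, 0.20, 0.15),
        hetero_traits=True,
    ))
    outcome: OutcomeSpec = field(default_factory=OutcomeSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    folds: int = 10
    cube_side_mm: float = 32.0
    expression_noise_sd: float = 0.15
    corr_ifng: float = 0.5
    beta: float = 0.3
    save_volumes: bool = False

    def __post_init__(self) -> None:
        # propagate the master seed into every stage that has its own RNG
        for obj, off in ((self.training, 1), (self.icb, 2), (self.outcome, 3),
                         (self.model, 4), (self.augmentation, 5)):
            obj.rng_seed = int(self.seed) * 10 + off

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        kwargs = dict(raw)
        for key, typ in (("training", PhantomSpec), ("icb", PhantomSpec),
                         ("outcome", OutcomeSpec), ("model", ModelConfig),
                         ("augmentation", AugmentationPolicy)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in kwargs[key].items()
                }
                kwargs[key] = typ(**sub)
        return cls(**kwargs)


def run_pipeline(config: RunConfig, out_dir: str | Path, verbose: bool = True) -> dict:
    """Execute the full synthetic study and write artifacts to ``out_dir``.

    Stages: phantom simulation, adaptive-threshold segmentation, expression
    scoring, cross-validated CNN training, application to a simulated ICB
    cohort, per-patient biomarkers, and the outcome statistics.  Returns the
    metrics dict (also written as ``metrics.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    t0 = time.time()

    def log(msg: str) -> None:
        if verbose:
            print(f"[immunopet] {msg}", flush=True)

    # --- training cohort ---------------------------------------------------
    log(f"simulating training cohort (n={config.training.n_patients})")
    vols, truth_masks, table = gen_phantom_cohort(config.training)

    log("segmenting training lesions")
    try:
        seg_masks, feats = segment_cohort(vols, truth_masks, beta=config.beta)
    except SegmentationError as exc:
        raise PipelineError(f"stage 'segment' failed: {exc}") from exc
    feats.to_csv(out / "training_pet_features.csv", index=False)

    log("scoring synthetic expression (CytAct)")
    expr = gen_expression(
        table.set_index("lesion_id")["u"],
        noise_sd=config.expression_noise_sd,
        corr_ifng=config.corr_ifng,
        rng_seed=config.seed * 10 + 6,
    )
    expr.write_tsv(out / "training_expression.tsv")
    scores = cytact(expr)
    table = table.assign(cytact=scores.loc[table["lesion_id"]].to_numpy())
    table.to_csv(out / "training_lesions.csv", index=False)

    log(f"training {config.folds}-fold CNN ensemble")
    cubes = cubes_from_cohort(vols, seg_masks, table, config.cube_side_mm)
    cv, models = train_cv(
        cubes, table["cytact"].to_numpy(), cfg=config.model,
        folds=config.folds, policy=config.augmentation, verbose=verbose,
    )
    save_ensemble(models, out / "models")
    pd.DataFrame(
        {"lesion_id": table["lesion_id"], "fold": cv.fold_id,
         "cytact": table["cytact"], "oof_pred": cv.oof_pred}
    ).to_csv(out / "training_oof_predictions.csv", index=False)

    # --- ICB cohort ----------------------------------------------------------
    log(f"simulating ICB cohort (n={config.icb.n_patients})")
    icb_vols, icb_truth, icb_table = gen_phantom_cohort(config.icb)
    icb_seg, _ = segment_cohort(icb_vols, icb_truth, beta=config.beta)
    icb_cubes = cubes_from_cohort(icb_vols, icb_seg, icb_table, config.cube_side_mm)
    preds = np.array([predict_cytact(models, c) for c in icb_cubes])
    lesion_df, patient_df = gen_icb_cohort(icb_table, config.outcome, predicted_cytact=preds)
    lesion_df.to_csv(out / "icb_lesions.csv", index=False)
    patient_df.to_csv(out / "icb_patients.csv", index=False)

    # --- biomarkers + statistics ---------------------------------------------
    log("computing biomarkers and statistics")
    bio = patient_biomarker_table(lesion_df)
    merged = bio.merge(patient_df, on="patient_id")
    roc_min = roc_analysis(merged["min_cytact"], merged["responder"])
    cutoff = roc_min.optimal_cutoff
    bio = patient_biomarker_table(lesion_df, cutoff=cutoff)
    merged = bio.merge(patient_df, on="patient_id")
    merged.to_csv(out / "icb_biomarkers.csv", index=False)

    lesion_rho = spearman_rho(lesion_df["predicted_cytact"], lesion_df["size_change_pct"])
    # univariate logistic regression: response ~ min CytAct (Firth fallback
    # when the groups separate perfectly)
    from .stats import SeparationError, logistic_fit

    merged_resp = merged["responder"].astype(float).to_numpy()
    try:
        logit = logistic_fit(merged_resp, merged[["min_cytact"]])
    except SeparationError:
        logit = logistic_fit(merged_resp, merged[["min_cytact"]], firth=True)
    multi = merged[merged["cytact_variance"].notna()]
    metrics = {
        "training_pooled_spearman": cv.pooled_spearman,
        "training_pooled_spearman_p": cv.pooled_spearman_p,
        "lesion_spearman_pred_vs_size_change": lesion_rho.statistic,
        "lesion_spearman_p": lesion_rho.p_value,
        "logistic_min_cytact_coef": float(logit.loc["min_cytact", "coef"]),
        "logistic_min_cytact_p": float(logit.loc["min_cytact", "p"]),
        "auc_min_cytact": roc_min.auc,
        "auc_mean_cytact": roc_analysis(merged["mean_cytact"], merged["responder"]).auc,
        "auc_max_cytact": roc_analysis(merged["max_cytact"], merged["responder"]).auc,
        "cutoff": cutoff,
        "n_patients_icb": int(len(merged)),
        "n_lesions_icb": int(len(lesion_df)),
        "n_multilesion": int(len(multi)),
        "runtime_s": round(time.time() - t0, 1),
    }
    if multi["responder"].nunique() == 2:
        vr = rank_sum_test(
            multi.loc[~multi["responder"], "cytact_variance"],
            multi.loc[multi["responder"], "cytact_variance"],
        )
        metrics["variance_ranksum_p"] = vr.p_value
    if merged["group"].nunique() == 2 and merged["pfs_event"].sum() > 0:
        surv = survival_analysis(merged["pfs_months"], merged["pfs_event"], merged["group"])
        metrics["pfs_logrank_p"] = surv.logrank_p
        if surv.hr_defined:
            # HR of the "low" group relative to "high" (alphabetical levels)
            metrics["pfs_hr_low_vs_high"] = surv.hazard_ratio

    (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
    log(f"done in {metrics['runtime_s']}s -> {out}")
    return metrics
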