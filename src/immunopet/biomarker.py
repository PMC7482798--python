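"""Per-patient biomarkers from lesion-level predicted CytAct.

RECIST-style target-lesion selection (lymph nodes >= 15 mm short axis, all
other lesions >= 10 mm long axis), aggregation of lesion predictions into a
representative per-patient value (the minimum, i.e. the least immunogenic
lesion), heterogeneity as the sample variance across a patient's lesions,
and dichotomization at a cutoff (ties go to the "low" group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_SITES = frozenset(
    {"lung", "lymph_node", "adrenal", "bone", "mediastinum", "pleura", "soft_tissue", "other"}
)
NODE_MIN_SHORT_AXIS_MM = 15.0
OTHER_MIN_LONG_AXIS_MM = 10.0
#: representative-CytAct cutoff from the original ROC analysis
DEFAULT_CUTOFF = -0.107

RESPONSES = ("PR", "SD", "PD")


class BiomarkerError(ValueError):
    pass


@dataclass
class LesionRecord:
    """One measurable lesion: RECIST size, size change and predicted CytAct."""

    patient_id: str
    lesion_id: str
    site: str
    baseline_size_mm: float  # long axis; short axis for lymph nodes
    predicted_cytact: float
    size_change_pct: float | None = None
    pdl1_pct: float | None = None

    def __post_init__(self) -> None:
        if self.site not in VALID_SITES:
            raise BiomarkerError(f"unknown site tag {self.site!r} for {self.lesion_id}")
        if self.baseline_size_mm <= 0:
            raise BiomarkerError(f"baseline size must be positive ({self.lesion_id})")
        if self.size_change_pct is not None and self.size_change_pct < -100:
            raise BiomarkerError("size change below -100%")


@dataclass
class PatientRecord:
    patient_id: str
    lesions: list[LesionRecord]
    best_response: str
    pfs_months: float | None = None
    pfs_event: int | None = None
    os_months: float | None = None
    os_event: int | None = None
    pdl1_pct: float | None = None

    def __post_init__(self) -> None:
        if not self.lesions:
            raise BiomarkerError(f"patient {self.patient_id} has no lesions")
        if self.best_response not in RESPONSES:
            raise BiomarkerError(f"best_response must be one of {RESPONSES}")
        for t in (self.pfs_months, self.os_months):
            if t is not None and t <= 0:
                raise BiomarkerError("survival times must be positive")

    @property
    def responder(self) -> bool:
        return self.best_response == "PR"


@dataclass
class PatientBiomarkers:
    patient_id: str
    min_cytact: float
    mean_cytact: float
    max_cytact: float
    cytact_variance: float | None  # None for single-lesion patients
    n_lesions: int
    group: str | None = None  # "high"/"low" after dichotomization


def filter_target_lesions(records: Iterable[LesionRecord]) -> list[LesionRecord]:
    """Keep RECIST-measurable target lesions.

    Lymph nodes qualify at >= 15 mm short axis; all other sites at >= 10 mm
    long axis.
    """
    kept = []
    for r in records:
        floor = NODE_MIN_SHORT_AXIS_MM if r.site == "lymph_node" else OTHER_MIN_LONG_AXIS_MM
        if r.baseline_size_mm >= floor:
            kept.append(r)
    return kept


def aggregate_patient(lesions: Sequence[LesionRecord]) -> PatientBiomarkers:
    """Min / mean / max predicted CytAct and (for >= 2 lesions) its variance."""
    if not lesions:
        raise BiomarkerError("empty lesion list")
    pid = lesions[0].patient_id
    if any(l.patient_id != pid for l in lesions):
        raise BiomarkerError("lesions from multiple patients")
    vals = np.array([l.predicted_cytact for l in lesions], dtype=float)
    var = float(vals.var(ddof=1)) if len(vals) >= 2 else None
    return PatientBiomarkers(
        patient_id=pid,
        min_cytact=float(vals.min()),
        mean_cytact=float(vals.mean()),
        max_cytact=float(vals.max()),
        cytact_variance=var,
        n_lesions=len(vals),
    )


def dichotomize(
    biomarkers: Sequence[PatientBiomarkers], cutoff: float = DEFAULT_CUTOFF
) -> list[str]:
    """Label patients "high" if min CytAct is strictly above the cutoff.

    Values exactly at the cutoff go to "low": the cutoff is the optimal ROC
    point for detecting responders among *higher* values.
    """
    labels = []
    for b in biomarkers:
        if not math.isfinite(b.min_cytact):
            raise BiomarkerError(f"min_cytact undefined for {b.patient_id}")
        lab = "high" if b.min_cytact > cutoff else "low"
        b.group = lab
        labels.append(lab)
    return labels


# ---------------------------------------------------------------------------
# table-level convenience
# ---------------------------------------------------------------------------

def lesions_from_frame(df: pd.DataFrame) -> list[LesionRecord]:
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            LesionRecord(
                patient_id=str(row.patient_id),
                lesion_id=str(row.lesion_id),
                site=str(row.site),
                baseline_size_mm=float(row.baseline_size_mm),
                predicted_cytact=float(row.predicted_cytact),
                size_change_pct=float(row.size_change_pct) if hasattr(row, "size_change_pct") else None,
                pdl1_pct=float(row.pdl1_pct) if hasattr(row, "pdl1_pct") else None,
            )
        )
    return recs


def patient_biomarker_table(
    lesion_df: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    apply_size_filter: bool = True,
) -> pd.DataFrame:
    """Per-patient biomarker table from a lesion table.

    Patients whose every lesion fails the RECIST size floors are dropped
    (they have no measurable target lesion).
    """
    records = lesions_from_frame(lesion_df)
    if apply_size_filter:
        records = filter_target_lesions(records)
    by_patient: dict[str, list[LesionRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    biomarkers = [aggregate_patient(ls) for ls in by_patient.values()]
    dichotomize(biomarkers, cutoff)
    return pd.DataFrame(
        {
            "patient_id": [b.patient_id for b in biomarkers],
            "n_lesions": [b.n_lesions for b in biomarkers],
            "min_cytact": [b.min_cytact for b in biomarkers],
            "mean_cytact": [b.mean_cytact for b in biomarkers],
            "max_cytact": [b.max_cytact for b in biomarkers],
            "cytact_variance": [b.cytact_variance for b in biomarkers],
            "group": [b.group for b in biomarkers],
        }
    )
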