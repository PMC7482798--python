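"""Seeded synthetic cohorts: PET phantoms, matched expression, ICB outcomes.

The generator encodes a latent per-lesion immune score ``u`` (standard
normal) into three observable layers:

* **imaging** — each lesion is an ellipsoidal blob whose rim-to-core uptake
  contrast and speckle amplitude increase strictly monotonically with ``u``
  (a stand-in for the unknown radiogenomic texture structure a CNN can
  learn at patch scale);
* **expression** — GZMA and PRF1 log2 values are affine in ``u`` plus noise,
  so the CytAct of the generated matrix recovers ``u``; six IFN-gamma genes
  are generated with a configurable target correlation to ``u``;
* **outcome** — per-lesion size change decreases linearly in ``u``; a patient
  responds (PR) only if *every* lesion shrinks past the RECIST partial
  response threshold, so response is driven by the worst lesion; survival
  hazards fall with the minimum lesion score and (optionally) rise with
  inter-lesion score variance.

Everything is driven by integer seeds and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .immune_scores import CYTACT_GENES, IFNG_GENES, ExpressionMatrix
from .pet_io import PETVolume, SegmentationMask

SITES = ("lung", "lymph_node", "adrenal", "bone", "mediastinum", "pleura", "soft_tissue")
#: site frequencies matching a metastatic lung-adenocarcinoma lesion mix
SITE_PROBS = (0.333, 0.283, 0.117, 0.100, 0.067, 0.050, 0.050)


def _subseed(seed: int, *keys: int) -> int:
    return int(np.random.SeedSequence([int(seed), *map(int, keys)]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# phantom imaging
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Imaging phantom cohort parameters.

    The texture link maps the latent score ``u`` to a rim-to-core uptake
    contrast ``c(u) = -0.35 + 1.3 * expit(1.2 u)`` (strictly increasing:
    cold-rim lesions at very low ``u``, hot-rim at high ``u``) and to a
    speckle gain multiplying the intra-lesion noise.
    """

    n_patients: int = 300
    lesions_per_patient_probs: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0)
    patient_corr: float = 0.5  # within-patient correlation of lesion scores
    # heterogeneity-trait mode (used for ICB cohorts): each patient carries a
    # latent mean and a lognormal within-patient spread, so some patients have
    # immunologically homogeneous lesions and others highly divergent ones
    hetero_traits: bool = False
    patient_mean_sd: float = 0.8
    lesion_spread_median: float = 0.5
    lesion_spread_logsd: float = 1.6
    lesion_spread_clip: tuple[float, float] = (0.1, 2.5)
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: float = 2.0
    radius_range_mm: tuple[float, float] = (8.0, 14.0)
    aspect_jitter: float = 0.15
    background_mean: float = 1.0
    background_sd: float = 0.05  # per-volume background level variation
    tumor_uptake: float = 6.0
    psf_sigma_mm: float = 1.0
    noise_sd: float = 0.08  # voxel noise (SUV); 0 switches all noise off
    rng_seed: int = 0

    def rim_contrast(self, u) -> np.ndarray:
        return -0.35 + 1.3 * expit(1.2 * np.asarray(u, dtype=float))

    def speckle_gain(self, u) -> np.ndarray:
        return 2.0 + 4.0 * expit(np.asarray(u, dtype=float))


def _lesion_profile(spec: PhantomSpec, radii_vox: np.ndarray, u: float,
                    shape: tuple[int, int, int], center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic lesion intensity and mask on the full volume grid."""
    grids = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    rho2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox))
    rho = np.sqrt(rho2)
    inside = rho <= 1.0
    rim = np.exp(-((rho - 0.75) ** 2) / (2 * 0.16**2))
    intensity = spec.tumor_uptake * (1.0 + spec.rim_contrast(u) * rim) * inside
    return intensity, inside


def texture_statistic(vol: PETVolume, center, radii_vox) -> float:
    """Brute-force rim/core uptake ratio from ground-truth lesion geometry.

    An independent check that the imaging actually encodes the latent score:
    mean uptake in the rim band (0.55 <= rho <= 0.95) over mean uptake in the
    core (rho <= 0.45).
    """
    shape = vol.data.shape
    grids = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    rho = np.sqrt(sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox)))
    core = vol.data[rho <= 0.45]
    band = vol.data[(rho >= 0.55) & (rho <= 0.95)]
    return float(band.mean() / core.mean())


def gen_latent_scores(spec: PhantomSpec) -> pd.DataFrame:
    """Draw patients, lesion counts and per-lesion latent scores."""
    rng = np.random.default_rng(_subseed(spec.rng_seed, 0))
    probs = np.asarray(spec.lesions_per_patient_probs, dtype=float)
    probs = probs / probs.sum()
    rows = []
    for p in range(spec.n_patients):
        n_lesions = int(rng.choice(len(probs), p=probs)) + 1
        if spec.hetero_traits:
            m = spec.patient_mean_sd * rng.standard_normal()
            spread = float(np.clip(
                spec.lesion_spread_median * np.exp(spec.lesion_spread_logsd * rng.standard_normal()),
                *spec.lesion_spread_clip,
            ))
        else:
            m = np.sqrt(spec.patient_corr) * rng.standard_normal()
            spread = np.sqrt(1 - spec.patient_corr)
        for l in range(n_lesions):
            u = m + spread * rng.standard_normal()
            rows.append({"patient_id": f"P{p:04d}", "lesion_id": f"P{p:04d}_L{l}", "u": u})
    return pd.DataFrame(rows)


def gen_phantom_cohort(
    spec: PhantomSpec, latent: pd.DataFrame | None = None
) -> tuple[list[PETVolume], list[SegmentationMask], pd.DataFrame]:
    """Generate one PET phantom volume (and ground-truth mask) per lesion.

    Returns volumes, masks and the lesion table (latent score, center and
    radii in voxels, and the analytic rim/core texture statistic).
    """
    table = (latent if latent is not None else gen_latent_scores(spec)).copy().reset_index(drop=True)
    shape = spec.volume_shape
    vols: list[PETVolume] = []
    masks: list[SegmentationMask] = []
    extra = {k: [] for k in ("cz", "cy", "cx", "rz", "ry", "rx", "texture_stat")}
    rmax_vox = spec.radius_range_mm[1] / spec.spacing_mm
    for i, row in table.iterrows():
        rng = np.random.default_rng(_subseed(spec.rng_seed, 1, i))
        u = float(row["u"])
        r_mm = rng.uniform(*spec.radius_range_mm)
        radii = (r_mm / spec.spacing_mm) * (1.0 + spec.aspect_jitter * rng.uniform(-1, 1, size=3))
        margin = int(np.ceil(rmax_vox * (1 + spec.aspect_jitter))) + 2
        if any(2 * margin >= s for s in shape):
            raise ValueError("lesion (plus margin) larger than volume")
        center = np.array([rng.integers(margin, s - margin) for s in shape])

        lesion, inside = _lesion_profile(spec, radii, u, shape, center)
        bg_level = spec.background_mean
        if spec.noise_sd > 0:
            bg_level = max(bg_level + spec.background_sd * rng.standard_normal(), 0.05)
        clean = bg_level + lesion
        sigma_vox = spec.psf_sigma_mm / spec.spacing_mm
        img = ndimage.gaussian_filter(clean, sigma=sigma_vox)
        if spec.noise_sd > 0:
            noise = spec.noise_sd * rng.standard_normal(shape)
            noise[inside] *= spec.speckle_gain(u)
            img = img + noise
        img = np.clip(img, 0, None)

        vols.append(PETVolume(data=img, spacing=(spec.spacing_mm,) * 3))
        masks.append(SegmentationMask(data=inside, spacing=(spec.spacing_mm,) * 3))
        for k, v in zip(("cz", "cy", "cx"), center):
            extra[k].append(int(v))
        for k, v in zip(("rz", "ry", "rx"), radii):
            extra[k].append(float(v))
        extra["texture_stat"].append(texture_statistic(vols[-1], center, radii))
    for k, v in extra.items():
        table[k] = v
    return vols, masks, table


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression(
    latent: pd.Series | np.ndarray,
    noise_sd: float = 0.15,
    corr_ifng: float = 0.5,
    rng_seed: int = 0,
    sample_ids=None,
) -> ExpressionMatrix:
    """Log2-scale expression matrix whose CytAct recovers the latent score.

    GZMA and PRF1 are affine in ``u`` with independent Gaussian noise; the
    six IFN-gamma genes load on a factor correlated with ``u`` at
    ``corr_ifng``.
    """
    u = np.asarray(latent, dtype=float)
    if sample_ids is None:
        sample_ids = (
            list(latent.index) if isinstance(latent, pd.Series)
            else [f"S{i:04d}" for i in range(len(u))]
        )
    rng = np.random.default_rng(rng_seed)
    n = len(u)
    rows = {}
    for gene, (a, b) in zip(CYTACT_GENES, ((8.0, 1.5), (7.0, 1.2))):
        rows[gene] = a + b * u + noise_sd * rng.standard_normal(n)
    c = float(np.clip(corr_ifng, -1, 1))
    factor = c * u + np.sqrt(1 - c**2) * rng.standard_normal(n)
    for gene in IFNG_GENES:
        a = rng.uniform(5, 9)
        b = rng.uniform(0.8, 1.5)
        rows[gene] = a + b * factor + noise_sd * rng.standard_normal(n)
    # housekeeping filler unrelated to the latent score
    for gene in ("ACTB", "GAPDH"):
        rows[gene] = rng.uniform(9, 11) + noise_sd * rng.standard_normal(n)
    df = pd.DataFrame(rows, index=sample_ids).T
    return ExpressionMatrix(values=df, log2=True)


# ---------------------------------------------------------------------------
# ICB outcomes
# ---------------------------------------------------------------------------

@dataclass
class OutcomeSpec:
    """Multi-lesion ICB outcome model.

    Size change (%) of a lesion is ``a - b * u + e * sd(u_patient) + eps``:
    the heterogeneity term ``e`` (``hetero_size_coef``) is the
    variance-linked resistance — patients with immunologically divergent
    lesions shrink less across the board (set 0 to disable).  A patient is
    PR only if every lesion changes by at most the RECIST partial-response
    threshold (-30%), so the worst (lowest-``u``) lesion drives response.
    Survival is exponential with log-hazard ``-c * min(u) + d * var(u)``
    (variance term active only for multi-lesion patients).  Defaults were
    set once to match a metastatic-LUAD checkpoint-blockade cohort's
    composition (roughly half of patients responding, about two lesions per
    patient, a strong negative lesion-wise score/size-change correlation).
    """

    size_intercept: float = -45.0  # a: mean % size change at u = 0
    size_slope: float = 20.0       # b: % size change per unit of u
    size_noise_sd: float = 4.0
    hetero_size_coef: float = 25.0  # e: variance-linked resistance, % per sd(u)
    pr_threshold_pct: float = -30.0
    pd_threshold_pct: float = 0.0   # any growing lesion counts as progression
    median_pfs_months: float = 6.0
    hazard_cytact_coef: float = 1.0   # c
    hazard_hetero_coef: float = 0.5   # d
    os_hazard_factor: float = 0.5     # OS hazard relative to PFS hazard
    censoring_rate: float = 0.2
    horizon_months: float = 30.0
    pred_noise_sd: float = 0.4        # predicted-CytAct noise when no model is supplied
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.size_slope <= 0 or self.hazard_cytact_coef <= 0:
            raise ValueError("size_slope and hazard_cytact_coef must be positive")


def _survival_times(rng, log_hr: np.ndarray, median0: float, spec: OutcomeSpec):
    lam = np.log(2) / median0 * np.exp(log_hr)
    t = rng.exponential(1.0 / lam)
    t = np.clip(t, 1e-3, None)
    event = np.ones(len(t), dtype=int)
    cens = rng.random(len(t)) < spec.censoring_rate
    t_cens = rng.uniform(0.5, np.maximum(t, 0.6))
    t = np.where(cens, t_cens, t)
    event = np.where(cens, 0, event)
    over = t > spec.horizon_months
    t = np.where(over, spec.horizon_months, t)
    event = np.where(over, 0, event)
    return t, event


def gen_icb_cohort(
    lesion_table: pd.DataFrame,
    spec: OutcomeSpec | None = None,
    predicted_cytact: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate lesion-level and patient-level ICB outcome tables.

    ``lesion_table`` needs ``patient_id``, ``lesion_id`` and ``u`` columns
    (as produced by :func:`gen_latent_scores`).  ``predicted_cytact``
    overrides the built-in noisy surrogate with model predictions.
    """
    spec = spec or OutcomeSpec()
    rng = np.random.default_rng(_subseed(spec.rng_seed, 10))
    lt = lesion_table.copy().reset_index(drop=True)
    n = len(lt)
    u = lt["u"].to_numpy(dtype=float)

    site_idx = rng.choice(len(SITES), size=n, p=np.asarray(SITE_PROBS))
    lt["site"] = [SITES[i] for i in site_idx]
    # target-lesion sizes: nodes measured on short axis (>= 15 mm floor),
    # everything else on long axis (>= 10 mm floor)
    is_node = lt["site"] == "lymph_node"
    size = np.where(is_node, rng.uniform(15, 35, size=n), rng.uniform(10, 60, size=n))
    lt["baseline_size_mm"] = np.round(size, 1)

    pct = spec.size_intercept - spec.size_slope * u + spec.size_noise_sd * rng.standard_normal(n)
    if spec.hetero_size_coef != 0:
        spread = lt.groupby("patient_id")["u"].transform(
            lambda g: g.std(ddof=1) if len(g) > 1 else 0.0
        ).to_numpy()
        pct = pct + spec.hetero_size_coef * spread
    lt["size_change_pct"] = np.clip(pct, -100.0, None)

    if predicted_cytact is None:
        predicted_cytact = u + spec.pred_noise_sd * rng.standard_normal(n)
    lt["predicted_cytact"] = np.asarray(predicted_cytact, dtype=float)
    lt["pdl1_pct"] = np.round(np.clip(30 + 25 * u + 20 * rng.standard_normal(n), 0, 100), 0)

    patients = []
    for pid, grp in lt.groupby("patient_id", sort=True):
        worst_pct = grp["size_change_pct"].max()
        if worst_pct <= spec.pr_threshold_pct:
            best = "PR"
        elif worst_pct >= spec.pd_threshold_pct:
            best = "PD"
        else:
            best = "SD"
        uu = grp["u"].to_numpy()
        log_hr = -spec.hazard_cytact_coef * uu.min()
        if len(uu) > 1:
            log_hr += spec.hazard_hetero_coef * uu.var(ddof=1)
        patients.append({"patient_id": pid, "best_response": best, "log_hr": log_hr})
    pt = pd.DataFrame(patients)
    pt["responder"] = pt["best_response"] == "PR"

    pfs, pfs_event = _survival_times(rng, pt["log_hr"].to_numpy(), spec.median_pfs_months, spec)
    os_, os_event = _survival_times(
        rng, pt["log_hr"].to_numpy() + np.log(spec.os_hazard_factor),
        spec.median_pfs_months, spec,
    )
    pt["pfs_months"], pt["pfs_event"] = np.round(pfs, 3), pfs_event
    pt["os_months"], pt["os_event"] = np.round(os_, 3), os_event
    pt = pt.drop(columns="log_hr")
    return lt, pt
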