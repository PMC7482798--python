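"""Adaptive-threshold tumor segmentation and conventional PET features.

A lesion is segmented semi-automatically: the user supplies an axis-aligned
seed box around the lesion, and the threshold is derived from the uptake
statistics inside and around that box,

    T = beta * I_70 + I_background

where ``I_70`` is the mean uptake of seed-box voxels brighter than 70% of the
seed-box maximum and ``I_background`` is the mean uptake of a shell of
voxels just outside the box.  ``beta`` defaults to 0.3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .pet_io import PETVolume, SegmentationMask

#: 26-connectivity structuring element for blob-like PET lesions.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(ValueError):
    pass


@dataclass
class SeedBox:
    """Half-open voxel box ``[z0, z1) x [y0, y1) x [x0, x1)``."""

    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        if not (self.z0 < self.z1 and self.y0 < self.y1 and self.x0 < self.x1):
            raise SegmentationError(f"empty seed box: {self}")
        if min(self.z0, self.y0, self.x0) < 0:
            raise SegmentationError(f"seed box outside volume: {self}")

    @classmethod
    def from_bounds(cls, bounds) -> "SeedBox":
        return cls(*[int(b) for b in bounds])

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(self.z0, self.z1), slice(self.y0, self.y1), slice(self.x0, self.x1))

    def validate_inside(self, shape: tuple[int, ...]) -> None:
        if self.z1 > shape[0] or self.y1 > shape[1] or self.x1 > shape[2]:
            raise SegmentationError(f"seed box {self} exceeds volume shape {shape}")


@dataclass
class ThresholdParams:
    """Parameters of the adaptive threshold.

    beta:
        Weight of the hot-core mean ``I_70`` in the threshold; 0.3 by default.
    seed_box:
        User-supplied box containing the lesion ("semi-automatic" step).
    background_shell_vox:
        Thickness (voxels) of the background shell dilated outside the box.
    """

    seed_box: SeedBox
    beta: float = 0.3
    background_shell_vox: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.beta <= 1):
            raise SegmentationError(f"beta must be in (0, 1], got {self.beta}")
        if self.background_shell_vox < 1:
            raise SegmentationError("background_shell_vox must be >= 1")


@dataclass
class PETFeatures:
    suv_max: float
    suv_mean: float
    mtv_ml: float
    threshold_used: float | None = None

    def to_dict(self) -> dict:
        return {
            "suv_max": self.suv_max,
            "suv_mean": self.suv_mean,
            "mtv_ml": self.mtv_ml,
            "threshold_used": self.threshold_used,
        }


def _background_shell(shape, box: SeedBox, thickness: int) -> tuple[slice, ...]:
    z0 = max(box.z0 - thickness, 0)
    y0 = max(box.y0 - thickness, 0)
    x0 = max(box.x0 - thickness, 0)
    z1 = min(box.z1 + thickness, shape[0])
    y1 = min(box.y1 + thickness, shape[1])
    x1 = min(box.x1 + thickness, shape[2])
    return (slice(z0, z1), slice(y0, y1), slice(x0, x1))


def adaptive_threshold(vol: PETVolume, params: ThresholdParams) -> float:
    """Compute the adaptive segmentation threshold T = beta*I_70 + I_background.

    The background shell is the set of voxels in the box dilated by
    ``background_shell_vox`` but outside the seed box itself, excluding any
    voxel brighter than 70% of the seed-box maximum (tumor spill-in).  If the
    exclusion empties the shell (e.g. a uniform volume), the mean over the
    full shell is used and a warning is issued.
    """
    box = params.seed_box
    box.validate_inside(vol.data.shape)
    sub = vol.data[box.slices()]
    vmax = float(sub.max())
    hot = sub > 0.70 * vmax
    if not hot.any():  # only possible when vmax <= 0
        raise SegmentationError("seed box contains no voxel above background")
    i70 = float(sub[hot].mean())

    inside = np.zeros(vol.data.shape, dtype=bool)
    inside[box.slices()] = True
    dilated = np.zeros_like(inside)
    dilated[_background_shell(vol.data.shape, box, params.background_shell_vox)] = True
    shell = dilated & ~inside
    if not shell.any():
        warnings.warn("seed box touches all volume bounds; I_background set to 0")
        i_bg = 0.0
    else:
        shell_vals = vol.data[shell]
        keep = shell_vals <= 0.70 * vmax
        if keep.any():
            i_bg = float(shell_vals[keep].mean())
        else:
            warnings.warn(
                "all background-shell voxels exceed 70% of seed-box max; "
                "using unfiltered shell mean (degenerate lesion?)"
            )
            i_bg = float(shell_vals.mean())

    threshold = params.beta * i70 + i_bg
    if i70 <= i_bg:
        warnings.warn(
            f"I_70 ({i70:.4g}) not greater than I_background ({i_bg:.4g}); "
            "lesion may be degenerate"
        )
    return threshold


def segment_tumor(vol: PETVolume, params: ThresholdParams) -> SegmentationMask:
    """Threshold the seed box at T and keep the component holding the box maximum.

    Voxels with uptake >= T inside the seed box are candidates; of these only
    the 26-connected component containing the seed-box maximum survives.
    """
    threshold = adaptive_threshold(vol, params)
    box = params.seed_box
    candidates = np.zeros(vol.data.shape, dtype=bool)
    sub = vol.data[box.slices()]
    candidates[box.slices()] = sub >= threshold
    if not candidates.any():
        raise SegmentationError(
            f"no lesion above threshold (T={threshold:.4g}) in seed box"
        )
    labels, _ = ndimage.label(candidates, structure=CONNECTIVITY_26)
    # seed point: first occurrence of the seed-box maximum (C order)
    local = np.unravel_index(int(np.argmax(sub)), sub.shape)
    seed = (local[0] + box.z0, local[1] + box.y0, local[2] + box.x0)
    lab = labels[seed]
    if lab == 0:  # max below threshold: can only happen in degenerate cases
        raise SegmentationError("seed-box maximum falls below the threshold")
    return SegmentationMask(data=labels == lab, spacing=vol.spacing)


def pet_features(vol: PETVolume, mask: SegmentationMask, threshold: float | None = None) -> PETFeatures:
    """SUVmax / SUVmean over the mask and metabolic tumor volume in mL."""
    if mask.data.shape != vol.data.shape:
        raise SegmentationError("mask and volume shapes differ")
    vals = vol.data[mask.data]
    if vals.size == 0:
        raise SegmentationError("empty mask")
    mtv_ml = mask.n_voxels * vol.voxel_volume_mm3 / 1000.0
    return PETFeatures(
        suv_max=float(vals.max()),
        suv_mean=float(vals.mean()),
        mtv_ml=float(mtv_ml),
        threshold_used=threshold,
    )
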