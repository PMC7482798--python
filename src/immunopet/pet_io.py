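"""Reading, writing and resampling of PET volumes.

Volumes are held as 3-D numpy arrays in ``(z, y, x)`` axis order with a
millimetre voxel spacing per axis.  NIfTI-1 is the canonical on-disk format;
acquisition metadata needed for SUV conversion (injected dose, body weight)
travels in a JSON sidecar next to the image file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage


class PETIOError(ValueError):
    """Raised for malformed volumes or metadata."""


@dataclass
class PETVolume:
    """A 3-D uptake volume.

    Parameters
    ----------
    data:
        Non-negative voxel values, axis order ``(z, y, x)``.  Units are SUV
        once :func:`suv_normalize` has been applied, otherwise whatever the
        scanner produced (typically kBq/mL).
    spacing:
        Voxel edge lengths in mm, one per array axis ``(dz, dy, dx)``.
    meta:
        Optional acquisition metadata, e.g. ``injected_dose_Bq``,
        ``body_weight_g``, ``suv`` flag.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise PETIOError(f"expected 3-D volume, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise PETIOError("voxel values must be finite")
        if np.any(self.data < 0):
            raise PETIOError("voxel values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise PETIOError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def is_isotropic(self, rtol: float = 1e-6) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0], rtol=rtol))


@dataclass
class SegmentationMask:
    """Boolean lesion mask aligned voxel-for-voxel with its parent volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise PETIOError(f"expected 3-D mask, got {self.data.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise PETIOError("spacing must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(path: str | Path) -> PETVolume:
    """Read a 3-D NIfTI volume (and its JSON sidecar, if present)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 4 and arr.shape[3] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise PETIOError(f"expected 3-D volume, got {arr.ndim}-D in {path}")
    zooms = img.header.get_zooms()[:3]
    # NIfTI stores (x, y, z); internal convention is (z, y, x).
    data = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    meta: dict[str, Any] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return PETVolume(data=data.astype(np.float64), spacing=spacing, meta=meta)


def write_volume(vol: PETVolume | SegmentationMask, path: str | Path) -> Path:
    """Write a volume or mask as NIfTI-1; metadata goes to a JSON sidecar."""
    path = Path(path)
    data = vol.data
    if isinstance(vol, SegmentationMask):
        data = data.astype(np.uint8)
    arr = np.transpose(data, (2, 1, 0))
    dz, dy, dx = vol.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr), affine), str(path))
    meta = getattr(vol, "meta", None)
    if meta:
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_mask(path: str | Path) -> SegmentationMask:
    vol = read_volume(path)
    return SegmentationMask(data=vol.data > 0.5, spacing=vol.spacing)


def suv_normalize(vol: PETVolume) -> PETVolume:
    """Convert activity concentration (Bq/mL) to standardized uptake value.

    SUV = concentration * body weight / injected dose; with weight in g and
    dose in Bq the (g/mL) tissue-density convention cancels the units.
    """
    dose = vol.meta.get("injected_dose_Bq")
    weight = vol.meta.get("body_weight_g")
    if dose is None or weight is None:
        raise PETIOError("meta must contain injected_dose_Bq and body_weight_g")
    if dose <= 0 or weight <= 0:
        raise PETIOError("injected dose and body weight must be positive")
    if vol.meta.get("suv"):
        raise PETIOError("volume is already SUV-normalized")
    data = vol.data * (float(weight) / float(dose))
    meta = dict(vol.meta)
    meta["suv"] = True
    return PETVolume(data=data, spacing=vol.spacing, meta=meta)


def resample_isotropic(vol: PETVolume, target_mm: float) -> PETVolume:
    """Resample to isotropic voxels of edge ``target_mm`` (trilinear)."""
    if target_mm <= 0:
        raise PETIOError("target_mm must be positive")
    if any(n < 2 for n in vol.data.shape):
        raise PETIOError("volume too small to resample (needs >= 2 voxels per axis)")
    if np.allclose(vol.spacing, target_mm):
        return replace(vol, data=vol.data.copy())
    factors = [s / target_mm for s in vol.spacing]
    # grid_mode treats voxels as cells, which keeps total activity
    # (sum times voxel volume) conserved for smooth fields
    data = ndimage.zoom(vol.data, factors, order=1, mode="grid-constant",
                        grid_mode=True, prefilter=False)
    data = np.clip(data, 0, None)
    return PETVolume(data=data, spacing=(target_mm,) * 3, meta=dict(vol.meta))


def resample_mask_isotropic(mask: SegmentationMask, target_mm: float) -> SegmentationMask:
    """Nearest-neighbour resampling for masks (keeps values boolean)."""
    if target_mm <= 0:
        raise PETIOError("target_mm must be positive")
    if np.allclose(mask.spacing, target_mm):
        return SegmentationMask(data=mask.data.copy(), spacing=mask.spacing)
    factors = [s / target_mm for s in mask.spacing]
    data = ndimage.zoom(mask.data.astype(np.float32), factors, order=0,
                        mode="grid-constant", grid_mode=True, prefilter=False)
    return SegmentationMask(data=data > 0.5, spacing=(target_mm,) * 3)
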