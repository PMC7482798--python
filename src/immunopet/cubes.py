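"""Cube extraction around segmented lesions and rotation augmentation.

The network consumes a fixed-size cubic patch centred on the lesion
centroid, cut from the isotropically resampled volume with the surrounding
context retained (the cube *contains* the lesion, it is not masked to it).
Augmentation rotates each cube by three independent uniform angles in
[0, 90] degrees about the z, y and x axes in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .pet_io import PETVolume, SegmentationMask

#: default cube edge in mm; 16 voxels at 2 mm isotropic spacing
DEFAULT_SIDE_MM = 32.0


class CubeError(ValueError):
    pass


@dataclass
class TumorCube:
    """Fixed-shape normalized cubic patch, the network input."""

    data: np.ndarray
    spacing_mm: float
    norm_mode: str = "max"
    patient_id: str = ""
    lesion_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        s = self.data.shape
        if self.data.ndim != 3 or not (s[0] == s[1] == s[2]):
            raise CubeError(f"cube must be cubic 3-D, got shape {s}")
        if not np.all(np.isfinite(self.data)):
            raise CubeError("cube values must be finite")
        if self.norm_mode not in ("max", "none"):
            raise CubeError(f"unknown norm_mode {self.norm_mode!r}")

    @property
    def side_vox(self) -> int:
        return self.data.shape[0]


@dataclass
class AugmentationPolicy:
    """Random-rotation augmentation: ``n_copies`` per cube, angles uniform
    in ``angle_range_deg`` sampled independently for the z, y, x axes."""

    n_copies: int = 15
    angle_range_deg: tuple[float, float] = (0.0, 90.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise CubeError("n_copies must be >= 1")
        lo, hi = self.angle_range_deg
        if not (0 <= lo < hi):
            raise CubeError(f"invalid angle range {self.angle_range_deg}")


def extract_cube(
    vol: PETVolume,
    mask: SegmentationMask,
    side_mm: float = DEFAULT_SIDE_MM,
    norm_mode: str = "max",
    patient_id: str = "",
    lesion_id: str = "",
) -> TumorCube:
    """Cut a cube of physical edge ``side_mm`` centred on the mask centroid.

    The volume must already be isotropic; regions falling outside the volume
    are zero-padded.  With ``norm_mode='max'`` intensities are divided by the
    cube maximum so inputs are scanner-scale invariant.
    """
    if not vol.is_isotropic():
        raise CubeError(f"volume must be isotropic, spacing={vol.spacing}")
    if mask.data.shape != vol.data.shape:
        raise CubeError("mask and volume shapes differ")
    if not mask.data.any():
        raise CubeError("empty mask")
    spacing = vol.spacing[0]
    side = int(round(side_mm / spacing))
    if side < 1:
        raise CubeError("cube side smaller than one voxel")

    idx = np.argwhere(mask.data)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    extent = hi - lo + 1
    if np.any(extent > side):
        raise CubeError(
            f"lesion exceeds cube: bounding box {tuple(extent)} voxels > side {side}"
        )
    centroid = np.round(idx.mean(axis=0)).astype(int)
    start = centroid - side // 2

    cube = np.zeros((side, side, side), dtype=np.float32)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + side, vol.data.shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    cube[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = vol.data[
        src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
    ]
    if norm_mode == "max":
        m = cube.max()
        if m > 0:
            cube /= m
    return TumorCube(
        data=cube,
        spacing_mm=spacing,
        norm_mode=norm_mode,
        patient_id=patient_id,
        lesion_id=lesion_id,
    )


#: rotation planes for angles about (z, y, x): in-plane axis pairs
_ROTATION_AXES = ((1, 2), (0, 2), (0, 1))


def rotate_cube(cube: TumorCube, angles_deg) -> TumorCube:
    """Rotate about z, then y, then x by the given angles (trilinear, fill 0).

    Exact multiples of 90 degrees map the voxel grid onto itself, so those
    rotations are exact axis permutations of the data.
    """
    if len(angles_deg) != 3:
        raise CubeError("need one angle per axis (z, y, x)")
    data = cube.data
    for angle, axes in zip(angles_deg, _ROTATION_AXES):
        if angle % 360 == 0:
            continue
        data = ndimage.rotate(
            data, float(angle), axes=axes, reshape=False,
            order=1, mode="constant", cval=0.0, prefilter=False,
        )
    return replace(cube, data=np.asarray(data, dtype=np.float32))


def random_rotate(cube: TumorCube, policy: AugmentationPolicy) -> list[TumorCube]:
    """Generate ``policy.n_copies`` randomly rotated copies (deterministic per seed)."""
    rng = np.random.default_rng(policy.rng_seed)
    lo, hi = policy.angle_range_deg
    out = []
    for _ in range(policy.n_copies):
        angles = rng.uniform(lo, hi, size=3)
        out.append(rotate_cube(cube, angles))
    return out
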