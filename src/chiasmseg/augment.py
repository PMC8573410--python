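"""Stochastic image/mask augmentation applied jointly before training.

Four transforms, applied in order: intensity normalization of the maximal
voxel to 1, random flips along any axis, random crop to a fixed cube, and a
random rigid affine (bounded rotation and translation) resampled with cubic
b-splines for the image and nearest neighbour for the mask.  Image and mask
always receive the identical spatial transform, and the whole pipeline is a
pure function of (input, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "AugmentParams",
    "normalize_intensity",
    "random_flip",
    "random_crop",
    "random_affine",
    "augment",
]


@dataclass
class AugmentParams:
    crop_size: tuple[int, int, int] = (160, 160, 160)
    max_rotation: float = 15.0  # degrees, per axis
    max_translation: float = 20.0  # voxels, per axis
    flip: bool = True
    affine: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_rotation < 0 or self.max_translation < 0:
            raise ValueError("rotation/translation bounds must be >= 0")


def normalize_intensity(vol: np.ndarray) -> np.ndarray:
    """Rescale so the maximal voxel intensity is exactly 1."""
    m = float(np.max(vol))
    if m <= 0:
        raise ValueError("maximal intensity must be positive to normalize")
    return np.asarray(vol, dtype=np.float64) / m


def random_flip(
    vol: np.ndarray, mask: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Flip each axis independently with probability 0.5, jointly on both grids."""
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes must match")
    axes = tuple(int(a) for a in range(3) if rng.random() < 0.5)
    if axes:
        vol = np.flip(vol, axis=axes)
        mask = np.flip(mask, axis=axes)
    return np.ascontiguousarray(vol), np.ascontiguousarray(mask)


def _pad_to(arr: np.ndarray, size: tuple[int, int, int]) -> np.ndarray:
    pads = []
    for s, t in zip(arr.shape, size):
        extra = max(0, t - s)
        pads.append((extra // 2, extra - extra // 2))
    return np.pad(arr, pads) if any(p != (0, 0) for p in pads) else arr


def random_crop(
    vol: np.ndarray,
    mask: np.ndarray,
    crop_size: tuple[int, int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Crop both grids to ``crop_size`` with one shared random offset.

    Inputs smaller than the crop are zero-padded (mask padding is zero, so
    binarity is preserved).
    """
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes must match")
    vol = _pad_to(vol, crop_size)
    mask = _pad_to(mask, crop_size)
    offs = [int(rng.integers(0, s - t + 1)) for s, t in zip(vol.shape, crop_size)]
    sl = tuple(slice(o, o + t) for o, t in zip(offs, crop_size))
    return vol[sl].copy(), mask[sl].copy()


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    return rz @ ry @ rx


def random_affine(
    vol: np.ndarray,
    mask: np.ndarray,
    max_rotation: float,
    max_translation: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One rigid transform (rotation about the centre + translation) for both grids.

    The image is resampled with cubic b-spline interpolation, the mask with
    nearest neighbour and re-binarized; voxels mapped from outside the field
    of view are filled with zeros.
    """
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes must match")
    angles = rng.uniform(-max_rotation, max_rotation, size=3)
    trans = rng.uniform(-max_translation, max_translation, size=3)
    rot = _rotation_matrix(angles)
    center = (np.array(vol.shape, dtype=float) - 1.0) / 2.0
    matrix = rot.T
    offset = center - matrix @ (center + trans)
    vol_t = ndimage.affine_transform(
        vol, matrix, offset=offset, order=3, mode="constant", cval=0.0
    )
    mask_t = ndimage.affine_transform(
        mask.astype(np.uint8), matrix, offset=offset, order=0, mode="constant", cval=0
    )
    return vol_t, (mask_t > 0).astype(np.uint8)


def augment(
    vol: np.ndarray,
    mask: np.ndarray,
    params: AugmentParams,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full pipeline: normalize -> flip -> crop -> affine.  Seed-reproducible."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    vol = normalize_intensity(vol)
    mask = np.asarray(mask, dtype=np.uint8)
    if params.flip:
        vol, mask = random_flip(vol, mask, rng)
    vol, mask = random_crop(vol, mask, tuple(params.crop_size), rng)
    if params.affine and (params.max_rotation > 0 or params.max_translation > 0):
        vol, mask = random_affine(
            vol, mask, params.max_rotation, params.max_translation, rng
        )
    return vol, mask
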