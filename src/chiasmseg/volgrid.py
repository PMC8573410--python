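"""Volume and mask data model, NIfTI I/O, and 3D grid primitives.

All volumes are kept in a fixed canonical orientation (RAS-like): axis 0 runs
left->right, axis 1 posterior->anterior, axis 2 inferior->superior, so an
axial slice is ``data[:, :, z]``.  Voxel indexing is 0-based throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "dsc",
    "largest_component",
    "dilate",
    "percentile",
    "binarize_band",
    "CONNECTIVITY_STRUCTURES",
    "DILATION_ELEMENTS",
]

#: scipy label() structuring elements keyed by face/edge/corner connectivity
CONNECTIVITY_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

#: dilation structuring elements: 6-neighbour cross or full 3x3x3 cube
DILATION_ELEMENTS = {
    "cross6": ndimage.generate_binary_structure(3, 1),
    "cube26": np.ones((3, 3, 3), dtype=bool),
}


@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if not all(s > 0 for s in self.data.shape):
            raise ValueError("all dimensions must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 strictly positive values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A 3D {0,1} grid on the same lattice as the Volume it annotates."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got {arr.ndim}D")
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be 0/1, found {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)


def _load_canonical(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(
            f"expected 3D volume, got shape {img.shape} from {path}"
        )
    canonical = nib.as_closest_canonical(img)
    orig = nib.aff2axcodes(img.affine)
    new = nib.aff2axcodes(canonical.affine)
    if orig != new:
        logger.info("reoriented %s: %s -> %s", path, orig, new)
    data = np.asarray(canonical.get_fdata())
    zooms = canonical.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 file and reorient it to the canonical axis order."""
    data, spacing = _load_canonical(path)
    return Volume(data=data, spacing=spacing)


def write_volume(v: Volume, path: str | Path) -> None:
    affine = np.diag(list(v.spacing) + [1.0])
    nib.save(nib.Nifti1Image(v.data.astype(np.float64), affine), str(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask; two-valued files like {0, 255} are normalized to {0,1}."""
    data, spacing = _load_canonical(path)
    vals = np.unique(data)
    if len(vals) > 2:
        raise ValueError(
            f"mask file {path} has {len(vals)} distinct values, expected at most 2"
        )
    if not set(vals.tolist()) <= {0.0, 1.0}:
        warnings.warn(
            f"mask values {vals.tolist()} normalized to {{0,1}} (max -> 1)",
            stacklevel=2,
        )
        data = (data == vals.max()).astype(np.uint8)
    return BinaryMask(data=data.astype(np.uint8), spacing=spacing)


def write_mask(m: BinaryMask, path: str | Path) -> None:
    affine = np.diag(list(m.spacing) + [1.0])
    nib.save(nib.Nifti1Image(m.data.astype(np.uint8), affine), str(path))


def dsc(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)`` between two masks.

    Ranges from 0 (disjoint) to 1 (identical).  Raises if both masks are
    empty: that case is undefined and silently returning a default would
    mask upstream errors.
    """
    a_arr = a.data if isinstance(a, BinaryMask) else np.asarray(a)
    b_arr = b.data if isinstance(b, BinaryMask) else np.asarray(b)
    if a_arr.shape != b_arr.shape:
        raise ValueError(f"shape mismatch: {a_arr.shape} vs {b_arr.shape}")
    na = int(np.count_nonzero(a_arr))
    nb = int(np.count_nonzero(b_arr))
    if na == 0 and nb == 0:
        raise ValueError("DSC undefined for two empty masks")
    inter = int(np.count_nonzero(np.logical_and(a_arr, b_arr)))
    return 2.0 * inter / (na + nb)


def largest_component(m: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Extract the biggest cluster of nonzero voxels.

    Ties between equal-size components are broken deterministically in
    favour of the component containing the smallest row-major linear index.
    """
    if connectivity not in CONNECTIVITY_STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(CONNECTIVITY_STRUCTURES)}")
    arr = m.astype_bool()
    if not arr.any():
        raise ValueError("largest_component of an empty mask")
    labels, n = ndimage.label(arr, structure=CONNECTIVITY_STRUCTURES[connectivity])
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = sizes.max()
    tied = set(np.flatnonzero(sizes == best).tolist())
    if len(tied) == 1:
        winner = tied.pop()
    else:
        flat = labels.ravel()
        # first voxel (row-major) belonging to any tied component decides
        winner = next(int(lab) for lab in flat if int(lab) in tied)
    return BinaryMask(data=(labels == winner).astype(np.uint8), spacing=m.spacing)


def dilate(m: BinaryMask, element: str = "cross6") -> BinaryMask:
    """Dilate a mask by one voxel using a cross (6-neighbour) or cube element."""
    if element not in DILATION_ELEMENTS:
        raise ValueError(f"element must be one of {sorted(DILATION_ELEMENTS)}")
    out = ndimage.binary_dilation(m.astype_bool(), structure=DILATION_ELEMENTS[element])
    return BinaryMask(data=out.astype(np.uint8), spacing=m.spacing)


def percentile(values, q: float) -> float:
    """Linear-interpolation percentile of a nonempty collection of reals."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("percentile of an empty collection")
    if not 0 <= q <= 100:
        raise ValueError("q must lie in [0, 100]")
    return float(np.percentile(arr, q, method="linear"))


def binarize_band(v: Volume, lo: float, hi: float) -> BinaryMask:
    """Mask of voxels whose intensity lies in the inclusive band [lo, hi]."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) must not exceed hi ({hi})")
    data = ((v.data >= lo) & (v.data <= hi)).astype(np.uint8)
    return BinaryMask(data=data, spacing=v.spacing)
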