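"""Seeded synthetic phantoms of the optic chiasm on a T1w-like background.

The phantom is an X-shaped white-matter structure built from two straight
tubular limbs crossing at the grid centre in an axial plane.  Three intensity
tiers mimic a T1w image around the chiasm: surrounding tissue, white matter,
and small hyperintense vessel-like blobs touching the structure's surface.
Partial volume is emulated by Gaussian blurring of the piecewise-constant
intensity field; the ground-truth ("manual") mask is defined before any
degradation as the voxels whose white-matter fraction exceeds 0.5.

"Malformed" phantoms change geometry only — narrower chiasm body and optic
nerves and a wider angle between the posterior (tract) limbs — never the
intensity model, so any downstream segmentation failure is attributable to
shape alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volgrid import BinaryMask, Volume, dsc, write_mask, write_volume

__all__ = [
    "PhantomParams",
    "PhantomSample",
    "malformed_preset",
    "make_phantom",
    "corrupt_to_initial",
    "make_cohort",
    "sample_seed",
    "MANIFEST_HEADER",
]

MANIFEST_HEADER = ["id", "label", "seed", "volume_path", "manual_mask_path", "initial_mask_path"]


@dataclass
class PhantomParams:
    """Geometry and intensity model of a synthetic chiasm phantom.

    Widths are in voxels, the tract angle is the opening between the two
    posterior limbs in degrees.  Intensities are arbitrary units ordered
    ``vessel > wm > background`` as in T1w contrast around the chiasm.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    chiasm_width: float = 7.0
    nerve_width: float = 4.5
    tract_angle: float = 90.0
    wm_intensity: float = 0.7
    background_intensity: float = 0.35
    vessel_intensity: float = 1.0
    noise_sd: float = 0.02
    blur_sd: float = 0.7
    malformed: bool = False
    seed: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not (self.vessel_intensity > self.wm_intensity > self.background_intensity):
            raise ValueError("require vessel_intensity > wm_intensity > background_intensity")
        if self.chiasm_width <= 0 or self.nerve_width <= 0:
            raise ValueError("widths must be positive")
        if not 0 < self.tract_angle < 180:
            raise ValueError("tract_angle must lie in (0, 180) degrees")
        if self.noise_sd < 0 or self.blur_sd < 0:
            raise ValueError("noise_sd and blur_sd must be >= 0")


def malformed_preset(params: PhantomParams) -> PhantomParams:
    """Malformed variant: chiasm width x0.5, nerve width x0.7, tract angle +30 deg."""
    return replace(
        params,
        chiasm_width=params.chiasm_width * 0.5,
        nerve_width=params.nerve_width * 0.7,
        tract_angle=params.tract_angle + 30.0,
        malformed=True,
    )


@dataclass
class PhantomSample:
    """One generated subject: T1w-like volume, ground truth, optional noisy atlas mask."""

    volume: Volume
    manual_mask: BinaryMask
    initial_mask: BinaryMask | None
    label: str  # "control" | "malformed"
    seed: int
    sample_id: str = ""


def _wm_fraction(params: PhantomParams) -> np.ndarray:
    """Per-voxel white-matter fraction of the two crossing tubular limbs."""
    shape = params.grid_shape
    center = (np.array(shape, dtype=float) - 1.0) / 2.0
    alpha = np.deg2rad(params.tract_angle / 2.0)
    dirs = [
        np.array([np.sin(alpha), np.cos(alpha), 0.0]),
        np.array([-np.sin(alpha), np.cos(alpha), 0.0]),
    ]
    half_len = 0.42 * min(shape[0], shape[1])
    chiasm_r = params.chiasm_width / 2.0
    nerve_r = params.nerve_width / 2.0
    taper = max(4.0, 0.18 * min(shape[0], shape[1]))

    # structure must fit with >= 2 voxels of margin in every direction
    max_r = max(chiasm_r, nerve_r)
    for u in dirs:
        end = center + half_len * np.abs(u)
        if np.any(end + max_r + 2 > np.array(shape) - 1) or np.any(
            center - half_len * np.abs(u) - max_r - 2 < 0
        ):
            raise ValueError("phantom structure does not fit in the grid")

    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"),
        axis=-1,
    )
    rel = grid - center
    frac = np.zeros(shape, dtype=float)
    for u in dirs:
        t = rel @ u
        d = np.linalg.norm(rel - t[..., None] * u, axis=-1)
        radius = nerve_r + (chiasm_r - nerve_r) * np.exp(-((t / taper) ** 2))
        # linear anti-aliasing over one voxel: fraction 0.5 on the surface
        limb = np.clip(radius - d + 0.5, 0.0, 1.0)
        limb[np.abs(t) > half_len] = 0.0
        frac = np.maximum(frac, limb)
    return frac


def make_phantom(params: PhantomParams) -> PhantomSample:
    """Generate a phantom volume and its ground-truth mask (no atlas corruption).

    The pre-degradation intensity field is piecewise constant (white matter
    inside the structure, background elsewhere, vessel blobs adjacent to the
    surface); blur then creates partial-volume surface voxels, and Gaussian
    noise is added last.  Identical params + seed give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    frac = _wm_fraction(params)
    manual = frac > 0.5

    vol = np.full(params.grid_shape, params.background_intensity, dtype=float)
    vol[manual] = params.wm_intensity

    # 1-3 vessel-like blobs touching the surface, strictly outside the mask
    surface = ndimage.binary_dilation(manual) & ~manual
    surf_idx = np.flatnonzero(surface.ravel())
    n_vessels = int(rng.integers(1, 4))
    grid_pts = np.indices(params.grid_shape).reshape(3, -1).T
    for _ in range(n_vessels):
        c = grid_pts[surf_idx[rng.integers(len(surf_idx))]]
        radius = float(rng.uniform(1.0, 1.8))
        lo = np.maximum(c - 3, 0)
        hi = np.minimum(c + 4, params.grid_shape)
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        local = np.indices([s.stop - s.start for s in sl]).reshape(3, -1).T + lo
        ball = np.linalg.norm(local - c, axis=1) <= radius
        blob = np.zeros(params.grid_shape, dtype=bool)
        blob[sl] = ball.reshape([s.stop - s.start for s in sl])
        blob &= ~manual
        vol[blob] = params.vessel_intensity

    if params.blur_sd > 0:
        vol = ndimage.gaussian_filter(vol, params.blur_sd)
    if params.noise_sd > 0:
        vol = vol + rng.normal(0.0, params.noise_sd, size=vol.shape)

    return PhantomSample(
        volume=Volume(data=vol, spacing=params.spacing),
        manual_mask=BinaryMask(data=manual.astype(np.uint8), spacing=params.spacing),
        initial_mask=None,
        label="malformed" if params.malformed else "control",
        seed=params.seed,
    )


def corrupt_to_initial(
    sample: PhantomSample, corruption_seed: int, severity: float = 0.5
) -> BinaryMask:
    """Degrade the ground-truth mask into a noisy atlas-like initial mask.

    Three seeded corruptions: per-voxel flips within a 2-voxel shell around
    the boundary, one random global dilation or erosion, and a contiguous
    false-positive blob of background voxels grown next to the mask.  At the
    default severity the resulting mask quality sits in the mid-0.5 DSC range
    typical of raw atlas segmentations of the chiasm.
    """
    if not 0 < severity <= 1:
        raise ValueError("severity must lie in (0, 1]")
    rng = np.random.default_rng(corruption_seed)
    manual = sample.manual_mask.astype_bool()
    out = manual.copy()

    # boundary jitter in a 2-voxel shell
    shell = ndimage.binary_dilation(manual, iterations=2) & ~ndimage.binary_erosion(
        manual, iterations=2, border_value=0
    )
    p_flip = 0.20 * severity
    flips = shell & (rng.random(manual.shape) < p_flip)
    out ^= flips

    # one random global morphological perturbation; certain at default
    # severity, vanishing as severity -> 0 so mild corruption stays near-identity
    cross = ndimage.generate_binary_structure(3, 1)
    if rng.random() < min(1.0, 2.0 * severity):
        if rng.random() < 0.5:
            out = ndimage.binary_dilation(out, structure=cross)
        else:
            eroded = ndimage.binary_erosion(out, structure=cross, border_value=0)
            if eroded.any():
                out = eroded

    # contiguous false-positive patch adjacent to the mask
    adjacent = ndimage.binary_dilation(manual) & ~manual
    cand = np.argwhere(adjacent)
    c = cand[rng.integers(len(cand))]
    radius = 1.0 + 2.0 * severity * rng.uniform(0.6, 1.0)
    lo = np.maximum(c - 5, 0)
    hi = np.minimum(c + 6, manual.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    local = np.indices([s.stop - s.start for s in sl]).reshape(3, -1).T + lo
    ball = (np.linalg.norm(local - c, axis=1) <= radius).reshape(
        [s.stop - s.start for s in sl]
    )
    out[sl] |= ball

    if not out.any():
        raise RuntimeError(
            f"corruption emptied the mask (corruption_seed={corruption_seed}, "
            f"severity={severity})"
        )
    return BinaryMask(data=out.astype(np.uint8), spacing=sample.manual_mask.spacing)


def sample_seed(master_seed: int, index: int) -> int:
    """Stable per-sample seed derived from (master_seed, sample index)."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0] % (2**31))


def make_cohort(
    n_control: int,
    n_malformed: int,
    base_params: PhantomParams | None = None,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
    corruption_severity: float = 0.5,
) -> list[PhantomSample]:
    """Generate a labelled cohort of control and malformed phantoms.

    Each sample gets a deterministic seed derived from the master seed and
    its index, a ground-truth mask, and a corrupted atlas-like initial mask.
    When ``out_dir`` is given, NIfTI files and a CSV manifest are written.
    """
    if n_control < 0 or n_malformed < 0:
        raise ValueError("cohort sizes must be >= 0")
    base = base_params or PhantomParams()
    samples: list[PhantomSample] = []
    labels = ["control"] * n_control + ["malformed"] * n_malformed
    for i, label in enumerate(labels):
        seed = sample_seed(master_seed, i)
        params = replace(base, seed=seed, malformed=False)
        if label == "malformed":
            params = malformed_preset(params)
        s = make_phantom(params)
        s.initial_mask = corrupt_to_initial(s, corruption_seed=seed + 1, severity=corruption_severity)
        s.sample_id = f"{label[:3]}{i:03d}"
        samples.append(s)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for s in samples:
            vp = out / f"{s.sample_id}_t1w.nii.gz"
            mp = out / f"{s.sample_id}_manual.nii.gz"
            ip = out / f"{s.sample_id}_initial.nii.gz"
            write_volume(s.volume, vp)
            write_mask(s.manual_mask, mp)
            write_mask(s.initial_mask, ip)
            rows.append([s.sample_id, s.label, s.seed, vp.name, mp.name, ip.name])
        with open(out / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(MANIFEST_HEADER)
            w.writerows(rows)
    return samples
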