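"""Dataset splitting, the supervised training loop, and CNN-mask inference.

Training minimizes the soft-Dice loss with Adam over mini-batches of
augmented image/target pairs.  The historical hyperparameter grid pairs
maximal epoch counts (13, 15, 30, 40, 100) with learning rates (0.0025,
0.0030, 0.0025, 0.0015, 0.0005); the combination reported best is 30 epochs
at 0.0025 with a prediction threshold of 1.  Inference binarizes the
foreground probability map at the threshold (interpreted as ``p >= tau -
epsilon`` so that a saturated softmax remains robust in float arithmetic)
and keeps the biggest cluster of suprathreshold voxels wherever it lies —
deliberately without an anatomical prior, so a failure mode where the
biggest cluster sits outside the chiasm is preserved as a legitimate,
flagged outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentParams, augment
from .nn import Adam, NetConfig, UNet3D, dice_loss, dice_loss_grad
from .volgrid import BinaryMask, Volume, largest_component

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "InferenceParams",
    "split_dataset",
    "train",
    "train_grid",
    "predict_probability",
    "extract_cnn_mask",
    "DEFAULT_GRID",
    "SELECTED_COMBINATION",
]

#: (max_epochs, learning_rate) pairs of the historical hyperparameter search
DEFAULT_GRID: tuple[tuple[int, float], ...] = (
    (13, 0.0025),
    (15, 0.0030),
    (30, 0.0025),
    (40, 0.0015),
    (100, 0.0005),
)
#: the best-performing combination (with threshold 1.0)
SELECTED_COMBINATION: tuple[int, float] = (30, 0.0025)


@dataclass
class TrainConfig:
    batch_size: int = 2
    max_epochs: int = 30
    learning_rate: float = 0.0025
    hyperparameter_grid: tuple[tuple[int, float], ...] = DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class InferenceParams:
    threshold: float = 1.0
    epsilon: float = 1e-6
    component_connectivity: int = 26

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")


def split_dataset(ids, counts: tuple[int, int, int], seed: int):
    """Seeded shuffle then contiguous partition into train/val/test id lists."""
    ids = list(ids)
    if sum(counts) != len(ids):
        raise ValueError(f"split counts {counts} do not sum to cohort size {len(ids)}")
    order = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    tr, va, _ = counts
    return shuffled[:tr], shuffled[tr : tr + va], shuffled[tr + va :]


def _as_array(x) -> np.ndarray:
    if isinstance(x, (Volume, BinaryMask)):
        return x.data
    return np.asarray(x)


def _epoch_loss(net: UNet3D, pairs, batch_size: int) -> float:
    """Mean soft-Dice loss over pairs without updating weights (eval mode)."""
    losses = []
    for i in range(0, len(pairs), batch_size):
        batch = pairs[i : i + batch_size]
        x = np.stack([v for v, _ in batch])[:, None].astype(np.float32)
        g = np.stack([m for _, m in batch]).astype(np.float32)
        probs = net.forward(x, train=False)
        losses.append(dice_loss(probs[:, 1], g))
    return float(np.mean(losses))


def train(
    samples,
    net_cfg: NetConfig | None = None,
    train_cfg: TrainConfig | None = None,
    aug_params: AugmentParams | None = None,
    val_samples=None,
) -> tuple[UNet3D, dict[str, list[float]]]:
    """Train a U-Net on (volume, target-mask) samples; returns net + history.

    ``samples`` is a sequence of objects with ``volume`` and a target mask
    (``initial_mask`` if present, else ``manual_mask``), or (volume, mask)
    tuples.  Everything — weight init, shuffling, augmentation — is driven
    by ``train_cfg.seed``.  A non-finite loss aborts with the offending
    batch identified.
    """
    net_cfg = net_cfg or NetConfig()
    train_cfg = train_cfg or TrainConfig()
    aug_params = aug_params or AugmentParams()
    if len(samples) == 0:
        raise ValueError("training set is empty")

    def unpack(s):
        if isinstance(s, tuple):
            v, m = s
        else:
            m = s.initial_mask if getattr(s, "initial_mask", None) is not None else s.manual_mask
            v = s.volume
        return _as_array(v).astype(np.float64), _as_array(m).astype(np.uint8)

    data = [unpack(s) for s in samples]
    val_data = [unpack(s) for s in val_samples] if val_samples else None

    net = UNet3D(net_cfg, seed=train_cfg.seed)
    opt = Adam(net.parameters(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed + 1)
    history: dict[str, list[float]] = {"train_loss": []}
    if val_data:
        history["val_loss"] = []

    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(len(data))
        epoch_losses = []
        for bstart in range(0, len(order), train_cfg.batch_size):
            idxs = order[bstart : bstart + train_cfg.batch_size]
            vols, masks = [], []
            for j, idx in enumerate(idxs):
                aseed = int(
                    np.random.SeedSequence(
                        (train_cfg.seed, epoch, int(idx))
                    ).generate_state(1)[0]
                    % (2**31)
                )
                v, m = augment(data[idx][0], data[idx][1], aug_params, seed=aseed)
                vols.append(v)
                masks.append(m)
            x = np.stack(vols)[:, None].astype(np.float32)
            g = np.stack(masks).astype(np.float32)
            probs = net.forward(x, train=True)
            loss, gfg = dice_loss_grad(probs[:, 1], g)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch indices {idxs.tolist()}"
                )
            gprobs = np.zeros_like(probs)
            gprobs[:, 1] = gfg
            net.backward(gprobs)
            opt.step(net.gradients())
            epoch_losses.append(loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if val_data:
            history["val_loss"].append(_epoch_loss(net, val_data, train_cfg.batch_size))
        logger.info(
            "epoch %d/%d train loss %.4f%s",
            epoch + 1,
            train_cfg.max_epochs,
            history["train_loss"][-1],
            f" val loss {history['val_loss'][-1]:.4f}" if val_data else "",
        )
    return net, history


def train_grid(samples, net_cfg=None, base_cfg: TrainConfig | None = None,
               aug_params=None, val_samples=None):
    """Run one training per (epochs, lr) combination of the default grid."""
    base = base_cfg or TrainConfig()
    out = {}
    for epochs, lr in base.hyperparameter_grid:
        cfg = TrainConfig(
            batch_size=base.batch_size,
            max_epochs=epochs,
            learning_rate=lr,
            hyperparameter_grid=base.hyperparameter_grid,
            seed=base.seed,
        )
        out[(epochs, lr)] = train(samples, net_cfg, cfg, aug_params, val_samples)
    return out


def predict_probability(net: UNet3D, volume) -> np.ndarray:
    """Foreground-probability map of a volume, same shape as the input.

    Sides not divisible by the network's downsampling factor are zero-padded
    to the next multiple and the output is cropped back.  Intensities are
    max-normalized exactly as during training.
    """
    arr = _as_array(volume).astype(np.float64)
    m = float(arr.max())
    if m > 0:
        arr = arr / m
    div = net.cfg.divisor
    pads = [(0, (-s) % div) for s in arr.shape]
    padded = np.pad(arr, pads) if any(p[1] for p in pads) else arr
    probs = net.forward(padded[None, None].astype(np.float32), train=False)
    fg = probs[0, 1]
    sl = tuple(slice(0, s) for s in arr.shape)
    return fg[sl]


def extract_cnn_mask(prob: np.ndarray, params: InferenceParams | None = None) -> BinaryMask:
    """Threshold the probability map and keep the biggest suprathreshold cluster."""
    params = params or InferenceParams()
    prob = np.asarray(prob)
    binary = prob >= (params.threshold - params.epsilon)
    if not binary.any():
        warnings.warn(
            f"no voxel reaches threshold {params.threshold}; returning empty mask",
            stacklevel=2,
        )
        return BinaryMask(data=np.zeros(prob.shape, dtype=np.uint8))
    return largest_component(
        BinaryMask(data=binary.astype(np.uint8)),
        connectivity=params.component_connectivity,
    )
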