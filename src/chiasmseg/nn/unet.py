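"""The 3D U-Net: encoder/decoder with skip connections and a softmax head.

Default configuration: five resolution levels (four pooled encoder levels
plus a bottleneck) starting at 10 feature maps and doubling per level
(10-20-40-80-160).  Each block is two 3x3x3 convolutions, each followed by
batch normalization and ReLU; block convolutions carry no bias (the
normalization's shift plays that role), 2x2x2 transposed up-convolutions
and the 1x1x1 two-channel head do.  With these conventions the default
network has exactly 2,206,482 trainable parameters, which
``parameter_count_formula`` reproduces in closed form and tests use as an
independent oracle.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .layers import (
    BatchNorm3d,
    Conv1x1,
    Conv3x3,
    MaxPool2,
    ReLU,
    UpConv2,
    softmax_backward,
    softmax_channels,
)

__all__ = ["NetConfig", "UNet3D", "parameter_count_formula"]


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters; channel count doubles per level."""

    levels: int = 5
    base_width: int = 10
    in_channels: int = 1
    out_channels: int = 2

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 resolution levels")
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")

    @property
    def channels(self) -> list[int]:
        return [self.base_width * 2**i for i in range(self.levels)]

    @property
    def divisor(self) -> int:
        return 2 ** (self.levels - 1)


def parameter_count_formula(cfg: NetConfig) -> int:
    """Closed-form trainable-parameter count of the architecture.

    Per 3x3x3 block convolution: 27*Cin*Cout (no bias); per normalization
    layer: 2*C; per 2x2x2 up-convolution: 8*Cin*Cout + Cout; head: Cin*K + K.
    """
    ch = cfg.channels
    total = 0
    prev = cfg.in_channels
    for c in ch:  # encoder blocks + bottleneck
        total += 27 * prev * c + 2 * c + 27 * c * c + 2 * c
        prev = c
    for i in range(cfg.levels - 2, -1, -1):  # decoder
        cin, cout = ch[i + 1], ch[i]
        total += 8 * cin * cout + cout  # up-convolution with bias
        total += 27 * (2 * cout) * cout + 2 * cout + 27 * cout * cout + 2 * cout
    total += ch[0] * cfg.out_channels + cfg.out_channels  # 1x1x1 head
    return total


class _Block:
    """Two (conv3 -> norm -> ReLU) stages."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.layers = [
            Conv3x3(c_in, c_out, rng),
            BatchNorm3d(c_out),
            ReLU(),
            Conv3x3(c_out, c_out, rng),
            BatchNorm3d(c_out),
            ReLU(),
        ]

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, gy):
        for lay in reversed(self.layers):
            gy = lay.backward(gy)
        return gy


class UNet3D:
    """Volumetric U-Net producing a two-channel voxelwise softmax."""

    def __init__(self, cfg: NetConfig | None = None, seed: int = 0):
        self.cfg = cfg or NetConfig()
        rng = np.random.default_rng(seed)
        ch = self.cfg.channels
        self.encoders = []
        prev = self.cfg.in_channels
        for c in ch[:-1]:
            self.encoders.append(_Block(prev, c, rng))
            prev = c
        self.pools = [MaxPool2() for _ in ch[:-1]]
        self.bottleneck = _Block(prev, ch[-1], rng)
        self.upconvs = []
        self.decoders = []
        for i in range(self.cfg.levels - 2, -1, -1):
            self.upconvs.append(UpConv2(ch[i + 1], ch[i], rng))
            self.decoders.append(_Block(2 * ch[i], ch[i], rng))
        self.head = Conv1x1(ch[0], self.cfg.out_channels, rng)
        self._probs = None
        self._skip_channels = [ch[i] for i in range(self.cfg.levels - 2, -1, -1)]

    # ------------------------------------------------------------------ params
    def _modules(self):
        mods = []
        for i, b in enumerate(self.encoders):
            for j, lay in enumerate(b.layers):
                mods.append((f"enc{i}.{j}", lay))
        for j, lay in enumerate(self.bottleneck.layers):
            mods.append((f"bottleneck.{j}", lay))
        for i, (u, b) in enumerate(zip(self.upconvs, self.decoders)):
            mods.append((f"up{i}", u))
            for j, lay in enumerate(b.layers):
                mods.append((f"dec{i}.{j}", lay))
        mods.append(("head", self.head))
        return mods

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{k}": v for name, lay in self._modules() for k, v in lay.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{k}": v for name, lay in self._modules() for k, v in lay.grads.items()
        }

    def parameter_count(self) -> int:
        return sum(int(p.size) for p in self.parameters().values())

    # ----------------------------------------------------------------- forward
    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 5 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected (N,{self.cfg.in_channels},D,H,W), got {x.shape}")
        div = self.cfg.divisor
        if any(s % div for s in x.shape[2:]):
            raise ValueError(
                f"input sides {x.shape[2:]} must be multiples of {div} "
                f"for {self.cfg.levels} resolution levels"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Probability tensor (N, 2, D, H, W); channels sum to 1 per voxel."""
        self._check_shape(x)
        if x.dtype != np.float64:  # float64 kept as-is (used by gradient checks)
            x = x.astype(np.float32, copy=False)
        skips = []
        for block, pool in zip(self.encoders, self.pools):
            x = block.forward(x, train=train)
            skips.append(x)
            x = pool.forward(x, train=train)
        x = self.bottleneck.forward(x, train=train)
        for up, dec in zip(self.upconvs, self.decoders):
            x = up.forward(x, train=train)
            skip = skips.pop()
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train=train)
        logits = self.head.forward(x, train=train)
        probs = softmax_channels(logits)
        if train:
            self._probs = probs
        return probs

    def backward(self, gprobs: np.ndarray) -> None:
        """Backpropagate dL/dprobs through the network (after a train forward)."""
        gy = softmax_backward(self._probs, gprobs.astype(np.float32))
        gy = self.head.backward(gy)
        gskips = []
        for i in range(len(self.decoders) - 1, -1, -1):
            gy = self.decoders[i].backward(gy)
            c_skip = self._skip_channels[i]
            gskip, gup = gy[:, :c_skip], gy[:, c_skip:]
            gskips.append(gskip)
            gy = self.upconvs[i].backward(np.ascontiguousarray(gup))
        gy = self.bottleneck.backward(gy)
        # gskips[k] holds the gradient flowing into the level-k skip connection
        for i in range(len(self.encoders) - 1, -1, -1):
            gy = self.pools[i].backward(gy)
            gy = gy + gskips[i]
            gy = self.encoders[i].backward(gy)

    # ------------------------------------------------------------ serialization
    def save(self, path: str | Path) -> None:
        """Checkpoint (pickled weights) plus a JSON architecture sidecar."""
        path = Path(path)
        state = {
            "cfg": asdict(self.cfg),
            "params": self.parameters(),
            "running": self._running_stats(),
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"cfg": asdict(self.cfg), "parameter_count": self.parameter_count()}, indent=2)
        )

    def _running_stats(self):
        out = {}
        for name, lay in self._modules():
            if isinstance(lay, BatchNorm3d):
                out[name] = (lay.running_mean.copy(), lay.running_var.copy())
        return out

    @classmethod
    def load(cls, path: str | Path) -> "UNet3D":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        net = cls(NetConfig(**state["cfg"]))
        params = net.parameters()
        for k, v in state["params"].items():
            params[k][...] = v
        for name, lay in net._modules():
            if name in state["running"]:
                lay.running_mean, lay.running_var = state["running"][name]
        return net
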