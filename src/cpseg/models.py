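"""Segmentation architectures: residual U-Net and a nested-skip (UNet++) variant.

Both map a batch of grayscale crops (B, 1, S, S) to confidence maps in
[0, 1] through a terminal sigmoid. The nested-skip variant carries one
segmentation head per nesting level; with deep supervision enabled the
returned map is the arithmetic mean of all heads. Scale (depth, base
channels) is configurable so the same code runs at desk scale for testing
and larger for real volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Module, ResBlock, Tensor
from .nn.tensor import avg_pool2, concat, upsample2


@dataclass
class SegmenterConfig:
    architecture: str = "resunet"   # "resunet" | "unetpp"
    depth: int = 3                  # number of down/up levels
    base_channels: int = 16
    in_channels: int = 1
    out_channels: int = 1
    deep_supervision: bool = False  # unetpp only

    def __post_init__(self):
        if self.architecture not in ("resunet", "unetpp"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.out_channels != 1:
            raise ValueError("this toolkit segments one binary structure at a time")
        if self.deep_supervision and self.architecture != "unetpp":
            raise ValueError("deep_supervision requires the unetpp architecture")

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture, "depth": self.depth,
            "base_channels": self.base_channels, "in_channels": self.in_channels,
            "out_channels": self.out_channels, "deep_supervision": self.deep_supervision,
        }


class ResUNet(Module):
    """Residual encoder-decoder with skip connections at every level."""

    def __init__(self, cfg: SegmenterConfig, rng: np.random.Generator):
        self.training = True
        d, b = cfg.depth, cfg.base_channels
        chans = [b * 2 ** i for i in range(d + 1)]
        self.encoders = [ResBlock(cfg.in_channels if i == 0 else chans[i - 1],
                                  chans[i], rng) for i in range(d)]
        self.bottleneck = ResBlock(chans[d - 1], chans[d], rng)
        self.decoders = [ResBlock(chans[i] + chans[i + 1], chans[i], rng)
                         for i in reversed(range(d))]
        self.head = Conv2d(chans[0], cfg.out_channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = avg_pool2(x)
        x = self.bottleneck(x)
        for dec, skip in zip(self.decoders, reversed(skips)):
            x = dec(concat([skip, upsample2(x)], axis=1))
        return self.head(x).sigmoid()


class UNetPP(Module):
    """Nested-skip encoder-decoder with one segmentation head per nesting level."""

    def __init__(self, cfg: SegmenterConfig, rng: np.random.Generator):
        self.training = True
        self.depth = cfg.depth
        d, b = cfg.depth, cfg.base_channels
        chans = [b * 2 ** i for i in range(d + 1)]
        self.backbone = [ResBlock(cfg.in_channels if i == 0 else chans[i - 1],
                                  chans[i], rng) for i in range(d + 1)]
        # nested nodes X[i][j], j >= 1: inputs are X[i][0..j-1] and up(X[i+1][j-1])
        self.nested = []
        for j in range(1, d + 1):
            row = []
            for i in range(0, d + 1 - j):
                cin = chans[i] * j + chans[i + 1]
                row.append(ResBlock(cin, chans[i], rng))
            self.nested.append(row)
        self.heads = [Conv2d(chans[0], cfg.out_channels, 1, rng) for _ in range(d)]
        self.deep_supervision = cfg.deep_supervision

    def __call__(self, x: Tensor) -> Tensor:
        d = self.depth
        grid = {}
        for i in range(d + 1):
            x = self.backbone[i](x)
            grid[(i, 0)] = x
            if i < d:
                x = avg_pool2(x)
        for j in range(1, d + 1):
            for i in range(0, d + 1 - j):
                inputs = [grid[(i, k)] for k in range(j)]
                inputs.append(upsample2(grid[(i + 1, j - 1)]))
                grid[(i, j)] = self.nested[j - 1][i](concat(inputs, axis=1))
        outs = [self.heads[j - 1](grid[(0, j)]).sigmoid() for j in range(1, d + 1)]
        if self.deep_supervision:
            acc = outs[0]
            for o in outs[1:]:
                acc = acc + o
            return acc * (1.0 / len(outs))
        return outs[-1]


@dataclass
class Segmenter:
    """A configured network plus the seed that initialized it."""

    config: SegmenterConfig
    net: Module
    init_seed: int

    def __call__(self, images) -> Tensor:
        return self.forward(images)

    def forward(self, images) -> Tensor:
        """Run the network; input (B, S, S) or (B, 1, S, S), square, side
        divisible by 2**depth. Returns a confidence map Tensor (B, 1, S, S)."""
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images))
        if x.ndim == 3:
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        side = x.shape[-1]
        if x.shape[-2] != side:
            raise ValueError("input crops must be square")
        if side % (2 ** self.config.depth) != 0:
            raise ValueError(
                f"input side {side} not divisible by 2^depth = {2 ** self.config.depth}")
        return self.net(x)

    def predict(self, images) -> np.ndarray:
        """Deterministic inference: eval mode, returns a numpy confidence map."""
        was_training = getattr(self.net, "training", True)
        self.net.eval()
        out = self.forward(images).data
        if was_training:
            self.net.train()
        return out

    def parameters(self):
        return self.net.parameters()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.net.parameters()))


def save_checkpoint(path, model: Segmenter) -> None:
    """Save weights + config + init seed as an .npz archive."""
    import json

    state = model.net.state_dict()
    np.savez(path, __config__=json.dumps(model.config.to_dict()),
             __init_seed__=model.init_seed, **state)


def load_checkpoint(path) -> Segmenter:
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg = SegmenterConfig(**json.loads(str(data["__config__"])))
        model = build_segmenter(cfg, init_seed=int(data["__init_seed__"]))
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    model.net.load_state_dict(state)
    return model


def build_segmenter(cfg: SegmenterConfig, init_seed: int) -> Segmenter:
    """Deterministically construct a segmenter from its config and seed."""
    rng = np.random.default_rng(init_seed)
    if cfg.architecture == "resunet":
        net = ResUNet(cfg, rng)
    else:
        net = UNetPP(cfg, rng)
    return Segmenter(config=cfg, net=net, init_seed=init_seed)
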