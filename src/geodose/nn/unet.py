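"""The 3D U-Net variant mapping the integrated CT+fluence volume to dose.

Descending arm: per level, two convolution layers each followed by a
Convolved CReLU (the channel-doubling concatenated rectification followed by
a convolution that restores the channel count), then group normalization;
levels are joined by dual-pool downsampling (max + average, concatenated)
with DropBlock regularization after each downsampling output. The ascending
arm mirrors this with dual-interpolation upsampling (nearest + trilinear,
concatenated) and same-level skip connections; a final 1x1x1 convolution
projects to the single dose channel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import NetConfig
from .layers import (
    Concat,
    Conv3d,
    CReLU,
    DropBlock3d,
    DualPool,
    DualUpsample,
    GroupNorm,
    Layer,
    Param,
)


class ConvBlock(Layer):
    """[conv -> CReLU -> conv] x2 -> GroupNorm, output width ``features``."""

    def __init__(self, c_in: int, features: int, kernel: int, groups: int,
                 rng: np.random.Generator, name: str, dtype=np.float64):
        f = features
        self.ops: list[Layer] = [
            Conv3d(c_in, f, kernel, rng, f"{name}.conv1", dtype=dtype),
            CReLU(),
            Conv3d(2 * f, f, kernel, rng, f"{name}.crelu_conv1", dtype=dtype),
            Conv3d(f, f, kernel, rng, f"{name}.conv2", dtype=dtype),
            CReLU(),
            Conv3d(2 * f, f, kernel, rng, f"{name}.crelu_conv2", dtype=dtype),
            GroupNorm(f, groups, f"{name}.gn", dtype=dtype),
        ]
        self.features = f

    def params(self):
        return [p for op in self.ops for p in op.params()]

    def forward(self, x, training=False):
        for op in self.ops:
            x = op.forward(x, training)
        return x

    def backward(self, dy):
        for op in reversed(self.ops):
            dy = op.backward(dy)
        return dy


class DoseUNet:
    """Dose-regression network; ``config.level_widths`` fixes all channel
    counts (e.g. 24/48/96/192 for the default four-level net)."""

    def __init__(self, config: NetConfig, seed: int = 0, dtype=np.float64):
        self.config = config
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.dropblock_rng = np.random.default_rng(seed + 1)
        widths = config.level_widths
        g, k = config.groups, config.kernel

        self.enc_blocks: list[ConvBlock] = []
        self.downs: list[DualPool] = []
        self.dropblocks: list[DropBlock3d] = []
        c_in = 1
        for lvl, f in enumerate(widths):
            self.enc_blocks.append(
                ConvBlock(c_in, f, k, g, rng, f"enc{lvl}", dtype=self.dtype)
            )
            if lvl < config.levels - 1:
                self.downs.append(DualPool())
                self.dropblocks.append(
                    DropBlock3d(config.dropblock_rate, config.dropblock_size,
                                self.dropblock_rng)
                )
                c_in = 2 * f  # dual-pool concat doubles channels
        self.ups: list[DualUpsample] = []
        self.skips: list[Concat] = []
        self.dec_blocks: list[ConvBlock] = []
        for lvl in range(config.levels - 2, -1, -1):
            f = widths[lvl]
            c_up = 2 * widths[lvl + 1]  # dual-interp concat doubles channels
            self.ups.append(DualUpsample())
            self.skips.append(Concat())
            self.dec_blocks.append(
                ConvBlock(c_up + f, f, k, g, rng, f"dec{lvl}", dtype=self.dtype)
            )
        self.head = Conv3d(widths[0], 1, 1, rng, "head", dtype=self.dtype)
        self.head.w.value[:] = 0.0  # start from a zero dose estimate
        # training metadata, persisted with checkpoints
        self.meta: dict = {"dose_scale": 1.0, "spacing": None}

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        out = []
        for blk in self.enc_blocks + self.dec_blocks:
            out.extend(blk.params())
        out.extend(self.head.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[:] = 0.0

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[:] = v

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        nx, ny, nz = self.config.input_dims
        if x.shape[2:] != (nz, ny, nx):
            raise ValueError(
                f"input spatial dims {x.shape[2:]} do not match configured "
                f"(nz, ny, nx) = {(nz, ny, nx)}"
            )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._check_input(x)
        x = np.asarray(x, dtype=self.dtype)
        feats = []
        for lvl, blk in enumerate(self.enc_blocks):
            x = blk.forward(x, training)
            feats.append(x)
            if lvl < self.config.levels - 1:
                x = self.downs[lvl].forward(x, training)
                x = self.dropblocks[lvl].forward(x, training)
        for i, lvl in enumerate(range(self.config.levels - 2, -1, -1)):
            x = self.ups[i].forward(x, training)
            x = self.skips[i].forward_pair(x, feats[lvl])
            x = self.dec_blocks[i].forward(x, training)
        return self.head.forward(x, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.head.backward(dy)
        skip_grads: dict[int, np.ndarray] = {}
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            lvl = self.config.levels - 2 - i
            dy = self.dec_blocks[i].backward(dy)
            dy, dskip = self.skips[i].backward(dy)
            skip_grads[lvl] = dskip
            dy = self.ups[i].backward(dy)
        for lvl in range(self.config.levels - 1, -1, -1):
            if lvl < self.config.levels - 1:
                dy = self.dropblocks[lvl].backward(dy)
                dy = self.downs[lvl].backward(dy)
                dy = dy + skip_grads[lvl]
            elif lvl in skip_grads:  # pragma: no cover - bottleneck has no skip
                dy = dy + skip_grads[lvl]
            dy = self.enc_blocks[lvl].backward(dy)
        return dy

    def predict_volume(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode forward for a single (D, H, W) volume."""
        return self.forward(x[None, None], training=False)[0, 0].astype(float)


def build_model(config: NetConfig, seed: int = 0, dtype=np.float64) -> DoseUNet:
    """Construct the network (raises at build time on invalid dims)."""
    return DoseUNet(config, seed=seed, dtype=dtype)


def save_model(model: DoseUNet, path: str | Path) -> None:
    """Persist parameters plus NetConfig and training metadata."""
    cfg = model.config
    header = {
        "config": {
            "levels": cfg.levels,
            "base_features": cfg.base_features,
            "kernel": cfg.kernel,
            "groupnorm_groups": cfg.groupnorm_groups,
            "dropblock_size": cfg.dropblock_size,
            "dropblock_rate": cfg.dropblock_rate,
            "input_dims": list(cfg.input_dims),
        },
        "meta": {
            "dtype": model.dtype.name,
            "dose_scale": model.meta.get("dose_scale", 1.0),
            "spacing": list(model.meta["spacing"]) if model.meta.get("spacing")
            else None,
        },
    }
    arrays = {f"p{i:04d}": p.value for i, p in enumerate(model.params())}
    np.savez_compressed(path, header=json.dumps(header), **arrays)


def load_model(path: str | Path) -> DoseUNet:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        cfg_d = header["config"]
        cfg_d["input_dims"] = tuple(cfg_d["input_dims"])
        model = DoseUNet(NetConfig(**cfg_d),
                         dtype=header["meta"].pop("dtype", "float64"))
        model.load_state([z[f"p{i:04d}"] for i in range(len(model.params()))])
        model.meta.update(header["meta"])
        if model.meta.get("spacing"):
            model.meta["spacing"] = tuple(model.meta["spacing"])
    return model
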