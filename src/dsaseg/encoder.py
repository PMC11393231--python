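"""Six-level residual-convolution encoder.

Level i of the hierarchy carries ``2**(i-1) * C`` channels at spatial
extents ``(D, H, W) / 2**(i-1)``: level 1 works at full resolution and
each deeper level halves every spatial axis with a stride-2 convolution
in the first block of its residual module.  Five halvings mean valid
inputs have extents divisible by 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .config import NetworkConfig
from .nn import Conv3d, InstanceNorm3d, Module, ModuleList, activation
from .volumes import MultiChannelVolume, ShapeError

__all__ = ["ResConv", "Encoder", "FeaturePyramid", "res_conv", "encode", "level_shape"]


def level_shape(cfg: NetworkConfig, input_shape: tuple[int, int, int],
                level: int) -> tuple[int, int, int, int]:
    """Expected (channels, d, h, w) of encoder level ``level`` (1-based)."""
    f = 2 ** (level - 1)
    d, h, w = input_shape
    return (f * cfg.first_filters, d // f, h // f, w // f)


@dataclass
class FeaturePyramid:
    """The ordered encoder feature maps x_1..x_6 (each (c, d, h, w))."""

    maps: list[np.ndarray]
    level_shapes: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.level_shapes:
            self.level_shapes = [tuple(m.shape) for m in self.maps]
        for i, (m, expect) in enumerate(zip(self.maps, self.level_shapes), start=1):
            if tuple(m.shape) != tuple(expect):
                raise ShapeError(f"level {i} has shape {m.shape}, expected {expect}")

    def __len__(self) -> int:
        return len(self.maps)

    def __getitem__(self, level: int) -> np.ndarray:
        """1-based level access matching the architecture's numbering."""
        if not 1 <= level <= len(self.maps):
            raise IndexError(f"level {level} out of range 1..{len(self.maps)}")
        return self.maps[level - 1]


class _Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ResConv(Module):
    """Two conv(3x3x3)-norm-act blocks with a residual connection.

    The shortcut is the identity when shape permits, otherwise a 1x1x1
    convolution with matching stride; the residual is added after the
    second activation, so zeroed conv weights make the module reduce to
    its (projected) shortcut.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 norm_kind: str = "instance", act_kind: str = "leaky_relu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        rng = rng or np.random.default_rng(0)
        self.act_kind = act_kind
        self.conv1 = Conv3d(in_channels, out_channels, 3, stride=stride, rng=rng)
        self.conv2 = Conv3d(out_channels, out_channels, 3, stride=1, rng=rng)
        if norm_kind == "instance":
            self.norm1 = InstanceNorm3d(out_channels)
            self.norm2 = InstanceNorm3d(out_channels)
        else:
            self.norm1 = _Identity()
            self.norm2 = _Identity()
        if in_channels != out_channels or stride != 1:
            self.shortcut = Conv3d(in_channels, out_channels, 1, stride=stride,
                                   padding=0, rng=rng)
        else:
            self.shortcut = _Identity()

    def forward(self, x: Tensor) -> Tensor:
        self._check_stride(x)
        h = activation(self.norm1(self.conv1(x)), self.act_kind)
        h = activation(self.norm2(self.conv2(h)), self.act_kind)
        return h + self.shortcut(x)

    def _check_stride(self, x: Tensor) -> None:
        stride = self.conv1.stride
        for name, ext in zip("DHW", x.shape[2:]):
            if ext % stride != 0:
                raise ShapeError(
                    f"axis {name} has extent {ext}, not divisible by stride {stride}"
                )


def res_conv(x: np.ndarray, out_channels: int | None = None, stride: int = 1,
             module: ResConv | None = None, seed: int = 0) -> np.ndarray:
    """Apply a residual-convolution module to an unbatched (c,d,h,w) array.

    A seeded module is built on the fly unless one is supplied (which
    lets callers pin or inspect the weights).
    """
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4:
        raise ShapeError(f"expected a (c, d, h, w) array, got shape {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")
    if module is None:
        if out_channels is None:
            raise ValueError("out_channels is required when no module is given")
        module = ResConv(x.shape[0], out_channels, stride=stride,
                         rng=np.random.default_rng(seed))
    out = module(Tensor(x[None]))
    return out.data[0]


class Encoder(Module):
    """The six-level hierarchy producing the multiscale feature pyramid."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        levels = []
        c_in = cfg.in_channels
        for i in range(1, cfg.levels + 1):
            c_out = 2 ** (i - 1) * cfg.first_filters
            stride = 1 if i == 1 else 2
            levels.append(ResConv(c_in, c_out, stride=stride,
                                  norm_kind=cfg.norm_kind, act_kind=cfg.act_kind,
                                  rng=rng))
            c_in = c_out
        self.levels = ModuleList(levels)

    def forward(self, x: Tensor) -> list[Tensor]:
        for name, ext in zip("DHW", x.shape[2:]):
            if ext % 32 != 0:
                raise ShapeError(f"axis {name} has extent {ext}, not divisible by 32")
        feats = []
        h = x
        for block in self.levels:
            h = block(h)
            feats.append(h)
        return feats


def encode(volume: MultiChannelVolume, cfg: NetworkConfig,
           encoder: Encoder | None = None, seed: int = 0) -> FeaturePyramid:
    """Run the encoder on one volume, returning the feature pyramid."""
    if volume.n_channels != cfg.in_channels:
        raise ShapeError(
            f"volume has {volume.n_channels} channels, config expects {cfg.in_channels}"
        )
    volume.check_divisible(32)
    if encoder is None:
        encoder = Encoder(cfg, rng=np.random.default_rng(seed))
    feats = encoder(Tensor(volume.values[None]))
    expected = [level_shape(cfg, volume.spatial_shape, i)
                for i in range(1, cfg.levels + 1)]
    return FeaturePyramid([f.data[0] for f in feats], level_shapes=expected)
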