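"""Decoder, prediction head, and assembly of the full segmentation network.

The decoder walks the hierarchy from level 6 up to level 1.  At each
step the deeper feature map is upsampled by a 2x2x2 transposed
convolution that halves its channels, concatenated with the skip for
that level — the transformer-pathway output z_i on levels 3-6, the raw
encoder feature x_i on levels 1-2 where no pathway exists — and fused by
a residual convolution.  A 1x1x1 convolution and a channel softmax turn
the full-resolution features into a two-channel lesion probability map
the same size as the input.
"""

from __future__ import annotations

import numpy as np

from .attention import Pathway
from .autodiff import Tensor, concatenate
from .config import AttentionConfig, ConfigError, NetworkConfig, VARIANTS
from .encoder import Encoder, ResConv, level_shape
from .nn import Conv3d, ConvTranspose3d, Module, ModuleList, activation
from .volumes import LesionProbabilityMap, MultiChannelVolume, ShapeError

__all__ = [
    "FusionBlock",
    "SegmentationNet",
    "upsample_fuse",
    "predict_head",
    "ms_dsa_net_forward",
    "build_model",
]


class FusionBlock(Module):
    """Deconv-upsample the deep map, concatenate the skip, convolve."""

    def __init__(self, deep_channels: int, skip_channels: int,
                 norm_kind: str = "instance", act_kind: str = "leaky_relu",
                 fusion_kind: str = "resconv",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        up_channels = deep_channels // 2
        self.up = ConvTranspose3d(deep_channels, up_channels, rng=rng)
        self.act_kind = act_kind
        if fusion_kind == "resconv":
            self.fuse = ResConv(up_channels + skip_channels, skip_channels,
                                stride=1, norm_kind=norm_kind, act_kind=act_kind,
                                rng=rng)
        else:
            self.fuse = _DoubleConv(up_channels + skip_channels, skip_channels,
                                    norm_kind, act_kind, rng)

    def forward(self, y_deep: Tensor, skip: Tensor) -> Tensor:
        for name, (de, se) in zip("DHW", zip(y_deep.shape[2:], skip.shape[2:])):
            if se != 2 * de:
                raise ShapeError(
                    f"axis {name}: skip extent {se} is not twice the deep extent {de}"
                )
        up = self.up(y_deep)
        return self.fuse(concatenate([up, skip], axis=1))


class _DoubleConv(Module):
    def __init__(self, cin, cout, norm_kind, act_kind, rng):
        super().__init__()
        from .nn import InstanceNorm3d
        self.act_kind = act_kind
        self.conv1 = Conv3d(cin, cout, 3, rng=rng)
        self.conv2 = Conv3d(cout, cout, 3, rng=rng)
        if norm_kind == "instance":
            self.norm1 = InstanceNorm3d(cout)
            self.norm2 = InstanceNorm3d(cout)
        else:
            from .encoder import _Identity
            self.norm1 = _Identity()
            self.norm2 = _Identity()

    def forward(self, x):
        h = activation(self.norm1(self.conv1(x)), self.act_kind)
        return activation(self.norm2(self.conv2(h)), self.act_kind)


def upsample_fuse(y_deep: np.ndarray, skip: np.ndarray,
                  module: FusionBlock | None = None, seed: int = 0) -> np.ndarray:
    """Functional fusion of unbatched (c, d, h, w) deep and skip maps."""
    y_deep = np.asarray(y_deep, dtype=np.float32)
    skip = np.asarray(skip, dtype=np.float32)
    if module is None:
        module = FusionBlock(y_deep.shape[0], skip.shape[0],
                             rng=np.random.default_rng(seed))
    out = module(Tensor(y_deep[None]), Tensor(skip[None]))
    return out.data[0]


class PredictHead(Module):
    """1x1x1 convolution to two channels followed by a channel softmax."""

    def __init__(self, in_channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv3d(in_channels, 2, 1, padding=0, rng=rng or np.random.default_rng(0))

    def forward(self, y1: Tensor) -> Tensor:
        logits = self.conv(y1)
        return logits.softmax(axis=1)


def predict_head(y1: np.ndarray, module: PredictHead | None = None,
                 seed: int = 0, spacing=(1.0, 1.0, 1.0),
                 affine: np.ndarray | None = None) -> LesionProbabilityMap:
    """Turn an unbatched (c, d, h, w) feature map into a probability map."""
    y1 = np.asarray(y1, dtype=np.float32)
    if module is None:
        module = PredictHead(y1.shape[0], rng=np.random.default_rng(seed))
    probs = module(Tensor(y1[None])).data[0]
    kwargs = {"spacing": spacing}
    if affine is not None:
        kwargs["affine"] = affine
    return LesionProbabilityMap(probs, **kwargs)


class SegmentationNet(Module):
    """The full encoder / transformer-pathway / decoder network.

    The model is bound to one patch geometry at build time because the
    positional embeddings and the token-axis projections of each DSA
    module are sized by the sequence length of their level.
    """

    def __init__(self, net_cfg: NetworkConfig, attn_cfg: AttentionConfig,
                 patch_size: tuple[int, int, int], variant: str = "dsa",
                 seed: int = 0):
        super().__init__()
        if variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}, got {variant!r}")
        patch_size = tuple(int(v) for v in patch_size)
        for name, ext in zip("DHW", patch_size):
            if ext % 32 != 0:
                raise ShapeError(f"patch axis {name} extent {ext} is not divisible by 32")
        self.net_cfg = net_cfg
        self.attn_cfg = attn_cfg
        self.patch_size = patch_size
        self.variant = variant
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(net_cfg, rng=rng)
        shapes = {i: level_shape(net_cfg, patch_size, i) for i in range(1, 7)}
        self.pathways = ModuleList([
            Pathway(shapes[lev][0], shapes[lev][1:], attn_cfg, variant=variant,
                    norm_kind=net_cfg.norm_kind, act_kind=net_cfg.act_kind, rng=rng)
            for lev in attn_cfg.pathway_levels
        ])
        # decoder: deepest skip (level 6 pathway output) is the start map
        skip_channels = {}
        for lev in range(1, 7):
            if lev in attn_cfg.pathway_levels:
                skip_channels[lev] = shapes[lev][0] // 2
            else:
                skip_channels[lev] = shapes[lev][0]
        self.fusions = ModuleList([
            FusionBlock(skip_channels[lev + 1], skip_channels[lev],
                        norm_kind=net_cfg.norm_kind, act_kind=net_cfg.act_kind,
                        fusion_kind=net_cfg.fusion_kind, rng=rng)
            for lev in range(5, 0, -1)
        ])
        self.head = PredictHead(skip_channels[1], rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, C0, D, H, W) -> probabilities (N, 2, D, H, W)."""
        if tuple(x.shape[2:]) != self.patch_size:
            raise ShapeError(
                f"input spatial shape {tuple(x.shape[2:])} does not match the "
                f"patch size {self.patch_size} the model was built for"
            )
        feats = self.encoder(x)
        skips = {lev: feats[lev - 1] for lev in range(1, 7)}
        for pathway, lev in zip(self.pathways, self.attn_cfg.pathway_levels):
            skips[lev] = pathway(skips[lev])
        y = skips[6]
        for fusion, lev in zip(self.fusions, range(5, 0, -1)):
            y = fusion(y, skips[lev])
        return self.head(y)

    def predict_volume(self, volume: MultiChannelVolume) -> LesionProbabilityMap:
        """Single-patch inference on a volume matching the patch size."""
        out = self.forward(Tensor(volume.values[None]))
        return LesionProbabilityMap(out.data[0], spacing=volume.spacing,
                                    affine=volume.affine)


def build_model(net_cfg: NetworkConfig | None = None,
                attn_cfg: AttentionConfig | None = None,
                patch_size: tuple[int, int, int] = (128, 128, 128),
                variant: str = "dsa", seed: int = 0) -> SegmentationNet:
    return SegmentationNet(net_cfg or NetworkConfig(), attn_cfg or AttentionConfig(),
                           patch_size, variant=variant, seed=seed)


def ms_dsa_net_forward(volume: MultiChannelVolume, net_cfg: NetworkConfig,
                       attn_cfg: AttentionConfig, variant: str = "dsa",
                       model: SegmentationNet | None = None,
                       seed: int = 0) -> LesionProbabilityMap:
    """One full forward pass on a volume (built fresh unless given)."""
    if model is None:
        model = SegmentationNet(net_cfg, attn_cfg, volume.spatial_shape,
                                variant=variant, seed=seed)
    return model.predict_volume(volume)
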