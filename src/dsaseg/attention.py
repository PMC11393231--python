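"""Transformer pathways built from dual-self-attention (DSA) modules.

A DSA module flattens a (c, d, h, w) feature map into n = d*h*w tokens,
adds a learnable positional embedding, layer-normalises, and runs two
parallel branches that share one query Q and one key K:

* spatial self-attention (SSA): K and the spatial value V_s are first
  projected along the token axis to p << n rows, so the attention map
  A_s = softmax(Q K_bar^T / sqrt(s)) is n x p and the cost is O(n*p)
  instead of the O(n^2) of dense attention;
* channel self-attention (CSA): A_c = softmax(Q^T K / sqrt(s)) is c x c
  and reweights channels via x_c = V_c A_c.

The rescale factor is s = c / n_h for n_h heads; heads partition the
channel axis.  The branch outputs are fused by addition and added back
to the tokens (z' = x + x_s + x_c); the result is reshaped to
(c, d, h, w) and refined by a residual convolution tail.  A pathway
chains m such modules after a channel-halving residual convolution, and
pathways are attached to encoder levels 3-6 (scales 1/4 to 1/32).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .config import AttentionConfig, ConfigError, NetworkConfig
from .encoder import ResConv
from .nn import Conv3d, LayerNorm, Linear, Module, ModuleList, Parameter, _he_init
from .volumes import ShapeError

__all__ = [
    "TokenSequence",
    "AttentionProjections",
    "tokenize",
    "detokenize",
    "spatial_self_attention",
    "channel_self_attention",
    "dsa_forward",
    "pathway_forward",
    "DSAModule",
    "Pathway",
]


@dataclass
class TokenSequence:
    """An (n, c) token matrix with its (d, h, w) spatial provenance."""

    tokens: np.ndarray
    origin_shape: tuple[int, int, int]
    level: int | None = None

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens)
        d, h, w = self.origin_shape
        if self.tokens.ndim != 2 or self.tokens.shape[0] != d * h * w:
            raise ShapeError(
                f"tokens shape {self.tokens.shape} inconsistent with origin {self.origin_shape}"
            )

    @property
    def n(self) -> int:
        return self.tokens.shape[0]

    @property
    def c(self) -> int:
        return self.tokens.shape[1]


@dataclass
class AttentionProjections:
    """The per-module attention inputs: shared Q/K, values, projections."""

    Q: np.ndarray
    K: np.ndarray
    Vs: np.ndarray | None = None
    Vc: np.ndarray | None = None
    K_bar: np.ndarray | None = None
    Vs_bar: np.ndarray | None = None
    e: np.ndarray | None = None


def _layer_norm_np(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


def tokenize(feature_map: np.ndarray, e: np.ndarray | None = None,
             level: int | None = None) -> TokenSequence:
    """Flatten a (c, d, h, w) map to (n, c) tokens, add the positional
    embedding, and layer-normalise over channels."""
    fm = np.asarray(feature_map)
    if fm.ndim != 4:
        raise ShapeError(f"expected (c, d, h, w), got shape {fm.shape}")
    c, d, h, w = fm.shape
    n = d * h * w
    tokens = fm.reshape(c, n).T
    if e is not None:
        e = np.asarray(e)
        if e.shape != (n, c):
            raise ShapeError(f"embedding shape {e.shape} does not match tokens ({n}, {c})")
        tokens = tokens + e
    tokens = _layer_norm_np(tokens)
    return TokenSequence(tokens, origin_shape=(d, h, w), level=level)


def detokenize(tokens: np.ndarray, origin_shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of the flatten/transpose step: (n, c) -> (c, d, h, w)."""
    tokens = np.asarray(tokens)
    d, h, w = origin_shape
    n, c = tokens.shape
    if n != d * h * w:
        raise ShapeError(f"{n} tokens cannot fill origin shape {origin_shape}")
    return tokens.T.reshape(c, d, h, w)


# ---------------------------------------------------------------------------
# Attention cores (autodiff Tensors, batched (N, n, c))
# ---------------------------------------------------------------------------

def _split_heads(t: Tensor, n_h: int) -> Tensor:
    """(N, n, c) -> (N, n_h, n, c/n_h); heads partition the channel axis."""
    N, n, c = t.shape
    if c % n_h != 0:
        raise ConfigError(f"heads={n_h} does not divide channels={c}")
    return t.reshape(N, n, n_h, c // n_h).transpose(0, 2, 1, 3)


def _merge_heads(t: Tensor) -> Tensor:
    N, n_h, n, ch = t.shape
    return t.transpose(0, 2, 1, 3).reshape(N, n, n_h * ch)


def ssa_core(Q: Tensor, K_bar: Tensor, Vs_bar: Tensor, n_h: int):
    """Spatial self-attention: returns (x_s (N,n,c), A_s (N,n_h,n,p))."""
    c = Q.shape[-1]
    s = c / n_h
    Qh = _split_heads(Q, n_h)                      # (N, nh, n, ch)
    Kh = _split_heads(K_bar, n_h)                  # (N, nh, p, ch)
    attn = (Qh @ Kh.swapaxes(-1, -2)) * (1.0 / np.sqrt(s))
    attn = attn.softmax(axis=-1)                   # rows sum to 1
    Vh = _split_heads(Vs_bar, n_h)                 # (N, nh, p, ch)
    return _merge_heads(attn @ Vh), attn


def csa_core(Q: Tensor, K: Tensor, Vc: Tensor, n_h: int):
    """Channel self-attention: returns (x_c (N,n,c), A_c (N,n_h,ch,ch))."""
    c = Q.shape[-1]
    s = c / n_h
    Qh = _split_heads(Q, n_h)
    Kh = _split_heads(K, n_h)
    attn = (Qh.swapaxes(-1, -2) @ Kh) * (1.0 / np.sqrt(s))
    attn = attn.softmax(axis=-1)                   # normalised along last axis
    Vh = _split_heads(Vc, n_h)
    return _merge_heads(Vh @ attn), attn


def _proj_array(proj: AttentionProjections, name: str) -> Tensor:
    arr = getattr(proj, name)
    if arr is None:
        raise ValueError(f"projection field {name!r} is required but missing")
    return Tensor(np.asarray(arr, dtype=float)[None])


def spatial_self_attention(proj: AttentionProjections, cfg: AttentionConfig,
                           return_attention: bool = False):
    """Functional SSA on unbatched (n, c) projections; returns x_s (n, c)."""
    Q = _proj_array(proj, "Q")
    K_bar = _proj_array(proj, "K_bar")
    Vs_bar = _proj_array(proj, "Vs_bar")
    n, p = Q.shape[1], K_bar.shape[1]
    if p > n:
        raise ConfigError(f"projection dimension p={p} exceeds sequence length n={n}")
    x_s, attn = ssa_core(Q, K_bar, Vs_bar, cfg.heads)
    if return_attention:
        a = attn.data[0]
        return x_s.data[0], (a[0] if cfg.heads == 1 else a)
    return x_s.data[0]


def channel_self_attention(proj: AttentionProjections, cfg: AttentionConfig,
                           return_attention: bool = False):
    """Functional CSA on unbatched (n, c) projections; returns x_c (n, c)."""
    Q = _proj_array(proj, "Q")
    K = _proj_array(proj, "K")
    Vc = _proj_array(proj, "Vc")
    x_c, attn = csa_core(Q, K, Vc, cfg.heads)
    if return_attention:
        a = attn.data[0]
        return x_c.data[0], (a[0] if cfg.heads == 1 else a)
    return x_c.data[0]


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class DSAModule(Module):
    """One dual-self-attention module bound to a fixed token geometry.

    ``variant`` selects the branch set: "dsa" (both), "ssa" (spatial
    only) or "csa" (channel only); the shared Q/K are built either way.
    """

    def __init__(self, channels: int, origin_shape: tuple[int, int, int],
                 cfg: AttentionConfig, variant: str = "dsa",
                 norm_kind: str = "instance", act_kind: str = "leaky_relu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if variant not in ("dsa", "ssa", "csa"):
            raise ConfigError(f"unknown variant {variant!r}")
        cfg.rescale(channels)  # validates head divisibility
        d, h, w = origin_shape
        self.variant = variant
        self.cfg = cfg
        self.channels = channels
        self.origin_shape = tuple(origin_shape)
        self.n = d * h * w
        self.p = min(cfg.proj_dim, self.n)
        self.call_count = 0
        c = channels
        self.embedding = Parameter(np.zeros((self.n, c)))
        self.ln = LayerNorm(c)
        self.wq = Linear(c, c, rng=rng)
        self.wk = Linear(c, c, rng=rng)
        if variant in ("dsa", "ssa"):
            self.wvs = Linear(c, c, rng=rng)
            self.proj_k = Parameter(_he_init(rng, (self.p, self.n), self.n))
            self.proj_vs = Parameter(_he_init(rng, (self.p, self.n), self.n))
        if variant in ("dsa", "csa"):
            self.wvc = Linear(c, c, rng=rng)
        self.tail_res = ResConv(c, c, stride=1, norm_kind=norm_kind,
                                act_kind=act_kind, rng=rng)
        self.tail_conv = Conv3d(c, c, 1, padding=0, rng=rng)
        self._dropout_rng = np.random.default_rng(rng.integers(2 ** 31))

    def _maybe_dropout(self, attn: Tensor) -> Tensor:
        rate = self.cfg.dropout
        if rate > 0.0 and self.training:
            keep = (self._dropout_rng.random(attn.shape) >= rate) / (1.0 - rate)
            return attn * Tensor(keep.astype(np.float32))
        return attn

    def attend_tokens(self, t: Tensor, return_parts: bool = False):
        """Attention branches + token residual: z' = x + (x_s + x_c)."""
        z = t
        x_s = x_c = None
        if self.variant in ("dsa", "ssa"):
            Q, K, Vs = self.wq(t), self.wk(t), self.wvs(t)
            K_bar = self.proj_k @ K
            Vs_bar = self.proj_vs @ Vs
            c = t.shape[-1]
            s = c / self.cfg.heads
            Qh = _split_heads(Q, self.cfg.heads)
            Kh = _split_heads(K_bar, self.cfg.heads)
            attn = ((Qh @ Kh.swapaxes(-1, -2)) * (1.0 / np.sqrt(s))).softmax(axis=-1)
            attn = self._maybe_dropout(attn)
            x_s = _merge_heads(attn @ _split_heads(Vs_bar, self.cfg.heads))
            z = z + x_s
            if self.variant == "dsa":
                Vc = self.wvc(t)
                x_c, _ = csa_core(Q, K, Vc, self.cfg.heads)
                z = z + x_c
        else:  # csa only
            Q, K, Vc = self.wq(t), self.wk(t), self.wvc(t)
            x_c, _ = csa_core(Q, K, Vc, self.cfg.heads)
            z = z + x_c
        if return_parts:
            return z, x_s, x_c
        return z

    def forward(self, x: Tensor, return_pre_tail: bool = False):
        """x: (N, c, d, h, w) -> same shape, attention-enriched."""
        self.call_count += 1
        N, c, d, h, w = x.shape
        if (d, h, w) != self.origin_shape or c != self.channels:
            raise ShapeError(
                f"input shape {(c, d, h, w)} does not match module geometry "
                f"({self.channels}, *{self.origin_shape})"
            )
        n = d * h * w
        t = x.reshape(N, c, n).swapaxes(1, 2) + self.embedding
        t = self.ln(t)
        z = self.attend_tokens(t)
        z4 = z.swapaxes(1, 2).reshape(N, c, d, h, w)
        out = z4 + self.tail_conv(self.tail_res(z4))
        if return_pre_tail:
            return out, z
        return out


class Pathway(Module):
    """Channel-halving ResConv followed by m sequential DSA modules."""

    def __init__(self, in_channels: int, origin_shape: tuple[int, int, int],
                 cfg: AttentionConfig, variant: str = "dsa",
                 norm_kind: str = "instance", act_kind: str = "leaky_relu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if in_channels % 2 != 0:
            raise ConfigError(f"pathway input channels {in_channels} must be even")
        self.out_channels = in_channels // 2
        self.pre = ResConv(in_channels, self.out_channels, stride=1,
                           norm_kind=norm_kind, act_kind=act_kind, rng=rng)
        self.dsa_modules = ModuleList([
            DSAModule(self.out_channels, origin_shape, cfg, variant=variant,
                      norm_kind=norm_kind, act_kind=act_kind, rng=rng)
            for _ in range(cfg.modules_per_pathway)
        ])

    def forward(self, x: Tensor) -> Tensor:
        h = self.pre(x)
        for mod in self.dsa_modules:
            h = mod(h)
        return h


# ---------------------------------------------------------------------------
# Functional wrappers over unbatched arrays
# ---------------------------------------------------------------------------

def dsa_forward(x: TokenSequence, module: DSAModule,
                return_pre_tail: bool = False):
    """Run one DSA module's branches + tail on an already-tokenised input.

    The tokens are assumed embedded and normalised (i.e. produced by
    :func:`tokenize` with this module's embedding); returns the enriched
    (c, d, h, w) feature map.
    """
    if x.origin_shape != module.origin_shape or x.c != module.channels:
        raise ShapeError(
            f"token geometry ({x.c}, *{x.origin_shape}) does not match module "
            f"({module.channels}, *{module.origin_shape})"
        )
    t = Tensor(np.asarray(x.tokens, dtype=np.float32)[None])
    z = module.attend_tokens(t)
    d, h, w = x.origin_shape
    z4 = z.swapaxes(1, 2).reshape(1, x.c, d, h, w)
    out = z4 + module.tail_conv(module.tail_res(z4))
    if return_pre_tail:
        return out.data[0], z.data[0]
    return out.data[0]


def pathway_forward(x_i: np.ndarray, cfg: AttentionConfig, level: int,
                    net_cfg: NetworkConfig | None = None,
                    module: Pathway | None = None, variant: str = "dsa",
                    seed: int = 0) -> np.ndarray:
    """Apply a transformer pathway to one unbatched encoder feature map."""
    if level not in cfg.pathway_levels:
        raise ConfigError(f"level {level} has no configured pathway {cfg.pathway_levels}")
    x_i = np.asarray(x_i, dtype=np.float32)
    if x_i.ndim != 4:
        raise ShapeError(f"expected (c, d, h, w), got shape {x_i.shape}")
    if module is None:
        net_cfg = net_cfg or NetworkConfig()
        module = Pathway(x_i.shape[0], x_i.shape[1:], cfg, variant=variant,
                         norm_kind=net_cfg.norm_kind, act_kind=net_cfg.act_kind,
                         rng=np.random.default_rng(seed))
    return module(Tensor(x_i[None])).data[0]
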