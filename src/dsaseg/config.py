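"""Configuration dataclasses and their YAML round-trip.

Every knob the network, loss, phantom generator and training loop expose
lives here so a run is fully described by one YAML file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "NetworkConfig",
    "AttentionConfig",
    "LossConfig",
    "RunConfig",
    "ConfigError",
]

VARIANTS = ("dsa", "ssa", "csa")
CHANNEL_SETS = {"t1": ("t1",), "flair": ("flair",), "t1+flair": ("t1", "flair")}


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class NetworkConfig:
    """Encoder/decoder hyper-parameters.

    ``first_filters`` is the filter count of the first encoder level
    (C); level i carries 2**(i-1) * C channels.  The encoder depth is
    fixed at six levels (five halvings), so valid inputs have spatial
    extents divisible by 32.
    """

    in_channels: int = 2
    first_filters: int = 16
    levels: int = 6
    norm_kind: str = "instance"
    act_kind: str = "leaky_relu"
    fusion_kind: str = "resconv"

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise ConfigError("in_channels must be >= 1")
        if self.first_filters < 1:
            raise ConfigError("first_filters must be >= 1")
        if self.levels != 6:
            raise ConfigError("the encoder depth is fixed at 6 levels")
        if self.norm_kind not in ("instance", "none"):
            raise ConfigError(f"unknown norm_kind {self.norm_kind!r}")
        if self.act_kind not in ("leaky_relu", "relu"):
            raise ConfigError(f"unknown act_kind {self.act_kind!r}")
        if self.fusion_kind not in ("resconv", "conv"):
            raise ConfigError(f"unknown fusion_kind {self.fusion_kind!r}")


@dataclass
class AttentionConfig:
    """Transformer-pathway hyper-parameters.

    ``proj_dim`` (p) is the token count after the linear down-projection
    of keys and spatial values; it is clamped to the sequence length n
    on pathways where n < p.  ``heads`` (n_h) must divide the channel
    count of every pathway; the attention rescale factor is s = c / n_h.
    ``modules_per_pathway`` (m) chains that many dual-self-attention
    modules per pathway.
    """

    heads: int = 8
    proj_dim: int = 64
    modules_per_pathway: int = 3
    pathway_levels: tuple[int, ...] = (3, 4, 5, 6)
    dropout: float = 0.0

    def __post_init__(self) -> None:
        self.pathway_levels = tuple(self.pathway_levels)
        if self.heads < 1:
            raise ConfigError("heads must be >= 1")
        if self.proj_dim < 1:
            raise ConfigError("proj_dim must be >= 1")
        if self.modules_per_pathway < 1:
            raise ConfigError("modules_per_pathway must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.pathway_levels != (3, 4, 5, 6):
            raise ConfigError("pathways are fixed to encoder levels 3-6 (scales 1/4 to 1/32)")

    def rescale(self, channels: int) -> float:
        """The attention rescale factor s = c / n_h."""
        if channels % self.heads != 0:
            raise ConfigError(f"heads={self.heads} does not divide channels={channels}")
        return channels / self.heads


@dataclass
class LossConfig:
    """Hybrid Dice + cross-entropy loss weights."""

    omega: float = 1.0
    epsilon: float = 1e-5
    prob_floor: float = 1e-7

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ConfigError("omega must be >= 0")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be > 0")


@dataclass
class RunConfig:
    """End-to-end run description: data, model, optimisation, inference."""

    patch_size: tuple[int, int, int] = (128, 128, 128)
    batch_size: int = 2
    epochs: int = 10
    steps_per_epoch: int = 50
    lr: float = 1e-4
    lr_schedule: str = "cosine"
    max_grad_norm: float | None = 1.0
    seed: int = 0
    input_channels: str = "t1+flair"
    variant: str = "dsa"
    overlap: float = 0.5
    lesion_patch_rate: float = 0.5
    connectivity: int = 26
    threshold: float = 0.5
    network: NetworkConfig = field(default_factory=NetworkConfig)
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        self.patch_size = tuple(int(v) for v in self.patch_size)
        if len(self.patch_size) != 3 or any(v % 32 != 0 for v in self.patch_size):
            raise ConfigError(f"patch_size {self.patch_size} must be three extents divisible by 32")
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.input_channels not in CHANNEL_SETS:
            raise ConfigError(f"input_channels must be one of {sorted(CHANNEL_SETS)}")
        if not 0.0 <= self.overlap <= 0.9:
            raise ConfigError("overlap must be in [0, 0.9]")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")
        expected = len(CHANNEL_SETS[self.input_channels])
        if self.network.in_channels != expected:
            self.network = dataclasses.replace(self.network, in_channels=expected)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return CHANNEL_SETS[self.input_channels]

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["patch_size"] = list(self.patch_size)
        d["attention"]["pathway_levels"] = list(self.attention.pathway_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("network", NetworkConfig), ("attention", AttentionConfig),
                         ("loss", LossConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def desk_scale(cls, seed: int = 0, variant: str = "dsa") -> "RunConfig":
        """A thin-width configuration for CPU-scale runs: 32^3 patches,
        4 first-level filters, 2 heads, 16-token projection, and a higher
        learning rate suited to short from-scratch schedules."""
        return cls(
            patch_size=(32, 32, 32),
            batch_size=2,
            epochs=4,
            steps_per_epoch=50,
            lr=1e-3,
            seed=seed,
            variant=variant,
            network=NetworkConfig(in_channels=2, first_filters=4),
            attention=AttentionConfig(heads=2, proj_dim=16),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
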