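"""Volume containers and NIfTI I/O.

The in-memory currency of the package: a multi-channel 3D image, a
binary lesion mask and a two-channel lesion probability map, each
carrying its voxel spacing and voxel-to-world affine.  Arrays are
indexed (channel, depth, height, width); NIfTI files store a single
channel each, so multi-channel volumes are assembled by stacking files.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "MultiChannelVolume",
    "BinaryLesionMask",
    "LesionProbabilityMap",
    "ShapeError",
    "load_nifti_channel",
    "save_nifti",
]


class ShapeError(ValueError):
    """Raised when array extents violate a structural contract."""


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class MultiChannelVolume:
    """A (C, D, H, W) real-valued image volume with spatial metadata."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 4:
            raise ShapeError(f"expected a (C, D, H, W) array, got shape {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("volume contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]

    def check_divisible(self, factor: int = 32) -> None:
        for name, ext in zip("DHW", self.spatial_shape):
            if ext % factor != 0:
                raise ShapeError(
                    f"axis {name} has extent {ext}, not divisible by {factor}"
                )


@dataclass
class BinaryLesionMask:
    """A (D, H, W) binary ground-truth / prediction mask."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ShapeError(f"expected a (D, H, W) array, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask is not binary; found values {uniq[:10]}")
        self.values = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())


@dataclass
class LesionProbabilityMap:
    """A (2, D, H, W) softmax output; channel 1 is the lesion probability."""

    probs: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 4 or self.probs.shape[0] != 2:
            raise ShapeError(f"expected a (2, D, H, W) array, got shape {self.probs.shape}")
        if self.probs.min() < -1e-5 or self.probs.max() > 1 + 1e-5:
            raise ValueError("probabilities outside [0, 1]")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-4):
            raise ValueError("per-voxel channel probabilities do not sum to 1")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def foreground(self) -> np.ndarray:
        return self.probs[1]

    def binarize(self, threshold: float = 0.5) -> BinaryLesionMask:
        return BinaryLesionMask(
            (self.foreground >= threshold).astype(np.uint8),
            spacing=self.spacing, affine=self.affine,
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def load_nifti_channel(path: str | Path, canonical: bool = True):
    """Load one NIfTI file; returns (data float32 (D,H,W), spacing, affine)."""
    img = nib.load(str(path))
    if canonical:
        img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine, dtype=float)


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3D array as NIfTI; ``.gz`` output is reproducible (mtime 0)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    if path.suffix == ".gz":
        raw = img.to_bytes()
        buf = io.BytesIO()
        with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as fh:
            fh.write(raw)
        path.write_bytes(buf.getvalue())
    else:
        nib.save(img, str(path))
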