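"""Seeded synthetic phantoms: two-channel volumes with one lesion blob.

Each phantom emulates a skull-stripped, co-registered T1 + FLAIR pair:
a spherical "brain" support holding concentric smooth cortex-like
intensity bands plus a smooth random bias field, zero outside the
support.  An optional lesion is a blurred ellipsoid perturbation that is
hyperintense on the FLAIR-like channel (and mildly altered on T1),
emulating the blurred gray-white junction and FLAIR hyperintensity of
cortical dysplasia.  The ground-truth mask is the pre-blur ellipsoid
support.  The geometry is deliberately non-anatomical; it provides the
statistical structure (contrast + blurred boundary + noise) the rest of
the package needs for testing without any download.

Intensities are z-scored over the brain support at generation time, so
the intensity-normalisation preprocessing step is a near-no-op on
phantoms.  A phantom is fully determined by its spec, including the
seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import BinaryLesionMask, MultiChannelVolume, save_nifti

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort", "split_counts"]

# proportions of the 62 / 6 / 17 split of 85 subjects
DEFAULT_SPLIT = (62 / 85, 6 / 85, 17 / 85)
SPLIT_NAMES = ("train", "val", "test")


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; the seed fully determines the output."""

    shape: tuple[int, int, int] = (64, 64, 64)
    n_channels: int = 2
    lesion_count: int = 1
    lesion_radius_range: tuple[float, float] = (3.0, 7.0)
    lesion_contrast: float = 1.5
    t1_contrast: float = 0.4
    edge_blur_sigma: float = 1.0
    noise_sd: float = 0.1
    n_bands: int = 4
    band_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_count not in (0, 1):
            raise ValueError("lesion_count must be 0 or 1")
        if self.lesion_contrast < 0:
            raise ValueError("lesion_contrast must be >= 0")
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise ValueError("invalid lesion_radius_range")
        if hi >= min(self.shape) / 2:
            raise ValueError("lesion radii do not fit inside the volume")


def _brain_support(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    center = [(s - 1) / 2 for s in shape]
    r = np.sqrt(sum(((g - c) / (s / 2)) ** 2
                    for g, c, s in zip(grids, center, shape)))
    support = r <= 0.9
    return support, r


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    q = sum(((g - c) / rad) ** 2 for g, c, rad in zip(grids, center, radii))
    return (q <= 1.0).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> tuple[MultiChannelVolume, BinaryLesionMask]:
    """Generate one (volume, mask) pair from a spec."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    support, r = _brain_support(shape)

    # concentric cortex-like bands + a smooth per-channel bias field
    bands = spec.band_amplitude * np.sin(2 * np.pi * spec.n_bands * r)
    channels = []
    for ch in range(spec.n_channels):
        base = 1.0 + (0.2 * ch)
        bias = ndimage.gaussian_filter(rng.normal(0, 1.0, shape), sigma=8.0)
        channels.append((base + bands * (1.0 - 0.3 * ch) + 0.4 * bias) * support)
    vol = np.stack(channels)

    mask = np.zeros(shape, dtype=np.uint8)
    if spec.lesion_count == 1:
        lo, hi = spec.lesion_radius_range
        placed = False
        for _ in range(100):
            radii = rng.uniform(lo, hi, size=3)
            margin = radii.max() + 2
            center = [rng.uniform(margin, s - 1 - margin) for s in shape]
            cand = _ellipsoid_mask(shape, center, radii)
            if cand.sum() > 0 and (support | ~cand.astype(bool)).all():
                mask = cand
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place a lesion inside the volume bounds")
        blur = ndimage.gaussian_filter(mask.astype(float), sigma=spec.edge_blur_sigma)
        # FLAIR-like hyperintensity on the last channel, milder T1 change
        vol[-1] += spec.lesion_contrast * blur * support
        if spec.n_channels > 1:
            vol[0] += spec.t1_contrast * blur * support

    vol += rng.normal(0, spec.noise_sd, vol.shape) * support

    # z-score over the brain support per channel; outside stays zero
    for ch in range(spec.n_channels):
        inside = vol[ch][support]
        vol[ch][support] = (inside - inside.mean()) / inside.std()
    vol *= support

    affine = np.eye(4)
    volume = MultiChannelVolume(vol.astype(np.float32), spacing=(1.0, 1.0, 1.0),
                                affine=affine)
    return volume, BinaryLesionMask(mask, spacing=(1.0, 1.0, 1.0), affine=affine)


def split_counts(n_subjects: int, proportions=DEFAULT_SPLIT) -> tuple[int, ...]:
    """Largest-remainder apportionment of n subjects across the splits."""
    props = np.asarray(proportions, dtype=float)
    if props.sum() <= 0:
        raise ValueError("split proportions must be positive")
    props = props / props.sum()
    raw = props * n_subjects
    counts = np.floor(raw).astype(int)
    remainder = n_subjects - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return tuple(int(c) for c in counts)


def generate_cohort(n_subjects: int, out_dir: str | Path,
                    spec: PhantomSpec | None = None, seed: int = 0,
                    proportions=DEFAULT_SPLIT,
                    nonlesional_fraction: float = 7 / 85,
                    overwrite: bool = False) -> pd.DataFrame:
    """Write a phantom cohort (t1/flair/mask NIfTI triplets + manifest).

    Subjects are assigned to train/val/test by a seeded shuffle at the
    requested proportions (default mirrors 62/6/17 of 85); a fraction of
    subjects (default 7/85, the MRI-negative rate of the cohort the
    defaults emulate) carries no lesion.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)

    counts = split_counts(n_subjects, proportions)
    assignment = np.repeat(np.arange(len(counts)), counts)
    rng.shuffle(assignment)

    n_nonlesional = int(round(nonlesional_fraction * n_subjects))
    lesion_flags = np.ones(n_subjects, dtype=int)
    if n_nonlesional:
        lesion_flags[rng.choice(n_subjects, size=n_nonlesional, replace=False)] = 0

    child_seeds = rng.integers(0, 2 ** 31, size=n_subjects)
    rows = []
    for i in range(n_subjects):
        sid = f"sub-{i:03d}"
        sub_spec = dataclasses.replace(spec, lesion_count=int(lesion_flags[i]),
                                       seed=int(child_seeds[i]))
        volume, mask = generate_phantom(sub_spec)
        names = ("t1", "flair") if spec.n_channels == 2 else tuple(
            f"ch{c}" for c in range(spec.n_channels))
        for ch, name in enumerate(names):
            save_nifti(volume.values[ch], volume.affine,
                       out_dir / f"{sid}_{name}.nii.gz")
        save_nifti(mask.values, mask.affine, out_dir / f"{sid}_mask.nii.gz")
        rows.append({"subject_id": sid, "split": SPLIT_NAMES[assignment[i]],
                     "has_lesion": int(lesion_flags[i])})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
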