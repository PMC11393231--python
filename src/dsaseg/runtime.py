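"""Run-time plumbing: subject I/O, intensity normalisation, patch
sampling, sliding-window inference, the seeded training loop, and
checkpointing.

All randomness flows from the single seed in :class:`RunConfig`; the
checkpoint stores parameters, optimiser state, the full config and the
sampler RNG state, so an interrupted run resumes bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .config import RunConfig
from .decoder import SegmentationNet
from .losses import hybrid_loss
from .metrics import cohort_metrics
from .nn import Adam
from .volumes import (BinaryLesionMask, LesionProbabilityMap,
                      MultiChannelVolume, ShapeError, load_nifti_channel)

__all__ = [
    "load_subject",
    "normalize_intensity",
    "sliding_window_predict",
    "split_dataset",
    "train",
    "save_checkpoint",
    "load_checkpoint",
    "TrainResult",
]

logger = logging.getLogger("dsaseg")


# ---------------------------------------------------------------------------
# I/O and preprocessing
# ---------------------------------------------------------------------------

def load_subject(channel_paths, mask_path=None, canonical: bool = True):
    """Stack per-channel NIfTI files into a volume; optionally a mask.

    Channels must agree in shape and affine (1e-3 elementwise tolerance
    on the affine).  Mask values are binarised (> 0) with a warning when
    labels other than {0, 1} are present.
    """
    channel_paths = [Path(p) for p in channel_paths]
    datas, spacings, affines = [], [], []
    for p in channel_paths:
        d, s, a = load_nifti_channel(p, canonical=canonical)
        datas.append(d)
        spacings.append(s)
        affines.append(a)
    ref = channel_paths[0]
    for p, d, a in zip(channel_paths[1:], datas[1:], affines[1:]):
        if d.shape != datas[0].shape:
            raise ShapeError(f"shape mismatch between {ref} {datas[0].shape} and {p} {d.shape}")
        if not np.allclose(a, affines[0], atol=1e-3):
            raise ValueError(f"affine mismatch between {ref} and {p}")
    volume = MultiChannelVolume(np.stack(datas), spacing=spacings[0],
                                affine=affines[0])
    mask = None
    if mask_path is not None:
        md, _, ma = load_nifti_channel(mask_path, canonical=canonical)
        if md.shape != datas[0].shape:
            raise ShapeError(f"shape mismatch between {ref} {datas[0].shape} and "
                             f"{mask_path} {md.shape}")
        if not np.allclose(ma, affines[0], atol=1e-3):
            raise ValueError(f"affine mismatch between {ref} and {mask_path}")
        labels = np.unique(md)
        if not np.isin(labels, (0, 1)).all():
            warnings.warn(f"{mask_path}: non-binary labels {labels[:10]} binarised to >0")
        mask = BinaryLesionMask((md > 0).astype(np.uint8), spacing=spacings[0],
                                affine=affines[0])
    return volume, mask


def normalize_intensity(volume: MultiChannelVolume) -> MultiChannelVolume:
    """Per-channel z-score over nonzero voxels; zero voxels stay zero."""
    out = volume.values.copy()
    for ch in range(volume.n_channels):
        data = out[ch]
        nz = data != 0
        vals = data[nz]
        if vals.size == 0 or vals.std() == 0:
            raise ValueError(f"channel {ch} is constant; cannot z-score")
        data[nz] = (vals - vals.mean()) / vals.std()
    return MultiChannelVolume(out, spacing=volume.spacing, affine=volume.affine)


# ---------------------------------------------------------------------------
# Sliding-window inference
# ---------------------------------------------------------------------------

def _gaussian_importance(patch_size: tuple[int, int, int]) -> np.ndarray:
    weight = np.ones(patch_size, dtype=np.float64)
    center = [(s - 1) / 2 for s in patch_size]
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in patch_size], indexing="ij")
    dist2 = sum(((g - c) / (s / 8.0)) ** 2 for g, c, s in zip(grids, center, patch_size))
    weight = np.exp(-0.5 * dist2)
    return np.maximum(weight, weight.max() * 1e-3)


def _window_starts(extent: int, patch: int, overlap: float) -> list[int]:
    if extent <= patch:
        return [0]
    step = max(1, int(round(patch * (1.0 - overlap))))
    starts = list(range(0, extent - patch + 1, step))
    if starts[-1] != extent - patch:
        starts.append(extent - patch)
    return starts


def sliding_window_predict(volume: MultiChannelVolume, model: SegmentationNet,
                           patch_size: tuple[int, int, int] | None = None,
                           overlap: float = 0.5) -> LesionProbabilityMap:
    """Tile the volume, predict each patch, blend with Gaussian weights.

    Volumes smaller than the patch along any axis are padded
    symmetrically and the output is cropped back.  Overlapping window
    predictions are averaged with centre-weighted Gaussian importance,
    which preserves per-voxel channel sums of 1.
    """
    if not 0.0 <= overlap <= 0.9:
        raise ValueError("overlap must be in [0, 0.9]")
    patch_size = tuple(patch_size or model.patch_size)
    values = volume.values
    spatial = values.shape[1:]
    pads = [(0, 0)]
    for ext, pt in zip(spatial, patch_size):
        short = max(0, pt - ext)
        pads.append((short // 2, short - short // 2))
    padded = np.pad(values, pads)
    pshape = padded.shape[1:]
    starts = [_window_starts(e, p, overlap) for e, p in zip(pshape, patch_size)]
    weight = _gaussian_importance(patch_size)
    accum = np.zeros((2,) + pshape, dtype=np.float64)
    norm = np.zeros(pshape, dtype=np.float64)
    model.eval()
    for sd in starts[0]:
        for sh in starts[1]:
            for sw in starts[2]:
                sl = (slice(sd, sd + patch_size[0]),
                      slice(sh, sh + patch_size[1]),
                      slice(sw, sw + patch_size[2]))
                patch = padded[(slice(None),) + sl]
                probs = model(Tensor(patch[None])).data[0]
                accum[(slice(None),) + sl] += probs * weight
                norm[sl] += weight
    model.train()
    probs = accum / norm
    crop = tuple(slice(p[0], p[0] + e) for p, e in zip(pads[1:], spatial))
    probs = probs[(slice(None),) + crop]
    return LesionProbabilityMap(probs.astype(np.float32), spacing=volume.spacing,
                                affine=volume.affine)


# ---------------------------------------------------------------------------
# Dataset handling
# ---------------------------------------------------------------------------

def split_dataset(subject_ids, proportions, seed: int = 0) -> pd.DataFrame:
    """Seeded, disjoint, exhaustive assignment of subjects to splits.

    ``proportions`` either sums to 1 (fractions) or to ``len(subject_ids)``
    (absolute counts).
    """
    from .phantom import SPLIT_NAMES, split_counts

    subject_ids = list(subject_ids)
    n = len(subject_ids)
    props = np.asarray(proportions, dtype=float)
    if n < len(props):
        raise ValueError(f"{n} subjects cannot fill {len(props)} splits")
    if np.isclose(props.sum(), 1.0):
        counts = split_counts(n, props)
    elif np.isclose(props.sum(), n):
        counts = tuple(int(round(p)) for p in props)
    else:
        raise ValueError("proportions must sum to 1 or to the number of subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.repeat(np.arange(len(counts)), counts)
    names = SPLIT_NAMES if len(counts) == 3 else tuple(
        f"split{i}" for i in range(len(counts)))
    rows = [{"subject_id": subject_ids[idx], "split": names[assignment[k]]}
            for k, idx in enumerate(order)]
    return pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)


@dataclass
class _Subject:
    sid: str
    volume: np.ndarray  # (C, D, H, W), normalised
    mask: np.ndarray    # (D, H, W)


def _load_split(dataset_dir: Path, split: str, channels) -> list[_Subject]:
    manifest = pd.read_csv(dataset_dir / "manifest.tsv", sep="\t")
    subjects = []
    for _, row in manifest[manifest.split == split].iterrows():
        sid = row.subject_id
        paths = [dataset_dir / f"{sid}_{name}.nii.gz" for name in channels]
        volume, mask = load_subject(paths, dataset_dir / f"{sid}_mask.nii.gz")
        volume = normalize_intensity(volume)
        subjects.append(_Subject(sid, volume.values, mask.values))
    return subjects


def _sample_patch(subject: _Subject, patch_size, rng: np.random.Generator,
                  lesion_centered: bool):
    spatial = subject.volume.shape[1:]
    pads = [(0, 0)]
    vol, mask = subject.volume, subject.mask
    if any(e < p for e, p in zip(spatial, patch_size)):
        for ext, pt in zip(spatial, patch_size):
            short = max(0, pt - ext)
            pads.append((short // 2, short - short // 2))
        vol = np.pad(vol, pads)
        mask = np.pad(mask, pads[1:])
        spatial = vol.shape[1:]
    lesion_idx = np.argwhere(mask > 0)
    if lesion_centered and len(lesion_idx) > 0:
        center = lesion_idx[rng.integers(len(lesion_idx))]
        starts = [int(np.clip(c - p // 2 + rng.integers(-p // 4, p // 4 + 1),
                              0, e - p))
                  for c, p, e in zip(center, patch_size, spatial)]
    else:
        starts = [int(rng.integers(0, e - p + 1)) for p, e in zip(patch_size, spatial)]
    sl = tuple(slice(s, s + p) for s, p in zip(starts, patch_size))
    return vol[(slice(None),) + sl], mask[sl]


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path: str | Path, model: SegmentationNet, config: RunConfig,
                    optimizer: Adam | None = None, step: int = 0,
                    rng: np.random.Generator | None = None,
                    extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": config.to_dict(),
        "seed": config.seed,
        "step": step,
        "variant": model.variant,
        "model_seed": model.seed,
        "patch_size": list(model.patch_size),
        "extra": extra or {},
    }
    if optimizer is not None:
        state = optimizer.state_dict()
        meta["opt_t"] = state["t"]
        for i, (m, v) in enumerate(zip(state["m"], state["v"])):
            arrays[f"opt_m/{i}"] = m
            arrays[f"opt_v/{i}"] = v
    if rng is not None:
        meta["rng_state"] = rng.bit_generator.state
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path):
    """Returns (model, config, optimizer_state | None, step, rng | None)."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode("utf-8"))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        config = RunConfig.from_dict(meta["config"])
        model = SegmentationNet(config.network, config.attention,
                                tuple(meta["patch_size"]),
                                variant=meta["variant"], seed=meta["model_seed"])
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
        model.load_state_dict(state)
        opt_state = None
        if "opt_t" in meta:
            n = len([k for k in data.files if k.startswith("opt_m/")])
            opt_state = {
                "t": meta["opt_t"],
                "m": [data[f"opt_m/{i}"] for i in range(n)],
                "v": [data[f"opt_v/{i}"] for i in range(n)],
            }
        rng = None
        if "rng_state" in meta:
            rng = np.random.default_rng(0)
            rng.bit_generator.state = meta["rng_state"]
    return model, config, opt_state, meta["step"], rng


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    history: pd.DataFrame
    best_checkpoint: Path
    last_checkpoint: Path
    best_val_dc: float
    model: SegmentationNet = field(repr=False, default=None)


def _validate(model: SegmentationNet, subjects, config: RunConfig) -> float:
    if not subjects:
        return float("nan")
    pairs = []
    for sub in subjects:
        vol = MultiChannelVolume(sub.volume)
        pred = sliding_window_predict(vol, model, config.patch_size, config.overlap)
        pairs.append((pred.binarize(config.threshold).values, sub.mask))
    cm = cohort_metrics(pairs, connectivity=config.connectivity)
    return cm.DC_mean


def train(config: RunConfig, dataset_dir: str | Path, out_dir: str | Path,
          resume_from: str | Path | None = None) -> TrainResult:
    """Seeded, resumable training on a cohort directory.

    Each step draws ``batch_size`` patches; a configured fraction is
    centred on a lesion voxel (with jitter) to counter the extreme
    foreground/background imbalance.  Every epoch logs the mean hybrid
    loss and its Dice / cross-entropy parts plus the validation Dice;
    the best checkpoint by validation Dice is kept alongside the last.
    """
    dataset_dir, out_dir = Path(dataset_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "train.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _train_inner(config, dataset_dir, out_dir, resume_from)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _train_inner(config, dataset_dir, out_dir, resume_from):
    train_subjects = _load_split(dataset_dir, "train", config.channel_names)
    val_subjects = _load_split(dataset_dir, "val", config.channel_names)
    if not train_subjects:
        raise ValueError(f"no training subjects found in {dataset_dir}")

    total_steps = config.epochs * config.steps_per_epoch
    start_step = 0
    if resume_from is not None:
        # the caller's config drives the run (so epochs can be extended);
        # weights, optimiser moments, step count and RNG come from the file
        model, _, opt_state, start_step, rng = load_checkpoint(resume_from)
        optimizer = Adam(model.parameters(), lr=config.lr,
                         total_steps=total_steps,
                         cosine=config.lr_schedule == "cosine",
                         max_grad_norm=config.max_grad_norm)
        if opt_state is not None:
            optimizer.load_state_dict(opt_state)
    else:
        model = SegmentationNet(config.network, config.attention,
                                config.patch_size, variant=config.variant,
                                seed=config.seed)
        optimizer = Adam(model.parameters(), lr=config.lr,
                         total_steps=total_steps,
                         cosine=config.lr_schedule == "cosine",
                         max_grad_norm=config.max_grad_norm)
        rng = np.random.default_rng(config.seed + 1)

    logger.info("training start: seed=%d variant=%s patch=%s subjects=%d",
                config.seed, config.variant, config.patch_size, len(train_subjects))
    config.to_yaml(out_dir / "config.yaml")

    history_rows = []
    best_dc = -np.inf
    best_path = out_dir / "checkpoint_best.npz"
    last_path = out_dir / "checkpoint_last.npz"
    step = start_step
    start_epoch = start_step // config.steps_per_epoch
    for epoch in range(start_epoch, config.epochs):
        epoch_l, epoch_dc_loss, epoch_ce = [], [], []
        for _ in range(config.steps_per_epoch):
            patches, masks = [], []
            for b in range(config.batch_size):
                lesion_centered = rng.random() < config.lesion_patch_rate
                sub = train_subjects[rng.integers(len(train_subjects))]
                pv, pm = _sample_patch(sub, config.patch_size, rng, lesion_centered)
                patches.append(pv)
                masks.append(pm)
            x = Tensor(np.stack(patches))
            g = np.stack(masks).astype(np.float32)
            probs = model(x)
            loss, l_dc, l_ce = _batch_loss(probs, g, config)
            model.zero_grad()
            loss.backward()
            optimizer.step()
            step += 1
            history_rows.append({"step": step, "epoch": epoch + 1,
                                 "L": loss.item(), "L_dc": l_dc.item(),
                                 "L_ce": l_ce.item(), "lr": optimizer.current_lr()})
        val_dc = _validate(model, val_subjects, config)
        mean_l = float(np.mean([r["L"] for r in history_rows[-config.steps_per_epoch:]]))
        logger.info("epoch %d: L=%.4f val_DC=%.4f", epoch + 1, mean_l, val_dc)
        save_checkpoint(last_path, model, config, optimizer, step=step, rng=rng,
                        extra={"val_dc": None if np.isnan(val_dc) else val_dc})
        if not np.isnan(val_dc) and val_dc > best_dc:
            best_dc = val_dc
            save_checkpoint(best_path, model, config, optimizer, step=step,
                            rng=rng, extra={"val_dc": val_dc})
    if not best_path.exists():
        save_checkpoint(best_path, model, config, optimizer, step=step, rng=rng)
    history = pd.DataFrame(history_rows)
    history.to_csv(out_dir / "history.csv", index=False)
    return TrainResult(history=history, best_checkpoint=best_path,
                       last_checkpoint=last_path,
                       best_val_dc=float(best_dc) if best_dc > -np.inf else float("nan"),
                       model=model)


def _batch_loss(probs: Tensor, g: np.ndarray, config: RunConfig):
    """Hybrid loss on the foreground channel, averaged over the batch."""
    n = probs.shape[0]
    total = None
    total_dc = None
    total_ce = None
    for b in range(n):
        # slice the foreground channel of sample b via reshape bookkeeping
        p_fore = _select_foreground(probs, b)
        l, l_dc, l_ce = hybrid_loss(p_fore, g[b], config.loss, return_parts=True)
        total = l if total is None else total + l
        total_dc = l_dc if total_dc is None else total_dc + l_dc
        total_ce = l_ce if total_ce is None else total_ce + l_ce
    inv = 1.0 / n
    return total * inv, total_dc * inv, total_ce * inv


def _select_foreground(probs: Tensor, b: int) -> Tensor:
    """Foreground-channel slice probs[b, 1] as a differentiable Tensor."""
    n, _, d, h, w = probs.shape
    data = probs.data[b, 1]

    def backward(grad):
        if probs.requires_grad:
            full = np.zeros_like(probs.data)
            full[b, 1] = grad
            probs._accumulate(full)

    return Tensor._make(data, (probs,), backward)
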