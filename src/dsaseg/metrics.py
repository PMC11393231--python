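"""Subject-level and voxel-level lesion evaluation.

Subject level: a lesion is *detected* when prediction and ground truth
overlap in at least one voxel; detection sensitivity is
sSens = TPs / (TPs + FNs) over lesional subjects.  False-positive
clusters (FPC) are predicted connected components containing no ground-
truth voxel; nFPC is their per-subject mean.

Voxel level: Prec = TP/(TP+FP), Sens = TP/(TP+FN) and the Dice
coefficient DC = 2TP/(2TP+FN+FP), reported as cohort mean +/- sd
(population sd).  Ratios with a zero denominator are undefined for that
subject and recorded as missing, not zero.

Connected components are delineated with 6-, 18- or 26-connectivity
(default 26, the standard for 3D lesion cluster counting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import BinaryLesionMask, ShapeError

__all__ = [
    "ClusterSet",
    "MetricCounts",
    "CohortMetrics",
    "connected_clusters",
    "subject_detected",
    "count_false_positive_clusters",
    "subject_counts",
    "cohort_metrics",
    "evaluate_directories",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def _as_binary(mask) -> np.ndarray:
    if isinstance(mask, BinaryLesionMask):
        return mask.values
    arr = np.asarray(mask)
    if arr.ndim != 3:
        raise ShapeError(f"expected a 3D mask, got shape {arr.shape}")
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError("mask is not binary")
    return arr.astype(np.uint8)


@dataclass
class ClusterSet:
    """Connected components of a binary mask, labelled in scan order."""

    labels: np.ndarray
    n_clusters: int
    sizes: np.ndarray
    overlaps_gt: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_clusters != len(self.sizes):
            raise ValueError("sizes length does not match cluster count")


@dataclass
class MetricCounts:
    """Voxel (TP/FP/FN) and subject (TPs/FNs) tallies plus FPC."""

    TP: int = 0
    FP: int = 0
    FN: int = 0
    TPs: int = 0
    FNs: int = 0
    FPC: int = 0


@dataclass
class CohortMetrics:
    """Cohort summary: sSens, nFPC and voxel metrics as mean +/- sd."""

    sSens: float
    nFPC_mean: float
    nFPC_sd: float
    Sens_mean: float
    Sens_sd: float
    Prec_mean: float
    Prec_sd: float
    DC_mean: float
    DC_sd: float
    per_subject: pd.DataFrame = field(repr=False, default=None)


def connected_clusters(mask, connectivity: int = 26,
                       gt=None) -> ClusterSet:
    """Label maximal connected components of a binary mask."""
    arr = _as_binary(mask)
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(arr, structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    overlaps = None
    if gt is not None:
        gt_arr = _as_binary(gt)
        overlaps = np.zeros(n, dtype=bool)
        hit = np.unique(labels[gt_arr.astype(bool)])
        overlaps[hit[hit > 0] - 1] = True
    return ClusterSet(labels=labels, n_clusters=int(n), sizes=sizes,
                      overlaps_gt=overlaps)


def subject_detected(pred, gt) -> bool:
    """True iff prediction and ground truth share at least one voxel."""
    p = _as_binary(pred)
    g = _as_binary(gt)
    if p.shape != g.shape:
        raise ShapeError(f"prediction shape {p.shape} != ground-truth shape {g.shape}")
    return bool((p & g).any())


def count_false_positive_clusters(pred, gt, connectivity: int = 26,
                                  min_cluster_size: int = 0) -> int:
    """Number of predicted clusters with no ground-truth lesion voxel."""
    clusters = connected_clusters(pred, connectivity=connectivity, gt=gt)
    if clusters.n_clusters == 0:
        return 0
    keep = clusters.sizes >= min_cluster_size
    return int((~clusters.overlaps_gt & keep).sum())


def subject_counts(pred, gt, connectivity: int = 26) -> MetricCounts:
    """Voxel and cluster tallies for one subject."""
    p = _as_binary(pred).astype(bool)
    g = _as_binary(gt).astype(bool)
    if p.shape != g.shape:
        raise ShapeError(f"prediction shape {p.shape} != ground-truth shape {g.shape}")
    tp = int((p & g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    detected = tp >= 1
    counts = MetricCounts(
        TP=tp, FP=fp, FN=fn,
        TPs=int(g.any() and detected),
        FNs=int(g.any() and not detected),
        FPC=count_false_positive_clusters(p.astype(np.uint8), g.astype(np.uint8),
                                          connectivity=connectivity),
    )
    return counts


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def cohort_metrics(pairs, connectivity: int = 26,
                   subject_ids=None) -> CohortMetrics:
    """Aggregate subject-level and voxel-level metrics over a cohort.

    ``pairs`` is a sequence of (pred, gt) binary masks.  Subjects with
    empty ground truth contribute to nFPC but are excluded from the
    sSens denominator (they have no lesion to detect); voxel ratios
    with zero denominator are recorded as missing and skipped in means.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cohort is empty")
    if subject_ids is None:
        subject_ids = [f"subject-{i:03d}" for i in range(len(pairs))]
    rows = []
    for sid, (pred, gt) in zip(subject_ids, pairs):
        c = subject_counts(pred, gt, connectivity=connectivity)
        rows.append({
            "subject": sid,
            "detected": int(c.TPs > 0),
            "has_lesion": int(_as_binary(gt).any()),
            "fpc": c.FPC,
            "tp": c.TP, "fp": c.FP, "fn": c.FN,
            "sens": _ratio(c.TP, c.TP + c.FN),
            "prec": _ratio(c.TP, c.TP + c.FP),
            "dc": _ratio(2 * c.TP, 2 * c.TP + c.FN + c.FP),
        })
    df = pd.DataFrame(rows)
    lesional = df[df.has_lesion == 1]
    tps = int(lesional.detected.sum())
    fns = int((1 - lesional.detected).sum())
    s_sens = _ratio(tps, tps + fns)

    def _mean_sd(col):
        vals = df[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=0))

    nfpc = _mean_sd("fpc")
    sens = _mean_sd("sens")
    prec = _mean_sd("prec")
    dc = _mean_sd("dc")
    return CohortMetrics(
        sSens=s_sens,
        nFPC_mean=nfpc[0], nFPC_sd=nfpc[1],
        Sens_mean=sens[0], Sens_sd=sens[1],
        Prec_mean=prec[0], Prec_sd=prec[1],
        DC_mean=dc[0], DC_sd=dc[1],
        per_subject=df,
    )


def evaluate_directories(pred_dir: str | Path, gt_dir: str | Path,
                         out_dir: str | Path, connectivity: int = 26) -> CohortMetrics:
    """Match prediction and ground-truth NIfTI masks by filename stem and
    write per-subject and cohort-summary CSV reports."""
    from .volumes import load_nifti_channel

    pred_dir, gt_dir, out_dir = Path(pred_dir), Path(gt_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stem(p: Path) -> str:
        name = p.name
        for suffix in (".nii.gz", ".nii"):
            if name.endswith(suffix):
                return name[: -len(suffix)]
        return p.stem

    preds = {stem(p): p for p in sorted(pred_dir.glob("*.nii*"))}
    gts = {stem(p): p for p in sorted(gt_dir.glob("*.nii*"))}
    common = sorted(set(preds) & set(gts))
    if not common:
        raise FileNotFoundError(
            f"no matching mask stems between {pred_dir} and {gt_dir}"
        )
    pairs = []
    for sid in common:
        p, _, _ = load_nifti_channel(preds[sid])
        g, _, _ = load_nifti_channel(gts[sid])
        pairs.append(((p > 0).astype(np.uint8), (g > 0).astype(np.uint8)))
    metrics = cohort_metrics(pairs, connectivity=connectivity, subject_ids=common)
    per = metrics.per_subject[
        ["subject", "detected", "fpc", "tp", "fp", "fn", "sens", "prec", "dc"]
    ]
    per.to_csv(out_dir / "per_subject.csv", index=False)
    summary = pd.DataFrame([{
        "sSens": metrics.sSens,
        "nFPC_mean": metrics.nFPC_mean, "nFPC_sd": metrics.nFPC_sd,
        "Sens_mean": metrics.Sens_mean, "Sens_sd": metrics.Sens_sd,
        "Prec_mean": metrics.Prec_mean, "Prec_sd": metrics.Prec_sd,
        "DC_mean": metrics.DC_mean, "DC_sd": metrics.DC_sd,
    }])
    summary.to_csv(out_dir / "cohort_summary.csv", index=False)
    return metrics
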