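"""Training objective and evaluation suite.

Objective: L_all = alpha * L_bce + beta * L_dice with alpha=0.5, beta=1.0 —
mean binary cross-entropy over voxels and channels plus a generalized Dice
loss whose per-channel weights w_c = 1 / (sum g_c)^2 re-balance the three
nested tumor regions (lesions occupy a tiny fraction of the brain, so an
unweighted objective is dominated by background).

Evaluation: per-region Dice = 2TP/(2TP+FN+FP), sensitivity = TP/(TP+FN),
symmetric (optionally percentile) Hausdorff distance between mask surfaces,
and across-case summary statistics (sample SD, median, quartiles).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import autodiff as ad
from .autodiff import Tensor

REGION_NAMES = ("wt", "tc", "et")

_CLIP = 1e-7
DICE_SMOOTH = 1e-5


class MetricError(ValueError):
    pass


@dataclass
class LossWeights:
    """Weights of the cross-entropy (alpha) and Dice (beta) terms."""

    alpha: float = 0.5
    beta: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class ContingencyCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise MetricError("contingency counts must be non-negative")


# ---------------------------------------------------------------------------
# losses (autodiff-aware)
# ---------------------------------------------------------------------------

def bce_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over voxels and channels; predictions are
    clipped away from {0,1} for finiteness."""
    p = ad.clip(pred, _CLIP, 1.0 - _CLIP)
    t = np.asarray(target, dtype=np.float32)
    ll = ad.add(ad.mul(Tensor(t), ad.log(p)),
                ad.mul(Tensor(1.0 - t), ad.log(ad.add(ad.mul(p, -1.0), 1.0))))
    return ad.mul(ad.tmean(ll), -1.0)


def generalized_dice_loss(pred: Tensor, target: np.ndarray,
                          weighting: str = "generalized") -> Tensor:
    """1 - generalized Dice overlap.

    With ``weighting='generalized'`` channels are weighted by
    w_c = 1/(sum g_c)^2 (volume re-balancing); ``'mean'`` gives the plain
    per-channel mean soft Dice.  A smoothing constant keeps empty channels
    finite.  Value lies in [0, 1].
    """
    t = np.asarray(target, dtype=np.float32)
    # channel sums pool over batch and space (conventional formulation)
    ch_axes = (0,) + tuple(range(2, pred.ndim))
    inter = ad.tsum(ad.mul(pred, Tensor(t)), axis=ch_axes)  # (C,)
    psum = ad.tsum(pred, axis=ch_axes)
    gsum = t.sum(axis=ch_axes, dtype=np.float64)
    if weighting == "generalized":
        w = 1.0 / (gsum ** 2 + DICE_SMOOTH)
    elif weighting == "mean":
        w = np.ones_like(gsum)
    else:
        raise ValueError(f"unknown dice weighting {weighting!r}")
    w = w.astype(np.float32)
    num = ad.add(ad.mul(ad.tsum(ad.mul(inter, Tensor(w))), 2.0), DICE_SMOOTH)
    den = ad.add(ad.tsum(ad.mul(ad.add(psum, Tensor(gsum.astype(np.float32))),
                                Tensor(w))), DICE_SMOOTH)
    return ad.add(ad.mul(ad.div(num, den), -1.0), 1.0)


def mixed_loss(pred, target, weights: LossWeights | None = None,
               dice_weighting: str = "generalized") -> Tensor:
    """L_all = alpha * L_bce + beta * L_dice on (N, 3, *spatial) inputs."""
    weights = weights or LossWeights()
    pred_t = ad.as_tensor(pred)
    target = np.asarray(target)
    if pred_t.shape != target.shape:
        raise MetricError(
            f"pred shape {pred_t.shape} != target shape {target.shape}")
    loss = ad.mul(generalized_dice_loss(pred_t, target, dice_weighting),
                  weights.beta)
    if weights.alpha:
        loss = ad.add(loss, ad.mul(bce_loss(pred_t, target), weights.alpha))
    return loss


# ---------------------------------------------------------------------------
# hard-mask metrics
# ---------------------------------------------------------------------------

def counts_from_masks(pred: np.ndarray, ref: np.ndarray) -> ContingencyCounts:
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise MetricError(f"shape mismatch {pred.shape} vs {ref.shape}")
    for name, m in (("pred", pred), ("ref", ref)):
        if m.dtype != bool and not np.isin(m, (0, 1)).all():
            raise MetricError(f"{name} mask is not binary")
    p = pred.astype(bool)
    r = ref.astype(bool)
    return ContingencyCounts(
        tp=int(np.count_nonzero(p & r)),
        fp=int(np.count_nonzero(p & ~r)),
        fn=int(np.count_nonzero(~p & r)),
    )


def dice_coefficient(counts: ContingencyCounts) -> float:
    """2TP / (2TP + FN + FP); 1.0 when both masks are empty."""
    denom = 2 * counts.tp + counts.fn + counts.fp
    if denom == 0:
        return 1.0
    return 2.0 * counts.tp / denom


def sensitivity(counts: ContingencyCounts) -> float:
    """TP / (TP + FN); an empty reference returns 1.0 with a warning."""
    denom = counts.tp + counts.fn
    if denom == 0:
        warnings.warn("sensitivity: empty reference mask", stacklevel=2)
        return 1.0
    return counts.tp / denom


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates of voxels on the mask boundary (mask minus erosion)."""
    mask = mask.astype(bool)
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff_distance(mask_a: np.ndarray, mask_b: np.ndarray,
                       spacing=None, percentile: float | None = None
                       ) -> float:
    """Symmetric Hausdorff distance between the surfaces of two masks.

    Euclidean metric in voxel units scaled by `spacing` (per-axis).  With
    ``percentile`` (e.g. 95) the robust percentile variant is returned
    instead of the maximum.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise MetricError(f"shape mismatch {a.shape} vs {b.shape}")
    for name, m in (("first", a), ("second", b)):
        if not m.any():
            raise MetricError(f"hausdorff: {name} mask is empty")
    spacing = np.ones(a.ndim) if spacing is None else np.asarray(spacing,
                                                                 dtype=float)
    pa = _surface_voxels(a) * spacing
    pb = _surface_voxels(b) * spacing
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    if percentile is None:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile),
                     np.percentile(d_ba, percentile)))


def soft_dice(pred: np.ndarray, ref: np.ndarray) -> float:
    """Plain (unweighted, per-pair) soft Dice overlap of two arrays."""
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    num = 2.0 * (pred * ref).sum() + DICE_SMOOTH
    den = pred.sum() + ref.sum() + DICE_SMOOTH
    return float(num / den)


# ---------------------------------------------------------------------------
# summaries / reports
# ---------------------------------------------------------------------------

def summarize(scores) -> dict[str, float]:
    """Sample SD, median and quartiles (linear-interpolation convention)."""
    scores = np.asarray(list(scores), dtype=np.float64)
    if scores.size == 0:
        raise MetricError("cannot summarize an empty score list")
    sd = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
    q25, med, q75 = np.quantile(scores, [0.25, 0.5, 0.75],
                                method="linear")
    return {"sd": sd, "median": float(med),
            "q25": float(q25), "q75": float(q75)}


def region_metrics(pred, ref, spacing=None,
                   hd_percentile: float | None = None) -> dict[str, dict]:
    """Dice/SEN/HD for each nested region of a predicted vs reference
    RegionMask.  HD on an empty mask is recorded as NaN (excluded from
    aggregation with a logged count)."""
    out = {}
    for name in REGION_NAMES:
        p = getattr(pred, name)
        r = getattr(ref, name)
        c = counts_from_masks(p, r)
        if not p.any() and r.any():
            dice, sen = 0.0, 0.0
        elif not r.any() and not p.any():
            dice, sen = 1.0, 1.0
        else:
            dice = dice_coefficient(c)
            sen = sensitivity(c)
        try:
            hd = hausdorff_distance(p, r, spacing=spacing,
                                    percentile=hd_percentile)
        except MetricError:
            hd = float("nan")
        out[name] = {"dice": dice, "sensitivity": sen, "hausdorff": hd}
    return out


def metric_report(per_case: dict[str, dict[str, dict]]) -> dict:
    """Aggregate per-case region metrics into a Table-2/3-style report.

    `per_case` maps case_id -> region -> {dice, sensitivity, hausdorff}.
    Returns mean/summary stats per region and the number of cases excluded
    from HD aggregation because a mask was empty.
    """
    if not per_case:
        raise MetricError("no cases to report")
    report: dict = {"n_cases": len(per_case), "regions": {}}
    for region in REGION_NAMES:
        entry: dict = {}
        for metric in ("dice", "sensitivity", "hausdorff"):
            vals = np.array([per_case[cid][region][metric]
                             for cid in per_case], dtype=float)
            if metric == "hausdorff":
                finite = vals[np.isfinite(vals)]
                entry["hd_excluded"] = int(vals.size - finite.size)
                vals = finite
            if vals.size == 0:
                entry[metric] = {"mean": float("nan")}
                continue
            stats = summarize(vals)
            stats["mean"] = float(vals.mean())
            entry[metric] = stats
        report["regions"][region] = entry
    return report


def report_to_table(report: dict) -> dict[str, float]:
    """Flatten a report to the conventional field names
    (Dice_WT, Sen_ET, HD-TC, ...)."""
    flat = {}
    key_map = {"dice": "Dice", "sensitivity": "Sen", "hausdorff": "HD"}
    for region in REGION_NAMES:
        up = region.upper()
        for metric, label in key_map.items():
            stats = report["regions"][region][metric]
            if "mean" in stats and np.isfinite(stats["mean"]):
                sep = "-" if label == "HD" else "_"
                flat[f"{label}{sep}{up}"] = stats["mean"]
    return flat
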