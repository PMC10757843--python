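"""Dice metrics at slice and volume level.

Two volume aggregates are reported side by side because they answer
different questions: the average of per-slice Dice values over-weights
slices with little foreground, while the 3D Dice (all voxels pooled) tells
you what fraction of the structure was captured. The 3D value is almost
always the higher of the two on sparse structures.
"""

from __future__ import annotations

import numpy as np

from .volume_io import DiceReport, MaskVolume


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.all(np.isin(np.unique(arr), [0, 1])):
        raise ValueError(f"{name} must be binary")
    return arr.astype(np.int64)


def dice_2d(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap of two binary slices; both-empty counts as perfect (1.0)."""
    pred = _check_binary(pred, "pred")
    gt = _check_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError("pred and gt shapes must match")
    denom = pred.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, gt).sum() / denom)


def _labels(v) -> np.ndarray:
    return v.labels if isinstance(v, MaskVolume) else np.asarray(v)


def average_dice(pred, gt, eval_slices) -> float:
    """Arithmetic mean of per-slice Dice over ``eval_slices``."""
    eval_slices = list(eval_slices)
    if not eval_slices:
        raise ValueError("eval_slices must be non-empty")
    p, g = _labels(pred), _labels(gt)
    return float(np.mean([dice_2d(p[z], g[z]) for z in eval_slices]))


def dice_3d(pred, gt, eval_slices) -> float:
    """Single Dice over all voxels of ``eval_slices`` pooled together."""
    eval_slices = list(eval_slices)
    if not eval_slices:
        raise ValueError("eval_slices must be non-empty")
    p, g = _labels(pred), _labels(gt)
    return dice_2d(p[eval_slices].reshape(-1), g[eval_slices].reshape(-1))


def labeled_fraction(n_labeled: int, n_total: int) -> float:
    """Annotated share of the stack as a percentage, rounded to one decimal."""
    if n_total < 1 or not (1 <= n_labeled <= n_total):
        raise ValueError("need 1 <= n_labeled <= n_total")
    return round(100.0 * n_labeled / n_total, 1)


def evaluate_volume(pred, gt, eval_slices, structure_name: str = "") -> DiceReport:
    """Per-slice Dice plus both volume aggregates over the evaluation slices."""
    eval_slices = sorted(eval_slices)
    p, g = _labels(pred), _labels(gt)
    per_slice = [(int(z), dice_2d(p[z], g[z])) for z in eval_slices]
    report = DiceReport(
        per_slice=per_slice,
        average_dice=float(np.mean([d for _, d in per_slice])),
        dice_3d=dice_3d(pred, gt, eval_slices),
        structure_name=structure_name,
    )
    report.validate()
    return report
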