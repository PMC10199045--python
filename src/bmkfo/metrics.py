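"""Confusion-count segmentation evaluation: precision, recall, Dice, and
per-episode metric reports (with AHD reported as an evaluation metric).

Conventions for degenerate cases: if ground truth and prediction are both
empty, precision = recall = Dice = 1 (the prediction is vacuously perfect);
if exactly one is empty, all three are 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hausdorff_losses import ahd, mask_to_pointset, validate_mask

__all__ = [
    "ConfusionCounts",
    "confusion",
    "precision",
    "recall",
    "dice",
    "MetricReport",
    "evaluate_pair",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between a predicted and true binary mask."""
    pred = validate_mask(pred, "pred")
    gt = validate_mask(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"pred shape {pred.shape} != gt shape {gt.shape}")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int((p & g).sum()),
        fp=int((p & ~g).sum()),
        fn=int((~p & g).sum()),
        tn=int((~p & ~g).sum()),
    )


def _degenerate(c: ConfusionCounts) -> float | None:
    n_pred = c.tp + c.fp
    n_gt = c.tp + c.fn
    if n_pred == 0 and n_gt == 0:
        return 1.0
    return None


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP) — purity of the positive predictions."""
    both_empty = _degenerate(c)
    if both_empty is not None:
        return both_empty
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN) — completeness with respect to the ground truth."""
    both_empty = _degenerate(c)
    if both_empty is not None:
        return both_empty
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def dice(c: ConfusionCounts) -> float:
    """2TP / (2TP + FP + FN) — the harmonic mean of precision and recall."""
    both_empty = _degenerate(c)
    if both_empty is not None:
        return both_empty
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom else 0.0


def evaluate_pair(
    pred: np.ndarray,
    gt: np.ndarray,
    metric: str = "chebyshev",
    mode: str = "foreground",
) -> dict:
    """Dice/precision/recall plus exact set AHD for one prediction.

    AHD is NaN when either mask is empty (the set distance is undefined).
    """
    c = confusion(pred, gt)
    pts_p = mask_to_pointset(pred, mode)
    pts_g = mask_to_pointset(gt, mode)
    if len(pts_p) and len(pts_g):
        a = ahd(pts_p, pts_g, metric)
    else:
        a = float("nan")
    return {
        "dice": dice(c),
        "precision": precision(c),
        "recall": recall(c),
        "ahd": a,
    }


class MetricReport:
    """Per-episode metric rows plus aggregate means.

    Rows carry ``episode_id``, ``class_id``, ``dice``, ``precision``,
    ``recall`` and ``ahd``; the aggregate is the arithmetic mean over episodes
    (AHD mean ignores NaN rows from empty masks).
    """

    COLUMNS = ["episode_id", "class_id", "dice", "precision", "recall", "ahd"]

    def __init__(self):
        self.rows: list[dict] = []

    def add(self, episode_id, class_id, metrics: dict) -> None:
        self.rows.append({"episode_id": episode_id, "class_id": class_id, **metrics})

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.COLUMNS)

    def aggregate(self) -> dict:
        df = self.frame()
        if df.empty:
            return {k: float("nan") for k in ("dice", "precision", "recall", "ahd")}
        return {
            "dice": float(df["dice"].mean()),
            "precision": float(df["precision"].mean()),
            "recall": float(df["recall"].mean()),
            "ahd": float(df["ahd"].mean(skipna=True)),
        }

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        payload = {"per_episode": self.rows, "aggregate": self.aggregate()}
        Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))

    def table(self) -> str:
        """Aggregate table with rates as percentages (two decimals), with a
        trailing Mean column over Dice/precision/recall."""
        agg = self.aggregate()
        pct = [agg["dice"] * 100, agg["precision"] * 100, agg["recall"] * 100]
        mean = float(np.mean(pct))
        header = f"{'Dice score':>10} | {'Precision':>9} | {'Recall':>7} | {'AHD':>7} | {'Mean':>6}"
        row = (
            f"{pct[0]:10.2f} | {pct[1]:9.2f} | {pct[2]:7.2f} | "
            f"{agg['ahd']:7.3f} | {mean:6.2f}"
        )
        return header + "\n" + row
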