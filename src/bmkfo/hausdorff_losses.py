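"""Hausdorff and average-Hausdorff set distances, a differentiable surrogate,
cross-entropy, and the combined segmentation objective.

The exact distances operate on finite point sets of pixel coordinates
``(row, col)`` under one of three grid metrics:

* ``manhattan`` — L1, sum of absolute coordinate differences;
* ``euclidean`` — L2;
* ``chebyshev`` — L∞, maximum absolute coordinate difference (the default:
  on a grid it measures distance equally in all eight directions).

The classical (symmetric) Hausdorff distance takes the worst best-match over
both directions and is therefore dominated by single outlier points.  The
average Hausdorff distance (AHD)

    AHD(X, Y) = ( mean_{x∈X} min_{y∈Y} d(x,y) + mean_{y∈Y} min_{x∈X} d(x,y) ) / 2

averages the per-point minimum distances in both directions, which makes it
robust to outliers and sensitive to the overall shape mismatch rather than
only to the intersection area — the property that motivates using it as a
segmentation training signal alongside cross-entropy.

Exact set distances involve a min/argmin over a thresholded point set and are
not differentiable in the predicted probabilities, so training uses
:func:`soft_ahd_loss`, a surrogate built from distance transforms: the first
(prediction→truth) term is a probability-weighted mean of the ground-truth
distance map and carries the gradient; the reverse term uses the distance map
of the thresholded prediction and is treated as a constant.  On a binary
prediction the surrogate coincides exactly with the set-based AHD in
foreground mode.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import distance_transform_cdt, distance_transform_edt
from scipy.spatial.distance import cdist

from .autodiff import Tensor, log as t_log, tsum

__all__ = [
    "METRICS",
    "point_distance",
    "directed_hd",
    "hd_loss",
    "ahd",
    "mask_to_pointset",
    "distance_transform",
    "soft_ahd_loss",
    "cross_entropy",
    "total_loss",
    "validate_mask",
]

logger = logging.getLogger(__name__)

METRICS = ("manhattan", "euclidean", "chebyshev")

_CDIST_NAME = {
    "manhattan": "cityblock",
    "euclidean": "euclidean",
    "chebyshev": "chebyshev",
}

#: value returned (with zero gradient) when the predicted foreground mass is zero
DEGENERATE_LOSS = 1.0e3

#: probability floor for cross-entropy
CE_EPS = 1.0e-7


def _check_metric(metric: str) -> None:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; valid metrics are {METRICS}")


def validate_mask(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    """Check that an array is a rectangular binary {0,1} grid."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError(f"{name} must be a non-empty 2-D grid")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0 and 1")
    return mask.astype(np.uint8)


def point_distance(x, y, metric: str = "chebyshev") -> float:
    """Distance between two grid coordinates under the chosen metric."""
    _check_metric(metric)
    dx = np.abs(np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64))
    if metric == "manhattan":
        return float(dx.sum())
    if metric == "euclidean":
        return float(np.sqrt((dx**2).sum()))
    return float(dx.max())


def _as_points(X) -> np.ndarray:
    pts = np.asarray(list(X) if not isinstance(X, np.ndarray) else X, dtype=np.float64)
    if pts.size == 0:
        raise ValueError("empty point set: Hausdorff distances are undefined")
    return pts.reshape(len(pts), -1)


def _min_dists(X, Y, metric: str) -> np.ndarray:
    """Per-point minimum distance from each x in X to the set Y."""
    return cdist(_as_points(X), _as_points(Y), metric=_CDIST_NAME[metric]).min(axis=1)


def directed_hd(X, Y, metric: str = "chebyshev") -> float:
    """Directed Hausdorff distance: max over X of the min distance to Y."""
    _check_metric(metric)
    return float(_min_dists(X, Y, metric).max())


def hd_loss(pred, gt, metric: str = "chebyshev") -> float:
    """Symmetric Hausdorff distance: max of the two directed distances."""
    _check_metric(metric)
    return max(directed_hd(pred, gt, metric), directed_hd(gt, pred, metric))


def ahd(X, Y, metric: str = "chebyshev") -> float:
    """Average Hausdorff distance between two point sets.

    Mean of the per-point minimum distances from X to Y and from Y to X,
    averaged over both directions.  Symmetric, zero iff the sets are equal,
    and never larger than the classical Hausdorff distance.
    """
    _check_metric(metric)
    return 0.5 * (
        float(_min_dists(X, Y, metric).mean()) + float(_min_dists(Y, X, metric).mean())
    )


def mask_to_pointset(mask: np.ndarray, mode: str = "foreground") -> np.ndarray:
    """Coordinates of a mask's foreground or boundary pixels.

    ``boundary`` keeps foreground pixels with at least one background
    4-neighbour; the image border counts as background.  An all-zero mask
    yields an empty (0, 2) array — callers decide how to handle it.
    """
    mask = validate_mask(mask)
    if mode == "foreground":
        keep = mask.astype(bool)
    elif mode == "boundary":
        padded = np.pad(mask, 1, constant_values=0)
        interior = (
            (padded[:-2, 1:-1] == 1)
            & (padded[2:, 1:-1] == 1)
            & (padded[1:-1, :-2] == 1)
            & (padded[1:-1, 2:] == 1)
        )
        keep = mask.astype(bool) & ~interior
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'foreground' or 'boundary'")
    return np.argwhere(keep)


def distance_transform(
    gt: np.ndarray, metric: str = "chebyshev", mode: str = "foreground"
) -> np.ndarray:
    """Grid of exact minimum distances to the mask's point set.

    Each cell holds the minimum :func:`point_distance` to the set extracted by
    :func:`mask_to_pointset`; cells inside the set hold zero.
    """
    _check_metric(metric)
    gt = validate_mask(gt, "gt")
    pts = mask_to_pointset(gt, mode)
    if len(pts) == 0:
        raise ValueError("empty point set: distance transform is undefined")
    member = np.zeros_like(gt, dtype=bool)
    member[pts[:, 0], pts[:, 1]] = True
    # scipy transforms measure distance to the nearest zero of the input
    inv = (~member).astype(np.uint8)
    if metric == "euclidean":
        return distance_transform_edt(inv).astype(np.float64)
    cdt_metric = "taxicab" if metric == "manhattan" else "chessboard"
    return distance_transform_cdt(inv, metric=cdt_metric).astype(np.float64)


def soft_ahd_loss(
    pred: Tensor | np.ndarray,
    gt: np.ndarray,
    metric: str = "chebyshev",
    threshold: float = 0.5,
    mode: str = "foreground",
) -> Tensor:
    """Differentiable average-Hausdorff surrogate.

    ``(⟨p, D_gt⟩/Σp + ⟨g, D_pred⟩/Σg) / 2`` where ``D_gt`` is the distance
    transform of the ground truth, ``D_pred`` the distance transform of the
    prediction thresholded at ``threshold``, ``p`` the probability grid and
    ``g`` the ground-truth grid.  Gradients flow through ``p`` in the first
    term only.  If the prediction has no mass (Σp = 0) a large constant with
    zero gradient is returned and a degenerate-prediction warning is logged.
    """
    _check_metric(metric)
    gt = validate_mask(gt, "gt")
    if not gt.any():
        raise ValueError("empty ground-truth foreground: AHD surrogate undefined")
    if not isinstance(pred, Tensor):
        pred = Tensor(pred)
    if pred.data.shape != gt.shape:
        raise ValueError(f"pred shape {pred.data.shape} != gt shape {gt.shape}")

    p_sum = float(pred.data.sum())
    if p_sum <= 0.0:
        logger.warning("degenerate prediction: zero foreground mass in soft AHD loss")
        return Tensor(DEGENERATE_LOSS)

    d_gt = Tensor(distance_transform(gt, metric, mode))
    fwd = tsum(pred * d_gt) / tsum(pred)

    pred_bin = (pred.data >= threshold).astype(np.uint8)
    if pred_bin.any():
        d_pred = distance_transform(pred_bin, metric, mode)
    else:
        # thresholded prediction vanished: penalise with the grid diameter
        d_pred = np.full(gt.shape, float(max(gt.shape)), dtype=np.float64)
    bwd_val = float((gt * d_pred).sum() / gt.sum())
    return 0.5 * (fwd + Tensor(bwd_val))


def cross_entropy(pred: Tensor | np.ndarray, gt_onehot: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy between class probabilities and one-hot truth.

    ``pred`` is a ``(C, H, W)`` stack of per-class probabilities summing to one
    per pixel (within 1e-6); probabilities are floored at ``CE_EPS``.
    """
    if not isinstance(pred, Tensor):
        pred = Tensor(pred)
    gt_onehot = np.asarray(gt_onehot, dtype=np.float64)
    if pred.data.shape != gt_onehot.shape:
        raise ValueError(
            f"pred shape {pred.data.shape} != one-hot gt shape {gt_onehot.shape}"
        )
    sums = pred.data.sum(axis=0)
    if np.abs(sums - 1.0).max() > 1e-6:
        raise ValueError("per-pixel class probabilities must sum to 1 (±1e-6)")
    n_pix = float(gt_onehot[0].size)
    floored = pred + Tensor(CE_EPS)
    return tsum(Tensor(gt_onehot) * -t_log(floored)) / n_pix


def total_loss(
    pred_probs: Tensor,
    gt: np.ndarray,
    w_ce: float = 1.0,
    w_ahd: float = 1.0,
    metric: str = "chebyshev",
    threshold: float = 0.5,
    mode: str = "foreground",
) -> tuple[Tensor, float, float]:
    """Combined objective ``w_ce·L_CE + w_ahd·L_AHD`` (defaults: unweighted sum).

    ``pred_probs`` is a ``(2, H, W)`` stack (background, foreground).  Returns
    the combined loss tensor plus the scalar values of each term.  Episodes
    whose ground truth has no foreground contribute cross-entropy only (the
    AHD term is undefined on an empty set); a counter is logged.
    """
    if w_ce < 0 or w_ahd < 0:
        raise ValueError("loss weights must be nonnegative")
    gt = validate_mask(gt, "gt")
    onehot = np.stack([1 - gt, gt]).astype(np.float64)
    ce = cross_entropy(pred_probs, onehot)
    if gt.any() and w_ahd > 0:
        ah = soft_ahd_loss(pred_probs_fg(pred_probs), gt, metric, threshold, mode)
    else:
        if not gt.any():
            logger.info("empty-foreground ground truth: AHD term skipped")
        ah = Tensor(0.0)
    combined = Tensor(w_ce) * ce + Tensor(w_ahd) * ah
    return combined, ce.item(), ah.item()


def pred_probs_fg(pred_probs: Tensor) -> Tensor:
    """Foreground probability plane of a (2, H, W) class-probability stack."""
    c, h, w = pred_probs.data.shape
    if c != 2:
        raise ValueError("expected a 2-class probability stack")
    from .autodiff import gather, reshape

    idx = np.arange(h * w) + h * w
    return reshape(gather(reshape(pred_probs, (-1,)), idx), (h, w))


# ---------------------------------------------------------------------------
# PNG / array-container IO for masks and probability maps
# ---------------------------------------------------------------------------


def save_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    from PIL import Image

    mask = validate_mask(mask)
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(path)


def load_mask_png(path) -> np.ndarray:
    """Read an 8-bit PNG into a {0,1} mask (any nonzero pixel is foreground)."""
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def save_probmap_png(prob: np.ndarray, path) -> None:
    """Write a [0,1] probability map as an 8-bit grayscale PNG."""
    from PIL import Image

    prob = np.clip(np.asarray(prob, dtype=np.float64), 0.0, 1.0)
    Image.fromarray(np.round(prob * 255).astype(np.uint8), mode="L").save(path)
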