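"""Evaluation suite: accuracy, sensitivity, Dice, AUC and boundary F1.

All scalar metrics follow the per-image-then-mean convention: each test
image contributes one ratio and the report aggregates mean +/- standard
deviation over images, the way segmentation benchmarks tabulate
results.

The boundary F1 (BF-Score) follows the contour-matching convention: a
boundary point counts as matched if it lies within a distance tolerance
of the other mask's boundary; the score is the harmonic mean of
boundary precision and recall.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import roc_auc_score

_STRUCT = {4: ndimage.generate_binary_structure(2, 1),
           8: ndimage.generate_binary_structure(2, 2)}

METRIC_NAMES = ("accuracy", "sensitivity", "dice", "auc", "bf_score")


@dataclass
class ConfusionCounts:
    """Pixel tallies for one image."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class BoundaryMatchConfig:
    """tolerance: match distance in pixels (None -> 0.75% of the image
    diagonal, the usual contour-matching default); connectivity: 4 or 8
    neighbourhood for boundary extraction."""

    tolerance: float | None = None
    connectivity: int = 4

    def __post_init__(self):
        if self.tolerance is not None and self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def resolve_tolerance(self, shape: tuple[int, int]) -> float:
        if self.tolerance is not None:
            return float(self.tolerance)
        return 0.0075 * float(np.hypot(*shape))


def _check_binary(name: str, m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1); found values {vals[:10]}")
    return m.astype(bool)


def confusion_counts(pred_mask, gt_mask) -> ConfusionCounts:
    """Exact per-pixel TP/FP/TN/FN tallies of two binary masks."""
    p = _check_binary("pred_mask", pred_mask)
    g = _check_binary("gt_mask", gt_mask)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    return ConfusionCounts(tp=int(np.sum(p & g)), fp=int(np.sum(p & ~g)),
                           tn=int(np.sum(~p & ~g)), fn=int(np.sum(~p & g)))


def scalar_metrics(counts: list[ConfusionCounts]) -> tuple[float, float, float]:
    """Mean accuracy, sensitivity and Dice over per-image ratios.

    Images with an empty ground-truth foreground have undefined
    sensitivity and Dice (0/0); they are excluded from those two means
    with a warning rather than silently biasing the aggregate.
    """
    if not counts:
        raise ValueError("no images to evaluate")
    accs, sens, dices = [], [], []
    skipped = 0
    for c in counts:
        accs.append((c.tp + c.tn) / c.total)
        if c.tp + c.fn == 0:
            skipped += 1
            continue
        sens.append(c.tp / (c.tp + c.fn))
        dices.append(2 * c.tp / (2 * c.tp + c.fp + c.fn))
    if skipped:
        warnings.warn(f"{skipped} image(s) with empty ground-truth foreground "
                      "excluded from sensitivity/Dice means")
    if not sens:
        raise ValueError("all images have empty ground-truth foreground")
    return float(np.mean(accs)), float(np.mean(sens)), float(np.mean(dices))


def auc_score(prob_map, gt_mask) -> float:
    """Pixelwise ROC AUC: the probability that a random foreground pixel
    outranks a random background pixel (ties count one half)."""
    g = _check_binary("gt_mask", gt_mask).ravel()
    p = np.asarray(prob_map, dtype=float).ravel()
    if p.shape != g.shape:
        raise ValueError("shape mismatch between prob_map and gt_mask")
    if g.all() or not g.any():
        raise ValueError("AUC is undefined for a single-class ground truth")
    return float(roc_auc_score(g, p))


def boundary_points(mask: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Boolean map of mask pixels with at least one background neighbour.

    Pixels outside the image are treated as foreground, so a mask
    touching the image border has no artificial boundary there.
    """
    m = _check_binary("mask", mask)
    eroded = ndimage.binary_erosion(m, structure=_STRUCT[connectivity],
                                    border_value=1)
    return m & ~eroded


def bf_score(pred_mask, gt_mask, cfg: BoundaryMatchConfig | None = None) -> float:
    """Boundary F1: harmonic mean of boundary precision and recall under
    a distance tolerance.  Two empty boundaries agree (score 1); exactly
    one empty boundary scores 0."""
    cfg = cfg or BoundaryMatchConfig()
    p = _check_binary("pred_mask", pred_mask)
    g = _check_binary("gt_mask", gt_mask)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    theta = cfg.resolve_tolerance(p.shape)
    pb = boundary_points(p, cfg.connectivity)
    gb = boundary_points(g, cfg.connectivity)
    if not pb.any() and not gb.any():
        return 1.0
    if not pb.any() or not gb.any():
        return 0.0
    dist_to_g = ndimage.distance_transform_edt(~gb)
    dist_to_p = ndimage.distance_transform_edt(~pb)
    precision = float(np.mean(dist_to_g[pb] <= theta))
    recall = float(np.mean(dist_to_p[gb] <= theta))
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class MetricReport:
    """Per-image metric table plus mean/std aggregates."""

    per_image: pd.DataFrame
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "MetricReport":
        cols = [c for c in METRIC_NAMES if c in table.columns]
        return cls(per_image=table,
                   mean={c: float(table[c].mean()) for c in cols},
                   std={c: float(table[c].std(ddof=0)) for c in cols})

    @property
    def n_images(self) -> int:
        return len(self.per_image)

    def to_csv(self, path) -> None:
        table = self.per_image.copy()
        agg = pd.DataFrame([
            {"image_id": "mean", **self.mean},
            {"image_id": "std", **self.std},
        ])
        pd.concat([table, agg], ignore_index=True).to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {"per_image": self.per_image.to_dict(orient="records"),
                   "mean": self.mean, "std": self.std}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def format_table(self) -> str:
        """Human-readable "mean +/- std" summary line per metric."""
        lines = [f"{name:<12s} {self.mean[name]:.4f} ± {self.std[name]:.4f}"
                 for name in self.mean]
        return "\n".join(lines)


def evaluate_batch(samples, threshold: float = 0.5,
                   cfg: BoundaryMatchConfig | None = None) -> MetricReport:
    """Score a batch of (prob_map, gt_mask[, image_id]) items.

    Probability maps are binarised at ``threshold``; the five metrics
    are computed per image and aggregated as mean +/- std.  AUC is
    recorded as NaN for single-class ground truths (and excluded from
    the aggregate by pandas' NaN handling).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample list")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    cfg = cfg or BoundaryMatchConfig()
    rows = []
    for i, item in enumerate(samples):
        prob, gt = np.asarray(item[0], dtype=float), np.asarray(item[1])
        image_id = item[2] if len(item) > 2 else f"image_{i:04d}"
        prob = prob.squeeze()
        gt = _check_binary("gt_mask", gt.squeeze()).astype(np.uint8)
        pred = (prob >= threshold).astype(np.uint8)
        c = confusion_counts(pred, gt)
        fg = c.tp + c.fn
        try:
            auc = auc_score(prob, gt)
        except ValueError:
            auc = np.nan
        rows.append({
            "image_id": image_id,
            "accuracy": (c.tp + c.tn) / c.total,
            "sensitivity": c.tp / fg if fg else np.nan,
            "dice": 2 * c.tp / (2 * c.tp + c.fp + c.fn) if fg or c.fp else np.nan,
            "auc": auc,
            "bf_score": bf_score(pred, gt, cfg),
        })
    return MetricReport.from_table(pd.DataFrame(rows))
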