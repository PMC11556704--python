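"""Segmentation-agreement metrics for binary mask pairs.

Pixel-level confusion counts and the usual overlap scores: Dice
coefficient 2·TP/(2·TP+FP+FN), per-class intersection-over-union, their
unweighted two-class mean (mIoU), and pixel accuracy.  The empty-vs-empty
case (0/0) is defined as perfect agreement (1.0).  Whether "mIoU" means
the two-class mean or foreground-only IoU varies across papers, so both
per-class IoUs are exposed alongside the mean.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "dice",
    "iou_per_class",
    "miou",
    "accuracy",
    "evaluate_pair",
    "evaluate_dirs",
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


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact pixel confusion counts between two binary rasters."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"pred {pred.shape} and truth {truth.shape} dimensions differ")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def _safe_div(num: float, den: float) -> float:
    return 1.0 if den == 0 else num / den


def dice(c: ConfusionCounts) -> float:
    return _safe_div(2.0 * c.tp, 2.0 * c.tp + c.fp + c.fn)


def iou_per_class(c: ConfusionCounts) -> tuple[float, float]:
    """(foreground IoU, background IoU)."""
    fg = _safe_div(float(c.tp), float(c.tp + c.fp + c.fn))
    bg = _safe_div(float(c.tn), float(c.tn + c.fp + c.fn))
    return fg, bg


def miou(c: ConfusionCounts) -> float:
    fg, bg = iou_per_class(c)
    return 0.5 * (fg + bg)


def accuracy(c: ConfusionCounts) -> float:
    return _safe_div(float(c.tp + c.tn), float(c.total))


def evaluate_pair(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """All metrics for one binary mask pair."""
    c = confusion(pred, truth)
    fg, bg = iou_per_class(c)
    return {
        "dice": dice(c),
        "miou": miou(c),
        "iou_foreground": fg,
        "iou_background": bg,
        "accuracy": accuracy(c),
    }


def evaluate_dirs(pred_dir: str | Path, truth_dir: str | Path, out_csv: str | Path | None = None) -> list[dict]:
    """Evaluate same-named mask files in two directories.

    Masks are binarized at > 0.  Returns one row per pair plus a summary
    row of unweighted means; optionally written as CSV.
    """
    from .fixtures import _read_raster  # shared raster reader

    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    names = sorted(
        p.name for p in pred_dir.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    rows: list[dict] = []
    for name in names:
        tpath = truth_dir / name
        if not tpath.exists():
            continue
        pred = _read_raster(pred_dir / name) > 0
        truth = _read_raster(tpath) > 0
        rows.append({"name": name, **evaluate_pair(pred, truth)})
    if not rows:
        raise ValueError(f"no matching mask pairs between {pred_dir} and {truth_dir}")
    keys = [k for k in rows[0] if k != "name"]
    summary = {"name": "mean", **{k: float(np.mean([r[k] for r in rows])) for k in keys}}
    rows.append(summary)
    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["name", *keys])
            writer.writeheader()
            writer.writerows(rows)
    return rows
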