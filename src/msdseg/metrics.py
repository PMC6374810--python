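"""Segmentation evaluation: Dice coefficient, recall rate, and the average
symmetric surface distance (ASD), with spacing-aware physical distances.

DSC = 2TP / (FP + 2TP + FN), RR = TP / (TP + FN), and ASD is the symmetric
mean of boundary-to-boundary minimum Euclidean distances in mm, where a
boundary voxel is a foreground voxel with at least one 6-connected
background neighbor (the volume border counts as background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegmentationPair:
    """A predicted mask and its ground truth on the same grid."""

    pred: np.ndarray
    truth: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.pred = np.asarray(self.pred).astype(bool)
        self.truth = np.asarray(self.truth).astype(bool)
        if self.pred.shape != self.truth.shape:
            raise ValueError(
                f"shape mismatch: pred {self.pred.shape} vs truth {self.truth.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)


def confusion_counts(pair: SegmentationPair):
    """Voxel-wise (TP, FP, FN, TN)."""
    tp = int(np.count_nonzero(pair.pred & pair.truth))
    fp = int(np.count_nonzero(pair.pred & ~pair.truth))
    fn = int(np.count_nonzero(~pair.pred & pair.truth))
    tn = pair.pred.size - tp - fp - fn
    return tp, fp, fn, tn


def dsc(pair: SegmentationPair) -> float:
    """Dice similarity coefficient (overlap index) in [0, 1].

    Two empty masks agree perfectly, so that case is defined as 1.
    """
    tp, fp, fn, _ = confusion_counts(pair)
    denom = fp + 2 * tp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def recall(pair: SegmentationPair) -> float:
    """Recall rate (sensitivity, true-positive rate); undefined for empty truth."""
    tp, _, fn, _ = confusion_counts(pair)
    if tp + fn == 0:
        raise ValueError("recall is undefined for an empty ground truth")
    return tp / (tp + fn)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean map of foreground voxels with a 6-connected background neighbor.

    Voxels on the volume border are boundary (outside counts as background).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("boundary of an empty mask is undefined")
    interior = ndimage.binary_erosion(mask, structure=_SIX_CONN, border_value=0)
    return mask & ~interior


def asd(pair: SegmentationPair) -> float:
    """Average symmetric surface distance in mm.

    Sums, over each boundary set, the minimum spacing-aware Euclidean
    distance to the other boundary set, and divides by the total number of
    boundary voxels.
    """
    if not pair.pred.any() or not pair.truth.any():
        raise ValueError("ASD requires both masks to be nonempty")
    bp = np.argwhere(boundary_voxels(pair.pred)) * np.asarray(pair.spacing)
    bg = np.argwhere(boundary_voxels(pair.truth)) * np.asarray(pair.spacing)
    d_pg = cKDTree(bg).query(bp, k=1)[0]
    d_gp = cKDTree(bp).query(bg, k=1)[0]
    return float((d_pg.sum() + d_gp.sum()) / (len(bp) + len(bg)))


def evaluate_pair(pair: SegmentationPair) -> dict:
    """Per-case report: DSC, RR and ASD (mm)."""
    return {"DSC": dsc(pair), "RR": recall(pair), "ASD_mm": asd(pair)}


def aggregate(reports, names=None) -> pd.DataFrame:
    """Stack per-case reports and append mean and sample-SD rows.

    ``reports`` is a sequence of dicts as returned by :func:`evaluate_pair`.
    For a single case the SD row is reported as 0 by convention.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one case")
    df = pd.DataFrame(reports)
    if names is not None:
        df.insert(0, "case", list(names))
    else:
        df.insert(0, "case", [f"case{i:03d}" for i in range(len(reports))])
    metric_cols = [c for c in df.columns if c != "case"]
    mean = df[metric_cols].mean()
    sd = (df[metric_cols].std(ddof=1) if len(df) > 1
          else pd.Series(0.0, index=metric_cols))
    out = pd.concat([df,
                     pd.DataFrame([{"case": "mean", **mean.to_dict()},
                                   {"case": "sd", **sd.to_dict()}])],
                    ignore_index=True)
    return out
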