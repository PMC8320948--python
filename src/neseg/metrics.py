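"""Segmentation accuracy metrics: Jaccard index and Hausdorff distance.

Both metrics are computed per slice.  The Jaccard similarity index
JI = TP / (TP + FP + FN) deliberately excludes true negatives, so it stays
strict on slices where the object is small against a large background.  The
Hausdorff distance is the symmetric max-min Euclidean distance between the
two boundary point sets, reported in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

from .volume import NucleusVolume, extract_envelope


class UndefinedMetricError(ValueError):
    """The metric has no value for this input (e.g. two empty masks)."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(seg: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts of a segmentation against ground truth."""
    seg = np.asarray(seg, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if seg.shape != gt.shape:
        raise ValueError(f"shape mismatch: {seg.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(seg & gt))
    fp = int(np.count_nonzero(seg & ~gt))
    fn = int(np.count_nonzero(~seg & gt))
    tn = seg.size - tp - fp - fn
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def jaccard(seg: np.ndarray, gt: np.ndarray) -> float:
    """Jaccard similarity index TP / (TP + FP + FN) of two binary masks."""
    c = confusion_counts(seg, gt)
    denom = c.TP + c.FP + c.FN
    if denom == 0:
        raise UndefinedMetricError("Jaccard index undefined for two empty masks")
    return c.TP / denom


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(N, 2) array of boundary pixel coordinates of a 2D mask."""
    return np.argwhere(extract_envelope(np.asarray(mask, dtype=bool)))


def hausdorff(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets, in pixel units.

    ``max`` over both directions of the sup-inf Euclidean distance.  Inputs
    are (N, k) coordinate arrays; boolean masks are converted to their pixel
    coordinates.
    """
    a = np.asarray(points_a)
    b = np.asarray(points_b)
    if a.dtype == bool:
        a = np.argwhere(a)
    if b.dtype == bool:
        b = np.argwhere(b)
    if a.size == 0 or b.size == 0:
        raise UndefinedMetricError("Hausdorff distance undefined for an empty set")
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def evaluate_volume(
    seg: NucleusVolume | np.ndarray,
    gt: np.ndarray,
    slice_range: tuple[int, int] | None = None,
    gt_envelope: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-slice JI and HD of a segmented nucleus against a ground-truth mask.

    JI is computed on the filled nucleus masks, HD on the envelope boundary
    pixel sets.  Slices where both masks are empty carry no information and
    are excluded; slices where exactly one mask is empty score JI = 0 and
    have no HD.  Means are reported over the inclusive ``slice_range``
    (default: all slices).

    Returns (table, summary) where ``table`` has one row per evaluated slice
    and ``summary`` holds ``mean_jaccard``, ``mean_hausdorff`` and counts.
    """
    if isinstance(seg, NucleusVolume):
        seg_mask, seg_env = seg.mask, seg.envelope
    else:
        seg_mask = np.asarray(seg, dtype=bool)
        seg_env = extract_envelope(seg_mask)
    gt = np.asarray(gt, dtype=bool)
    if seg_mask.shape != gt.shape:
        raise ValueError(f"shape mismatch: {seg_mask.shape} vs {gt.shape}")
    if gt_envelope is None:
        gt_envelope = extract_envelope(gt)

    n_d = seg_mask.shape[2]
    lo, hi = slice_range if slice_range is not None else (0, n_d - 1)
    if not (0 <= lo <= hi < n_d):
        raise ValueError(f"invalid slice range ({lo}, {hi}) for {n_d} slices")

    rows = []
    for k in range(lo, hi + 1):
        s = seg_mask[:, :, k]
        g = gt[:, :, k]
        s_any, g_any = bool(s.any()), bool(g.any())
        if not s_any and not g_any:
            continue
        ji = jaccard(s, g)
        if s_any and g_any:
            hd = hausdorff(np.argwhere(seg_env[:, :, k]), np.argwhere(gt_envelope[:, :, k]))
        else:
            hd = np.nan
        rows.append({"slice_index": k, "jaccard": ji, "hausdorff": hd})

    table = pd.DataFrame(rows, columns=["slice_index", "jaccard", "hausdorff"])
    summary = {
        "mean_jaccard": float(table["jaccard"].mean()) if len(table) else np.nan,
        "mean_hausdorff": float(table["hausdorff"].mean()) if len(table) else np.nan,
        "n_slices": int(len(table)),
        "slice_range": (lo, hi),
    }
    return table, summary
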