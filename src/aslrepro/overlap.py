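"""Agreement metrics between binary activation masks.

True-positive mask construction (reference activation intersected with
task-related region labels, then dilated with a 3x3x3 structuring
element), precision = 100 * TP / (TP + FP), the Dice similarity
coefficient 2*|A&B| / (|A| + |B|), and aggregation of scores by the
rest/task separation interval.

Undefined cases (empty candidate for precision; both masks empty for
Dice) return NaN rather than 0 so that group averages are not silently
biased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "OverlapResult",
    "dilate_mask",
    "make_tp_mask",
    "precision",
    "dice",
    "aggregate_by_separation",
]

CUBE_3 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class OverlapResult:
    """Overlap scores for one candidate activation map."""

    separation_label: str
    tp_count: int
    fp_count: int
    precision: float  # percent, NaN when undefined
    dice: float  # dimensionless, NaN when undefined
    subject: str | None = None
    run: int | None = None


def _as_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError(f"{name} must be strictly binary")
        arr = arr.astype(bool)
    return arr


def dilate_mask(mask: np.ndarray, passes: int = 1) -> np.ndarray:
    """Morphological dilation with the full 3x3x3 cube (26-connectivity).

    A background voxel becomes one if the structuring element centred on it
    overlaps the mask in at least one voxel; the image border is clipped.
    """
    arr = _as_binary(mask)
    if passes == 0:
        return arr.copy()
    return ndimage.binary_dilation(arr, structure=CUBE_3, iterations=passes)


def make_tp_mask(
    reference_activation: np.ndarray,
    task_region_mask: np.ndarray,
    mode: str = "reference",
    dilation_passes: int = 1,
) -> np.ndarray:
    """True-positive mask for precision scoring.

    mode="reference" (default): the reference (within-session) activation
    intersected with the union of task-related region labels, then dilated.
    mode="anatomical": the task-related regions alone (robustness variant
    that avoids re-using task data), also dilated.
    """
    ref = _as_binary(reference_activation, "reference_activation")
    region = _as_binary(task_region_mask, "task_region_mask")
    if ref.shape != region.shape:
        raise ValueError("grid mismatch between activation and region masks")
    if not region.any():
        raise ValueError("task region mask is empty")
    if mode == "anatomical":
        core = region
    elif mode == "reference":
        core = ref & region
        if not core.any():
            warnings.warn("reference activation does not intersect task regions; "
                          "TP mask is empty")
            return core
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return dilate_mask(core, passes=dilation_passes)


def overlap_counts(candidate: np.ndarray, tp_mask: np.ndarray) -> tuple[int, int]:
    """(TP, FP) voxel counts of a candidate mask against the TP mask."""
    cand = _as_binary(candidate, "candidate")
    tp = _as_binary(tp_mask, "tp_mask")
    if cand.shape != tp.shape:
        raise ValueError("grid mismatch")
    return int((cand & tp).sum()), int((cand & ~tp).sum())


def precision(candidate: np.ndarray, tp_mask: np.ndarray) -> float:
    """100 * TP / (TP + FP); NaN (undefined) when the candidate is empty."""
    tp, fp = overlap_counts(candidate, tp_mask)
    if tp + fp == 0:
        warnings.warn("empty candidate mask: precision undefined")
        return float("nan")
    return 100.0 * tp / (tp + fp)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2*|A&B| / (|A| + |B|); NaN when both masks are empty."""
    a = _as_binary(a, "a")
    b = _as_binary(b, "b")
    if a.shape != b.shape:
        raise ValueError("grid mismatch")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        warnings.warn("both masks empty: Dice undefined")
        return float("nan")
    return 2.0 * int((a & b).sum()) / size


def aggregate_by_separation(
    results: list[OverlapResult] | pd.DataFrame,
    reference_label: str = "within-session_DR",
) -> pd.DataFrame:
    """Mean +/- SD of precision and Dice per separation label.

    Between-session rows are additionally expressed as a percentage of the
    ``reference_label`` (within-session, different-run) mean.  Undefined
    (NaN) scores are excluded from the averages with counts reported.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        if not results:
            raise ValueError("no overlap results to aggregate")
        df = pd.DataFrame([vars(r) for r in results])
    rows = []
    for label, grp in df.groupby("separation_label", sort=False):
        row = {"separation_label": label, "n": len(grp)}
        for metric in ("precision", "dice"):
            vals = grp[metric].dropna()
            row[f"{metric}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{metric}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            row[f"{metric}_n_undefined"] = int(grp[metric].isna().sum())
        rows.append(row)
    table = pd.DataFrame(rows)
    ref = table[table["separation_label"] == reference_label]
    if len(ref):
        for metric in ("precision", "dice"):
            ref_mean = float(ref[f"{metric}_mean"].iloc[0])
            table[f"{metric}_pct_of_{reference_label}"] = (
                100.0 * table[f"{metric}_mean"] / ref_mean if ref_mean else np.nan
            )
    return table
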