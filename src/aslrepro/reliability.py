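"""Test-retest reproducibility and reliability of resting CBF.

Voxel-wise repeated-measures variance decomposition (two-way subject x
repeat ANOVA, method of moments), the within-subject coefficient of
variation (wsCV), the two-way mixed-model intraclass correlation
coefficient (ICC), minimal detectable change, global (grey-matter mean)
normalization, ROI aggregation and motion QC.

Definitions
-----------
wsCV(%) = 100 * sqrt(sigma2_se + sigma2_er) / grand_mean — the SD between
repeated measurements over the mean, where sigma2_se is the systemic
(between repeated measures) variance and sigma2_er the residual error.

ICC = sigma2_bs / (sigma2_bs + sigma2_se + sigma2_er) — between-subject
variance over total variance; range 0-1, values above 0.75 are
conventionally classified as excellent reliability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "variance_components",
    "fit_variance_components",
    "wscv_map",
    "icc_map",
    "mdc_map",
    "normalize_global",
    "roi_summary",
    "qc_motion_report",
    "MAX_TRANSLATION_MM",
    "MAX_ROTATION_DEG",
]

MAX_TRANSLATION_MM = 3.0
MAX_ROTATION_DEG = 3.0


@dataclass
class VarianceComponents:
    """Per-voxel variance components from a balanced subject x repeat table."""

    sigma2_bs: np.ndarray  # between-subject
    sigma2_se: np.ndarray  # systemic (between repeated measures)
    sigma2_er: np.ndarray  # residual error
    grand_mean: np.ndarray
    n_subjects: int
    n_repeats: int
    n_truncated_bs: int = 0
    n_truncated_se: int = 0

    @property
    def total(self) -> np.ndarray:
        return self.sigma2_bs + self.sigma2_se + self.sigma2_er


def variance_components(table: np.ndarray) -> VarianceComponents:
    """Method-of-moments components from a (subjects, repeats[, voxels]) table.

    Two-way ANOVA mean squares: MS_R over subjects (rows), MS_C over
    repeats (columns), MS_E residual.  Components:

        sigma2_er = MS_E
        sigma2_se = max(0, (MS_C - MS_E) / n_subjects)
        sigma2_bs = max(0, (MS_R - MS_E) / n_repeats)

    Negative moment estimates are truncated at zero and the truncation
    events counted.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim < 2:
        raise ValueError("table must be (subjects, repeats[, voxels...])")
    ns, nr = table.shape[0], table.shape[1]
    if ns < 2 or nr < 2:
        raise ValueError("need at least 2 subjects and 2 repeats")
    if not np.isfinite(table).all():
        raise ValueError("balanced design required: non-finite cells present")

    grand = table.mean(axis=(0, 1))
    row = table.mean(axis=1)  # (subjects, ...)
    col = table.mean(axis=0)  # (repeats, ...)

    ss_r = nr * ((row - grand) ** 2).sum(axis=0)
    ss_c = ns * ((col - grand) ** 2).sum(axis=0)
    resid = table - row[:, None] - col[None, :] + grand
    ss_e = (resid**2).sum(axis=(0, 1))

    ms_r = ss_r / (ns - 1)
    ms_c = ss_c / (nr - 1)
    ms_e = ss_e / ((ns - 1) * (nr - 1))

    raw_bs = (ms_r - ms_e) / nr
    raw_se = (ms_c - ms_e) / ns
    return VarianceComponents(
        sigma2_bs=np.maximum(raw_bs, 0.0),
        sigma2_se=np.maximum(raw_se, 0.0),
        sigma2_er=ms_e,
        grand_mean=grand,
        n_subjects=ns,
        n_repeats=nr,
        n_truncated_bs=int(np.sum(raw_bs < 0)),
        n_truncated_se=int(np.sum(raw_se < 0)),
    )


def fit_variance_components(stack: np.ndarray, mode: str) -> VarianceComponents:
    """Variance components from a (subjects, sessions, runs[, voxels]) stack.

    mode="within-session": repeats are the runs of a session; components
    are estimated per session and averaged across sessions.
    mode="between-session": repeats are the per-subject session means
    (runs averaged first).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim < 3:
        raise ValueError("stack must be (subjects, sessions, runs[, voxels...])")
    if not np.isfinite(stack).all():
        raise ValueError("balanced design required: non-finite cells present")
    if mode == "between-session":
        return variance_components(stack.mean(axis=2))
    if mode != "within-session":
        raise ValueError(f"unknown mode {mode!r}")
    per_session = [variance_components(stack[:, s]) for s in range(stack.shape[1])]
    k = len(per_session)
    return VarianceComponents(
        sigma2_bs=sum(v.sigma2_bs for v in per_session) / k,
        sigma2_se=sum(v.sigma2_se for v in per_session) / k,
        sigma2_er=sum(v.sigma2_er for v in per_session) / k,
        grand_mean=stack.mean(axis=(0, 1, 2)),
        n_subjects=per_session[0].n_subjects,
        n_repeats=per_session[0].n_repeats,
        n_truncated_bs=sum(v.n_truncated_bs for v in per_session),
        n_truncated_se=sum(v.n_truncated_se for v in per_session),
    )


def wscv_map(vc: VarianceComponents) -> np.ndarray:
    """Within-subject coefficient of variation, percent.

    100 * sqrt(sigma2_se + sigma2_er) / grand_mean; NaN (undefined) where
    the mean is not positive.
    """
    sd = np.sqrt(vc.sigma2_se + vc.sigma2_er)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * sd / vc.grand_mean
    return np.where(vc.grand_mean > 0, out, np.nan)


def icc_map(vc: VarianceComponents) -> np.ndarray:
    """Intraclass correlation coefficient in [0, 1]; NaN where total variance is 0."""
    tot = vc.total
    with np.errstate(divide="ignore", invalid="ignore"):
        out = vc.sigma2_bs / tot
    return np.where(tot > 0, out, np.nan)


def mdc_map(
    vc: VarianceComponents, n: int, t_crit: float, form: str = "multiplicative"
) -> np.ndarray:
    """Minimal detectable CBF change from the paired-test relation.

    Default ("multiplicative"): dCBF_min = (SD_dCBF / sqrt(n)) * t_crit,
    the standard paired-test detectability bound, with SD_dCBF =
    sqrt(sigma2_se + sigma2_er) and n the number of perfusion images per
    run.  form="printed" divides by t_crit instead of multiplying.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if t_crit <= 0:
        raise ValueError("t_crit must be positive")
    sd = np.sqrt(vc.sigma2_se + vc.sigma2_er)
    base = sd / np.sqrt(n)
    if form == "multiplicative":
        return base * t_crit
    if form == "printed":
        return base / t_crit
    raise ValueError(f"unknown form {form!r}")


def normalize_global(cbf: np.ndarray, gm_mask: np.ndarray) -> np.ndarray:
    """Relative CBF: divide by the mean value over the grey-matter mask.

    The output is dimensionless with GM mean exactly 1, and is invariant to
    any positive rescaling of the input.
    """
    cbf = np.asarray(cbf, dtype=float)
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if not gm_mask.any():
        raise ValueError("empty grey-matter mask")
    mean = cbf[gm_mask].mean()
    if not mean > 0:
        raise ValueError("nonpositive mean grey-matter CBF")
    return cbf / mean


def roi_summary(metric_maps: dict, roi_masks: dict) -> pd.DataFrame:
    """Mean +/- SD of voxel values inside each dichotomous ROI mask.

    Undefined (NaN) voxels are excluded, with counts reported, matching
    the convention of multiplying metric images by binary masks and
    averaging within the region.
    """
    rows = []
    for roi, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"empty ROI mask {roi!r}")
        for metric, vol in metric_maps.items():
            vals = np.asarray(vol, dtype=float)[mask]
            ok = np.isfinite(vals)
            rows.append(
                {
                    "roi": roi,
                    "metric": metric,
                    "mean": float(vals[ok].mean()) if ok.any() else np.nan,
                    "sd": float(vals[ok].std(ddof=1)) if ok.sum() > 1 else np.nan,
                    "n_voxels": int(ok.sum()),
                    "n_undefined": int((~ok).sum()),
                }
            )
    return pd.DataFrame(rows)


def qc_motion_report(motion: pd.DataFrame | list) -> pd.DataFrame:
    """Flag runs whose alignment magnitudes exceed 3 mm or 3 degrees.

    ``motion`` rows need ``translation_mm`` and ``rotation_deg`` columns
    (plus any identifier columns, which are carried through).
    """
    df = pd.DataFrame(motion).copy()
    for colname in ("translation_mm", "rotation_deg"):
        if colname not in df.columns:
            raise ValueError(f"missing column {colname!r}")
        if df[colname].isna().any():
            raise ValueError(f"missing entries in {colname!r}")
    df["translation_ok"] = df["translation_mm"] <= MAX_TRANSLATION_MM
    df["rotation_ok"] = df["rotation_deg"] <= MAX_ROTATION_DEG
    df["qc_pass"] = df["translation_ok"] & df["rotation_ok"]
    return df
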