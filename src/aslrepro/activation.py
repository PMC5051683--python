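"""Rest/task activation mapping on CBF series.

Assembles rest and task CBF segments within and across sessions, fits a
voxel-wise general linear model (intercept + task indicator, equivalent to
the pooled-variance two-sample t-test), and thresholds the t-map with
family-wise error control — Bonferroni by default, permutation max-T as an
exact alternative — or Benjamini-Hochberg FDR.

Contrast scheme for the three-session, two-run design (task data fixed,
rest source varies):

* within-session:      rest and task from the same session and run
* within-session_DR:   rest from the other run of the same session
* 1-week:              session 2 rest vs session 1 task (same run)
* 3-week:              session 3 rest vs session 2 task
* 1-month:             session 3 rest vs session 1 task
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from math import comb

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "ContrastAssembly",
    "ActivationResult",
    "assemble_contrasts",
    "smooth_gaussian",
    "fit_glm",
    "threshold_fwe",
    "threshold_fdr",
    "SEPARATION_LABELS",
]

#: (rest_session, task_session) -> separation label for cross-session pairs
SEPARATION_LABELS = {(2, 1): "1-week", (3, 2): "3-week", (3, 1): "1-month"}

WITHIN = "within-session"
WITHIN_DR = "within-session_DR"


@dataclass
class ContrastAssembly:
    """Rest-then-task CBF series concatenated from two (session, run) sources."""

    rest_source: tuple[int, int]
    task_source: tuple[int, int]
    separation_label: str
    cbf_series: np.ndarray  # (..., volumes)
    condition: np.ndarray  # bool, True = task volume

    def __post_init__(self) -> None:
        self.condition = np.asarray(self.condition, dtype=bool)
        n_task = int(self.condition.sum())
        if n_task == 0 or n_task == self.condition.size:
            raise ValueError("rest and task segments must both be nonempty")


@dataclass
class ActivationResult:
    """Voxel-wise GLM output with (optional) significance thresholding."""

    beta_task: np.ndarray
    t_map: np.ndarray
    df: int
    mask: np.ndarray
    assembly: ContrastAssembly | None = None
    threshold: float | None = None
    threshold_info: dict | None = None
    significance_mask: np.ndarray | None = None


def _segments(series: np.ndarray, conditions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    conditions = np.asarray(conditions)
    rest = series[..., conditions == "REST"]
    task = series[..., conditions == "TASK"]
    return rest, task


def assemble_contrasts(
    cbf_runs: dict,
    sessions: tuple[int, ...] = (1, 2, 3),
    runs: tuple[int, ...] = (1, 2),
) -> list[ContrastAssembly]:
    """Build all rest/task pairings for one subject.

    ``cbf_runs`` maps (session, run) to a tuple ``(series, conditions)``
    where series is a per-pair CBF array (..., pairs) and conditions a
    per-pair REST/TASK label vector.  Missing sources raise KeyError with
    the offending key.
    """
    def seg(key: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        if key not in cbf_runs:
            raise KeyError(f"missing source run {key}")
        return _segments(*cbf_runs[key])

    out: list[ContrastAssembly] = []

    def emit(rest_key, task_key, label) -> None:
        rest, _ = seg(rest_key)
        _, task = seg(task_key)
        series = np.concatenate([rest, task], axis=-1)
        cond = np.r_[np.zeros(rest.shape[-1], bool), np.ones(task.shape[-1], bool)]
        out.append(
            ContrastAssembly(
                rest_source=rest_key,
                task_source=task_key,
                separation_label=label,
                cbf_series=series,
                condition=cond,
            )
        )

    for s in sessions:
        for r in runs:
            emit((s, r), (s, r), WITHIN)
            if len(runs) > 1:
                other = runs[1] if r == runs[0] else runs[0]
                emit((s, other), (s, r), WITHIN_DR)
    for (s_rest, s_task), label in SEPARATION_LABELS.items():
        if s_rest in sessions and s_task in sessions:
            for r in runs:
                emit((s_rest, r), (s_task, r), label)
    return out


def smooth_gaussian(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: tuple[float, float, float],
) -> np.ndarray:
    """Separable isotropic Gaussian smoothing, sigma = FWHM / (2 sqrt(2 ln 2)).

    Works on a 3D volume or a 4D series (smoothed per volume).  Boundaries
    use a renormalized truncated kernel: the filtered volume is divided by
    the filtered all-ones volume, so constant images are preserved exactly
    at the edges.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if any(v <= 0 for v in voxel_size_mm):
        raise ValueError("voxel sizes must be positive")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return volume.copy()
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / v for v in voxel_size_mm]
    if volume.ndim == 4:
        sigma = sigma_vox + [0.0]
        norm_shape = volume.shape[:3]
    elif volume.ndim == 3:
        sigma = sigma_vox
        norm_shape = volume.shape
    else:
        raise ValueError("expected a 3D volume or 4D series")
    num = ndimage.gaussian_filter(volume, sigma=sigma, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(
        np.ones(norm_shape), sigma=sigma_vox, mode="constant", cval=0.0
    )
    if volume.ndim == 4:
        den = den[..., None]
    return num / den


def fit_glm(assembly: ContrastAssembly, mask: np.ndarray | None = None) -> ActivationResult:
    """Per-voxel OLS on [intercept, task indicator].

    The task-effect t-statistic equals the pooled-variance two-sample
    t-test for this design: t = beta_task / SE(beta_task), df = N - 2.
    """
    series = np.asarray(assembly.cbf_series, dtype=float)
    cond = assembly.condition
    n1 = int((~cond).sum())
    n2 = int(cond.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 volumes per condition")
    rest = series[..., ~cond]
    task = series[..., cond]
    m1 = rest.mean(axis=-1)
    m2 = task.mean(axis=-1)
    beta = m2 - m1
    ss = ((rest - m1[..., None]) ** 2).sum(axis=-1) + (
        (task - m2[..., None]) ** 2
    ).sum(axis=-1)
    df = n1 + n2 - 2
    s2 = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    # zero residual variance: identical values within each condition, so the
    # effect is either exactly zero or noiselessly separated
    degenerate = np.where(beta > 0, np.inf, np.where(beta < 0, -np.inf, 0.0))
    t = np.where(s2 > 0, t, degenerate)
    if mask is None:
        mask = np.ones(beta.shape, dtype=bool)
    return ActivationResult(
        beta_task=beta, t_map=t, df=df, mask=np.asarray(mask, bool), assembly=assembly
    )


def _p_values(t: np.ndarray, df: int, two_sided: bool) -> np.ndarray:
    if two_sided:
        return 2.0 * stats.t.sf(np.abs(t), df)
    return stats.t.sf(t, df)


def _max_t_distribution(
    series2d: np.ndarray, cond: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Max-over-voxels t for permuted condition labels.

    series2d is (volumes, voxels).  Uses the identity that the pooled
    variance depends on the permutation only through the group means, so
    each permutation costs two matrix-vector reductions.
    """
    n = series2d.shape[0]
    n2 = int(cond.sum())
    n1 = n - n2
    df = n - 2
    total_sum = series2d.sum(axis=0)
    total_ss = (series2d**2).sum(axis=0)

    n_exact = comb(n, n2)
    if n_exact <= n_perm:
        perms = np.zeros((n_exact, n), dtype=float)
        for i, picks in enumerate(itertools.combinations(range(n), n2)):
            perms[i, list(picks)] = 1.0
    else:
        perms = np.zeros((n_perm, n), dtype=float)
        perms[0, cond] = 1.0  # include the observed labelling
        for i in range(1, n_perm):
            perms[i, rng.choice(n, size=n2, replace=False)] = 1.0

    sum2 = perms @ series2d  # (perms, voxels) task-group sums
    m2 = sum2 / n2
    m1 = (total_sum[None, :] - sum2) / n1
    ss = total_ss[None, :] - n1 * m1**2 - n2 * m2**2
    s2 = np.maximum(ss, 0.0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    t = np.where(s2 > 0, t, 0.0)
    return t.max(axis=1)


def threshold_fwe(
    result: ActivationResult,
    alpha: float = 0.05,
    method: str = "bonferroni",
    two_sided: bool = False,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ActivationResult:
    """Family-wise error control over the analysis mask, no cluster threshold.

    "bonferroni": voxel-wise p <= alpha / V.  "permutation": threshold at
    the (1 - alpha) quantile of the max-t distribution over condition-label
    permutations (exhaustive when the number of distinct labelings does not
    exceed ``n_permutations``; random otherwise, requiring more than 10
    volumes per condition).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    mask = result.mask
    v = int(mask.sum())
    if v == 0:
        raise ValueError("empty analysis mask")
    if method == "bonferroni":
        p = _p_values(result.t_map, result.df, two_sided)
        sig = (p <= alpha / v) & mask
        thr = float(stats.t.isf((alpha / v) / (2 if two_sided else 1), result.df))
        info = {"method": "bonferroni", "alpha": alpha, "n_voxels": v,
                "two_sided": two_sided}
    elif method == "permutation":
        if result.assembly is None:
            raise ValueError("permutation thresholding needs the source assembly")
        cond = result.assembly.condition
        n = cond.size
        n2 = int(cond.sum())
        n_exact = comb(n, n2)
        if n_exact < int(np.ceil(1.0 / alpha)):
            raise ValueError(
                "insufficient volumes: the permutation distribution cannot "
                f"resolve alpha={alpha} with {n_exact} distinct labelings"
            )
        if n_exact <= n_permutations or min(n2, n - n2) <= 10:
            # few volumes: random draws would repeat; enumerate exhaustively
            n_permutations = min(n_exact, 200_000)
        series2d = result.assembly.cbf_series.reshape(-1, n)[mask.ravel()].T
        stat = np.abs if two_sided else (lambda x: x)
        maxt = _max_t_distribution(
            np.asarray(series2d, float), cond, n_permutations, np.random.default_rng(seed)
        )
        thr = float(np.quantile(stat(maxt), 1.0 - alpha, method="higher"))
        sig = (stat(result.t_map) >= thr) & mask
        info = {"method": "permutation", "alpha": alpha, "n_permutations": len(maxt),
                "two_sided": two_sided}
    else:
        raise ValueError(f"unknown FWE method {method!r}")
    return replace(
        result, threshold=thr, threshold_info=info, significance_mask=sig, assembly=result.assembly
    )


def threshold_fdr(
    result: ActivationResult, q: float = 0.05, two_sided: bool = False
) -> ActivationResult:
    """Benjamini-Hochberg step-up over voxel p-values on the analysis mask."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    from statsmodels.stats.multitest import multipletests

    mask = result.mask
    p = _p_values(result.t_map, result.df, two_sided)[mask]
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    sig = np.zeros(mask.shape, dtype=bool)
    sig[mask] = reject
    thr = float(result.t_map[sig].min()) if sig.any() else np.inf
    info = {"method": "fdr_bh", "q": q, "two_sided": two_sided}
    return replace(result, threshold=thr, threshold_info=info, significance_mask=sig)
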