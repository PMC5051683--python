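"""End-to-end study replica: simulate, quantify, map reliability, run
activation contrasts, and score overlap.

The defaults mirror the emulated study design: three sessions with two
rest/task runs each (96 control-tag pairs per run, label duration 1500 ms,
PLD 1200 ms) plus one five-PLD transit-time acquisition per session, grey-
and white-matter masks by probability thresholding (80% / 60%), 6 mm FWHM
smoothing of the difference images, voxel-wise GLM activation with
Bonferroni FWE control at alpha = 0.05, and precision/Dice scoring against
the dilated within-session true-positive mask.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import activation as act
from . import overlap as ovl
from . import reliability as rel
from .kinetics import fit_att_cbf, quantify_cbf
from .synthetic import (
    AcquisitionSpec,
    Phantom,
    PhantomSpec,
    VariancePlan,
    build_phantom,
    simulate_att_run,
    simulate_dataset,
)

__all__ = ["StudyConfig", "StudyReport", "mask_from_probability", "run_study",
           "att_variability", "DEFAULT_ATT_PLDS"]

logger = logging.getLogger("aslrepro")

DEFAULT_ATT_PLDS = (700.0, 1300.0, 1900.0, 2500.0, 3100.0)


def default_att_acquisition() -> AcquisitionSpec:
    return AcquisitionSpec(pld=DEFAULT_ATT_PLDS, pairs_per_pld=5)


@dataclass
class StudyConfig:
    """Configuration of a full synthetic study analysis."""

    n_subjects: int = 4
    n_sessions: int = 3
    n_runs: int = 2
    phantom_spec: PhantomSpec = field(default_factory=PhantomSpec)
    plan: VariancePlan = field(default_factory=VariancePlan)
    acq: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    att_acq: AcquisitionSpec | None = field(default_factory=default_att_acquisition)
    #: voxel size of the low-resolution transit-time acquisition, mm; the
    #: per-pair noise SD of ATT runs is scaled by the voxel-volume ratio so
    #: that per-voxel SNR grows with voxel volume
    att_voxel_size: tuple = (12.0, 8.0, 6.0)
    gm_threshold: float = 0.8
    wm_threshold: float = 0.6
    smooth_fwhm: float = 6.0
    alpha: float = 0.05
    fwe_method: str = "bonferroni"
    scales: tuple = ("aCBF", "rCBF")
    seed: int | None = None

    def __post_init__(self) -> None:
        for thr in (self.gm_threshold, self.wm_threshold):
            if not 0 <= thr <= 1:
                raise ValueError("tissue probability thresholds must lie in [0, 1]")
        if self.seed is not None:
            self.phantom_spec = dc_replace(self.phantom_spec, seed=self.seed)
        if "rCBF" in self.scales and "aCBF" not in self.scales:
            raise ValueError(
                "rCBF scoring needs the aCBF within-session reference maps; "
                "include 'aCBF' in scales"
            )
        if tuple(self.scales) and tuple(self.scales)[0] != "aCBF":
            self.scales = ("aCBF",) + tuple(s for s in self.scales if s != "aCBF")


@dataclass
class StudyReport:
    """Bundle of every analysis product of :func:`run_study`."""

    config: StudyConfig
    phantom: Phantom
    masks: dict
    reliability_maps: dict  # (scale, mode) -> {"vc", "wscv", "icc", "mdc"}
    reliability_table: pd.DataFrame
    att: dict
    overlap_results: pd.DataFrame
    overlap_tables: dict  # scale -> aggregated DataFrame
    qc: pd.DataFrame
    event_counts: dict


def mask_from_probability(prob_map: np.ndarray, threshold: float) -> np.ndarray:
    """Dichotomous mask: voxel included iff probability >= threshold."""
    prob = np.asarray(prob_map, dtype=float)
    if (prob < 0).any() or (prob > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return prob >= threshold


def _quantify_run(ds, fwhm: float, voxel_size) -> tuple[np.ndarray, np.ndarray]:
    """Subtract, smooth the difference series, quantify per pair -> CBF series."""
    dm = ds.delta_m()
    smoothed = act.smooth_gaussian(dm.values, fwhm, voxel_size)
    cbf = quantify_cbf(
        smoothed, ds.m0_volume, float(ds.acquisition.pld),
        ds.acquisition.kinetic_params,
    )
    return cbf.values.astype(np.float32), ds.condition_labels


def att_variability(att_stack: np.ndarray, gm_mask: np.ndarray) -> dict:
    """Between-session and between-subject coefficients of variation of ATT.

    ``att_stack`` is (subjects, sessions, *volume); NaN marks voxels whose
    fit did not converge, and any voxel that is NaN for any subject/session
    is excluded from the grey-matter summaries.

    Between-session CV: per-subject SD over sessions divided by the
    per-subject mean (percent), averaged across subjects per voxel.
    Between-subject CV: SD of subject-mean ATT across subjects over the
    grand mean, per voxel.
    """
    stack = np.asarray(att_stack, dtype=float)
    if stack.shape[0] < 2 or stack.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    valid = np.isfinite(stack).all(axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        per_subj_cv = 100.0 * stack.std(axis=1, ddof=1) / stack.mean(axis=1)
        bse_cv = per_subj_cv.mean(axis=0)
        subj_means = stack.mean(axis=1)
        bsub_cv = 100.0 * subj_means.std(axis=0, ddof=1) / subj_means.mean(axis=0)
    sel = valid & np.asarray(gm_mask, bool)

    def _summ(vol: np.ndarray) -> tuple[float, float]:
        v = vol[sel]
        v = v[np.isfinite(v)]
        return (float(v.mean()), float(v.std(ddof=1))) if v.size > 1 else (np.nan, np.nan)

    gm_att_by_session = [
        float(np.nanmean(stack[:, k][:, sel].mean(axis=0))) for k in range(stack.shape[1])
    ]
    return {
        "between_session_cv_map": np.where(valid, bse_cv, np.nan),
        "between_subject_cv_map": np.where(valid, bsub_cv, np.nan),
        "gm_between_session_cv": _summ(bse_cv),
        "gm_between_subject_cv": _summ(bsub_cv),
        "gm_att_by_session": gm_att_by_session,
        "n_excluded_voxels": int((~valid & np.asarray(gm_mask, bool)).sum()),
    }


def _score_overlap(
    sig: dict, scale: str, subject: int, motor_mask: np.ndarray,
    sessions: range, runs: range,
) -> list[ovl.OverlapResult]:
    """Precision/Dice of every assembly against its within-session reference."""
    results = []
    tp_masks = {
        key: ovl.make_tp_mask(sig[act.WITHIN][key], motor_mask)
        for key in sig[act.WITHIN]
    }
    subj_id = f"sub-{subject:02d}"
    # within-session precision (candidate is the reference map itself)
    for (ses, run), cand in sig[act.WITHIN].items():
        tp, fp = ovl.overlap_counts(cand, tp_masks[(ses, run)])
        p = 100.0 * tp / (tp + fp) if tp + fp else np.nan
        results.append(ovl.OverlapResult(act.WITHIN, tp, fp, p, np.nan, subj_id, run))
    # within-session Dice: the two runs of a session compared to each other
    for ses in sessions:
        if (ses, 1) in sig[act.WITHIN] and (ses, 2) in sig[act.WITHIN]:
            a, b = sig[act.WITHIN][(ses, 1)], sig[act.WITHIN][(ses, 2)]
            d = ovl.dice(a, b) if (a.any() or b.any()) else np.nan
            results.append(
                ovl.OverlapResult(act.WITHIN + "_dice", 0, 0, np.nan, d, subj_id, None)
            )
    # different-run and between-session maps vs the within-session reference
    for label in [act.WITHIN_DR, *act.SEPARATION_LABELS.values()]:
        for key, cand in sig.get(label, {}).items():
            ref = sig[act.WITHIN][key]
            tp, fp = ovl.overlap_counts(cand, tp_masks[key])
            p = 100.0 * tp / (tp + fp) if tp + fp else np.nan
            d = ovl.dice(cand, ref) if (cand.any() or ref.any()) else np.nan
            results.append(ovl.OverlapResult(label, tp, fp, p, d, subj_id, key[1]))
    return results


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Execute the full pipeline on a synthetic cohort.

    Stages: phantom construction; per-run simulation, pairwise subtraction,
    smoothing and CBF quantification; within/between-session reliability
    maps on absolute and grey-matter-normalized CBF; multi-PLD (CBF, ATT)
    fits and ATT variability; contrast assembly, GLM and FWE thresholding;
    true-positive masks, precision and Dice aggregated by separation.
    Deterministic for a fixed config (one master seed).
    """
    events: dict = {}
    phantom = build_phantom(config.phantom_spec)
    vs = config.phantom_spec.voxel_size
    gm_mask = mask_from_probability(phantom.tissue_probs["gm"], config.gm_threshold)
    wm_mask = mask_from_probability(phantom.tissue_probs["wm"], config.wm_threshold)
    brain = mask_from_probability(
        phantom.tissue_probs["gm"] + phantom.tissue_probs["wm"], 0.5
    )
    masks = {"gm": gm_mask, "wm": wm_mask, "brain": brain}
    logger.info("phantom built: grid %s, GM %d, WM %d, brain %d voxels",
                phantom.grid_shape, gm_mask.sum(), wm_mask.sum(), brain.sum())

    subjects = range(1, config.n_subjects + 1)
    sessions = range(1, config.n_sessions + 1)
    runs = range(1, config.n_runs + 1)

    # --- simulate + quantify -------------------------------------------------
    cbf_runs: dict = {}   # (subj, ses, run) -> (series, conditions)
    rest_mean: dict = {}  # (subj, ses, run) -> rest-average CBF volume
    gm_rest_mean: dict = {}
    for s in subjects:
        for ses in sessions:
            for r in runs:
                ds = simulate_dataset(phantom, config.plan, config.acq, s, ses, r)
                series, cond = _quantify_run(ds, config.smooth_fwhm, vs)
                cbf_runs[(s, ses, r)] = (series, cond)
                rm = series[..., cond == "REST"].mean(axis=-1)
                rest_mean[(s, ses, r)] = rm
                gm_rest_mean[(s, ses, r)] = float(rm[gm_mask].mean())
    logger.info("simulated and quantified %d runs", len(cbf_runs))

    # --- reliability ---------------------------------------------------------
    vol_shape = phantom.grid_shape
    stack_a = np.empty((config.n_subjects, config.n_sessions, config.n_runs) + vol_shape)
    for s in subjects:
        for ses in sessions:
            for r in runs:
                stack_a[s - 1, ses - 1, r - 1] = rest_mean[(s, ses, r)]
    stacks = {"aCBF": stack_a}
    if "rCBF" in config.scales:
        stack_r = stack_a.copy()
        for s in subjects:
            for ses in sessions:
                for r in runs:
                    stack_r[s - 1, ses - 1, r - 1] = rel.normalize_global(
                        rest_mean[(s, ses, r)], gm_mask
                    )
        stacks["rCBF"] = stack_r

    n_pairs = config.acq.n_pairs
    df_glm = n_pairs - 2
    t_crit = float(stats.t.isf(config.alpha / int(brain.sum()), df_glm))
    reliability_maps: dict = {}
    rel_rows = []
    for scale in config.scales:
        for mode in ("within-session", "between-session"):
            vc = rel.fit_variance_components(stacks[scale], mode)
            maps = {
                "vc": vc,
                "wscv": rel.wscv_map(vc),
                "icc": rel.icc_map(vc),
                "mdc": rel.mdc_map(vc, n=n_pairs, t_crit=t_crit),
            }
            reliability_maps[(scale, mode)] = maps
            events[f"truncated_se[{scale},{mode}]"] = vc.n_truncated_se
            events[f"truncated_bs[{scale},{mode}]"] = vc.n_truncated_bs
            summ = rel.roi_summary(
                {k: maps[k] for k in ("wscv", "icc", "mdc")},
                {"gm": gm_mask, "wm": wm_mask},
            )
            summ.insert(0, "scale", scale)
            summ.insert(1, "mode", mode)
            rel_rows.append(summ)
    reliability_table = pd.concat(rel_rows, ignore_index=True)
    logger.info("reliability maps done (t_crit=%.3f, n=%d)", t_crit, n_pairs)

    # --- ATT -----------------------------------------------------------------
    att_report: dict = {}
    if config.att_acq is not None and config.n_subjects >= 2 and config.n_sessions >= 2:
        att_stack = np.full(
            (config.n_subjects, config.n_sessions) + vol_shape, np.nan
        )
        n_nonconv = 0
        vol_ratio = float(np.prod(vs) / np.prod(config.att_voxel_size))
        att_plan = dc_replace(
            config.plan, sd_temporal=config.plan.sd_temporal * vol_ratio
        )
        for s in subjects:
            for ses in sessions:
                ds = simulate_att_run(phantom, config.att_acq, att_plan, s, ses)
                _, att_map = fit_att_cbf(
                    ds.delta_m(), ds.m0_volume, config.att_acq.kinetic_params,
                    mask=gm_mask,
                )
                vals = np.where(att_map.converged, att_map.values, np.nan)
                att_stack[s - 1, ses - 1] = vals
                n_nonconv += int((~att_map.converged & gm_mask).sum())
        att_report = att_variability(att_stack, gm_mask)
        att_report["n_nonconverged"] = n_nonconv
        events["att_nonconverged"] = n_nonconv
        logger.info("ATT variability done (%d non-converged voxels)", n_nonconv)

    # --- activation + overlap ------------------------------------------------
    all_results: list[ovl.OverlapResult] = []
    motor_mask = phantom.region_mask("motor")
    between_labels = list(act.SEPARATION_LABELS.values())
    for s in subjects:
        per_scale_sig: dict = {}
        runs_a = {
            (ses, r): cbf_runs[(s, ses, r)] for ses in sessions for r in runs
        }
        assemblies = {"aCBF": act.assemble_contrasts(
            runs_a, tuple(sessions), tuple(runs))}
        if "rCBF" in config.scales:
            runs_r = {
                key: (series / gm_rest_mean[(s,) + key], cond)
                for key, (series, cond) in runs_a.items()
            }
            # within-session maps are scale-invariant; keep aCBF only
            assemblies["rCBF"] = [
                a for a in act.assemble_contrasts(runs_r, tuple(sessions), tuple(runs))
                if a.separation_label != act.WITHIN
            ]
        for scale in config.scales:
            sig: dict = {lab: {} for lab in [act.WITHIN, act.WITHIN_DR, *between_labels]}
            for asm in assemblies[scale]:
                res = act.fit_glm(asm, mask=brain)
                res = act.threshold_fwe(res, config.alpha, config.fwe_method)
                sig[asm.separation_label][asm.task_source] = res.significance_mask
            if scale == "rCBF":
                sig[act.WITHIN] = per_scale_sig["aCBF"][act.WITHIN]
            per_scale_sig[scale] = sig
            scored = _score_overlap(sig, scale, s, motor_mask, sessions, runs)
            for row in scored:
                all_results.append((scale, row))
    overlap_df = pd.DataFrame(
        [{"scale": sc, **vars(r)} for sc, r in all_results]
    )
    # fold the within-session Dice rows back into the within-session label
    overlap_df["separation_label"] = overlap_df["separation_label"].str.replace(
        act.WITHIN + "_dice", act.WITHIN, regex=False
    )
    overlap_tables = {
        sc: ovl.aggregate_by_separation(overlap_df[overlap_df["scale"] == sc])
        for sc in config.scales
    }
    logger.info("activation/overlap done: %d scored maps", len(overlap_df))

    # --- QC ------------------------------------------------------------------
    qc_rows = [
        {"subject": f"sub-{s:02d}", "session": ses, "run": r,
         "translation_mm": 0.0, "rotation_deg": 0.0}
        for s in subjects for ses in sessions for r in runs
    ]
    qc = rel.qc_motion_report(pd.DataFrame(qc_rows))

    report = StudyReport(
        config=config,
        phantom=phantom,
        masks=masks,
        reliability_maps=reliability_maps,
        reliability_table=reliability_table,
        att=att_report,
        overlap_results=overlap_df,
        overlap_tables=overlap_tables,
        qc=qc,
        event_counts=events,
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: StudyReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.reliability_table.to_csv(out / "reliability_roi.tsv", sep="\t", index=False)
    report.overlap_results.to_csv(out / "overlap_results.tsv", sep="\t", index=False)
    for scale, table in report.overlap_tables.items():
        table.to_csv(out / f"overlap_by_separation_{scale}.tsv", sep="\t", index=False)
    report.qc.to_csv(out / "qc_motion.tsv", sep="\t", index=False)
    summary = {
        "event_counts": report.event_counts,
        "att": {
            k: v for k, v in report.att.items() if not isinstance(v, np.ndarray)
        },
        "config": {
            "n_subjects": report.config.n_subjects,
            "n_sessions": report.config.n_sessions,
            "n_runs": report.config.n_runs,
            "seed": report.config.phantom_spec.seed,
            "alpha": report.config.alpha,
            "fwe_method": report.config.fwe_method,
            "smooth_fwhm": report.config.smooth_fwhm,
            "variance_plan": asdict(report.config.plan),
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
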