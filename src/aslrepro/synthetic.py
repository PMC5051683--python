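"""Synthetic multi-session pCASL study generator.

Builds a digital head phantom (tissue probability maps, CBF, ATT, M0, a
motor activation region) and simulates labeled/control image series for a
multi-subject, multi-session, multi-run study design: single-PLD rest/task
runs plus a low-SNR multi-PLD acquisition for transit-time mapping.

The signal model is hierarchical: per-voxel true CBF is perturbed by
additive Gaussian offsets at the subject, session and run level, and by a
multiplicative session-level global factor modelling day-to-day basal
fluctuations.  The control/tag pair signals are produced by the forward
kinetic model in :mod:`aslrepro.kinetics`, so noise-free generation is the
exact inverse of quantification (at zero transit time).

Reproducibility: one master seed; per-(subject, session, run) child
streams are derived with ``numpy.random.SeedSequence`` spawn keys so each
dataset is reproducible independently of generation order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .kinetics import KineticParams, DeltaMSeries, forward_delta_m, pairwise_subtract

__all__ = [
    "PhantomSpec",
    "Phantom",
    "VariancePlan",
    "AcquisitionSpec",
    "ASLDataset",
    "build_phantom",
    "simulate_dataset",
    "simulate_att_run",
    "write_study",
    "read_study",
]

#: static tissue signal after background suppression, as a fraction of M0
STATIC_SIGNAL_FRACTION = 0.3

REST, TASK = "REST", "TASK"


@dataclass
class PhantomSpec:
    """Parameters of the digital head phantom.

    Any of the explicit volume fields (``tissue_prob_maps`` etc.) may be
    supplied directly; when left ``None`` they are synthesized from the
    geometric defaults by :func:`build_phantom`.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size: tuple[float, float, float] = (3.8, 3.8, 6.0)
    cbf_by_tissue: dict = field(
        default_factory=lambda: {"gm": 60.0, "wm": 20.0, "csf": 0.0}
    )
    m0_by_tissue: dict = field(
        default_factory=lambda: {"gm": 1000.0, "wm": 850.0, "csf": 1150.0}
    )
    att_range: tuple[float, float] = (600.0, 1200.0)
    activation_fraction: float = 0.4
    activation_radius_vox: float = 2.4
    seed: int = 0
    # optional explicit volumes (override the synthesized geometry)
    tissue_prob_maps: dict | None = None
    att_field: np.ndarray | None = None
    activation_roi: np.ndarray | None = None
    tp_region_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.activation_fraction < 0:
            raise ValueError("activation fraction must be >= 0")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too small; need >= 8 voxels per axis")


@dataclass
class Phantom:
    """Ground-truth volume set produced by :func:`build_phantom`."""

    spec: PhantomSpec
    tissue_probs: dict  # name -> 3D probability map
    cbf_rest: np.ndarray  # ml/100g/min
    att: np.ndarray  # ms
    m0: np.ndarray
    activation_roi: np.ndarray  # bool
    region_labels: np.ndarray  # int label map
    region_names: dict  # name -> label value

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.cbf_rest.shape

    @property
    def cbf_task(self) -> np.ndarray:
        boost = 1.0 + self.spec.activation_fraction * self.activation_roi
        return self.cbf_rest * boost

    def region_mask(self, *names: str) -> np.ndarray:
        labels = [self.region_names[n] for n in names]
        return np.isin(self.region_labels, labels)


@dataclass
class VariancePlan:
    """Hierarchical variance components of the simulated study.

    Additive offsets (ml/100g/min) act on CBF at the subject, session and
    run level; ``sd_global_fraction`` is a multiplicative session-level
    whole-brain scaling (day-to-day basal fluctuation); ``sd_temporal`` is
    i.i.d. per-pair noise in dM signal units; ``sd_att_subject_fraction``
    is a multiplicative per-subject scaling of the transit-time field
    (transit times differ between people but are stable across sessions).
    Setting every SD to zero yields bit-identical repeats across sessions.
    """

    sd_between_subject: float = 5.0
    sd_between_session: float = 2.0
    sd_between_run: float = 1.0
    sd_temporal: float = 2.0
    sd_global_fraction: float = 0.10
    sd_att_subject_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class AcquisitionSpec:
    """pCASL acquisition timing and labeling parameters (ms)."""

    tau: float = 1500.0
    pld: float | tuple = 1200.0
    pairs_per_pld: int = 96
    alpha: float = 0.86
    t1a: float = 1650.0
    lambda_: float = 0.9
    condition_schedule: tuple | None = None  # per-pair REST/TASK

    @property
    def is_multi_pld(self) -> bool:
        return isinstance(self.pld, (tuple, list, np.ndarray))

    @property
    def pld_list(self) -> tuple:
        return tuple(self.pld) if self.is_multi_pld else (float(self.pld),)

    @property
    def n_pairs(self) -> int:
        return self.pairs_per_pld * len(self.pld_list)

    @property
    def kinetic_params(self) -> KineticParams:
        return KineticParams(
            lambda_=self.lambda_, alpha=self.alpha, tau=self.tau, t1a=self.t1a
        )

    def schedule(self) -> np.ndarray:
        """Per-pair condition labels; default = first half rest, second half task
        for single-PLD runs (rest period precedes each task period), all rest
        for multi-PLD transit-time runs."""
        if self.condition_schedule is not None:
            sched = np.asarray(self.condition_schedule, dtype=object)
            if sched.size != self.n_pairs:
                raise ValueError("condition_schedule length != number of pairs")
            return sched
        if self.is_multi_pld:
            return np.full(self.n_pairs, REST, dtype=object)
        half = self.n_pairs // 2
        return np.array([REST] * half + [TASK] * (self.n_pairs - half), dtype=object)

    def pld_per_pair(self) -> np.ndarray:
        return np.repeat(np.asarray(self.pld_list, dtype=float), self.pairs_per_pld)


@dataclass
class ASLDataset:
    """Control/tag series for one subject/session/run, with ground truth."""

    subject_id: str
    session_index: int
    run_index: int
    control_series: np.ndarray  # (x, y, z, pairs)
    tag_series: np.ndarray
    m0_volume: np.ndarray
    acquisition: AcquisitionSpec
    condition_labels: np.ndarray
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if self.control_series.shape != self.tag_series.shape:
            raise ValueError("control and tag series must have identical shape")
        if self.control_series.shape[-1] != len(self.condition_labels):
            raise ValueError("pair count does not match condition_labels length")

    def delta_m(self) -> DeltaMSeries:
        return pairwise_subtract(
            self.control_series,
            self.tag_series,
            self.acquisition.pld_per_pair(),
            self.condition_labels,
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Construct the ground-truth volume set.

    Geometry: an ellipsoidal brain with a white-matter core, a cortical
    grey-matter shell, a central CSF ventricle and CSF background; smooth
    tissue probabilities summing to one per voxel.  True CBF is the
    probability-weighted tissue mixture.  ATT increases smoothly toward
    medial voxels.  A spherical "motor" activation region sits in the
    lateral grey-matter shell; the label map names it (plus a contralateral
    control region) for precision scoring.
    """
    nx, ny, nz = spec.grid_shape
    if spec.tissue_prob_maps is not None:
        probs = {k: np.asarray(v, dtype=float) for k, v in spec.tissue_prob_maps.items()}
    else:
        ax = [np.linspace(-1.0, 1.0, n) for n in (nx, ny, nz)]
        ux, uy, uz = np.meshgrid(*ax, indexing="ij")
        rho = np.sqrt(ux**2 + uy**2 + uz**2)
        p_brain = _sigmoid((0.92 - rho) / 0.04)
        p_core = _sigmoid((0.60 - rho) / 0.05)
        p_vent = _sigmoid((0.18 - rho) / 0.04)
        gm = p_brain * (1.0 - p_core)
        wm = p_core * (1.0 - p_vent)
        csf = 1.0 - gm - wm
        probs = {"gm": gm, "wm": wm, "csf": csf}

    shapes = {v.shape for v in probs.values()}
    if len(shapes) != 1:
        raise ValueError("inconsistent grid shapes among tissue probability maps")
    grid = shapes.pop()
    total = sum(probs.values())
    if np.any([(v < -1e-9).any() or (v > 1 + 1e-9).any() for v in probs.values()]) or (
        np.abs(total - 1.0) > 1e-6
    ).any():
        raise ValueError("tissue probabilities must lie in [0,1] and sum to 1")

    cbf = sum(probs[t] * spec.cbf_by_tissue[t] for t in probs)
    m0 = sum(probs[t] * spec.m0_by_tissue[t] for t in probs)

    if spec.att_field is not None:
        att = np.asarray(spec.att_field, dtype=float)
    else:
        ax = [np.linspace(-1.0, 1.0, n) for n in grid]
        ux, uy, uz = np.meshgrid(*ax, indexing="ij")
        rho = np.sqrt(ux**2 + uy**2 + uz**2)
        lo, hi = spec.att_range
        att = lo + (hi - lo) * np.clip(1.0 - rho / 0.92, 0.0, 1.0)
    if att.shape != grid:
        raise ValueError("att_field grid shape mismatch")
    if np.any(att < 0):
        raise ValueError("att_field must be nonnegative")

    if spec.activation_roi is not None:
        roi = np.asarray(spec.activation_roi, dtype=bool)
        if roi.shape != grid:
            raise ValueError("activation_roi grid shape mismatch")
    else:
        centre = np.array([(n - 1) / 2.0 for n in grid])
        # lateral GM shell (rho ~ 0.76 along +x), mid-axial
        c = centre + np.array([0.76 * (grid[0] - 1) / 2.0, 0.0, 0.0])
        ii = np.indices(grid, dtype=float)
        dist = np.sqrt(sum((ii[k] - c[k]) ** 2 for k in range(3)))
        roi = dist <= spec.activation_radius_vox

    if spec.tp_region_labels is not None:
        labels = np.asarray(spec.tp_region_labels)
        names = {"motor": 1, "control_region": 2}
    else:
        from scipy.ndimage import binary_dilation

        labels = np.zeros(grid, dtype=np.int16)
        motor = binary_dilation(roi, structure=np.ones((3, 3, 3), bool), iterations=2)
        labels[motor] = 1
        mirror = roi[::-1, :, :]  # contralateral control region
        labels[mirror & (labels == 0)] = 2
        names = {"motor": 1, "control_region": 2}

    return Phantom(
        spec=spec,
        tissue_probs=probs,
        cbf_rest=cbf,
        att=att,
        m0=m0,
        activation_roi=roi,
        region_labels=labels,
        region_names=names,
    )


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Child generator keyed by a fixed spawn key (order-independent)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _draw_offsets(
    phantom: Phantom, plan: VariancePlan, subject: int, session: int, run: int
) -> dict:
    seed = phantom.spec.seed
    b = float(_rng(seed, 1, subject).normal(0.0, plan.sd_between_subject)) \
        if plan.sd_between_subject > 0 else 0.0
    s = float(_rng(seed, 2, subject, session).normal(0.0, plan.sd_between_session)) \
        if plan.sd_between_session > 0 else 0.0
    r = float(_rng(seed, 3, subject, session, run).normal(0.0, plan.sd_between_run)) \
        if plan.sd_between_run > 0 else 0.0
    g = 1.0 + (
        float(_rng(seed, 4, subject, session).normal(0.0, plan.sd_global_fraction))
        if plan.sd_global_fraction > 0 else 0.0
    )
    a = 1.0 + (
        float(_rng(seed, 7, subject).normal(0.0, plan.sd_att_subject_fraction))
        if plan.sd_att_subject_fraction > 0 else 0.0
    )
    return {
        "subject_offset": b,
        "session_offset": s,
        "run_offset": r,
        "global_factor": max(g, 0.05),
        "att_scale": max(a, 0.05),
    }


def _effective_cbf(true_cbf: np.ndarray, off: dict) -> np.ndarray:
    eff = true_cbf * off["global_factor"] + (
        off["subject_offset"] + off["session_offset"] + off["run_offset"]
    )
    if np.any(eff < 0):
        warnings.warn("negative effective CBF after offsets; clipping to 0")
        eff = np.clip(eff, 0.0, None)
    return eff


def _build_series(
    phantom: Phantom,
    plan: VariancePlan,
    acq: AcquisitionSpec,
    off: dict,
    noise_rng: np.random.Generator | None,
    subject: int,
    session: int,
    run: int,
) -> ASLDataset:
    params = acq.kinetic_params
    sched = acq.schedule()
    plds = acq.pld_per_pair()
    n_pairs = sched.size

    eff_rest = _effective_cbf(phantom.cbf_rest, off)
    boost = 1.0 + phantom.spec.activation_fraction * phantom.activation_roi
    eff_task = _effective_cbf(phantom.cbf_rest * boost, off)
    att_eff = phantom.att * off["att_scale"]

    # dM volumes are needed once per (condition, PLD) combination only
    dm_cache: dict = {}
    static = STATIC_SIGNAL_FRACTION * phantom.m0
    shape = phantom.grid_shape + (n_pairs,)
    control = np.empty(shape)
    tag = np.empty(shape)
    for i in range(n_pairs):
        key = (sched[i], plds[i])
        if key not in dm_cache:
            eff = eff_task if sched[i] == TASK else eff_rest
            dm_cache[key] = forward_delta_m(eff, att_eff, plds[i], phantom.m0, params)
        dm = dm_cache[key]
        control[..., i] = static + dm / 2.0
        tag[..., i] = static - dm / 2.0
    if noise_rng is not None and plan.sd_temporal > 0:
        sd = plan.sd_temporal / np.sqrt(2.0)
        control += noise_rng.normal(0.0, sd, size=shape)
        tag += noise_rng.normal(0.0, sd, size=shape)

    gt = {
        "cbf_rest_effective": eff_rest,
        "cbf_task_effective": eff_task,
        "cbf_rest_true": phantom.cbf_rest,
        "att_true": att_eff,
        **off,
    }
    return ASLDataset(
        subject_id=f"sub-{subject:02d}",
        session_index=session,
        run_index=run,
        control_series=control,
        tag_series=tag,
        m0_volume=phantom.m0.copy(),
        acquisition=acq,
        condition_labels=sched,
        ground_truth=gt,
    )


def simulate_dataset(
    phantom: Phantom,
    plan: VariancePlan,
    acq: AcquisitionSpec,
    subject: int,
    session: int,
    run: int,
) -> ASLDataset:
    """Simulate one single-PLD rest/task run for (subject, session, run)."""
    off = _draw_offsets(phantom, plan, subject, session, run)
    noise = _rng(phantom.spec.seed, 5, subject, session, run) \
        if plan.sd_temporal > 0 else None
    return _build_series(phantom, plan, acq, off, noise, subject, session, run)


def simulate_att_run(
    phantom: Phantom,
    acq: AcquisitionSpec,
    plan: VariancePlan | None = None,
    subject: int = 0,
    session: int = 1,
) -> ASLDataset:
    """Simulate a multi-PLD transit-time acquisition (all-rest pairs)."""
    if not acq.is_multi_pld:
        raise ValueError("simulate_att_run requires a list of PLDs")
    if len(set(acq.pld_list)) < 3:
        raise ValueError("fewer than 3 distinct PLDs: the fit would be under-determined")
    if plan is None:
        plan = VariancePlan(0.0, 0.0, 0.0, 0.0, 0.0)
    off = _draw_offsets(phantom, plan, subject, session, run=0)
    noise = _rng(phantom.spec.seed, 6, subject, session) if plan.sd_temporal > 0 else None
    return _build_series(phantom, plan, acq, off, noise, subject, session, run=0)


# ---------------------------------------------------------------------------
# on-disk study layout (BIDS-like)
# ---------------------------------------------------------------------------

def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def _save_nii(path: Path, data: np.ndarray, voxel_size) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size)), path)


def _sidecar(acq: AcquisitionSpec, sched: np.ndarray) -> dict:
    return {
        "LabelingDuration": acq.tau,
        "PostLabelingDelay": list(acq.pld_list),
        "PairsPerPLD": acq.pairs_per_pld,
        "LabelingEfficiency": acq.alpha,
        "ArterialBloodT1": acq.t1a,
        "PartitionCoefficient": acq.lambda_,
        "ConditionSchedule": [str(c) for c in sched],
    }


def write_study(
    out_dir: str | Path,
    phantom: Phantom,
    plan: VariancePlan,
    acq: AcquisitionSpec,
    n_subjects: int,
    n_sessions: int = 3,
    n_runs: int = 2,
    att_acq: AcquisitionSpec | None = None,
    force: bool = False,
) -> Path:
    """Write a simulated study tree (NIfTI + JSON sidecars + manifest).

    Layout: sub-XX/ses-YY/sub-XX_ses-YY_run-ZZ_asl.nii.gz with control and
    tag volumes interleaved (control first), one aslcontext TSV and JSON
    sidecar per series, one M0 per session, the ground truth under
    ``ground_truth/``, and a manifest recording seeds and parameters.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    vs = phantom.spec.voxel_size
    files: list[str] = []

    def _write_run(ds: ASLDataset, base: Path) -> None:
        n = ds.control_series.shape[-1]
        inter = np.empty(ds.control_series.shape[:-1] + (2 * n,), dtype=np.float32)
        inter[..., 0::2] = ds.control_series
        inter[..., 1::2] = ds.tag_series
        _save_nii(base.with_name(base.name + "_asl.nii.gz"), inter, vs)
        rows = "volume_type\n" + "\n".join(["control\nlabel"] * n) + "\n"
        base.with_name(base.name + "_aslcontext.tsv").write_text(rows)
        base.with_name(base.name + "_asl.json").write_text(
            json.dumps(_sidecar(ds.acquisition, ds.condition_labels), indent=1)
        )
        files.extend(
            str(base.with_name(base.name + ext).relative_to(out))
            for ext in ("_asl.nii.gz", "_aslcontext.tsv", "_asl.json")
        )

    for subj in range(1, n_subjects + 1):
        for ses in range(1, n_sessions + 1):
            ses_dir = out / f"sub-{subj:02d}" / f"ses-{ses:02d}"
            ses_dir.mkdir(parents=True, exist_ok=True)
            stem = f"sub-{subj:02d}_ses-{ses:02d}"
            _save_nii(ses_dir / f"{stem}_m0.nii.gz", phantom.m0, vs)
            files.append(str((ses_dir / f"{stem}_m0.nii.gz").relative_to(out)))
            for run in range(1, n_runs + 1):
                ds = simulate_dataset(phantom, plan, acq, subj, ses, run)
                _write_run(ds, ses_dir / f"{stem}_run-{run:02d}")
            if att_acq is not None:
                ds = simulate_att_run(phantom, att_acq, plan, subj, ses)
                _write_run(ds, ses_dir / f"{stem}_acq-att")

    gt_dir = out / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    _save_nii(gt_dir / "cbf_rest.nii.gz", phantom.cbf_rest, vs)
    _save_nii(gt_dir / "att.nii.gz", phantom.att, vs)
    _save_nii(gt_dir / "m0.nii.gz", phantom.m0, vs)
    _save_nii(gt_dir / "activation_roi.nii.gz", phantom.activation_roi, vs)
    _save_nii(gt_dir / "region_labels.nii.gz", phantom.region_labels, vs)
    for t, p in phantom.tissue_probs.items():
        _save_nii(gt_dir / f"prob_{t}.nii.gz", p, vs)

    manifest = {
        "seed": phantom.spec.seed,
        "n_subjects": n_subjects,
        "n_sessions": n_sessions,
        "n_runs": n_runs,
        "grid_shape": list(phantom.grid_shape),
        "voxel_size": list(vs),
        "variance_plan": asdict(plan),
        "acquisition": _sidecar(acq, acq.schedule()),
        "att_acquisition": _sidecar(att_acq, att_acq.schedule()) if att_acq else None,
        "region_names": phantom.region_names,
        "activation_fraction": phantom.spec.activation_fraction,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _read_run(base: Path) -> ASLDataset:
    img = nib.load(str(base) + "_asl.nii.gz")
    data = np.asarray(img.dataobj, dtype=np.float32)
    ctx = (Path(str(base) + "_aslcontext.tsv")).read_text().strip().splitlines()[1:]
    vt = np.array(ctx)
    control = data[..., vt == "control"]
    tag = data[..., vt == "label"]
    meta = json.loads(Path(str(base) + "_asl.json").read_text())
    pld = meta["PostLabelingDelay"]
    acq = AcquisitionSpec(
        tau=meta["LabelingDuration"],
        pld=tuple(pld) if len(pld) > 1 else pld[0],
        pairs_per_pld=meta["PairsPerPLD"],
        alpha=meta["LabelingEfficiency"],
        t1a=meta["ArterialBloodT1"],
        lambda_=meta["PartitionCoefficient"],
        condition_schedule=tuple(meta["ConditionSchedule"]),
    )
    name = base.name  # sub-XX_ses-YY_run-ZZ or sub-XX_ses-YY_acq-att
    parts = dict(p.split("-", 1) for p in name.split("_"))
    m0_img = nib.load(base.parent / f"sub-{parts['sub']}_ses-{parts['ses']}_m0.nii.gz")
    return ASLDataset(
        subject_id=f"sub-{parts['sub']}",
        session_index=int(parts["ses"]),
        run_index=int(parts.get("run", 0)),
        control_series=control,
        tag_series=tag,
        m0_volume=np.asarray(m0_img.dataobj, dtype=np.float32),
        acquisition=acq,
        condition_labels=np.array(meta["ConditionSchedule"], dtype=object),
    )


def read_study(path: str | Path) -> dict:
    """Load a study tree written by :func:`write_study`.

    Returns ``{"manifest": ..., "runs": {(subject, session, run): ASLDataset},
    "att_runs": {(subject, session): ASLDataset}, "ground_truth": {...}}``.
    """
    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    runs: dict = {}
    att_runs: dict = {}
    for subj in range(1, manifest["n_subjects"] + 1):
        for ses in range(1, manifest["n_sessions"] + 1):
            ses_dir = root / f"sub-{subj:02d}" / f"ses-{ses:02d}"
            stem = f"sub-{subj:02d}_ses-{ses:02d}"
            for run in range(1, manifest["n_runs"] + 1):
                runs[(subj, ses, run)] = _read_run(ses_dir / f"{stem}_run-{run:02d}")
            if manifest.get("att_acquisition"):
                att_runs[(subj, ses)] = _read_run(ses_dir / f"{stem}_acq-att")
    gt_dir = root / "ground_truth"
    gt = {
        p.name.replace(".nii.gz", ""): np.asarray(nib.load(p).dataobj, dtype=np.float32)
        for p in sorted(gt_dir.glob("*.nii.gz"))
    }
    return {"manifest": manifest, "runs": runs, "att_runs": att_runs, "ground_truth": gt}
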