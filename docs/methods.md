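# Methods

This note documents the models, estimators, numerical choices and known
limitations of `aslrepro`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and quantification

Control/tag pCASL pairs are subtracted element-wise; the difference ΔM is
converted to CBF with the single-compartment expression

    f = 6000 λ ΔM e^(PLD/T1a) / (2 α M0 T1a (1 − e^(−(τ+PLD)/T1a)))

All timings are milliseconds at the interface and seconds internally; the
factor 6000 converts ml g⁻¹ s⁻¹ to ml/100g/min. Defaults: λ = 0.9 g/ml,
α = 0.86, τ = 1500 ms, T1a = 1650 ms. The bracket (1 − e^(−(τ+PLD)/T1a)) is
a deliberate variant of the consensus single-PLD form (which uses
(1 − e^(−τ/T1a)) and is available via `model="consensus"`); keeping the
variant as the default makes quantification the exact algebraic inverse of
the forward model below at zero transit time, which in turn makes the whole
simulate → quantify chain testable to 1e-9 relative error.

Voxels with nonpositive M0 inside the analysis mask are flagged invalid
(NaN), never silently zeroed, so downstream averages cannot be biased by
fabricated zeros.

## Transit-time forward model and fit

The multi-delay model is single-compartment with arterial T1 decay only (no
dispersion, no tissue-T1 exchange, no crusher gradients):

    ΔM(f, att; PLD) = 0                                        PLD + τ ≤ att
    ΔM(f, att; PLD) = K e^(−max(att,PLD)/T1a) (1 − e^(−(τ+PLD−att)/T1a))

with K = 2 α M0 T1a f / (6000 λ). The expression is continuous in both att
and PLD, strictly decreasing in att while PLD ≥ att, and reduces to the
quantification inverse at att = 0.

`fit_att_cbf` averages pairs within each distinct PLD and solves, per
voxel, bounded nonlinear least squares over (f, att) with
f ∈ [0, 300] ml/100g/min and att ∈ [100, 3500] ms (scipy `least_squares`,
trf, analytic Jacobian). Starting points come from the att grid
{400, 800, 1200, 1600, 2000} ms; because the model is linear in f, the
profiled residual at each start is available in closed form, so the starts
are ranked exactly and only the best `n_refine` (default 2, up to all 5)
are optimized, the lowest-residual solution winning. This pruning changes
no result on the recovery grids tested (noise-free errors stay at the
optimizer tolerance, ~0.02 ms) and keeps a 2500-voxel grey-matter fit under
ten seconds. All-zero curves are flagged degenerate (f = 0, att at the
lower bound); non-convergent voxels are flagged and excluded from
grey-matter summaries.

## Synthetic study generator

The generator emulates a three-session test–retest motor-activation design:
per subject, three sessions of two rest/task runs (96 control-tag pairs per
run, first half rest then task; label duration 1500 ms, PLD 1200 ms), plus
one five-delay ATT acquisition per session (5 pairs per PLD at
{700, 1300, 1900, 2500, 3100} ms).

**Phantom** (default 32×32×16 voxels of 3.8×3.8×6 mm): an ellipsoidal
brain with a white-matter core, cortical grey-matter shell, central
ventricle and CSF background, built from smooth sigmoid probability maps
that sum to one per voxel. True CBF is the probability-weighted mixture of
tissue values (GM 60, WM 20, CSF 0 ml/100g/min); M0 likewise (GM 1000,
WM 850, CSF 1150 signal units). ATT rises smoothly from 600 ms at the brain
edge to 1200 ms medially. A spherical "motor" region (radius 2.4 voxels) in
the lateral grey-matter shell gains 40% CBF during task blocks; the label
map marks that region (dilated by two voxels to absorb smoothing spread)
plus a contralateral control region for precision scoring.

**Hierarchical variance model.** Effective CBF for a run is

    CBF_eff = CBF_true · (1 + activation·is_task) · g_session
              + b_subject + s_session + r_run

with additive Gaussian offsets b, s, r (defaults 5, 2, 1 ml/100g/min) and a
multiplicative session-level global factor g ~ 1 + N(0, 0.10) modelling
day-to-day basal fluctuation — the additive/multiplicative split is what
lets grey-matter normalization (rCBF) remove the global term while leaving
the additive ones. The transit-time field is scaled per subject by
1 + N(0, 0.10), constant across sessions: between-subject transit-time
variability in adults is roughly twice the between-session variability, and
without a subject-level term the generator would invert that ordering.
Negative effective CBF after offsets is clipped to zero with a warning.

Control and tag signals are `0.3·M0 ± ΔM/2` plus i.i.d. Gaussian noise; the
0.3 is a fixed stand-in for background-suppressed static tissue (only the
difference signal matters downstream). The per-pair ΔM noise SD defaults to
2.0 signal units, i.e. grey-matter ΔM SNR ≈ 5 per pair (GM ΔM ≈ 10 units at
f = 60, M0 = 1000, att ≈ 700 ms). For the low-resolution ATT acquisition
the pipeline scales that SD by the voxel-volume ratio of the two protocols
(3.8×3.8×6 vs 12×8×6 mm → factor ≈ 0.15), i.e. per-voxel SNR proportional
to voxel volume.

**Randomness.** One master seed; every random quantity is drawn from a
`numpy.random.SeedSequence` child keyed by a fixed tuple
(stream id, subject, session, run), so any dataset is reproducible
independently of generation order, and setting all variance components to
zero yields bit-identical repeats. Series are float64 so the noise-free
simulate → quantify round trip is exact to machine precision.

**What the generator does not emulate:** k-space acquisition and
through-plane blurring, background-suppression pulse timing, head motion
and realignment (an integer-voxel shift hook exists only to exercise the
3 mm / 3° QC report), spatially varying *subject* CBF patterns (subject
effects are scalar offsets — see Limitations), dispersion of the labeled
bolus, and partial-volume effects beyond the probabilistic mixture. Passing
tests therefore demonstrate correctness of the estimators under the stated
model, not performance on scanner data.

## Reliability estimation

Resting CBF per run is the mean over the rest pairs of the smoothed,
per-pair-quantified CBF series (isotropic Gaussian, FWHM 6 mm,
σ = FWHM/(2√(2 ln 2)); boundary handling by renormalized truncated kernel —
the filtered volume divided by the filtered all-ones volume — which
preserves constants exactly at edges; total signal is conserved exactly
only while the support stays clear of the grid boundary).

Per voxel, the balanced two-way table (subjects × repeats) gives mean
squares MS_R (subjects), MS_C (repeats), MS_E (residual), and
method-of-moments components

    σ²_er = MS_E,   σ²_se = max(0, (MS_C − MS_E)/n_subjects),
    σ²_bs = max(0, (MS_R − MS_E)/n_repeats),

with truncation events counted and reported. Within-session mode treats the
two runs of each session as repeats, estimating components per session and
averaging across sessions; between-session mode uses the per-subject
session means (runs averaged first). wsCV uses all non-subject variance,
sqrt(σ²_se + σ²_er), over the grand mean; ICC is σ²_bs over the total.
Voxels with zero total variance are flagged undefined (NaN) and excluded
from ROI averages rather than set to 0 or 1.

The minimal detectable change defaults to the standard paired-test form
ΔCBF_min = (SD/√n)·t_crit (n = pairs per run; t_crit = the Bonferroni
FWE-corrected t threshold of the within-session GLM). A variant that
*divides* by t_crit is kept behind `form="printed"`: the two conventions
circulate and the multiplicative one is the detectability bound consistent
with a paired t-test, so it is the default while the other remains
available for comparison.

**Estimator calibration.** The plug-in ICC ratio is biased at finite sample
size. Two facts matter for interpreting the tests: (i) the bias is O(1/n)
in the number of subjects only for the terms driven by σ̂²_bs and
truncation; (ii) σ̂²_se rests on n_repeats − 1 degrees of freedom no matter
how many subjects are scanned, so with a nonzero systemic component a
residual ratio bias persists at any subject count. The calibration test
therefore checks that the Monte-Carlo 95% interval of the estimates covers
the truth (and that the replicate mean sits within two replicate SDs),
rather than demanding an unbiased mean; the consistency test runs in the
σ²_se = 0 regime where every bias term genuinely shrinks with n.

## Activation mapping

CBF conversion happens per subtraction pair *before* the GLM, so the GLM
operates on CBF series. Contrasts concatenate a rest segment with a task
segment: same session and run (within-session), the other run of the same
session (within-session_DR), and rest from a later session against task
from an earlier one (session 2 vs 1 = "1-week", 3 vs 2 = "3-week",
3 vs 1 = "1-month"), for each run. rCBF series divide each run's volumes by
the grey-matter mean of that run's rest-segment average — the session
global factor then cancels from both segments without dividing the task
effect out of task volumes. Within-session maps are scale-invariant under
that normalization, so only the absolute-scale ones are computed.

The per-voxel GLM is OLS on [intercept, task indicator]; the task t equals
the pooled-variance two-sample t with df = N − 2. Pairs are treated as
serially independent (ASL difference series are approximately uncorrelated,
and no autocorrelation correction is applied). Testing is one-sided
(task > rest) by default. Zero residual variance yields t = 0 for a zero
effect and ±inf for a noiseless separation, keeping degenerate voxels
meaningful rather than silently null.

Family-wise error control is Bonferroni by default (p ≤ α/V over the
analysis mask, no cluster threshold) with permutation max-T as the exact
alternative: the threshold is the (1 − α) quantile of the maximum t over
condition-label permutations (observed labeling included; exhaustive
enumeration when the distinct labelings fit the budget or when a condition
has ≤ 10 volumes; an error if the permutation distribution cannot resolve
α). Random-field-theory FWE is out of scope: it needs smoothness estimation
that adds nothing testable here, while Bonferroni is conservative and
exactly checkable and permutation is exact under exchangeability.
Benjamini–Hochberg FDR is provided as a less stringent variant.

## Overlap scoring

The true-positive mask intersects the within-session activation map with
the union of task-related region labels, then applies one pass of
morphological dilation with the full 3×3×3 cube (a background voxel turns
on if the structuring element overlaps the mask anywhere; borders clipped).
A single dilation pass is the default — a conservative margin for
activation-pattern variation — with the pass count exposed. An
"anatomical" mode uses the region labels alone as the TP core, avoiding
re-use of task data. Precision is 100·TP/(TP+FP) of a candidate map against
the TP mask; Dice is 2|A∩B|/(|A|+|B|) against the within-session map that
shares the candidate's task source; the within-session Dice reference
compares the two runs of each session. Empty candidates (precision) and
empty pairs (Dice) are flagged undefined, not scored 0. Scores aggregate as
mean ± SD per separation label, with between-session rows also expressed as
a percentage of the within-session_DR mean; aggregation pools runs and
subjects within a label (the order is configurable through the per-row
table that is always emitted alongside).

## Pipeline and problem sizes

`run_study` executes simulate → quantify → reliability (within/between ×
aCBF/rCBF) → ATT fit and variability → contrasts → GLM → FWE → overlap,
logging truncation, undefined-voxel and convergence counts so no data loss
is silent, and is deterministic for a fixed config. The default replica
uses 4 subjects × 3 sessions × 2 runs on the 32×32×16 grid (~90 s on one
CPU), sized so that the full suite — including 500-repetition error-control
simulations and a 500-voxel noisy recovery study — runs comfortably on a
laptop. ATT fits are restricted to the grey-matter mask (≈ 2,500 voxels).

ATT variability: between-session CV is the per-subject SD over sessions
divided by the per-subject mean (×100), averaged across subjects per voxel;
between-subject CV is the SD of subject-mean ATT across subjects over the
grand mean. Grey-matter summaries are mean ± SD of voxel values; the
per-session grey-matter ATT means are reported alongside. Note the
small-sample SD factor: with 3 sessions the expected sample SD is
c₄(3) ≈ 0.886 of the population SD, so a planted 5% jitter is recovered as
≈ 4.4% — the tests account for this rather than "correcting" the estimator.

## Known limitations

* Subject effects are spatially constant scalars. Real subjects differ in
  spatial CBF topography; as a consequence the voxel-wise ICC of the
  replica is driven by a handful of shared scalar draws, and with few
  subjects σ̂²_bs can truncate to zero at every voxel simultaneously.
  Between-subject reliability numbers from the replica are therefore
  illustrative, not representative of scanner data.
* The forward model omits dispersion and tissue-T1 exchange; fitted ATT
  represents the labeling-plane-to-voxel delay of this idealized bolus.
* Single-PLD quantification assumes att = 0; with the phantom's nonzero
  transit times the absolute CBF maps are biased low by the known
  transit-time factor. Reliability and overlap metrics are ratios and are
  unaffected.
* No motion is simulated by default and realignment is out of scope; the QC
  report exists to flag magnitudes supplied by a generator manifest or an
  external preprocessing log.
* The permutation max-T assumes exchangeability of volumes under the null,
  which the generator satisfies by construction but drifting scanner data
  may not.
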