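# aslrepro

Longitudinal arterial spin labeling (ASL) analysis: quantify cerebral
blood flow (CBF) and arterial transit time (ATT) from labeled/control
pCASL series, map the voxel-wise test–retest reproducibility (wsCV) and
reliability (ICC) of resting CBF across runs and sessions, build rest/task
activation maps from contrasts assembled within and between sessions, and
score their agreement with precision and Dice overlap metrics.

The package is aimed at perfusion-MRI methods researchers who want to ask:
*if rest and task images are acquired days or weeks apart, how much
activation fidelity is lost to day-to-day fluctuations in basal blood flow
and transit time?* Because no public dataset accompanies that question at
the desk scale, `aslrepro` ships a synthetic multi-session study generator
with full ground truth — a digital head phantom plus a hierarchical noise
model — so every stage of the pipeline is testable end to end.

## The model

**Quantification.** Pair-wise subtraction of control and tag volumes gives
the perfusion-weighted signal ΔM, converted to flow with a
single-compartment model:

    f = 6000 · λ · ΔM · e^(PLD/T1a) / (2 α M0 T1a (1 − e^(−(τ+PLD)/T1a)))

with λ = 0.9 g/ml (blood/tissue partition coefficient), α = 0.86 (labeling
efficiency), τ = 1500 ms (label duration), T1a = 1650 ms (arterial blood
T1), PLD = 1200 ms (post-labeling delay), f in ml/100g/min. The consensus
single-PLD variant with the (1 − e^(−τ/T1a)) bracket is available via
`model="consensus"`.

**Transit time.** A one-compartment, arterial-T1-only forward model

    ΔM(f, att) = 0                                          PLD + τ ≤ att
    ΔM(f, att) = K e^(−max(att,PLD)/T1a) (1 − e^(−(τ+PLD−att)/T1a))   otherwise

(K = 2 α M0 T1a f / 6000 λ) reduces exactly to the inverse of the
quantification formula at att = 0. Five-delay acquisitions
(PLD ∈ {700, 1300, 1900, 2500, 3100} ms) are fit per voxel by bounded
multi-start nonlinear least squares over (f, att).

**Reliability.** Per voxel, a balanced two-way (subject × repeat)
repeated-measures ANOVA yields method-of-moments variance components
σ²_bs (between-subject), σ²_se (systemic), σ²_er (residual), from which

    wsCV(%) = 100 · sqrt(σ²_se + σ²_er) / mean,
    ICC     = σ²_bs / (σ²_bs + σ²_se + σ²_er),
    ΔCBF_min = (sqrt(σ²_se + σ²_er) / √n) · t_crit.

Within-session repeats are the two runs of a session; between-session
repeats are the per-subject session means. Analyses run on absolute CBF
(aCBF) and on CBF normalized by the mean grey-matter value (rCBF).

**Activation and overlap.** Rest/task CBF series are concatenated within
session, across runs (within-session_DR), and across sessions (1 week,
3 weeks, 1 month separations), fit with a per-voxel GLM
[intercept, task], and thresholded with family-wise error control
(Bonferroni, or permutation max-T) with no cluster-extent filter. A
true-positive mask — within-session activation intersected with the
task-related ("motor") region labels, dilated once by a 3×3×3 cube —
defines precision = 100·TP/(TP+FP); map agreement uses
Dice = 2|A∩B|/(|A|+|B|).

## Worked example

```sh
aslrepro run-all --out report --subjects 4 --seed 1
```

simulates the default study replica (4 subjects × 3 sessions × 2 runs of
96 control-tag pairs each, a 40% CBF increase in the motor region during
task blocks, 10% session-level global CBF fluctuation, plus one five-delay
ATT acquisition per session), then quantifies, maps reliability, runs all
contrasts and writes the report tables. It prints, among others:

```
GM within-session rCBF wscv: 1.3 +/- 0.287
GM within-session rCBF icc: 0.237 +/- 0.19
```

i.e. after grey-matter normalization the within-session voxel-wise
reproducibility of resting CBF is ~1.3% (the mean absolute-scale wsCV is
2.9%). The aggregated overlap table (`overlap_by_separation_aCBF.tsv`)
shows the cost of separating rest and task by days to a month on absolute
CBF:

| separation        | precision (%) | Dice |
|-------------------|---------------|------|
| within-session    | 99.8          | 0.92 |
| within-session_DR | 85.1          | 0.80 |
| 1-week            | 73.6          | 0.56 |
| 3-week            | 28.4          | 0.22 |
| 1-month           | 20.7          | 0.21 |

while the rCBF table shows that normalizing by mean grey-matter CBF
recovers most of that loss (between-session precision 78–99%, Dice
0.78–0.94) — global basal fluctuation, not anatomy, drives the false
activation. The ATT maps are stable across sessions (grey-matter
between-session CV 4.8 ± 2.1%) and vary more between subjects
(12.2 ± 2.8%), so transit time is not the limiting factor for longitudinal
comparisons in this regime.

Every stage is also callable on its own (`aslrepro simulate | quantify |
att-fit | reliability | activation | overlap`) or from Python:

```python
import aslrepro as ar

phantom = ar.build_phantom(ar.PhantomSpec(seed=1))
ds = ar.simulate_dataset(phantom, ar.VariancePlan(), ar.AcquisitionSpec(),
                         subject=1, session=1, run=1)
cbf = ar.quantify_cbf(ds.delta_m().mean("REST"), ds.m0_volume, 1200.0,
                      ds.acquisition.kinetic_params)
```

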