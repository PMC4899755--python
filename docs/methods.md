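# Methods

## Kinase activation model

The model tracks one conserved kinase pool (IKK or ERK under one stimulus)
switching between inactive `K` and active `K*`:

    dK*/dt = (k1·signal(t) + k4·PF(t)) · K/(km1 + K) − (k2 + k5·NF(t)) · K*/(km2 + K*)

with `K + K* = total` and `K*(0) = 0`. Both conversion arms are
Michaelis–Menten in their substrate. The assumptions baked in:

* **Activity units are relative.** Immunoblot quantification gives
  ratio-scale, unitless activities, so `total = 1` by default; the absolute
  scale is unidentifiable and is absorbed into `k1` and `k4`. For the same
  reason the signal amplitude is fixed at 1 during fitting.
* **Pre-stimulation baseline is zero.** `K*(0) = 0` treats the assay
  baseline as the origin; there is no basal (signal-independent) activation
  term.
* **Feedback enters as measured drives, not as state variables.** `PF(t)`
  (newly synthesized IAP protein: untreated minus cycloheximide-treated
  level, clipped at zero, normalized to its own maximum) and `NF(t)` (the
  per-gene max-normalized, pointwise-averaged expression kinetics of the
  negative regulators) are shape-preserving piecewise-cubic Hermite (pchip)
  interpolants of sampled kinetics. Pchip hits every knot exactly and never
  overshoots between monotone knots. Outside the sampled window the value is
  held constant — the model is only simulated inside the measured 0–120 min
  window, so holding is the least-assumption extrapolation. Knots are
  interpolated as measured, without smoothing.
* **The upstream signal is phenomenological.** `signal(t) =
  A·(e^(−a·t) − e^(−b·t))` with `b > a ≥ 0`: zero at stimulation, a single
  peak at `ln(b/a)/(b−a)`, then decay. No receptor-proximal mechanism is
  modelled. In the fitting vocabulary the rise rate is parametrized as
  `b = a + gap` with `gap > 0`, which keeps the pulse constraint inside box
  bounds.

Regime switches implement the perturbation experiments exactly: the
cycloheximide condition is `k4 = k5 = 0` (no protein synthesis, hence no
transcriptional feedback), the IAP-inhibitor condition is `k4 = 0`.
Mid-course interventions (e.g. inhibitor added 10 min after stimulation) stop
the integration at the event time, change the named parameter, and restart —
discontinuous right-hand sides are never handed to the adaptive solver.

Integration uses LSODA (stiff-capable) at rtol 1e-6 / atol 1e-9; both states
are integrated so conservation is a real numerical check (observed drift
< 1e-14). The right-hand side lives in one function
(`model_a_kinase._rhs`) so the structural form can be audited or amended in
one place. Fixed-step RK4 at Δt = 0.001 min serves as an independent
cross-check in the tests; agreement is ~1e-6, far inside the 1e-4 test
tolerance.

## Transcriptional readout

A single gene with synthesis-side Hill drive and first-order decay:

    dX/dt = k_syn · K*(t)^n / (k_half^n + K*(t)^n) − k_deg · X,  X(0) = 0

`X` is fold-induction above baseline (hence zero initial condition and no
basal transcription term; mRNA and protein are not distinguished and there
are no delays). Because the Hill term is monotone in `K*`, a pointwise-larger
kinase trajectory gives a pointwise-larger `X` — the structural reason
removing positive feedback can only lower the readout. Under constant drive
the equation has the closed form `(k_syn/k_deg)·H·(1 − e^(−k_deg t))`, used
as an exactness check (relative error ~1e-9 at rtol 1e-8).

Defaults for the demonstration readout: `k_syn = 0.05 /min`,
`k_deg = 0.02 /min` (≈35 min half-life), `k_half = 0.3` (mid-range of the
simulated activities), `n = 2` (mild cooperativity).

## Demonstration system (P0)

The packaged fixture is a plausible BCR→IKK-like system, chosen once:
`k1 = 0.5, k2 = 0.15, k4 = 0.25, k5 = 0.4 /min`, `km1 = 0.5, km2 = 0.3`,
`total = 1`, signal `a = 0.02, b = 0.15 /min` (pulse peaking ≈15.5 min).
The negative regulator peaks at 30 min (A20-like immediate-early kinetics);
IAP synthesis follows the same induction pulse with 0.01 /min protein
turnover, giving a cumulative newly-synthesized curve that saturates late.
These values produce the qualitative phenotype of interest — positive
feedback extends time-above-half-maximum from ~35 to ~113 min and raises
late-window readout expression ~4.6-fold — without being estimates of any
real dataset.

## Parameter estimation

The loss is a weighted sum of squares over regimes and timepoints,
`Σ ((model − mean)/max(sd, floor))²` with `floor = 0.05·max(mean)` per
curve: a duplicate-based sample s.d. is an unstable weight and is exactly
zero for noiseless synthetic data. Optimization is bounded least squares
(trust-region reflective) in log10 parameter space, multi-started from
log-uniform draws (default 20 starts; ties broken by lowest start index;
deterministic given the problem seed). Stages follow the perturbation logic:

1. CHX curve → `k1, k2, km1, km2, a, gap` with `k4 = k5 = 0`;
2. inhibitor curve → `k5`, stage-1 estimates frozen;
3. wild-type curve → `k4`, everything else frozen.

`fit_staged(..., joint_refine=True)` then re-optimizes all free parameters
against all regimes, warm-started from the staged solution. Inside the
objective the forward model is a numba-compiled fixed-step RK4 (Δt =
0.02 min) with the feedback drives precomputed on the half-step grid; its
error (~1e-9) is far below measurement noise, and the public `simulate`
keeps the adaptive solver.

**Identifiability.** With noiseless data the staged fit recovers the
generating parameters essentially exactly (< 1e-5 relative). With realistic
duplicate measurements at 10% CV, the six-parameter feedback-free core is
practically non-identifiable from the single CHX curve: `km1`/`k1` and
`km2`/`k2` trade off along sloppy Michaelis-scaling directions, and the best
stage-1 fit routinely beats the generating parameters' own loss. Those core
errors propagate into `k4` and `k5`. Joint refinement (recommended, and the
pipeline default) reduces the median relative error over 20 noise
realizations to ≈20% for `k4` and ≈30% for `k5`; this is the statistical
limit of the design, not an optimizer failure — multi-start joint fits find
the same optima. `profile_parameter` exposes the diagnostics: profiles are
sharply curved around `k4`/`k5` given a fixed core, and flat along the
constructed `k1`–`km1` degeneracy when `km1 ≫ total`. Users who need tighter
feedback-rate estimates should tighten the core first (more timepoints or
replicates in the CHX arm, or an independently measured signal pulse).

## Transcriptome screen

Input is a log-scale genes × (condition, time, replicate) matrix; every
condition must include the time-0 baseline, and matrices with missing values
are rejected rather than imputed. Per gene, responsiveness is a one-way
ANOVA across timepoint groups (replicates within timepoints), adjusted by
Benjamini–Hochberg over all genes; genes with q < FDR (default 0.05) are
selected. This statistic needs ≥ 2 replicates per timepoint (the within-group
degrees of freedom); with duplicates it controls the false discovery rate as
advertised but has limited power — a 3-s.d. peak effect needs roughly
quadruplicate measurements to reach 90% detection. Any selected-gene counts
are therefore method- and design-dependent.

Selected profiles are replicate-averaged, z-scored per gene across
timepoints (shape, not amplitude, drives the grouping), and clustered with
k-means (k = 8 by default, k-means++ seeding, 50 restarts, best inertia,
deterministic under the seed). Cluster ids are renumbered by centroid peak
time so "cluster 1" is reproducibly the earliest-peaking **induced** cluster;
centroids whose z-scored maximum sits at t = 0 (down-regulated or flat
profiles, i.e. never induced) sort after all rising clusters. Triage returns
the members of cluster 1 ranked by raw induction amplitude (profile maximum
minus its time-0 value) — the shortlist where immediate-early feedback
regulators such as A20 surface.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis assumes:

* duplicate kinase measurements on a 0–120 min, 10-min grid with
  multiplicative lognormal noise (mean-one; `cv` default 0.1 — the assays'
  true noise magnitude is unknown, so `cv` is a fixture parameter, not a
  claim about data);
* early-peaking regulator kinetics as difference-of-exponential pulses,
  normalized to per-gene maxima, zero at t = 0;
* cumulative IAP levels under untreated vs synthesis-blocked conditions via
  the exact integrating-factor solution, with newly synthesized protein as
  their clipped difference;
* expression matrices at the 0/15/30/45/60/90-min design with planted
  temporal clusters (four canonical shapes — immediate transient, sustained
  rise, mid pulse, late ramp — in up- and down-regulated versions; peak
  log2 induction `effect_size` default 2.0 ≈ 4-fold, typical for
  immediate-early genes) plus time-invariant null genes.

Every generator is a pure function of its arguments including the seed.
Not emulated: array-platform artefacts (probe effects, normalization),
correlated noise between timepoints, cell-to-cell heterogeneity, and any
mRNA-versus-protein distinction. Passing tests on these fixtures therefore
demonstrate correctness and calibration of the *methods*, not performance on
any real microarray or immunoblot dataset.

## Numerical and design choices

* Solver tolerances: rtol 1e-6 / atol 1e-9 (simulation); rtol 1e-9 for
  ground-truth generation; rtol 1e-8 for the readout gene.
* Tiny negative solver excursions (≤ 1e-6·total) are clipped to zero;
  anything larger raises a model-violation error.
* Duration (time above half-maximum) interpolates the threshold crossings
  linearly; AUC is trapezoidal; an all-zero trajectory has zero duration by
  convention.
* k-means ties in centroid peak time break by raw cluster index; triage ties
  in amplitude break alphabetically — all orderings are deterministic.
* The pipeline fans one top-level seed out per stage through a counter
  (`SeedSequence([seed, stage_index])`), so runs are reproducible from
  config + seed alone and stages stay independently reseedable.

## Problem sizes

The shipped studies use the sizes stated above: 13 timepoints per regime,
duplicate replicates, 20 noise realizations for the recovery study, and
900-gene matrices (8 × 50 planted + 500 null) for the screen; the full test
suite and the acceptance script each run in about a minute on one CPU.
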