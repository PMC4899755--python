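# bsignal

Transcriptional-feedback control of kinase activation dynamics in B cells —
an ODE modelling and screening toolkit, fully exercisable on synthetic data.

## The problem

When B cells are stimulated through the B-cell receptor (BCR) or CD40, the
kinases IKK and ERK switch on quickly but differ strikingly in how *long*
they stay active. That duration is not set by the receptor-proximal
machinery alone: newly transcribed genes feed back on the pathway within the
first hour. An E3 ubiquitin ligase of the IAP family (cIAP1/BIRC2) acts as a
transcriptionally induced **positive** regulator that prolongs kinase
activity, while immediate-early genes such as A20 (TNFAIP3), DUSP5 and SPRY2
act as **negative** regulators. `bsignal` implements the complete
computational side of that analysis for anyone studying stimulus-dependent
feedback on signalling dynamics:

* a kinase activation model driven by a transient upstream signal and by
  measured feedback kinetics,
* a Hill-type gene-expression readout that converts kinase duration into
  late-phase transcription,
* staged parameter estimation from perturbation time courses
  (cycloheximide, IAP inhibitor, wild type),
* in-silico feedback knockouts and mid-course inhibitor interventions,
* the upstream time-course transcriptome screen (FDR selection, k-means
  clustering, candidate triage) that nominates feedback regulators,
* synthetic-data generators for every input, so nothing needs downloading.

## The model

A conserved kinase pool cycles between inactive (`K`) and active (`K*`)
states with Michaelis–Menten kinetics; transcriptional feedback enters
through two measured, time-dependent drives:

```
dK*/dt = (k1·signal(t) + k4·PF(t)) · K/(km1 + K)  −  (k2 + k5·NF(t)) · K*/(km2 + K*)
K + K* = total,   K*(0) = 0
```

* `signal(t) = A·(e^(−a·t) − e^(−b·t))`, `b > a` — a phenomenological pulse
  of upstream receptor activity (zero at stimulation, single peak, decay).
* `PF(t)` — newly synthesized IAP protein (untreated minus
  cycloheximide-treated level), pchip-interpolated and normalized to its own
  maximum; its scale is absorbed into `k4`.
* `NF(t)` — the average of the negative regulators' expression kinetics,
  each normalized to its own maximum (A20 for BCR; DUSP5 + SPRY2 for CD40).
* Setting `k4 = 0` reproduces the IAP-inhibitor condition ("no positive
  feedback"); `k4 = k5 = 0` the cycloheximide condition ("no feedback").

Downstream, a readout gene X follows the minimal transcriptional motif

```
dX/dt = k_syn · K*(t)^n / (k_half^n + K*(t)^n) − k_deg · X,   X(0) = 0
```

so a kinase that stays above `k_half` longer sustains late-phase expression.

Fitting is staged to mirror the perturbation logic: the cycloheximide curve
pins the feedback-free core (`k1, k2, km1, km2` and the signal pulse), the
inhibitor curve adds `k5`, the wild-type curve adds `k4`; an optional joint
refinement re-polishes all parameters against all three curves.

## Worked example

`python examples/simulate_feedback_knockouts.py` prints:

```
scenario                  peak  peak_t  t_half     auc
full                     0.427   120.0   113.1    34.6
no_positive              0.229    11.0    35.4    11.8
no_feedback              0.733    21.5    60.6    46.7
inhibitor_at_10min       0.245    10.0    31.7    11.9
```

`t_half` is the time (minutes) the active kinase spends above half its
peak — the central duration phenotype. With the full feedback circuit the
demonstration system stays active for 113 min of the 120-min window; remove
the positive feedback (or add the IAP inhibitor 10 min after stimulation)
and duration collapses to ~32–35 min. Without any transcriptional feedback
the curve is taller (no negative feedback pulling it down) but not
sustained. Feeding these trajectories into the readout gene
(`python examples/expression_readout.py`):

```
regime          X peak  X t_half late mean X
full             1.246      61.9       0.948
no_positive      0.298     103.2       0.208
```

late-window (t ≥ 60 min) expression is 4.6-fold higher with the positive
feedback — the mechanism by which IAP induction converts kinase duration
into sustained gene expression.

The other examples cover parameter fitting from noisy duplicates
(`fit_parameters.py`), the transcriptome screen on a planted matrix
(`run_screen.py`), and the one-config end-to-end pipeline
(`end_to_end_pipeline.py`). A thin CLI wraps the pipeline:
`bsignal run --outdir out --seed 1` (subcommands: `run`, `synth`,
`simulate`, `fit`, `screen`, `report`, `validate`).

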