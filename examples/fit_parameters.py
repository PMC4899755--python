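"""Staged parameter estimation from the three perturbation regimes.

Generates duplicate noisy measurements of the kinase time course under
cycloheximide (no transcriptional feedback), IAP inhibitor (no positive
feedback) and wild-type conditions, then runs the staged fit: the CHX data
pin the feedback-free core, the inhibitor data add the negative-feedback
rate k5, wild-type data add the positive-feedback rate k4.  The optional
joint refinement re-polishes all parameters against all three curves.
"""

import numpy as np

import bsignal as b
from bsignal import fitting
from bsignal.presets import demo_feedback_inputs, demo_kinase_params

truth = demo_kinase_params()
pf, nf = demo_feedback_inputs()
grid = np.arange(0.0, 121.0, 10.0)

datasets = {}
for i, regime in enumerate(("no_feedback", "no_positive", "full")):
    clean = b.generate_true_kinase_timecourse(truth, pf, nf, regime=regime, grid=grid)
    datasets[regime] = b.add_measurement_noise(clean, b.NoiseSpec(cv=0.1, n_replicates=2, seed=10 + i))

problem = b.FitProblem(datasets=datasets, pf=pf, nf=nf, n_starts=8, seed=0)
result = b.fit_staged(problem, joint_refine=True)

true_vals = fitting.params_to_dict(truth)
print(f"{'parameter':<12}{'true':>8}{'estimate':>10}{'rel err %':>10}")
for name, est in result.estimates.items():
    t = true_vals[name]
    print(f"{name:<12}{t:>8.3f}{est:>10.3f}{100 * abs(est - t) / t:>10.1f}")
print(f"\nweighted SSR = {result.loss:.2f} over {sum(len(tc) for tc in datasets.values())} points")
print(
    "Estimates come from duplicate measurements at 10% noise; the feedback"
    "\nrates k4/k5 typically carry ~20-40% uncertainty at this noise level."
)
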