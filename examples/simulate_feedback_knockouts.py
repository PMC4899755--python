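"""Simulate kinase activation with, without, and with partially removed feedback.

Builds the demonstration system (a BCR→IKK-like pair), runs the kinase model
under the three regulatory regimes plus a mid-course IAP-inhibitor
intervention, and prints duration metrics.  The time-above-half-maximum is
the central phenotype: transcriptionally induced positive feedback (newly
synthesized IAP) prolongs it.
"""

import bsignal as b
from bsignal.presets import demo_feedback_inputs, demo_kinase_params

params = demo_kinase_params()
pf, nf = demo_feedback_inputs()

print(f"{'scenario':<22}{'peak':>8}{'peak_t':>8}{'t_half':>8}{'auc':>8}")
for regime in ("full", "no_positive", "no_feedback"):
    traj = b.simulate(params, pf=pf, nf=nf, regime=regime)
    m = b.duration_metrics(traj)
    print(f"{regime:<22}{m['peak']:>8.3f}{m['peak_time']:>8.1f}{m['t_half_duration']:>8.1f}{m['auc']:>8.1f}")

# IAP inhibitor added 10 min after stimulation: k4 -> 0 mid-course
sched = b.InterventionSchedule(events=((10.0, "k4", 0.0),))
traj = b.simulate(params, pf=pf, nf=nf, regime="full", schedule=sched)
m = b.duration_metrics(traj)
print(f"{'inhibitor_at_10min':<22}{m['peak']:>8.3f}{m['peak_time']:>8.1f}{m['t_half_duration']:>8.1f}{m['auc']:>8.1f}")

print(
    "\nt_half is the time (min) the active kinase spends above half its peak:"
    "\nremoving the positive feedback (no_positive, or the 10-min inhibitor)"
    "\nshortens it relative to the full model."
)
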