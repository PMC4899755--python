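"""Feed simulated kinase activity into the Hill-type gene-expression readout.

Compares the readout gene X under the full model and under the model without
positive feedback: a kinase that stays active longer keeps the Hill drive on
longer, so the late-phase (t >= 60 min) expression stays high.
"""

import bsignal as b
from bsignal.presets import demo_feedback_inputs, demo_kinase_params, demo_model_b_params

params = demo_kinase_params()
pf, nf = demo_feedback_inputs()
pb = demo_model_b_params()

report = b.compare_feedback_outputs(params, pb, pf, nf)

print(f"{'regime':<14}{'X peak':>8}{'X t_half':>10}{'late mean X':>12}")
for regime in ("full", "no_positive"):
    entry = report["regimes"][regime]
    em = entry["expression_metrics"]
    print(f"{regime:<14}{em['peak']:>8.3f}{em['t_half_duration']:>10.1f}{entry['late_mean_expression']:>12.3f}")

ratio = report["regimes"]["full"]["late_mean_expression"] / report["regimes"]["no_positive"]["late_mean_expression"]
print(f"\npointwise dominance X_full >= X_no_positive: {report['dominance_ok']}")
print(f"late-window expression ratio (full / no positive): {ratio:.2f}")
print(
    "Without positive feedback the kinase input decays early, so the gene's"
    "\nlate-phase expression collapses — elevated and sustained output needs"
    "\nthe IAP-driven prolongation of kinase activity."
)
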