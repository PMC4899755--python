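"""Canonical demonstration fixture: one fully specified (stimulus, kinase) system.

These are the generating parameters used throughout the examples, tests and
the end-to-end pipeline when no user values are supplied — a plausible
BCR-to-IKK-like system on the 0–120 min window, not estimates from any
particular experiment.  The signal pulse peaks around 15 min, the negative
regulator (A20-like) expression peaks at 30 min, IAP synthesis accumulates
over the first hour, and positive feedback visibly prolongs the active-kinase
phase.
"""

from __future__ import annotations

import numpy as np

from .feedback_inputs import FeedbackInput, build_negative_feedback, build_positive_feedback
from .model_a_kinase import ModelAParams, SignalParams
from .model_b_expression import ModelBParams
from .synthetic_data import DEFAULT_KINASE_GRID, generate_iap_synthesis, generate_regulator_kinetics

__all__ = ["P0", "demo_kinase_params", "demo_model_b_params", "demo_feedback_inputs"]


def demo_kinase_params() -> ModelAParams:
    """The fixture parameter set P0 for the kinase model."""
    return ModelAParams(
        k1=0.5,
        k2=0.15,
        k4=0.25,
        k5=0.4,
        km1=0.5,
        km2=0.3,
        total=1.0,
        signal_params=SignalParams(amplitude=1.0, rise_rate=0.15, decay_rate=0.02),
    )


#: Alias used in test fixtures and docs.
P0 = demo_kinase_params


def demo_model_b_params() -> ModelBParams:
    """Readout-gene parameters: ~35 min transcript half-life, cooperative drive."""
    return ModelBParams(k_syn=0.05, k_deg=0.02, k_half=0.3, n=2.0)


def demo_feedback_inputs(grid=DEFAULT_KINASE_GRID) -> tuple[FeedbackInput, FeedbackInput]:
    """(PF, NF) built the same way the pipeline builds them from data.

    NF averages an A20-like regulator pulse peaking at 30 min; PF comes from
    the newly synthesized IAP difference curve (untreated minus CHX) with a
    synthesis rate proportional to a 30-min regulator pulse and a slow
    protein turnover.
    """
    grid = np.asarray(grid, dtype=float)
    regulator = generate_regulator_kinetics(peak_time=30.0, decay_rate=0.02, grid=grid)
    nf = build_negative_feedback([regulator])
    rate = generate_regulator_kinetics(peak_time=30.0, decay_rate=0.02, grid=grid)
    _, _, newly = generate_iap_synthesis(rate, degradation=0.01, grid=grid, initial_level=1.0)
    pf = build_positive_feedback(newly)
    return pf, nf
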