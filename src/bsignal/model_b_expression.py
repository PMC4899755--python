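"""Downstream transcriptional readout of kinase activity (model B).

A single gene X is synthesized under a Hill-type drive from the active kinase
and decays with first-order kinetics:

    dX/dt = k_syn · Kinase*(t)^n / (k_half^n + Kinase*(t)^n) − k_deg · X

with X(0) = 0 (fold-induction above baseline).  This is the minimal
transcriptional motif: synthesis saturates in kinase activity with
half-saturation k_half and steepness n; decay is kinase-independent.  Because
the Hill term is monotone in its input, a pointwise-larger kinase trajectory
yields a pointwise-larger expression trajectory — which is how
feedback-lengthened kinase duration translates into sustained late-phase
gene expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .feedback_inputs import FeedbackInput
from .model_a_kinase import KinaseTrajectory, ModelAParams, duration_metrics, simulate

__all__ = ["ModelBParams", "GeneTrajectory", "simulate_expression", "constant_input_solution", "compare_feedback_outputs"]


@dataclass(frozen=True)
class ModelBParams:
    """Synthesis/decay rates and Hill parameters of the readout gene."""

    k_syn: float   # maximal synthesis rate, expression units/min
    k_deg: float   # first-order decay rate, 1/min
    k_half: float  # Hill half-saturation threshold, activity units
    n: float = 1.0  # Hill coefficient

    def __post_init__(self) -> None:
        for name in ("k_syn", "k_deg", "k_half", "n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def hill(self, active):
        a = np.asarray(active, dtype=float)
        an = np.power(a, self.n)
        return an / (self.k_half**self.n + an)


@dataclass(frozen=True)
class GeneTrajectory:
    """Expression level X(t), relative units, X(0) = 0."""

    times: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_min": self.times, "expression": self.x})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_expression(
    kinase_traj: KinaseTrajectory,
    p: ModelBParams,
    t_eval=None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> GeneTrajectory:
    """Integrate the readout gene driven by a simulated kinase trajectory.

    The active-kinase input is linearly interpolated between the
    trajectory's output points.
    """
    if kinase_traj.times.size == 0:
        raise ValueError("empty kinase trajectory")
    kt, ka = kinase_traj.times, kinase_traj.active
    if t_eval is None:
        t_eval = kt
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval[0] < kt[0] or t_eval[-1] > kt[-1]:
        raise ValueError("requested window extends beyond the kinase trajectory")

    def rhs(t, y):
        active = np.interp(t, kt, ka)
        return [p.k_syn * float(p.hill(active)) - p.k_deg * y[0]]

    sol = solve_ivp(
        rhs,
        (t_eval[0], t_eval[-1]),
        [0.0],
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        max_step=float(np.min(np.diff(kt))) if kt.size > 1 else np.inf,
    )
    if not sol.success:
        raise RuntimeError(f"expression solver failed: {sol.message}")
    return GeneTrajectory(times=sol.t, x=np.clip(sol.y[0], 0.0, None))


def constant_input_solution(times, c: float, p: ModelBParams) -> GeneTrajectory:
    """Closed-form X(t) for constant kinase input c.

    With a constant drive H = c^n/(k_half^n + c^n) the linear ODE solves to
    X(t) = (k_syn/k_deg)·H·(1 − e^(−k_deg·t)).
    """
    times = np.asarray(times, dtype=float)
    h = float(p.hill(c))
    return GeneTrajectory(times=times, x=(p.k_syn / p.k_deg) * h * (1.0 - np.exp(-p.k_deg * times)))


def compare_feedback_outputs(
    params_a: ModelAParams,
    p: ModelBParams,
    pf: FeedbackInput | None,
    nf: FeedbackInput | None,
    window: tuple[float, float] = (0.0, 120.0),
    late_window_start: float = 60.0,
    t_eval=None,
) -> dict:
    """Run model A with and without positive feedback and compare the readout.

    Returns per-regime kinase and gene trajectories plus duration metrics of
    X, and verifies the structural dominance X_full(t) >= X_no_positive(t)
    that follows from PF >= 0 and the monotone Hill drive.
    """
    report: dict = {"regimes": {}}
    trajs = {}
    for regime in ("full", "no_positive"):
        kin = simulate(params_a, pf=pf, nf=nf, regime=regime, window=window, t_eval=t_eval)
        gene = simulate_expression(kin, p)
        trajs[regime] = (kin, gene)
        late = gene.times >= late_window_start
        report["regimes"][regime] = {
            "kinase": kin,
            "gene": gene,
            "kinase_metrics": duration_metrics(kin),
            "expression_metrics": duration_metrics(
                KinaseTrajectory(gene.times, gene.x, np.zeros_like(gene.x), total=1.0)
            ),
            "late_mean_expression": float(np.mean(gene.x[late])) if late.any() else float("nan"),
        }
    x_full = trajs["full"][1].x
    x_nopos = trajs["no_positive"][1].x
    gap = x_nopos - x_full
    report["dominance_ok"] = bool(np.all(gap <= 1e-7 * max(1.0, float(np.max(x_full), ))))
    report["max_dominance_violation"] = float(np.max(gap, initial=0.0))
    report["late_mean_ratio"] = (
        report["regimes"]["no_positive"]["late_mean_expression"]
        / report["regimes"]["full"]["late_mean_expression"]
        if report["regimes"]["full"]["late_mean_expression"] > 0
        else float("nan")
    )
    return report
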