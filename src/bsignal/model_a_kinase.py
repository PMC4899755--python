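"""Kinase activation model with transcriptional feedback (model A).

A single conserved kinase pool (IKK or ERK) cycles between an inactive and an
active state.  Activation is driven by a transient upstream signal and by the
transcriptionally induced positive feedback PF(t) (newly synthesized IAP);
deactivation has a basal component plus the induced negative feedback NF(t).
Both conversion rates follow Michaelis–Menten kinetics in their substrate:

    d[Kinase*]/dt = (k1·signal(t) + k4·PF(t)) · [Kinase] / (km1 + [Kinase])
                  − (k2 + k5·NF(t)) · [Kinase*] / (km2 + [Kinase*])

with [Kinase] + [Kinase*] = total conserved.  Setting k4 = 0 removes the
positive feedback (the IAP-inhibitor regime); k4 = k5 = 0 removes all
transcriptional feedback (the cycloheximide regime).  Mid-course
interventions — e.g. adding the IAP inhibitor 10 min after stimulation — are
modelled by stopping the integration at the event time, changing the named
parameter, and restarting, which keeps the stiff solver honest across the
discontinuity.

The upstream signal is a phenomenological two-exponential pulse
A·(e^(−a·t) − e^(−b·t)) with b > a ≥ 0: zero at t = 0, a single peak at
ln(b/a)/(b−a), decaying back to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .feedback_inputs import FeedbackInput

__all__ = [
    "SignalParams",
    "ModelAParams",
    "KinaseTrajectory",
    "InterventionSchedule",
    "REGIMES",
    "signal_input",
    "simulate",
    "duration_metrics",
    "SimulationError",
]

REGIMES = ("full", "no_positive", "no_feedback")

# Tunable parameter names an intervention event may target.
_MUTABLE_PARAMS = ("k1", "k2", "k4", "k5", "km1", "km2")


class SimulationError(RuntimeError):
    """ODE integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last successful time: {last_time:g} min)")
        self.last_time = last_time


@dataclass(frozen=True)
class SignalParams:
    """Two-exponential upstream signal pulse A·(e^(−a t) − e^(−b t)), b > a."""

    amplitude: float = 1.0
    rise_rate: float = 0.1   # b, 1/min — fast exponential shaping the rise
    decay_rate: float = 0.02  # a, 1/min — slow exponential shaping the decay

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.rise_rate <= self.decay_rate:
            raise ValueError(
                f"rise_rate must exceed decay_rate for a pulse (got b={self.rise_rate}, a={self.decay_rate})"
            )

    @property
    def peak_time(self) -> float:
        """Closed-form argmax ln(b/a)/(b−a); +inf for a = 0 means no interior peak."""
        a, b = self.decay_rate, self.rise_rate
        if a == 0:
            return math.inf
        return math.log(b / a) / (b - a)


def signal_input(t, sp: SignalParams):
    """Upstream signalling activity at time(s) ``t`` (minutes)."""
    t = np.asarray(t, dtype=float)
    out = sp.amplitude * (np.exp(-sp.decay_rate * t) - np.exp(-sp.rise_rate * t))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModelAParams:
    """Rate and Michaelis constants for one (stimulus, kinase) pair.

    All rates are 1/min, Michaelis constants and ``total`` are in the relative
    activity units of the immunoblot quantification; ``total`` defaults to 1
    since the absolute scale is unidentifiable and absorbed into k1/k4.
    """

    k1: float   # signal-driven activation rate
    k2: float   # basal deactivation rate
    k4: float   # positive-feedback (IAP) activation rate
    k5: float   # negative-feedback deactivation rate
    km1: float  # Michaelis constant of the activation step
    km2: float  # Michaelis constant of the deactivation step
    total: float = 1.0
    signal_params: SignalParams = field(default_factory=SignalParams)

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k4", "k5", "km1", "km2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total <= 0:
            raise ValueError("total must be > 0")

    def for_regime(self, regime: str) -> "ModelAParams":
        if regime == "full":
            return self
        if regime == "no_positive":
            return replace(self, k4=0.0)
        if regime == "no_feedback":
            return replace(self, k4=0.0, k5=0.0)
        raise ValueError(f"unknown regime {regime!r}; valid regimes: {', '.join(REGIMES)}")


@dataclass(frozen=True)
class InterventionSchedule:
    """Parameter switches applied mid-simulation, e.g. ('k4' -> 0 at 10 min)."""

    events: tuple[tuple[float, str, float], ...] = ()

    def __post_init__(self) -> None:
        events = tuple((float(t), str(name), float(v)) for t, name, v in self.events)
        times = [e[0] for e in events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        for _, name, _ in events:
            if name not in _MUTABLE_PARAMS:
                raise ValueError(f"cannot schedule parameter {name!r}; allowed: {_MUTABLE_PARAMS}")
        object.__setattr__(self, "events", events)


@dataclass(frozen=True)
class KinaseTrajectory:
    """Simulated (time, active, inactive) trajectory of one kinase."""

    times: np.ndarray
    active: np.ndarray
    inactive: np.ndarray
    total: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "active", np.asarray(self.active, dtype=float))
        object.__setattr__(self, "inactive", np.asarray(self.inactive, dtype=float))

    def conservation_error(self) -> float:
        return float(np.max(np.abs(self.active + self.inactive - self.total)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_min": self.times, "active": self.active, "inactive": self.inactive})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _rhs(t, y, p: ModelAParams, pf: FeedbackInput | None, nf: FeedbackInput | None):
    """The model's right-hand side, isolated so the structural form lives in one place."""
    active, inactive = y
    pf_t = float(pf(t)) if (pf is not None and p.k4 != 0.0) else 0.0
    nf_t = float(nf(t)) if (nf is not None and p.k5 != 0.0) else 0.0
    v_act = (p.k1 * signal_input(t, p.signal_params) + p.k4 * pf_t) * inactive / (p.km1 + inactive)
    v_deact = (p.k2 + p.k5 * nf_t) * active / (p.km2 + active)
    flux = v_act - v_deact
    return (flux, -flux)


def simulate(
    params: ModelAParams,
    pf: FeedbackInput | None = None,
    nf: FeedbackInput | None = None,
    regime: str = "full",
    window: tuple[float, float] = (0.0, 120.0),
    schedule: InterventionSchedule | None = None,
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> KinaseTrajectory:
    """Integrate the kinase model over ``window`` with active(0) = 0.

    ``regime`` overrides the feedback parameters: ``no_positive`` forces
    k4 = 0, ``no_feedback`` forces k4 = k5 = 0 regardless of ``params``.
    ``schedule`` events stop and restart the integration with the named
    parameter updated.  Uses a stiff-capable implicit solver (LSODA).
    """
    p = params.for_regime(regime)
    if p.k4 > 0 and pf is None:
        raise ValueError("k4 > 0 requires a positive-feedback input pf")
    if p.k5 > 0 and nf is None:
        raise ValueError("k5 > 0 requires a negative-feedback input nf")
    t0, t_end = float(window[0]), float(window[1])
    if t_end <= t0:
        raise ValueError("window must satisfy T > t0")
    if t_eval is None:
        t_eval = np.linspace(t0, t_end, int(round((t_end - t0) * 2)) + 1)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.size and (t_eval[0] < t0 or t_eval[-1] > t_end):
        raise ValueError("t_eval must lie within the simulation window")

    events = list(schedule.events) if schedule is not None else []
    for t_ev, _, _ in events:
        if not (t0 <= t_ev <= t_end):
            raise ValueError(f"event time {t_ev} outside window {window}")
    breaks = [t0] + [e[0] for e in events if t0 < e[0] < t_end] + [t_end]
    # Events at exactly t0 just update parameters before integration starts.
    for t_ev, name, value in events:
        if t_ev == t0:
            p = replace(p, **{name: value})

    y = np.array([0.0, p.total])
    times_out: list[np.ndarray] = []
    y_out: list[np.ndarray] = []
    for seg_start, seg_end in zip(breaks[:-1], breaks[1:]):
        for t_ev, name, value in events:
            if t_ev == seg_start and t_ev != t0:
                p = replace(p, **{name: value})
        mask = (t_eval >= seg_start) & (t_eval <= seg_end)
        seg_eval = np.unique(np.concatenate([t_eval[mask], [seg_start, seg_end]]))
        sol = solve_ivp(
            _rhs,
            (seg_start, seg_end),
            y,
            method="LSODA",
            t_eval=seg_eval,
            args=(p, pf, nf),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            last = sol.t[-1] if sol.t.size else seg_start
            raise SimulationError(f"solver failed: {sol.message}", last_time=float(last))
        keep = np.isin(sol.t, t_eval[mask])
        times_out.append(sol.t[keep])
        y_out.append(sol.y[:, keep])
        y = sol.y[:, -1]

    times = np.concatenate(times_out)
    ys = np.concatenate(y_out, axis=1)
    # Segment boundaries shared by t_eval appear once per adjacent segment.
    times, idx = np.unique(times, return_index=True)
    active, inactive = ys[0, idx], ys[1, idx]
    if np.min(active) < -1e-6 * p.total or np.min(inactive) < -1e-6 * p.total:
        raise SimulationError("negative state beyond tolerance (model violation)", last_time=float(times[-1]))
    np.clip(active, 0.0, None, out=active)
    np.clip(inactive, 0.0, None, out=inactive)
    return KinaseTrajectory(times=times, active=active, inactive=inactive, total=p.total)


def duration_metrics(traj: KinaseTrajectory) -> dict[str, float]:
    """Peak, peak time, time-above-half-max and AUC of the active kinase.

    The duration metric is the total time the active fraction spends at or
    above half its peak, with linear interpolation at the threshold
    crossings; AUC is the trapezoid integral.  An all-zero trajectory gets
    peak = 0 and duration = 0 by convention.
    """
    t = traj.times
    x = traj.active
    if t.size == 0:
        raise ValueError("empty trajectory")
    peak = float(np.max(x))
    auc = float(np.trapezoid(x, t))
    if peak <= 0:
        return {"peak": 0.0, "peak_time": 0.0, "t_half_duration": 0.0, "auc": auc}
    peak_time = float(t[int(np.argmax(x))])
    half = peak / 2.0
    duration = 0.0
    for i in range(t.size - 1):
        x0, x1 = x[i], x[i + 1]
        dt = t[i + 1] - t[i]
        if x0 >= half and x1 >= half:
            duration += dt
        elif x0 < half and x1 < half:
            continue
        else:
            # one crossing inside the segment (linear interpolation)
            frac = (half - x0) / (x1 - x0)
            duration += dt * (1.0 - frac) if x1 >= half else dt * frac
    return {"peak": peak, "peak_time": peak_time, "t_half_duration": float(duration), "auc": auc}
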