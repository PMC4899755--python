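"""Staged estimation of the kinase-model parameters from perturbation regimes.

The three experimental regimes dissect the model: cycloheximide (CHX) blocks
all protein synthesis and hence all transcriptional feedback, so CHX data pin
the feedback-free core (k1, k2, km1, km2 and the signal pulse); the IAP
inhibitor removes only the positive feedback, so inhibitor data add k5; wild
type data then add k4.  Fitting proceeds in those three stages, each a
bounded nonlinear least-squares in log10 parameter space with multi-start
initialization (ODE objectives are multimodal), earlier stages frozen.

The objective weights residuals by the measurement s.d. with a floor of
5% of the curve maximum — duplicate-based sample s.d. is an unstable weight
and occasionally (or, for noiseless synthetic data, always) zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from ._fastsim import DriveCache, active_on_grid
from .feedback_inputs import FeedbackInput
from .model_a_kinase import ModelAParams, SignalParams, SimulationError
from .timecourse import TimeCourse

__all__ = ["FitProblem", "FitResult", "loss", "fit_staged", "profile_parameter", "DEFAULT_BOUNDS"]

# Regime name -> dataset key, in stage order.
_STAGES = (
    ("no_feedback", ("k1", "k2", "km1", "km2", "sig_decay", "sig_gap")),
    ("no_positive", ("k5",)),
    ("full", ("k4",)),
)

# Box bounds (natural scale); optimization runs in log10 space, multi-start
# draws log-uniform. The signal pulse rate b is parametrized as a + gap to
# keep b > a inside the box.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k1": (1e-3, 10.0),
    "k2": (1e-3, 2.0),
    "k4": (1e-3, 10.0),
    "k5": (1e-3, 10.0),
    "km1": (1e-2, 10.0),
    "km2": (1e-2, 10.0),
    "sig_decay": (1e-4, 0.5),
    "sig_gap": (1e-3, 2.0),
}

_PARAM_NAMES = tuple(DEFAULT_BOUNDS)


def _params_from_dict(values: dict[str, float], total: float = 1.0) -> ModelAParams:
    sp = SignalParams(
        amplitude=1.0,  # absorbed into k1; not a free parameter
        decay_rate=values["sig_decay"],
        rise_rate=values["sig_decay"] + values["sig_gap"],
    )
    return ModelAParams(
        k1=values["k1"], k2=values["k2"], k4=values.get("k4", 0.0), k5=values.get("k5", 0.0),
        km1=values["km1"], km2=values["km2"], total=total, signal_params=sp,
    )


def params_to_dict(p: ModelAParams) -> dict[str, float]:
    """Flatten ModelAParams into the fitting parameter vocabulary."""
    return {
        "k1": p.k1, "k2": p.k2, "k4": p.k4, "k5": p.k5, "km1": p.km1, "km2": p.km2,
        "sig_decay": p.signal_params.decay_rate,
        "sig_gap": p.signal_params.rise_rate - p.signal_params.decay_rate,
    }


@dataclass(frozen=True)
class FitProblem:
    """Datasets, feedback inputs and search settings for a staged fit.

    ``datasets`` maps regime names (subset of no_feedback / no_positive /
    full) to measured kinase time courses.  The CHX (no_feedback) regime is
    mandatory: stage 1 cannot be skipped.
    """

    datasets: dict[str, TimeCourse]
    pf: FeedbackInput | None = None
    nf: FeedbackInput | None = None
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    fixed: dict[str, float] = field(default_factory=dict)
    n_starts: int = 20
    seed: int = 0
    sd_floor_frac: float = 0.05
    total: float = 1.0

    def __post_init__(self) -> None:
        bad = set(self.datasets) - {"no_feedback", "no_positive", "full"}
        if bad:
            raise ValueError(f"unknown regimes {sorted(bad)}")
        if not self.datasets:
            raise ValueError("no datasets")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi < np.inf):
                raise ValueError(f"bounds for {name} must be finite with 0 < lo < hi")

    def weights(self, regime: str) -> np.ndarray:
        tc = self.datasets[regime]
        floor = self.sd_floor_frac * float(np.max(tc.value))
        return np.maximum(tc.sd, floor)


@dataclass(frozen=True)
class FitResult:
    """Point estimates plus diagnostics of a (staged) fit."""

    estimates: dict[str, float]
    loss: float
    per_regime_loss: dict[str, float]
    converged: bool
    start_index: int
    stage_results: tuple = ()

    def to_params(self, total: float = 1.0) -> ModelAParams:
        return _params_from_dict(self.estimates, total=total)

    def to_json(self, path) -> None:
        payload = {
            "estimates": self.estimates,
            "loss": self.loss,
            "per_regime_loss": self.per_regime_loss,
            "converged": self.converged,
            "start_index": self.start_index,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# which feedback drives each regime actually uses
_REGIME_DRIVES = {"no_feedback": (False, False), "no_positive": (False, True), "full": (True, True)}


def _make_caches(problem: FitProblem) -> dict[str, DriveCache]:
    caches = {}
    for regime, tc in problem.datasets.items():
        use_pf, use_nf = _REGIME_DRIVES[regime]
        caches[regime] = DriveCache(tc.time, problem.pf, problem.nf, use_pf, use_nf)
    return caches


def _regime_values(values: dict[str, float], regime: str) -> dict[str, float]:
    v = dict(values)
    if regime == "no_feedback":
        v["k4"] = v["k5"] = 0.0
    elif regime == "no_positive":
        v["k4"] = 0.0
    return v


def _residuals_regime(
    values: dict[str, float], problem: FitProblem, regime: str, caches: dict[str, DriveCache] | None = None
) -> np.ndarray:
    tc = problem.datasets[regime]
    cache = (caches or _make_caches(problem))[regime]
    try:
        pred = active_on_grid(_regime_values(values, regime), cache, total=problem.total)
    except (SimulationError, ValueError, FloatingPointError):
        return np.full(len(tc), 1e6)  # rejected point
    if not np.all(np.isfinite(pred)):
        return np.full(len(tc), 1e6)
    return (pred - tc.value) / problem.weights(regime)


def loss(params: ModelAParams, problem: FitProblem) -> float:
    """Weighted sum of squared residuals over every regime in the problem."""
    values = params_to_dict(params)
    caches = _make_caches(problem)
    return float(sum(np.sum(_residuals_regime(values, problem, r, caches) ** 2) for r in problem.datasets))


def per_regime_loss(params: ModelAParams, problem: FitProblem) -> dict[str, float]:
    values = params_to_dict(params)
    caches = _make_caches(problem)
    return {r: float(np.sum(_residuals_regime(values, problem, r, caches) ** 2)) for r in problem.datasets}


def _minimize_stage(
    problem: FitProblem,
    regime: str,
    free: tuple[str, ...],
    fixed_values: dict[str, float],
    rng: np.random.Generator,
    caches: dict[str, DriveCache] | None = None,
    x0_extra: list[np.ndarray] | None = None,
) -> tuple[dict[str, float], float, bool, int]:
    lo = np.log10([problem.bounds[n][0] for n in free])
    hi = np.log10([problem.bounds[n][1] for n in free])
    caches = caches or _make_caches(problem)

    def resid(logx):
        values = dict(fixed_values)
        values.update({n: 10.0**v for n, v in zip(free, logx)})
        return _residuals_regime(values, problem, regime, caches)

    starts = list(x0_extra or [])
    starts += [lo + rng.random(len(free)) * (hi - lo) for _ in range(problem.n_starts)]
    best = None
    for idx, x0 in enumerate(starts):
        try:
            sol = least_squares(
                resid, np.clip(x0, lo, hi), bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best[0].cost:
            best = (sol, idx)
    if best is None:
        raise RuntimeError(f"every start failed to converge in the {regime} stage")
    sol, idx = best
    est = dict(fixed_values)
    est.update({n: float(10.0**v) for n, v in zip(free, sol.x)})
    return est, float(2 * sol.cost), bool(sol.success), idx


def fit_staged(
    problem: FitProblem,
    joint_refine: bool = False,
    warm_start: dict[str, float] | None = None,
) -> FitResult:
    """Three-stage fit: CHX core, then k5 on inhibitor data, then k4 on WT.

    Stage 1 fits the feedback-free core (k1, k2, km1, km2 and the signal
    pulse) to the CHX regime with k4 = k5 = 0; stage 2 freezes those and fits
    k5 to the inhibitor regime; stage 3 fits k4 to wild type.  Stages whose
    regime is absent from the problem are skipped (their parameters stay 0
    unless fixed).  ``joint_refine`` re-optimizes all free parameters from
    the staged solution against all regimes at the end.

    Each stage is deterministic given the problem seed; ties between starts
    are broken by the lowest start index.
    """
    if "no_feedback" not in problem.datasets:
        raise ValueError("the CHX (no_feedback) regime is mandatory: stage 1 pins the core parameters")
    values: dict[str, float] = {n: 0.0 for n in ("k4", "k5")}
    values.update(problem.fixed)
    caches = _make_caches(problem)
    stage_records = []
    start_index = -1
    converged = True
    for stage_idx, (regime, free_all) in enumerate(_STAGES):
        if regime not in problem.datasets:
            continue
        free = tuple(n for n in free_all if n not in problem.fixed)
        rng = np.random.default_rng(np.random.SeedSequence([int(problem.seed), stage_idx]))
        if not free:
            continue
        fixed_values = {n: v for n, v in values.items() if n not in free}
        x0_extra = None
        if warm_start is not None and all(n in warm_start and warm_start[n] > 0 for n in free):
            lo = np.log10([problem.bounds[n][0] for n in free])
            hi = np.log10([problem.bounds[n][1] for n in free])
            x0_extra = [np.clip(np.log10([warm_start[n] for n in free]), lo, hi)]
        est, stage_loss, ok, idx = _minimize_stage(problem, regime, free, fixed_values, rng, caches, x0_extra)
        values = est
        stage_records.append({"regime": regime, "free": free, "loss": stage_loss, "start_index": idx, "converged": ok})
        converged = converged and ok
        start_index = idx

    if joint_refine:
        free = tuple(n for rec in stage_records for n in rec["free"])
        rng = np.random.default_rng(np.random.SeedSequence([int(problem.seed), 99]))
        lo = np.log10([problem.bounds[n][0] for n in free])
        hi = np.log10([problem.bounds[n][1] for n in free])

        def resid_all(logx):
            v = dict(values)
            v.update({n: 10.0**x for n, x in zip(free, logx)})
            return np.concatenate([_residuals_regime(v, problem, r, caches) for r in problem.datasets])

        x0 = np.clip(np.log10([values[n] for n in free]), lo, hi)
        sol = least_squares(resid_all, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        values.update({n: float(10.0**x) for n, x in zip(free, sol.x)})
        converged = converged and bool(sol.success)

    params = _params_from_dict(values, total=problem.total)
    prl = per_regime_loss(params, problem)
    return FitResult(
        estimates={n: float(values.get(n, 0.0)) for n in _PARAM_NAMES},
        loss=float(sum(prl.values())),
        per_regime_loss=prl,
        converged=converged,
        start_index=start_index,
        stage_results=tuple(stage_records),
    )


def profile_parameter(problem: FitProblem, result: FitResult, name: str, grid) -> np.ndarray:
    """1-D profile likelihood: re-minimize the other free parameters per grid value.

    The profiled parameter is fixed at each grid value and the full staged
    fit re-run (warm-started from the fit's estimates); the returned array
    holds the total loss at each grid point.  A profile flat over a wide
    range flags a non-identifiable parameter.
    """
    if name not in DEFAULT_BOUNDS:
        raise ValueError(f"unknown parameter {name!r}")
    if name in problem.fixed:
        raise ValueError(f"{name} was fixed, not fitted")
    grid = np.asarray(grid, dtype=float)
    losses = np.empty(grid.shape)
    for i, v in enumerate(grid):
        sub = replace(problem, fixed={**problem.fixed, name: float(v)}, n_starts=max(2, problem.n_starts // 4))
        res = fit_staged(sub, warm_start=result.estimates)
        losses[i] = res.loss
    return losses
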