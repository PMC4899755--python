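"""Synthetic inputs with the statistical structure the analysis assumes.

Everything the pipeline consumes can be generated here: noiseless model-A
kinase trajectories, duplicate immunoblot-style measurements with
multiplicative lognormal noise, early-peaking regulator expression kinetics
normalized to per-gene maxima, cumulative IAP synthesis under protein-synthesis
block (cycloheximide) versus untreated, and a gene x (condition, time)
expression matrix with planted temporal cluster structure plus null genes.

All generators are pure functions of their arguments including the seed:
identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .feedback_inputs import FeedbackInput
from .model_a_kinase import ModelAParams, REGIMES, simulate
from .timecourse import TimeCourse

__all__ = [
    "NoiseSpec",
    "PlantedClusterSpec",
    "DEFAULT_KINASE_GRID",
    "DEFAULT_EXPRESSION_TIMEPOINTS",
    "generate_true_kinase_timecourse",
    "add_measurement_noise",
    "generate_regulator_kinetics",
    "generate_iap_synthesis",
    "generate_expression_matrix",
    "cluster_templates",
]

# Kinase observables are read every 10 min over the 0-120 min stimulation
# window; expression is read at the microarray design timepoints.
DEFAULT_KINASE_GRID = tuple(range(0, 121, 10))
DEFAULT_EXPRESSION_TIMEPOINTS = (0, 15, 30, 45, 60, 90)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: multiplicative lognormal, duplicate replicates.

    ``cv`` is the coefficient of variation of a single measurement;
    immunoblot quantification is ratio-scale, hence multiplicative noise.
    """

    cv: float = 0.1
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def log_sd(self) -> float:
        """Standard deviation of log-measurements implied by the cv."""
        return float(np.sqrt(np.log1p(self.cv**2)))


@dataclass(frozen=True)
class PlantedClusterSpec:
    """Design of a synthetic expression matrix with known cluster structure."""

    n_clusters: int = 8
    genes_per_cluster: int = 50
    n_null_genes: int = 500
    timepoints: tuple = DEFAULT_EXPRESSION_TIMEPOINTS
    effect_size: float = 2.0  # peak log2 induction of responsive genes (~4-fold)
    baseline: float = 7.0     # log2 baseline expression
    conditions: tuple = ("WT-BCR",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.genes_per_cluster < 1 or self.n_null_genes < 0:
            raise ValueError("invalid gene counts")
        tp = tuple(float(t) for t in self.timepoints)
        if tp[0] != 0 or any(t2 <= t1 for t1, t2 in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        object.__setattr__(self, "timepoints", tp)


def generate_true_kinase_timecourse(
    params: ModelAParams,
    pf: FeedbackInput | None,
    nf: FeedbackInput | None,
    regime: str = "full",
    grid=DEFAULT_KINASE_GRID,
) -> TimeCourse:
    """Noiseless active-kinase trajectory on ``grid`` (delegates to model A)."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; valid regimes: {', '.join(REGIMES)}")
    grid = np.asarray(grid, dtype=float)
    if grid[0] < 0 or grid[-1] > 120:
        raise ValueError("grid must lie within [0, 120] min")
    # tighter-than-default tolerances: ground truth should be exact to ~1e-9
    traj = simulate(
        params, pf=pf, nf=nf, regime=regime, window=(grid[0], grid[-1]), t_eval=grid, rtol=1e-9, atol=1e-12
    )
    return TimeCourse(time=grid, value=traj.active, condition=regime)


def add_measurement_noise(tc: TimeCourse, noise: NoiseSpec) -> TimeCourse:
    """Replicate mean +/- sample s.d. after multiplicative lognormal noise.

    Each timepoint gets ``n_replicates`` independent draws value * L where L
    is lognormal with mean 1 and the specified cv; the returned series holds
    the replicate mean and the sample standard deviation (0 if a single
    replicate or cv = 0).
    """
    if not tc.is_noiseless:
        raise ValueError("input time course must be noiseless (sd = 0)")
    rng = np.random.default_rng(noise.seed)
    m = len(tc)
    if noise.cv == 0:
        mean, sd = tc.value.copy(), np.zeros(m)
    else:
        sigma = noise.log_sd
        draws = tc.value[:, None] * rng.lognormal(-0.5 * sigma**2, sigma, size=(m, noise.n_replicates))
        mean = draws.mean(axis=1)
        sd = draws.std(axis=1, ddof=1) if noise.n_replicates > 1 else np.zeros(m)
    return TimeCourse(
        time=tc.time,
        value=mean,
        sd=sd,
        n=np.full(m, noise.n_replicates),
        condition=tc.condition,
        stimulus=tc.stimulus,
        observable=tc.observable,
    )


def _rate_pair_for_peak(peak_time: float, decay_rate: float) -> tuple[float, float]:
    """Find b > a so that A(e^(-a t) - e^(-b t)) peaks at ``peak_time``."""
    a = decay_rate
    peak = float(peak_time)

    def f(b):
        return np.log(b / a) / (b - a) - peak

    # peak time decreases from 1/a (as b -> a) to 0 (as b -> inf)
    if peak >= 1.0 / a:
        raise ValueError(
            f"peak_time must be < 1/decay_rate = {1.0 / a:g} min for a difference-of-exponentials pulse"
        )
    lo, hi = a * (1 + 1e-6), a * 1e6
    return a, float(brentq(f, lo, hi))


def generate_regulator_kinetics(peak_time: float, decay_rate: float, grid) -> TimeCourse:
    """Early-peaking regulator expression, normalized to its grid maximum.

    A difference-of-exponentials pulse — the simplest unimodal early-response
    shape — with the continuous-time peak placed at ``peak_time``, evaluated
    on ``grid`` and rescaled so the maximum over the grid is exactly 1.
    Expression is 0 at t = 0 (no transcript before stimulation).
    """
    if peak_time <= 0:
        raise ValueError("peak_time must be > 0")
    if decay_rate <= 0:
        raise ValueError("decay_rate must be > 0")
    grid = np.asarray(grid, dtype=float)
    a, b = _rate_pair_for_peak(peak_time, decay_rate)
    values = np.exp(-a * grid) - np.exp(-b * grid)
    vmax = values.max()
    if vmax <= 0:
        raise ValueError("grid does not sample the expression pulse")
    return TimeCourse(time=grid, value=values / vmax)


def generate_iap_synthesis(
    rate_curve: TimeCourse,
    degradation: float,
    grid,
    initial_level: float = 1.0,
) -> tuple[TimeCourse, TimeCourse, TimeCourse]:
    """Cumulative IAP protein under untreated vs protein-synthesis-blocked cells.

    Untreated cells integrate dP/dt = r(t) - delta*P from the initial level;
    cycloheximide-treated cells only decay (synthesis blocked).  Newly
    synthesized IAP is their difference, clipped at 0 — the same subtraction
    applied to the immunoblot quantifications.  Both branches are solved with
    the exact integrating factor e^(delta*t) and trapezoid quadrature of the
    synthesis rate, so degradation = 0 with constant rate r gives exactly
    r*t on the grid.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.shape != rate_curve.time.shape or np.any(grid != rate_curve.time):
        raise ValueError("rate_curve grid must match the requested grid")
    if degradation < 0:
        raise ValueError("degradation must be >= 0")
    r = rate_curve.value
    if np.any(r < 0):
        raise ValueError("synthesis rate must be >= 0")
    delta = float(degradation)
    decay = np.exp(-delta * grid)
    synth = cumulative_trapezoid(r * np.exp(delta * grid), grid, initial=0.0) * decay
    untreated = initial_level * decay + synth
    chx = initial_level * decay
    newly = np.clip(untreated - chx, 0.0, None)
    mk = lambda v, cond: TimeCourse(time=grid, value=v, condition=cond, observable="IAP")
    return mk(untreated, "untreated"), mk(chx, "CHX"), mk(newly, "newly_synthesized")


def _pulse(tp: np.ndarray, peak: float) -> np.ndarray:
    a = np.log(4.0) / (3.0 * peak)  # with b = 4a the pulse peaks at ln4/(3a) = peak
    s = np.exp(-a * tp) - np.exp(-4.0 * a * tp)
    return s / s.max()


def cluster_templates(n_clusters: int, timepoints) -> np.ndarray:
    """Temporal response templates, one per planted cluster.

    Four canonical early-response shapes — immediate transient pulse,
    sustained saturating rise, mid-course pulse, late ramp — each in an up-
    and a down-regulated version, chosen to stay mutually distinguishable
    after per-gene standardization on a sparse time grid.  Templates beyond
    eight reuse pulses at intermediate peak times.  Every template is 0 at
    t = 0 and scaled to unit maximum absolute response.
    """
    tp = np.asarray(timepoints, dtype=float)
    tmax = tp[-1]
    shapes = [
        _pulse(tp, 0.15 * tmax),               # immediate-early transient (A20-like)
        1.0 - np.exp(-4.0 * tp / tmax),        # sustained saturating rise
        _pulse(tp, 0.5 * tmax),                # mid-course pulse
        tp / tmax,                             # late ramp
    ]
    extra_peak = 0.3
    while len(shapes) < (n_clusters + 1) // 2:
        shapes.append(_pulse(tp, extra_peak * tmax))
        extra_peak += 0.15
    templates = np.empty((n_clusters, tp.size))
    for j in range(n_clusters):
        shape = shapes[j // 2] / np.abs(shapes[j // 2]).max()
        templates[j] = shape if j % 2 == 0 else -shape
    return templates


def generate_expression_matrix(spec: PlantedClusterSpec, noise: NoiseSpec):
    """Log-scale expression matrix with planted clusters plus null genes.

    Responsive genes follow one of ``n_clusters`` templates scaled by
    ``effect_size`` on top of a flat baseline; null genes are baseline plus
    noise at every timepoint.  Noise is additive Gaussian on the log scale
    with the log-sd implied by the NoiseSpec cv (the same lognormal
    measurement model as the protein assays).  Returns the matrix (from
    :mod:`bsignal.transcriptome_screen`) and the true labels: cluster ids
    1..n_clusters for planted genes, 0 for nulls.
    """
    from .transcriptome_screen import ExpressionMatrix

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(noise.seed)]))
    tp = np.asarray(spec.timepoints, dtype=float)
    templates = cluster_templates(spec.n_clusters, tp)
    n_resp = spec.n_clusters * spec.genes_per_cluster
    n_genes = n_resp + spec.n_null_genes

    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    labels = np.concatenate(
        [np.repeat(np.arange(1, spec.n_clusters + 1), spec.genes_per_cluster), np.zeros(spec.n_null_genes, int)]
    )

    true_profiles = np.full((n_genes, tp.size), spec.baseline)
    for g in range(n_resp):
        true_profiles[g] += spec.effect_size * templates[labels[g] - 1]

    sigma = noise.log_sd
    cols, data = [], []
    for cond in spec.conditions:
        for t in tp:
            for rep in range(1, noise.n_replicates + 1):
                cols.append((cond, float(t), rep))
        block = np.repeat(true_profiles, noise.n_replicates, axis=1)
        data.append(block + rng.normal(0.0, sigma, size=block.shape))
    values = np.concatenate(data, axis=1)
    columns = pd.MultiIndex.from_tuples(cols, names=["condition", "time_min", "replicate"])
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=columns)
    return ExpressionMatrix(df), pd.Series(labels, index=gene_ids, name="true_cluster")
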