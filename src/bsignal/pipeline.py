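"""End-to-end pipeline: synth -> feedback -> fit -> simulate -> model_b -> screen.

Ties the stages into the full analysis story: generate (or load) the
measurement tables, build the feedback drives PF(t)/NF(t), fit the kinase
model across the three perturbation regimes, run the in-silico feedback
knockouts and the mid-course inhibitor intervention, push the kinase
trajectories through the transcriptional readout, and run the transcriptome
screen.  A run is reproducible from its config plus seed alone: every stage's
randomness derives from the single top-level seed via a per-stage counter,
and a manifest records inputs, seeds, checksums and wall time.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fitting, model_b_expression, synthetic_data, transcriptome_screen
from .feedback_inputs import build_negative_feedback, build_positive_feedback, FeedbackInput
from .fitting import FitProblem, fit_staged
from .model_a_kinase import InterventionSchedule, ModelAParams, SignalParams, duration_metrics, simulate
from .presets import demo_kinase_params, demo_model_b_params
from .synthetic_data import (
    DEFAULT_KINASE_GRID,
    NoiseSpec,
    PlantedClusterSpec,
    add_measurement_noise,
    generate_expression_matrix,
    generate_iap_synthesis,
    generate_regulator_kinetics,
    generate_true_kinase_timecourse,
)
from .timecourse import TimeCourse, read_timecourses, write_timecourses

STAGES = ("synth", "feedback", "fit", "simulate", "model_b", "screen")

__all__ = ["PipelineConfig", "run_pipeline", "validate_timecourse_file", "TimeCourseValidationError", "STAGES"]


@dataclass
class PipelineConfig:
    """Serializable run configuration; config + seed fully determine a run."""

    outdir: str = "bsignal_run"
    seed: int = 0
    stages: tuple = STAGES
    kinase_params: dict = field(default_factory=dict)   # overrides on the demo P0 set
    model_b_params: dict = field(default_factory=dict)
    noise: dict = field(default_factory=lambda: {"cv": 0.1, "n_replicates": 2})
    screen: dict = field(default_factory=dict)          # PlantedClusterSpec overrides + fdr/k
    fit: dict = field(default_factory=lambda: {"n_starts": 20})
    grid: tuple = DEFAULT_KINASE_GRID

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
        self.stages = tuple(s for s in STAGES if s in self.stages)  # dependency order

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "outdir": self.outdir,
            "seed": self.seed,
            "stages": list(self.stages),
            "kinase_params": dict(self.kinase_params),
            "model_b_params": dict(self.model_b_params),
            "noise": dict(self.noise),
            "screen": dict(self.screen),
            "fit": dict(self.fit),
            "grid": list(self.grid),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        # single top-level seed fanned out by stage counter, for auditability
        return int(np.random.SeedSequence([int(self.seed), STAGES.index(stage)]).generate_state(1)[0] % (2**31))


class TimeCourseValidationError(ValueError):
    """Schema violation in a time-course file, with line-numbered diagnostics."""

    def __init__(self, path, diagnostics: list[str]):
        self.diagnostics = list(diagnostics)
        super().__init__(f"{path}: " + "; ".join(self.diagnostics))


def validate_timecourse_file(path: str | Path) -> TimeCourse:
    """Load a tidy time-course TSV, or raise precise diagnostics.

    Checks the column schema, strictly increasing unique times, non-negative
    sd and replicate counts; diagnostics name the offending line of the file
    (header = line 1).  Nothing is returned on failure — no partial loads.
    """
    df = pd.read_csv(path, sep="\t")
    diagnostics = []
    missing = [c for c in ("time_min", "value", "sd", "n") if c not in df.columns]
    if missing:
        raise TimeCourseValidationError(path, [f"line 1: missing required columns {missing}"])
    seen: dict[float, int] = {}
    prev_t = -np.inf
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        t = row["time_min"]
        if t in seen:
            diagnostics.append(f"line {line}: duplicated timepoint {t:g} (first at line {seen[t]})")
        else:
            seen[t] = line
        if t < prev_t:
            diagnostics.append(f"line {line}: column 'time_min' not increasing ({t:g} after {prev_t:g})")
        prev_t = max(prev_t, t)
        if row["sd"] < 0:
            diagnostics.append(f"line {line}: column 'sd' is negative ({row['sd']:g})")
        if row["n"] < 1:
            diagnostics.append(f"line {line}: column 'n' must be >= 1 ({row['n']:g})")
    if diagnostics:
        raise TimeCourseValidationError(path, diagnostics)
    if "condition" not in df.columns:
        df = df.assign(condition="", stimulus="", kinase_or_gene="")
    return TimeCourse.from_frame(df)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_params(overrides: dict) -> ModelAParams:
    base = fitting.params_to_dict(demo_kinase_params())
    base.update(overrides or {})
    sig = SignalParams(amplitude=1.0, decay_rate=base["sig_decay"], rise_rate=base["sig_decay"] + base["sig_gap"])
    return ModelAParams(
        k1=base["k1"], k2=base["k2"], k4=base["k4"], k5=base["k5"],
        km1=base["km1"], km2=base["km2"], total=1.0, signal_params=sig,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run manifest.

    Each stage writes its outputs under ``outdir`` and later stages read
    them back from disk, so a stage run without its upstream outputs fails
    with an error naming the missing stage.  Identical configs produce
    byte-identical stage outputs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    manifest: dict = {"stages": {}, "seed": config.seed, "config": str(out / "config.yaml")}
    config.to_yaml(out / "config.yaml")

    grid = np.asarray(config.grid, dtype=float)
    true_params = _build_params(config.kinase_params)

    def require(stage: str, path: Path) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"missing upstream output {path.name!r}: run the {stage!r} stage first"
            )
        return path

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in sorted(files)},
            "seed": config.stage_seed(stage),
        }

    if "synth" in config.stages:
        seed = config.stage_seed("synth")
        noise = NoiseSpec(cv=config.noise.get("cv", 0.1), n_replicates=config.noise.get("n_replicates", 2), seed=seed)
        regulator = generate_regulator_kinetics(30.0, 0.02, grid).with_labels(
            condition="WT", stimulus="BCR", observable="A20"
        )
        rate = generate_regulator_kinetics(30.0, 0.02, grid)
        untreated, chx, newly = generate_iap_synthesis(rate, degradation=0.01, grid=grid)
        courses = [regulator, untreated.with_labels(stimulus="BCR"), chx.with_labels(stimulus="BCR"),
                   newly.with_labels(stimulus="BCR")]
        for i, regime in enumerate(("no_feedback", "no_positive", "full")):
            pf_tmp = build_positive_feedback(newly)
            nf_tmp = build_negative_feedback([regulator])
            clean = generate_true_kinase_timecourse(true_params, pf_tmp, nf_tmp, regime=regime, grid=grid)
            noisy = add_measurement_noise(
                clean, NoiseSpec(noise.cv, noise.n_replicates, seed + 1 + i)
            ).with_labels(condition=regime, stimulus="BCR", observable="IKK")
            courses.append(noisy)
        write_timecourses(courses, out / "measurements.tsv")
        record("synth", [out / "measurements.tsv"])

    if "feedback" in config.stages:
        path = require("synth", out / "measurements.tsv")
        courses = {(tc.condition, tc.observable): tc for tc in read_timecourses(path)}
        newly = courses[("newly_synthesized", "IAP")]
        regulator = courses[("WT", "A20")]
        pf = build_positive_feedback(newly)
        nf = build_negative_feedback([regulator])
        pf.to_tsv(out / "pf_knots.tsv")
        nf.to_tsv(out / "nf_knots.tsv")
        record("feedback", [out / "pf_knots.tsv", out / "nf_knots.tsv"])

    if "fit" in config.stages:
        path = require("synth", out / "measurements.tsv")
        pf = FeedbackInput.from_tsv(require("feedback", out / "pf_knots.tsv"))
        nf = FeedbackInput.from_tsv(require("feedback", out / "nf_knots.tsv"))
        courses = {(tc.condition, tc.observable): tc for tc in read_timecourses(path)}
        datasets = {r: courses[(r, "IKK")] for r in ("no_feedback", "no_positive", "full")}
        problem = FitProblem(
            datasets=datasets, pf=pf, nf=nf,
            n_starts=config.fit.get("n_starts", 20), seed=config.stage_seed("fit"),
        )
        result = fit_staged(problem, joint_refine=config.fit.get("joint_refine", True))
        result.to_json(out / "fit_result.json")
        overlay = []
        for regime, tc in datasets.items():
            traj = simulate(result.to_params(), pf=pf, nf=nf, regime=regime,
                            window=(tc.time[0], tc.time[-1]), t_eval=tc.time)
            overlay.append(pd.DataFrame({"regime": regime, "time_min": tc.time,
                                         "measured": tc.value, "fitted": traj.active}))
        pd.concat(overlay, ignore_index=True).to_csv(out / "fit_overlay.tsv", sep="\t", index=False)
        record("fit", [out / "fit_result.json", out / "fit_overlay.tsv"])

    if "simulate" in config.stages:
        pf = FeedbackInput.from_tsv(require("feedback", out / "pf_knots.tsv"))
        nf = FeedbackInput.from_tsv(require("feedback", out / "nf_knots.tsv"))
        fit_path = out / "fit_result.json"
        if fit_path.exists():
            with open(fit_path) as fh:
                est = json.load(fh)["estimates"]
            params = _build_params(est)
        else:
            params = true_params
        rows, metrics = [], {}
        for regime in ("full", "no_positive", "no_feedback"):
            traj = simulate(params, pf=pf, nf=nf, regime=regime, window=(grid[0], grid[-1]))
            rows.append(traj.to_frame().assign(scenario=regime))
            metrics[regime] = duration_metrics(traj)
        sched = InterventionSchedule(events=((10.0, "k4", 0.0),))
        traj = simulate(params, pf=pf, nf=nf, regime="full", window=(grid[0], grid[-1]), schedule=sched)
        rows.append(traj.to_frame().assign(scenario="inhibitor_at_10min"))
        metrics["inhibitor_at_10min"] = duration_metrics(traj)
        pd.concat(rows, ignore_index=True).to_csv(out / "simulations.tsv", sep="\t", index=False)
        with open(out / "duration_metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
        record("simulate", [out / "simulations.tsv", out / "duration_metrics.json"])

    if "model_b" in config.stages:
        pf = FeedbackInput.from_tsv(require("feedback", out / "pf_knots.tsv"))
        nf = FeedbackInput.from_tsv(require("feedback", out / "nf_knots.tsv"))
        pb_kwargs = {"k_syn": 0.05, "k_deg": 0.02, "k_half": 0.3, "n": 2.0}
        pb_kwargs.update(config.model_b_params)
        report = model_b_expression.compare_feedback_outputs(
            true_params, model_b_expression.ModelBParams(**pb_kwargs), pf, nf,
            window=(grid[0], grid[-1]),
        )
        rows = []
        summary = {}
        for regime, entry in report["regimes"].items():
            rows.append(entry["gene"].to_frame().assign(regime=regime))
            summary[regime] = {
                "late_mean_expression": entry["late_mean_expression"],
                **{f"kinase_{k}": v for k, v in entry["kinase_metrics"].items()},
                **{f"expression_{k}": v for k, v in entry["expression_metrics"].items()},
            }
        summary["dominance_ok"] = report["dominance_ok"]
        pd.concat(rows, ignore_index=True).to_csv(out / "gene_expression.tsv", sep="\t", index=False)
        with open(out / "model_b_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        record("model_b", [out / "gene_expression.tsv", out / "model_b_summary.json"])

    if "screen" in config.stages:
        seed = config.stage_seed("screen")
        spec_kwargs = {k: v for k, v in config.screen.items() if k not in ("fdr", "k", "cv", "n_replicates")}
        spec = PlantedClusterSpec(seed=seed, **spec_kwargs)
        noise = NoiseSpec(cv=config.screen.get("cv", 0.15),
                          n_replicates=config.screen.get("n_replicates", 2), seed=seed)
        matrix, labels = generate_expression_matrix(spec, noise)
        matrix.to_tsv(out / "expression_matrix.tsv")
        labels.to_csv(out / "true_labels.tsv", sep="\t")
        cond = matrix.conditions[0]
        fdr = config.screen.get("fdr", 0.05)
        selected, qvals = transcriptome_screen.select_responsive(matrix, cond, fdr=fdr)
        qvals.to_csv(out / "q_values.tsv", sep="\t")
        k = config.screen.get("k", 8)
        result = transcriptome_screen.cluster_profiles(matrix, selected, condition=cond, k=k, seed=seed)
        result.labels.to_csv(out / "cluster_labels.tsv", sep="\t")
        result.centroids.to_csv(out / "cluster_centroids.tsv", sep="\t")
        triage = transcriptome_screen.triage_candidates(result)
        (out / "triage_candidates.txt").write_text("\n".join(triage) + "\n")
        record("screen", [out / p for p in (
            "expression_matrix.tsv", "true_labels.tsv", "q_values.tsv",
            "cluster_labels.tsv", "cluster_centroids.tsv", "triage_candidates.txt")])

    manifest["wall_time_s"] = round(time.time() - t_start, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
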